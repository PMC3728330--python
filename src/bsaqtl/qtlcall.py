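"""QTL interval calling from a thresholded G' track.

A QTL's *full interval* is a maximal run of consecutive SNPs with G' at or
above the significance threshold (runs separated by small gaps are merged);
runs that are too short or too SNP-poor are reported separately as minor
peaks rather than QTLs.  The *most probable interval* operationalises the
visual "head above the shoulder" of a peak: the contiguous region around the
summit where G' >= threshold + head_fraction * (summit - threshold).  The
trait-increasing allele's source parent is read off the sign of the NAFD
profile at the summit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nafd import nafd_at

DEFAULT_MERGE_GAP = 500_000
DEFAULT_MIN_SPAN = 500_000
DEFAULT_MIN_SNPS = 50
DEFAULT_HEAD_FRACTION = 0.75


@dataclass
class Interval:
    chrom: str
    start: int
    end: int
    n_snps: int


@dataclass
class QtlCall:
    """One called QTL, in the shape of a mapping-report row."""

    name: str
    chrom: str
    full_interval: tuple[int, int]
    probable_interval: tuple[int, int]
    summit_pos: int
    summit_gprime: float
    summit_nafd: float | None
    source_parent: str  # "parent1" | "parent2" | "undetermined"


def full_intervals(
    track: pd.DataFrame,
    threshold: float,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_span: int = DEFAULT_MIN_SPAN,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> tuple[list[Interval], list[Interval]]:
    """(major, minor) supra-threshold intervals per chromosome.

    Maximal runs of consecutive SNPs with G' >= threshold are merged when
    separated by less than ``merge_gap`` bp; merged runs spanning less than
    ``min_span`` bp or containing fewer than ``min_snps`` SNPs are classified
    minor (reported, never silently dropped).
    """
    if not np.isfinite(threshold):
        raise ValueError("finite threshold required")
    major, minor = [], []
    for chrom, grp in track.groupby("chrom", sort=False, observed=True):
        pos = grp["pos"].to_numpy()
        above = grp["Gprime"].to_numpy() >= threshold
        if not above.any():
            continue
        edges = np.diff(above.astype(np.int8))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(above))
        runs = list(zip(starts, ends))
        merged = [runs[0]]
        for s, e in runs[1:]:
            if pos[s] - pos[merged[-1][1] - 1] < merge_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        for s, e in merged:
            # count only supra-threshold SNPs (merging may bridge a dip)
            iv = Interval(
                chrom, int(pos[s]), int(pos[e - 1]), int(above[s:e].sum())
            )
            span = iv.end - iv.start
            if span >= min_span and iv.n_snps >= min_snps:
                major.append(iv)
            else:
                minor.append(iv)
    return major, minor


def summit(track: pd.DataFrame, interval: Interval) -> tuple[int, float]:
    """(position, G') of the highest SNP inside an interval; ties leftmost."""
    grp = track.loc[
        (track["chrom"] == interval.chrom)
        & (track["pos"] >= interval.start)
        & (track["pos"] <= interval.end)
    ]
    if len(grp) == 0:
        raise ValueError("interval contains no SNP")
    gp = grp["Gprime"].to_numpy()
    i = int(np.argmax(gp))  # argmax returns first maximum: leftmost tie rule
    return int(grp["pos"].to_numpy()[i]), float(gp[i])


def probable_interval(
    track: pd.DataFrame,
    interval: Interval,
    threshold: float,
    head_fraction: float = DEFAULT_HEAD_FRACTION,
) -> tuple[int, int]:
    """The "head" of the peak: the maximal contiguous run around the summit
    with G' >= threshold + head_fraction * (summit - threshold).  With
    head_fraction 0 this reduces to the full interval."""
    if not 0.0 <= head_fraction <= 1.0:
        raise ValueError("head_fraction must be in [0, 1]")
    grp = track.loc[
        (track["chrom"] == interval.chrom)
        & (track["pos"] >= interval.start)
        & (track["pos"] <= interval.end)
    ]
    pos = grp["pos"].to_numpy()
    gp = grp["Gprime"].to_numpy()
    i_summit = int(np.argmax(gp))
    head_level = threshold + head_fraction * (gp[i_summit] - threshold)
    ok = gp >= head_level
    lo = i_summit
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i_summit
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    return int(pos[lo]), int(pos[hi])


def allele_source(summit_nafd) -> str:
    """Which parent carries the trait-increasing allele: the reference parent
    (parent 1) when NAFD > 0 at the summit, parent 2 when NAFD < 0."""
    if summit_nafd is None:
        return "undetermined"
    if summit_nafd > 0:
        return "parent1"
    if summit_nafd < 0:
        return "parent2"
    return "undetermined"


def _split_valley(track, iv: Interval, threshold: float, head_fraction: float):
    """Optional sub-calls for a double peak separated by an internal valley
    (e.g. a centromere): split at the interior minimum when it drops below
    the head level and both flanks carry a maximum above the threshold."""
    grp = track.loc[
        (track["chrom"] == iv.chrom)
        & (track["pos"] >= iv.start)
        & (track["pos"] <= iv.end)
    ]
    pos = grp["pos"].to_numpy()
    gp = grp["Gprime"].to_numpy()
    if len(gp) < 5:
        return None
    i_summit = int(np.argmax(gp))
    head_level = threshold + head_fraction * (gp[i_summit] - threshold)
    interior = slice(1, len(gp) - 1)
    i_min = 1 + int(np.argmin(gp[interior]))
    if gp[i_min] >= head_level:
        return None
    if gp[:i_min].max() < threshold or gp[i_min + 1 :].max() < threshold:
        return None
    left = Interval(iv.chrom, int(pos[0]), int(pos[i_min]), i_min + 1)
    right = Interval(iv.chrom, int(pos[i_min]), int(pos[-1]), len(pos) - i_min)
    return left, right


def call_qtls(
    track: pd.DataFrame,
    nafd_track: pd.DataFrame,
    threshold: float,
    name_prefix: str = "qQTL",
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_span: int = DEFAULT_MIN_SPAN,
    min_snps: int = DEFAULT_MIN_SNPS,
    head_fraction: float = DEFAULT_HEAD_FRACTION,
    split_valleys: bool = False,
) -> tuple[list[QtlCall], list[Interval]]:
    """End-to-end interval calling; returns (QTL calls, minor peaks).

    Names are ``<prefix>-<chrom>`` with a/b/... suffixes (ordered by
    position) when one chromosome yields several calls.
    """
    major, minor = full_intervals(track, threshold, merge_gap, min_span, min_snps)
    intervals: list[Interval] = []
    for iv in major:
        split = _split_valley(track, iv, threshold, head_fraction) if split_valleys else None
        intervals.extend(split if split else [iv])
    calls = []
    for iv in intervals:
        s_pos, s_gp = summit(track, iv)
        prob = probable_interval(track, iv, threshold, head_fraction)
        s_nafd = nafd_at(nafd_track, iv.chrom, s_pos)
        calls.append(
            QtlCall(
                name="",
                chrom=iv.chrom,
                full_interval=(iv.start, iv.end),
                probable_interval=prob,
                summit_pos=s_pos,
                summit_gprime=s_gp,
                summit_nafd=s_nafd,
                source_parent=allele_source(s_nafd),
            )
        )
    calls.sort(key=lambda c: (str(c.chrom), c.full_interval[0]))
    per_chrom: dict = {}
    for c in calls:
        per_chrom.setdefault(c.chrom, []).append(c)
    for chrom, group in per_chrom.items():
        if len(group) == 1:
            group[0].name = f"{name_prefix}-{chrom}"
        else:
            for i, c in enumerate(group):
                c.name = f"{name_prefix}-{chrom}{chr(ord('a') + i)}"
    return calls, minor


REPORT_COLUMNS = [
    "name", "chrom", "full_start", "full_end", "probable_start",
    "probable_end", "summit_pos", "summit_gprime", "summit_nafd",
    "source_parent",
]


def report(calls: list[QtlCall], path=None, fmt: str = "tsv"):
    """Mapping-report table (one row per QTL).  ``fmt`` is "tsv" or "json";
    with ``path`` None the TSV form returns a DataFrame and the JSON form a
    list of dicts."""
    rows = [
        {
            "name": c.name,
            "chrom": c.chrom,
            "full_start": c.full_interval[0],
            "full_end": c.full_interval[1],
            "probable_start": c.probable_interval[0],
            "probable_end": c.probable_interval[1],
            "summit_pos": c.summit_pos,
            "summit_gprime": c.summit_gprime,
            "summit_nafd": c.summit_nafd,
            "source_parent": c.source_parent,
        }
        for c in calls
    ]
    if fmt == "tsv":
        df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        if path is None:
            return df
        df.to_csv(path, sep="\t", index=False)
        return df
    if fmt == "json":
        if path is not None:
            with open(path, "w") as fh:
                json.dump(rows, fh, indent=2)
        return rows
    raise ValueError(f"unknown report format: {fmt!r}")


def calls_from_json(path) -> list[QtlCall]:
    """Read back a JSON report into QtlCall objects."""
    with open(path) as fh:
        rows = json.load(fh)
    return [
        QtlCall(
            name=r["name"],
            chrom=r["chrom"],
            full_interval=(r["full_start"], r["full_end"]),
            probable_interval=(r["probable_start"], r["probable_end"]),
            summit_pos=r["summit_pos"],
            summit_gprime=r["summit_gprime"],
            summit_nafd=r["summit_nafd"],
            source_parent=r["source_parent"],
        )
        for r in rows
    ]


def write_interval_bed(calls: list[QtlCall], path, which: str = "full") -> None:
    """BED export (0-based half-open) of full or probable intervals."""
    if which not in ("full", "probable"):
        raise ValueError("which must be 'full' or 'probable'")
    with open(path, "w") as fh:
        for c in calls:
            start, end = getattr(c, f"{which}_interval")
            fh.write(f"{c.chrom}\t{start - 1}\t{end}\t{c.name}\n")
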