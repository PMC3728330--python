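"""Sliding-window reference-parent allele frequency difference (NAFD).

For each pool, the parent-1 (reference, e.g. Nipponbare) allele frequency in
a window is the depth-pooled estimate

    fhat = sum_i a_i / sum_i (a_i + b_i)

over the m SNPs in the window, where a_i/b_i are the parent-1/parent-2
allele depths — pooled counts, not a mean of per-SNP frequencies.  NAFD is
fhat(ET) - fhat(ES) in a 300-kb window stepped every 10 kb; at a QTL its
sign identifies the parent contributing the trait-increasing allele
(parent 1 if NAFD > 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 300_000
DEFAULT_STEP = 10_000


def window_frequency(snps: pd.DataFrame, pool: str) -> float:
    """Depth-pooled parent-1 frequency of the given pool ("ES" or "ET") over
    the SNPs in ``snps``."""
    if pool not in ("ES", "ET"):
        raise ValueError("pool must be 'ES' or 'ET'")
    if len(snps) == 0:
        raise ValueError("no SNPs in window")
    a = snps[f"n1_{pool}"].to_numpy(dtype=float).sum()
    b = snps[f"n2_{pool}"].to_numpy(dtype=float).sum()
    if a + b == 0:
        raise ValueError("zero window depth")
    return a / (a + b)


def nafd_scan(
    snps: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """NAFD profile over tiled windows.

    Windows are anchored at position 1 on each chromosome with closed-open
    spans [start, start + window); windows containing no SNP are omitted.
    Returns ``chrom start end m f_ES f_ET nafd`` (end is inclusive-style
    start + window - 1, 1-based coordinates).
    """
    out = []
    for chrom, grp in snps.groupby("chrom", sort=False, observed=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on {chrom}")
        cums = {
            c: np.concatenate([[0.0], np.cumsum(grp[c].to_numpy(dtype=float))])
            for c in ("n1_ES", "n2_ES", "n1_ET", "n2_ET")
        }
        starts = np.arange(1, pos[-1] + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        m = hi - lo
        keep = m > 0
        lo, hi, starts, m = lo[keep], hi[keep], starts[keep], m[keep]

        def winsum(col):
            return cums[col][hi] - cums[col][lo]

        a_es, b_es = winsum("n1_ES"), winsum("n2_ES")
        a_et, b_et = winsum("n1_ET"), winsum("n2_ET")
        f_es = a_es / (a_es + b_es)
        f_et = a_et / (a_et + b_et)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window - 1,
                    "m": m,
                    "f_ES": f_es,
                    "f_ET": f_et,
                    "nafd": f_et - f_es,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "m", "f_ES", "f_ET", "nafd"]
        )
    return pd.concat(out, ignore_index=True)


def nafd_at(nafd_track: pd.DataFrame, chrom, pos: int):
    """NAFD of the window whose centre is nearest ``pos`` on ``chrom``;
    None when the chromosome has no emitted window."""
    grp = nafd_track.loc[nafd_track["chrom"] == chrom]
    if len(grp) == 0:
        return None
    centers = (grp["start"].to_numpy() + grp["end"].to_numpy()) / 2.0
    i = int(np.argmin(np.abs(centers - pos)))
    return float(grp["nafd"].to_numpy()[i])


def write_nafd_bed(nafd_track: pd.DataFrame, path) -> None:
    """BED export (0-based half-open spans) of the NAFD profile."""
    df = nafd_track.copy()
    df["start"] = df["start"] - 1
    df["end"] = df["end"]  # 1-based inclusive end == 0-based half-open end
    df[["chrom", "start", "end", "nafd"]].to_csv(
        path, sep="\t", header=False, index=False
    )
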