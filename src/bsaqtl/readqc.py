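"""Quality trimming and filtering of FASTQ reads (modified Mott algorithm).

Each base with PHRED quality q has error probability p = 10^(-q/10).  Given
an error-probability limit (default 0.05) the base scores are s_i = limit -
p_i, and the retained segment is the contiguous run maximising the summed
score — the maximum-scoring-segment formulation of Mott trimming.  A read
whose scores are all negative is trimmed to nothing.  Trimmed reads shorter
than 25 bp or containing more than 2 ambiguous bases are then discarded.

Qualities are Sanger/PHRED+33 only; ambiguous (N) bases are assigned error
probability 0.75 regardless of their stated quality so they can never rescue
a segment.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_ERROR_LIMIT = 0.05
DEFAULT_MAX_AMBIGUOUS = 2
DEFAULT_MIN_LENGTH = 25
N_ERROR_PROB = 0.75


def phred_to_error(q):
    """Error probability 10^(-q/10) of a PHRED score (scalar or array)."""
    q = np.asarray(q)
    if np.any(q < 0):
        raise ValueError("negative PHRED score")
    return 10.0 ** (-q / 10.0)


def _scores(bases: str, quals, limit: float) -> np.ndarray:
    p = phred_to_error(np.asarray(quals, dtype=float))
    is_n = np.frombuffer(bases.upper().encode(), dtype="S1") == b"N"
    p = np.where(is_n, N_ERROR_PROB, p)
    return limit - p


def mott_trim(bases: str, quals, limit: float = DEFAULT_ERROR_LIMIT):
    """Maximum-scoring contiguous segment of a read, as (start, end) in
    half-open 0-based coordinates; (0, 0) when every base scores negative.

    Ties between equal-sum segments are broken leftmost-first, then longest
    (so a segment is never shortened by a zero-sum extension ambiguity).
    """
    if len(bases) != len(quals):
        raise ValueError("bases and qualities differ in length")
    if len(bases) == 0:
        return (0, 0)
    s = _scores(bases, quals, limit)
    cur = s[0]
    cur_start = 0
    best = cur
    best_start, best_end = 0, 1
    for i in range(1, len(s)):
        # reset only on strict improvement, so earlier starts win ties;
        # a zero-valued prefix is kept (leftmost-longest rule)
        if cur < 0.0:
            cur = s[i]
            cur_start = i
        else:
            cur = cur + s[i]
        if cur > best or (cur == best and cur_start == best_start):
            best = cur
            best_start, best_end = cur_start, i + 1
    if best < 0.0:
        return (0, 0)
    return (best_start, best_end)


def filter_read(
    bases: str,
    max_ambiguous: int = DEFAULT_MAX_AMBIGUOUS,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> bool:
    """Keep an (already trimmed) read iff it is at least ``min_len`` bp and
    contains at most ``max_ambiguous`` N bases."""
    return len(bases) >= min_len and bases.upper().count("N") <= max_ambiguous


@dataclass
class TrimSummary:
    """Read-accounting line after trimming: raw and kept counts, kept
    percentage, and mean kept length."""

    raw_reads: int
    kept_reads: int
    total_kept_length: int

    @property
    def kept_pct(self) -> float:
        return 100.0 * self.kept_reads / self.raw_reads if self.raw_reads else 0.0

    @property
    def mean_length(self) -> float:
        return self.total_kept_length / self.kept_reads if self.kept_reads else 0.0


def _open(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def trim_record(record, limit=DEFAULT_ERROR_LIMIT):
    """Mott-trim one Bio.SeqRecord (Sanger FASTQ); returns the trimmed record."""
    quals = record.letter_annotations["phred_quality"]
    start, end = mott_trim(str(record.seq), quals, limit)
    return record[start:end]


def trim_fastq(
    in_path,
    out_path,
    limit: float = DEFAULT_ERROR_LIMIT,
    max_ambiguous: int = DEFAULT_MAX_AMBIGUOUS,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> TrimSummary:
    """Trim and filter a (plain or gzipped) FASTQ file; Sanger qualities only."""
    summary = TrimSummary(0, 0, 0)
    with _open(in_path) as fin, _open(out_path, "wt") as fout:
        for record in SeqIO.parse(fin, "fastq"):
            summary.raw_reads += 1
            trimmed = trim_record(record, limit)
            if filter_read(str(trimmed.seq), max_ambiguous, min_len):
                summary.kept_reads += 1
                summary.total_kept_length += len(trimmed)
                SeqIO.write(trimmed, fout, "fastq")
    return summary


def trim_fastq_paired(
    in1,
    in2,
    out1,
    out2,
    limit: float = DEFAULT_ERROR_LIMIT,
    max_ambiguous: int = DEFAULT_MAX_AMBIGUOUS,
    min_len: int = DEFAULT_MIN_LENGTH,
    drop_orphans: bool = True,
) -> TrimSummary:
    """Paired-end trimming.  With ``drop_orphans`` (default) a pair is kept
    only if both mates survive; otherwise a failing mate is written as an
    empty-sequence placeholder is NOT produced — the surviving mate is
    written alone to its file."""
    summary = TrimSummary(0, 0, 0)
    with _open(in1) as f1, _open(in2) as f2, _open(out1, "wt") as o1, _open(
        out2, "wt"
    ) as o2:
        it2 = SeqIO.parse(f2, "fastq")
        for rec1 in SeqIO.parse(f1, "fastq"):
            rec2 = next(it2, None)
            if rec2 is None:
                raise ValueError("paired FASTQ files differ in read count")
            summary.raw_reads += 2
            t1 = trim_record(rec1, limit)
            t2 = trim_record(rec2, limit)
            k1 = filter_read(str(t1.seq), max_ambiguous, min_len)
            k2 = filter_read(str(t2.seq), max_ambiguous, min_len)
            if drop_orphans and not (k1 and k2):
                continue
            if k1:
                summary.kept_reads += 1
                summary.total_kept_length += len(t1)
                SeqIO.write(t1, o1, "fastq")
            if k2:
                summary.kept_reads += 1
                summary.total_kept_length += len(t2)
                SeqIO.write(t2, o2, "fastq")
        if next(it2, None) is not None:
            raise ValueError("paired FASTQ files differ in read count")
    return summary
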