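"""SNP allele-count I/O, the three-rule SNP filter, and mapping summaries.

The package-standard table holds one biallelic SNP per row with the parental
allele depths of the two pools::

    chrom  pos  n1_ES  n2_ES  n1_ET  n2_ET

where parent 1 is by convention the reference parent (Nipponbare in the rice
cross this pipeline was designed around) and ES/ET are the extremely
sensitive (low-trait) and extremely tolerant (high-trait) pools.  Tables can
be read from this TSV dialect or from a two-sample VCF carrying FORMAT/AD.

The SNP filter reproduces the three screening requirements applied before
QTL analysis: the overall parent-1 frequency across both pools must lie in
[0.20, 0.80], the total depth in [100, 400], and each pool's depth must be at
least 40 ("neither <X nor >Y" read as a closed interval).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gprime import COUNT_COLUMNS

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["chrom", "pos", *COUNT_COLUMNS]


@dataclass(frozen=True)
class MappingSummary:
    """Read-accounting and genome-coverage numbers for one pool (or total)."""

    raw_reads: int
    kept_reads: int
    uniquely_mapped_reads: int
    total_mapped_length: int
    covered_length: int
    genome_length: int

    def __post_init__(self):
        if self.kept_reads > self.raw_reads:
            raise ValueError("kept_reads exceeds raw_reads")
        if self.covered_length > self.genome_length:
            raise ValueError("covered_length exceeds genome_length")


def coverage_summary(ms: MappingSummary) -> dict:
    """Percentages and mean depth in the style of the sequencing-statistics
    tables: kept%, uniquely-mapped% (of kept), genome coverage rate %, and
    mean depth over the covered length."""
    if ms.raw_reads <= 0 or ms.kept_reads <= 0 or ms.genome_length <= 0:
        raise ValueError("positive denominators required")
    if ms.covered_length <= 0:
        raise ValueError("zero covered_length")
    return {
        "kept_pct": 100.0 * ms.kept_reads / ms.raw_reads,
        "unique_pct": 100.0 * ms.uniquely_mapped_reads / ms.kept_reads,
        "coverage_rate_pct": 100.0 * ms.covered_length / ms.genome_length,
        "depth": ms.total_mapped_length / ms.covered_length,
    }


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    if (df["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    if any((df[c] < 0).any() for c in COUNT_COLUMNS):
        raise ValueError("negative allele depth")
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicated (chrom, pos) records")
    sorted_df = df.sort_values(["chrom", "pos"], kind="stable")
    if not sorted_df.index.equals(df.index):
        warnings.warn("input SNPs were not sorted; sorting by (chrom, pos)")
        df = sorted_df.reset_index(drop=True)
    return df


def read_counts(path, fmt: str = "tsv", alt_is_parent1: bool = False) -> pd.DataFrame:
    """Load a SNP allele-count table.

    ``fmt="tsv"`` expects the package TSV dialect (tab-separated, header row,
    ``#`` comment lines).  ``fmt="vcf"`` expects a VCF with exactly two
    samples, ES first and ET second, carrying FORMAT/AD; parent 1 is the REF
    allele unless ``alt_is_parent1``.  Multiallelic records and records with
    missing AD are dropped (logged).  Unsorted input is sorted with a
    warning; duplicated (chrom, pos) is an error.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"TSV is missing columns: {missing}")
        return _finalize(df[TSV_COLUMNS])
    if fmt == "vcf":
        return _finalize(_read_vcf(path, alt_is_parent1))
    raise ValueError(f"unknown format: {fmt!r}")


def _read_vcf(path, alt_is_parent1: bool) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise ValueError(
            f"expected exactly two samples (ES, ET), got {vcf.samples}"
        )
    rows = []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_dropped += 1
            continue
        ad = v.format("AD")
        if ad is None or ad.shape != (2, 2) or (ad < 0).any():
            n_dropped += 1
            continue
        (ref_es, alt_es), (ref_et, alt_et) = ad.astype(int)
        if alt_is_parent1:
            ref_es, alt_es = alt_es, ref_es
            ref_et, alt_et = alt_et, ref_et
        rows.append((v.CHROM, v.POS, ref_es, alt_es, ref_et, alt_et))
    if n_dropped:
        logger.info("dropped %d multiallelic/missing-AD records", n_dropped)
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_counts(snps: pd.DataFrame, path) -> None:
    """Write the package TSV dialect; inverse of ``read_counts(fmt='tsv')``."""
    snps[TSV_COLUMNS].to_csv(path, sep="\t", index=False)


def write_vcf(snps: pd.DataFrame, path, chrom_lengths: dict | None = None) -> None:
    """Write a minimal two-sample VCF (samples ES, ET) with FORMAT/AD.

    REF/ALT are placeholder A/G alleles: pooled data carries allele depths,
    not base identities, once counts are the unit of analysis.
    """
    if chrom_lengths is None:
        chrom_lengths = (
            snps.groupby("chrom", sort=False)["pos"].max().astype(int).to_dict()
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=bsaqtl\n')
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref, alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tES\tET\n"
        )
        for row in snps.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\tA\tG\t.\tPASS\t.\tAD\t"
                f"{int(row.n1_ES)},{int(row.n2_ES)}\t"
                f"{int(row.n1_ET)},{int(row.n2_ET)}\n"
            )


def filter_snps(
    snps: pd.DataFrame,
    freq_range: tuple[float, float] = (0.20, 0.80),
    total_depth_range: tuple[float, float] = (100, 400),
    min_pool_depth: float = 40,
) -> tuple[pd.DataFrame, dict]:
    """Apply the three SNP screening rules; returns (kept, rejection counts).

    Rules, in order: (1) overall parent-1 frequency within ``freq_range``;
    (2) total depth within ``total_depth_range``; (3) each pool's depth at
    least ``min_pool_depth``.  All bounds are inclusive.  A SNP failing
    several rules is attributed to the first failing rule; a zero-total-depth
    SNP is rejected under rule 2 (its frequency is undefined, so rule 1 does
    not claim it).
    """
    n1, n2, n3, n4 = (snps[c].to_numpy(dtype=float) for c in COUNT_COLUMNS)
    total = n1 + n2 + n3 + n4
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, (n1 + n3) / np.where(total > 0, total, 1), 0.5)
    ok1 = (freq >= freq_range[0]) & (freq <= freq_range[1])
    ok2 = (total >= total_depth_range[0]) & (total <= total_depth_range[1])
    ok3 = ((n1 + n2) >= min_pool_depth) & ((n3 + n4) >= min_pool_depth)
    rejected = {
        "frequency": int((~ok1).sum()),
        "total_depth": int((ok1 & ~ok2).sum()),
        "pool_depth": int((ok1 & ok2 & ~ok3).sum()),
    }
    kept = snps.loc[ok1 & ok2 & ok3].reset_index(drop=True)
    return kept, rejected


def frequency_summary(snps: pd.DataFrame, bin_width: float = 0.02) -> dict:
    """Mean and fixed-width histogram of the overall parent-1 frequency
    (n1+n3)/N per SNP — the sanity check that segregation is near 1:1."""
    if len(snps) == 0:
        raise ValueError("empty SNP table")
    n1, n2, n3, n4 = (snps[c].to_numpy(dtype=float) for c in COUNT_COLUMNS)
    total = n1 + n2 + n3 + n4
    if np.any(total == 0):
        raise ValueError("zero total depth; filter first")
    freq = (n1 + n3) / total
    nbins = int(round(1.0 / bin_width))
    counts, edges = np.histogram(freq, bins=nbins, range=(0.0, 1.0))
    return {"mean": float(freq.mean()), "hist_counts": counts, "hist_edges": edges}
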