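"""Per-SNP G statistic and the tricube-smoothed G' genome scan.

At each SNP the read counts of the two parental alleles in the two pools form
a 2x2 contingency table ``(n1, n2; n3, n4)``: n1/n2 are the parent-1/parent-2
allele depths in the low-trait (ES) pool, n3/n4 the same in the high-trait
(ET) pool.  Under the null hypothesis of no QTL linked to the SNP, allele and
pool are independent, and the likelihood-ratio statistic

    G = 2 * sum_i n_i * ln(n_i / nhat_i),      nhat_i = row * col / N

is asymptotically chi-squared with 1 df.  Because individual SNPs are noisy,
the scan statistic G' at a SNP is the tricube-weighted average of G over all
SNPs inside a fixed-width window (default 1000 kb) centred on that SNP:
weights k_j = (1 - D_j^3)^3 with D_j the distance from the centre standardised
by the half-width, renormalised to sum to one within the window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COUNT_COLUMNS = ("n1_ES", "n2_ES", "n1_ET", "n2_ET")


def _as_counts(n1, n2, n3, n4):
    arrs = [np.asarray(a, dtype=float) for a in (n1, n2, n3, n4)]
    if any((a < 0).any() for a in arrs):
        raise ValueError("allele depths must be non-negative")
    return arrs


def expected_counts(n1, n2, n3, n4):
    """Expected cell counts under pool/allele independence.

    Accepts scalars or aligned arrays; returns four arrays (or scalars)
    preserving both margins of each table.  Raises on zero total depth.
    """
    n1, n2, n3, n4 = _as_counts(n1, n2, n3, n4)
    total = n1 + n2 + n3 + n4
    if np.any(total == 0):
        raise ValueError("zero total depth at some SNP")
    r1, r2 = n1 + n2, n3 + n4
    c1, c2 = n1 + n3, n2 + n4
    return r1 * c1 / total, r1 * c2 / total, r2 * c1 / total, r2 * c2 / total


def g_statistic(n1, n2, n3, n4):
    """Likelihood-ratio G of the 2x2 pool-by-allele table, with 0*ln(0) = 0."""
    n1, n2, n3, n4 = _as_counts(n1, n2, n3, n4)
    expected = expected_counts(n1, n2, n3, n4)
    g = 0.0
    for obs, exp in zip((n1, n2, n3, n4), expected):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = obs * np.log(obs / exp)
        g = g + np.where(obs > 0, term, 0.0)
    return 2.0 * g


def tricube_weights(positions, center, half_width):
    """Normalised tricube weights for SNPs in a window around ``center``.

    D_j = |pos_j - center| / half_width must lie in [0, 1]; raw weights
    (1 - D_j^3)^3 are renormalised to sum to one.  A SNP exactly at the edge
    gets zero raw weight.  Raises on an empty window or an out-of-window SNP.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("empty window")
    d = np.abs(positions - center) / float(half_width)
    if np.any(d > 1.0):
        raise ValueError("SNP position outside the window")
    raw = (1.0 - d**3) ** 3
    s = raw.sum()
    if s == 0.0:
        raise ValueError("all weights zero (only edge SNPs in window)")
    return raw / s


def gprime_scan(snps: pd.DataFrame, window: int = 1_000_000) -> pd.DataFrame:
    """Tricube-smoothed G' at every SNP.

    Parameters
    ----------
    snps
        Filtered SNP table with columns ``chrom pos n1_ES n2_ES n1_ET n2_ET``,
        sorted by (chrom, pos).
    window
        Full window width in bp (1000 kb is the conventional choice); the
        window at each SNP spans +-window/2 around it and never crosses a
        chromosome boundary (it is truncated at chromosome ends by virtue of
        there being no SNPs beyond them).

    Returns
    -------
    DataFrame with columns ``chrom pos G Gprime n_snps_in_window``.
    """
    half = window / 2.0
    out = []
    for chrom, grp in snps.groupby("chrom", sort=False, observed=True):
        pos = grp["pos"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on {chrom}")
        g = g_statistic(*(grp[c].to_numpy() for c in COUNT_COLUMNS))
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        gp = np.empty_like(g)
        for i in range(pos.size):
            sl = slice(lo[i], hi[i])
            d = np.abs(pos[sl] - pos[i]) / half
            raw = (1.0 - d**3) ** 3
            s = raw.sum()
            # centre SNP always carries weight 1, so s > 0 in practice;
            # guard the degenerate all-edge case anyway
            gp[i] = g[sl] @ raw / s if s > 0 else g[i]
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": grp["pos"].to_numpy(),
                    "G": g,
                    "Gprime": gp,
                    "n_snps_in_window": hi - lo,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["chrom", "pos", "G", "Gprime", "n_snps_in_window"]
        )
    return pd.concat(out, ignore_index=True)
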