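"""Jensen-Shannon divergence scan for differential SNPs between the pools.

The two pools' allele distributions at a SNP are P_ES = (n1, n2)/N_ES and
P_ET = (n3, n4)/N_ET.  With mixture weights proportional to pool depths,
pi = (N_ES/N, N_ET/N), the depth-weighted JSD is

    JSD = H(pi1*P_ES + pi2*P_ET) - pi1*H(P_ES) - pi2*H(P_ET)   (natural log)

which satisfies the exact identity  2*N*JSD = G  with the likelihood-ratio
G statistic of the same table.  The scan therefore refers 2*N*JSD to the
chi-squared(1 df) distribution and applies a Bonferroni family-wise
correction across all tested SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .gprime import COUNT_COLUMNS

LN2 = float(np.log(2.0))


def _xlogx(p):
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * np.log(p)
    return np.where(p > 0, t, 0.0)


def jsd_weighted(n1, n2, n3, n4):
    """Depth-weighted Jensen-Shannon divergence (nats) between pool allele
    distributions; 0 iff the two pools have identical allele frequencies."""
    n1, n2, n3, n4 = (np.asarray(a, dtype=float) for a in (n1, n2, n3, n4))
    n_es = n1 + n2
    n_et = n3 + n4
    if np.any(n_es == 0) or np.any(n_et == 0):
        raise ValueError("a pool has zero depth at some SNP")
    total = n_es + n_et

    def entropy2(p1, p2):
        return -(_xlogx(p1) + _xlogx(p2))

    h_mix = entropy2((n1 + n3) / total, (n2 + n4) / total)
    h_es = entropy2(n1 / n_es, n2 / n_es)
    h_et = entropy2(n3 / n_et, n4 / n_et)
    jsd = h_mix - (n_es / total) * h_es - (n_et / total) * h_et
    return np.clip(jsd, 0.0, LN2)


def jsd_test(n1, n2, n3, n4):
    """Per-SNP divergence test: statistic 2*N*JSD (= the G statistic) against
    chi-squared with 1 df.  Returns (jsd_nats, statistic, pvalue) arrays."""
    n1, n2, n3, n4 = (np.asarray(a, dtype=float) for a in (n1, n2, n3, n4))
    j = jsd_weighted(n1, n2, n3, n4)
    stat = 2.0 * (n1 + n2 + n3 + n4) * j
    pval = stats.chi2.sf(stat, df=1)
    return j, stat, pval


def differential_scan(snps: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Genome-wide differential-SNP scan with Bonferroni FWER control.

    A SNP is flagged significant iff its chi-squared p-value is at most
    alpha / M, where M is the number of SNPs tested.

    Returns a DataFrame ``chrom pos jsd_nats jsd_bits statistic pvalue
    significant``.
    """
    if len(snps) == 0:
        raise ValueError("no SNPs to test")
    j, stat, pval = jsd_test(*(snps[c].to_numpy() for c in COUNT_COLUMNS))
    cutoff = alpha / len(snps)
    return pd.DataFrame(
        {
            "chrom": snps["chrom"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "jsd_nats": j,
            "jsd_bits": j / LN2,
            "statistic": stat,
            "pvalue": pval,
            "significant": pval <= cutoff,
        }
    )
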