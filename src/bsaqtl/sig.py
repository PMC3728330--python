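"""Empirical-null significance for the G' scan.

In non-QTL regions G' is assumed to follow a log-normal lnN(mu, sigma^2);
observed G' values are a mixture of that null and contaminating components
under QTL peaks.  The null parameters are estimated robustly:

1.  x = ln G'; values with x - Median(x) > c * Median(z), where z =
    Median(x) - x over the lower half (x <= Median(x)) and c = 5.2, are
    discarded (one-sided trimming of the high outliers).
2.  mu = ln Median(G') and sigma^2 = mu - ln Mode(G') on the trimmed set —
    the median/mode identities of the log-normal.
3.  Upper-tail p-values of all G' under lnN(mu, sigma^2) are ranked and the
    Benjamini-Hochberg step-up rule at FDR q* picks the largest k with
    p_k <= q* k / n; the G' threshold is the null quantile at p_k.

To damp the uneven SNP density and the strong local correlation of G',
parameter estimation draws one G' per 200-kb bin from putative non-QTL
regions, repeated (default 20 times) and averaged; the threshold is then
derived from genome-wide one-per-bin subsamples the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TRIM_CONSTANT = 5.2
DEFAULT_SPACING = 200_000
DEFAULT_REPS = 20


@dataclass
class NullModel:
    """Fitted log-normal null of G' and the FDR-derived scan threshold."""

    mu: float
    sigma2: float
    qstar: float = 0.05
    p_threshold: float = float("nan")
    gprime_threshold: float = float("inf")
    trim_constant: float = TRIM_CONSTANT
    spacing: int = DEFAULT_SPACING
    reps: int = DEFAULT_REPS
    seed: int | None = None
    exclude: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma2": self.sigma2,
            "qstar": self.qstar,
            "p_threshold": self.p_threshold,
            "gprime_threshold": self.gprime_threshold,
            "trim_constant": self.trim_constant,
            "spacing": self.spacing,
            "reps": self.reps,
            "seed": self.seed,
        }


def trim_gprime(values, c: float = TRIM_CONSTANT) -> np.ndarray:
    """One-sided robust trimming of high G' outliers (see module docstring)."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 G' values to trim")
    if np.any(values <= 0):
        raise ValueError("G' values must be positive")
    x = np.log(values)
    med_x = np.median(x)
    z = med_x - x[x <= med_x]
    med_z = np.median(z)
    if med_z == 0:
        raise ValueError(
            "Median(z) is zero — the lower half of ln(G') is degenerate "
            "(all values equal?); cannot set a trimming scale"
        )
    return values[x - med_x <= c * med_z]


def half_sample_mode(values) -> float:
    """Mode by the iterated shortest-half estimator (bandwidth-free)."""
    x = np.sort(np.asarray(values, dtype=float))
    while x.size > 3:
        k = (x.size + 1) // 2
        widths = x[k - 1 :] - x[: x.size - k + 1]
        i = int(np.argmin(widths))
        x = x[i : i + k]
    if x.size == 1:
        return float(x[0])
    if x.size == 2:
        return float(0.5 * (x[0] + x[1]))
    return float(
        0.5 * (x[0] + x[1]) if (x[1] - x[0]) < (x[2] - x[1]) else 0.5 * (x[1] + x[2])
    )


def lognormal_mode_kde(values, bw_mult: float = 2.5, gridsize: int = 400) -> float:
    """Mode of the density of a positive sample via Gaussian KDE of x = ln v.

    The density of v satisfies f_v(e^x) proportional to f_x(x) e^{-x}, so the
    mode solves argmax[log f_x(x) - x].  For near-normal x, kernel smoothing
    with bandwidth h shifts that argmax down by exactly h^2 (a N(m, s^2)
    density smoothed by N(0, h^2) is N(m, s^2 + h^2), and the exponential
    tilt of a normal moves its mode by the variance), so h^2 is added back.
    A deliberately wide bandwidth (``bw_mult`` times Scott's rule) suppresses
    argmax variance at no bias cost under near-normality.
    """
    x = np.log(np.asarray(values, dtype=float))
    kde = stats.gaussian_kde(x, bw_method=lambda k: bw_mult * k.scotts_factor())
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(np.quantile(x, 0.001), np.quantile(x, 0.999), gridsize)
    obj = np.log(np.maximum(kde(grid), 1e-300)) - grid
    i = int(np.argmax(obj))
    xhat = grid[i]
    if 0 < i < gridsize - 1:  # parabolic vertex refinement
        y0, y1, y2 = obj[i - 1 : i + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            xhat += 0.5 * (y0 - y2) / denom * (grid[1] - grid[0])
    return float(np.exp(xhat + h * h))


def fit_null(trimmed, mode_method: str = "kde") -> tuple[float, float]:
    """(mu, sigma2) of the log-normal null from a trimmed G' sample.

    mu = ln Median, sigma2 = mu - ln Mode.  ``mode_method`` is "kde"
    (default; bias-corrected log-scale KDE) or "hsm" (half-sample mode).
    Refuses to fit when Mode >= Median (no log-normal right skew).
    """
    trimmed = np.asarray(trimmed, dtype=float)
    if trimmed.size == 0:
        raise ValueError("empty trimmed sample")
    if np.any(trimmed <= 0):
        raise ValueError("G' values must be positive")
    mu = float(np.log(np.median(trimmed)))
    if mode_method == "kde":
        mode = lognormal_mode_kde(trimmed)
    elif mode_method == "hsm":
        mode = half_sample_mode(trimmed)
    else:
        raise ValueError(f"unknown mode_method: {mode_method!r}")
    sigma2 = mu - float(np.log(mode))
    if sigma2 <= 0:
        raise ValueError(
            f"Mode ({mode:.4g}) >= Median ({np.exp(mu):.4g}): sample is not "
            "right-skewed on the log scale; refusing to fit a log-normal null"
        )
    return mu, sigma2


def null_pvalues(gprime, mu: float, sigma2: float) -> np.ndarray:
    """Upper-tail p-values of G' under lnN(mu, sigma2)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    gprime = np.asarray(gprime, dtype=float)
    return stats.norm.sf(np.log(gprime), loc=mu, scale=np.sqrt(sigma2))


def bh_select(pvals, qstar: float = 0.05):
    """Benjamini-Hochberg step-up: largest k with p_(k) <= q* k / n.

    Returns (k, p_k) with k 1-based in the sorted order, or None when no
    p-value passes.
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value list")
    n = p.size
    ok = p <= qstar * np.arange(1, n + 1) / n
    if not ok.any():
        return None
    k = int(np.max(np.nonzero(ok)[0])) + 1
    return k, float(p[k - 1])


def _bin_index(track: pd.DataFrame, spacing: int) -> np.ndarray:
    """Genome-wide bin id per SNP: bins of ``spacing`` bp anchored at
    position 1 on each chromosome (final partial bin kept)."""
    track = track.reset_index(drop=True)
    bins = np.empty(len(track), dtype=np.int64)
    offset = 0
    for _, grp in track.groupby("chrom", sort=False, observed=True):
        idx = grp.index.to_numpy()
        b = (grp["pos"].to_numpy(dtype=np.int64) - 1) // spacing
        bins[idx] = b + offset
        offset += int(b.max()) + 1 if len(b) else 0
    return bins


def _in_intervals(track: pd.DataFrame, intervals) -> np.ndarray:
    mask = np.zeros(len(track), dtype=bool)
    pos = track["pos"].to_numpy()
    chrom = track["chrom"].to_numpy()
    for c, start, end in intervals:
        mask |= (chrom == c) & (pos >= start) & (pos <= end)
    return mask


def _one_per_bin(rng, bins: np.ndarray, eligible: np.ndarray) -> np.ndarray:
    """Indices of one uniformly chosen eligible SNP per nonempty bin."""
    idx = np.nonzero(eligible)[0]
    if idx.size == 0:
        raise ValueError("no eligible SNPs (all bins excluded)")
    keys = rng.random(idx.size)
    order = np.lexsort((keys, bins[idx]))
    sorted_bins = bins[idx][order]
    first = np.ones(sorted_bins.size, dtype=bool)
    first[1:] = sorted_bins[1:] != sorted_bins[:-1]
    return idx[order[first]]


def _merge_positions(track: pd.DataFrame, mask: np.ndarray, merge_gap: int):
    """Merge flagged SNP positions into (chrom, start, end) intervals,
    bridging gaps up to ``merge_gap`` bp."""
    out = []
    flagged = track.loc[mask]
    for chrom, grp in flagged.groupby("chrom", sort=False, observed=True):
        pos = np.sort(grp["pos"].to_numpy())
        start = prev = pos[0]
        for x in pos[1:]:
            if x - prev > merge_gap:
                out.append((chrom, int(start), int(prev)))
                start = x
            prev = x
        out.append((chrom, int(start), int(prev)))
    return out


def auto_exclude_regions(
    track: pd.DataFrame,
    p_cut: float = 0.001,
    merge_gap: int = 1_000_000,
    spacing: int = DEFAULT_SPACING,
    reps: int = DEFAULT_REPS,
    mode_method: str = "kde",
    seed: int | None = None,
    max_iter: int = 10,
) -> list[tuple]:
    """Data-driven putative-QTL regions to exclude from null estimation — an
    automated stand-in for excluding the visually obvious major G' peaks.

    The exclusion set is seeded with the robust-trimming outlier rule applied
    along the genome (SNPs whose ln G' exceeds the genome median by more than
    the trim constant times the lower-half median deviation, merged across
    gaps up to ``merge_gap`` bp), then grown iteratively: a null is fitted on
    the remaining regions and SNPs with p < ``p_cut`` under it join the
    exclusion.  Growth is monotone (union with the previous set), so the
    procedure converges; it stops when the flagged set stops growing.
    """
    track = track.reset_index(drop=True)
    gp = track["Gprime"].to_numpy()
    x = np.log(gp)
    med = np.median(x)
    med_z = np.median(med - x[x <= med])
    mask = x - med > TRIM_CONSTANT * med_z
    for _ in range(max_iter):
        exclude = _merge_positions(track, mask, merge_gap)
        try:
            mu, s2 = estimate_null_params(
                track, exclude, spacing=spacing, reps=reps,
                mode_method=mode_method, seed=seed,
            )
        except ValueError:  # exclusion swallowed every bin; stop growing
            break
        new_mask = mask | (null_pvalues(gp, mu, s2) < p_cut)
        if new_mask.sum() == mask.sum():
            break
        mask = new_mask
    return _merge_positions(track, mask, merge_gap)


def estimate_null_params(
    track: pd.DataFrame,
    exclude,
    spacing: int = DEFAULT_SPACING,
    reps: int = DEFAULT_REPS,
    mode_method: str = "kde",
    seed: int | None = None,
) -> tuple[float, float]:
    """Repeatedly subsample one G' per bin outside ``exclude``, trim, fit,
    and average (mu, sigma2) over the repetitions."""
    rng = np.random.default_rng(seed)
    bins = _bin_index(track, spacing)
    eligible = ~_in_intervals(track, exclude)
    mus, s2s = [], []
    for _ in range(reps):
        pick = _one_per_bin(rng, bins, eligible)
        trimmed = trim_gprime(track["Gprime"].to_numpy()[pick])
        mu, s2 = fit_null(trimmed, mode_method=mode_method)
        mus.append(mu)
        s2s.append(s2)
    return float(np.mean(mus)), float(np.mean(s2s))


def estimate_threshold(
    track: pd.DataFrame,
    exclude="auto",
    spacing: int = DEFAULT_SPACING,
    reps: int = DEFAULT_REPS,
    qstar: float = 0.05,
    mode_method: str = "kde",
    seed: int | None = None,
) -> NullModel:
    """Full null-estimation and FDR-threshold procedure on a G' track.

    ``exclude`` is a list of (chrom, start, end) intervals unlikely to be
    usable for null estimation (QTL peaks), "auto" for the data-driven
    default, or None/[] for no exclusion.  Parameters (mu, sigma2) are the
    averages over ``reps`` one-per-bin subsamples outside the excluded
    regions; the step-up p-value cut p_k is averaged over ``reps``
    genome-wide one-per-bin subsamples (those with at least one rejection),
    and the G' threshold is the null quantile at the averaged p_k, so the
    quantile-inversion identity holds exactly for the reported pair.
    """
    if len(track) == 0:
        raise ValueError("empty G' track")
    if exclude == "auto":
        exclude = auto_exclude_regions(
            track, spacing=spacing, reps=reps, mode_method=mode_method, seed=seed
        )
    elif exclude is None:
        exclude = []
    mu, sigma2 = estimate_null_params(
        track, exclude, spacing=spacing, reps=reps, mode_method=mode_method,
        seed=seed,
    )
    rng = np.random.default_rng(None if seed is None else seed + 1)
    bins = _bin_index(track, spacing)
    gp = track["Gprime"].to_numpy()
    all_eligible = np.ones(len(track), dtype=bool)
    pks = []
    for _ in range(reps):
        pick = _one_per_bin(rng, bins, all_eligible)
        sel = bh_select(null_pvalues(gp[pick], mu, sigma2), qstar)
        if sel is not None:
            pks.append(sel[1])
    model = NullModel(
        mu=mu, sigma2=sigma2, qstar=qstar, spacing=spacing, reps=reps,
        seed=seed, exclude=list(exclude),
    )
    if not pks:
        warnings.warn("no G' value passes the FDR step-up rule; threshold is +inf")
        return model
    p_thr = float(np.mean(pks))
    model.p_threshold = p_thr
    model.gprime_threshold = float(
        np.exp(mu + np.sqrt(sigma2) * stats.norm.isf(p_thr))
    )
    return model
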