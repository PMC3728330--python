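"""Synthetic pooled extreme-segregant (bulked segregant) data generator.

The generator emulates the experimental design the analysis assumes: a
biparental cross selfed to a large F3 population (default 10,800
individuals), an additive multi-QTL trait, truncation selection of the
opposite ~4% phenotypic tails into two pools (defaults 430 extremely
sensitive / 385 extremely tolerant individuals), and pooled short-read
sequencing of the two bulks at ~70x / 89x mean depth over unevenly spaced
SNPs on a rice-sized 12-chromosome genome.

Meiosis uses the Haldane map function with no interference at a constant
200 kb per cM (the standard rice-scale approximation), which makes the
gamete inheritance pattern along a chromosome a two-state Markov chain with
switch probability r = (1 - exp(-2d))/2 between adjacent SNPs at genetic
distance d Morgans.  F3 individuals are produced as one (configurable)
selfed offspring of each of N independent F2 plants, which reproduces the
F3 marginal genotype frequencies (3/8, 1/4, 3/8).

Sequencing draws each pool's per-SNP depth from a negative binomial
(gamma-Poisson) around the pool mean, truncated at 1, and the parent-1 read
count from Binomial(depth, f), where f is the true pooled allele frequency
(mean genotype / 2), optionally perturbed by a symmetric sequencing-error
flip rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .gprime import COUNT_COLUMNS

#: Approximate chromosome lengths (bp) of the 12 rice chromosomes, summing
#: to ~373 Mb — the genome scale the default configuration emulates.
RICE_CHROM_LENGTHS = (
    43_300_000, 35_900_000, 36_400_000, 35_500_000, 29_900_000, 31_200_000,
    29_700_000, 28_400_000, 23_000_000, 23_200_000, 29_000_000, 27_500_000,
)

BP_PER_CM = 200_000.0  # 1 cM ~ 200 kb at rice genome scale


@dataclass(frozen=True)
class Qtl:
    """One additive QTL: ``effect`` (> 0) is the phenotype increment per
    parent-1 allele when ``source_parent`` is 1, per parent-2 allele when it
    is 2 (the high-trait, 'tolerant' direction)."""

    chrom: str
    pos: int
    effect: float
    source_parent: int = 1

    def __post_init__(self):
        if not math.isfinite(self.effect) or self.effect < 0:
            raise ValueError("QTL effect must be finite and non-negative")
        if self.source_parent not in (1, 2):
            raise ValueError("source_parent must be 1 or 2")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one simulated experiment.

    Defaults reproduce the pooled-rice design: 10,800 F3 individuals, 4%
    opposite tails pooled as 430 ES / 385 ET, pool depths 70x / 89x, and a
    12-chromosome ~373-Mb genome with ~18.7-kb mean SNP spacing (~20,000
    SNPs).  Exactly one of ``heritability`` / ``residual_sd`` applies:
    with ``heritability`` set, the residual standard deviation is derived
    from the realised genetic variance.
    """

    chrom_lengths: tuple = RICE_CHROM_LENGTHS
    chrom_names: tuple | None = None
    snp_positions: tuple | None = None  # per-chromosome sorted arrays
    mean_spacing: float = 18_700.0
    spacing_cv: float = 1.0  # gamma-distributed gaps; 1 = Poisson process
    qtls: tuple = ()
    heritability: float | None = None
    residual_sd: float | None = None
    pop_size: int = 10_800
    tail_fraction: float = 0.04
    pool_sizes: tuple = (430, 385)
    mean_depth: tuple = (70.0, 89.0)
    depth_dispersion: float | None = 5.0  # NB size; None = Poisson depth
    seq_error: float = 0.0
    offspring_per_family: int = 1
    bp_per_cm: float = BP_PER_CM
    seed: int | None = None

    def __post_init__(self):
        if self.chrom_names is None:
            object.__setattr__(
                self,
                "chrom_names",
                tuple(f"chr{i + 1:02d}" for i in range(len(self.chrom_lengths))),
            )
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names/chrom_lengths length mismatch")
        object.__setattr__(self, "qtls", tuple(self.qtls))
        if not 0.0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5)")
        cap = math.ceil(self.tail_fraction * self.pop_size)
        if max(self.pool_sizes) > cap:
            raise ValueError(
                f"pool sizes {self.pool_sizes} exceed the tail capacity "
                f"ceil(tail_fraction * pop_size) = {cap}"
            )
        names = set(self.chrom_names)
        for q in self.qtls:
            if q.chrom not in names:
                raise ValueError(f"QTL chromosome {q.chrom!r} not declared")
            length = self.chrom_lengths[self.chrom_names.index(q.chrom)]
            if not 1 <= q.pos <= length:
                raise ValueError(f"QTL position {q.pos} outside {q.chrom}")
        if self.heritability is not None and self.residual_sd is not None:
            raise ValueError("give heritability or residual_sd, not both")
        if self.heritability is not None and not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        if min(self.mean_depth) <= 0:
            raise ValueError("mean pool depths must be positive")

    @property
    def effective_residual_sd(self) -> float:
        return 1.0 if self.residual_sd is None else self.residual_sd


@dataclass
class SimGenotypes:
    """F3 genotypes: per-chromosome SNP positions and an (individuals x
    SNPs) matrix of parent-1 allele counts in {0, 1, 2}."""

    chrom_names: tuple
    positions: list  # list of int64 arrays, one per chromosome
    genotypes: np.ndarray  # int8, columns concatenated over chromosomes

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def col_offsets(self) -> np.ndarray:
        sizes = [len(p) for p in self.positions]
        return np.concatenate([[0], np.cumsum(sizes)])

    def column_of(self, chrom: str, pos: int) -> int:
        """Column index of the SNP nearest ``pos`` on ``chrom``."""
        ci = self.chrom_names.index(chrom)
        p = self.positions[ci]
        if len(p) == 0:
            raise ValueError(f"no SNPs on {chrom}")
        return int(self.col_offsets[ci]) + int(np.argmin(np.abs(p - pos)))


def draw_snp_positions(cfg: SimConfig, rng) -> list:
    """Per-chromosome sorted SNP positions: declared positions, or gaps drawn
    from a gamma with mean ``mean_spacing`` and CV ``spacing_cv`` (CV 1 is a
    Poisson point process; larger CVs cluster the SNPs)."""
    if cfg.snp_positions is not None:
        return [np.asarray(p, dtype=np.int64) for p in cfg.snp_positions]
    shape = 1.0 / cfg.spacing_cv**2
    scale = cfg.mean_spacing * cfg.spacing_cv**2
    out = []
    for length in cfg.chrom_lengths:
        n_max = int(2 * length / cfg.mean_spacing) + 20
        gaps = rng.gamma(shape, scale, size=n_max)
        pos = np.cumsum(gaps)
        pos = pos[pos <= length]
        out.append(np.maximum(pos.astype(np.int64), 1))
    return out


def _recomb_fractions(positions: np.ndarray, bp_per_cm: float) -> np.ndarray:
    """Haldane recombination fraction between adjacent SNPs."""
    d_morgans = np.diff(positions) / (bp_per_cm * 100.0)
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def _gamete_patterns(rng, n: int, rec: np.ndarray) -> np.ndarray:
    """(n, m) matrix of 0/1 inheritance patterns of n independent meioses
    over m loci: random start phase, switches between adjacent loci with the
    Haldane probabilities (Markov property of a no-interference map)."""
    m = rec.size + 1
    pat = np.empty((n, m), dtype=np.uint8)
    pat[:, 0] = rng.random(n) < 0.5
    if m > 1:
        pat[:, 1:] = rng.random((n, m - 1)) < rec
    np.bitwise_xor.accumulate(pat, axis=1, out=pat)
    return pat


def simulate_f3_genotypes(cfg: SimConfig, rng=None) -> SimGenotypes:
    """Simulate F3 genotypes by F1 -> F2 -> F3 meiosis with crossover.

    Each of ceil(pop_size / offspring_per_family) F2 plants (two independent
    F1 gametes; the F1 is heterozygous everywhere, so an F1 gamete *is* its
    inheritance pattern) contributes ``offspring_per_family`` selfed F3
    offspring (two independent gametes of that F2).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    positions = draw_snp_positions(cfg, rng)
    n_fam = math.ceil(cfg.pop_size / cfg.offspring_per_family)
    fam_of = np.repeat(np.arange(n_fam), cfg.offspring_per_family)[: cfg.pop_size]
    blocks = []
    for name, pos in zip(cfg.chrom_names, positions):
        if len(pos) == 0:
            warnings.warn(f"chromosome {name} has no SNPs; contributing no columns")
            continue
        rec = _recomb_fractions(pos, cfg.bp_per_cm)
        # F2 haplotypes: two independent F1 gametes per family
        hap_a = _gamete_patterns(rng, n_fam, rec)
        hap_b = _gamete_patterns(rng, n_fam, rec)
        # F3: two gametes of the family's F2, each selecting hap_a/hap_b
        geno = np.zeros((cfg.pop_size, len(pos)), dtype=np.int8)
        for _ in range(2):
            choice = _gamete_patterns(rng, cfg.pop_size, rec)
            a = hap_a[fam_of]
            b = hap_b[fam_of]
            # gamete allele = b XOR ((a XOR b) AND choice)
            geno += (b ^ ((a ^ b) & choice)).astype(np.int8)
        blocks.append(geno)
    genotypes = (
        np.concatenate(blocks, axis=1)
        if blocks
        else np.zeros((cfg.pop_size, 0), dtype=np.int8)
    )
    kept = [(n, p) for n, p in zip(cfg.chrom_names, positions) if len(p) > 0]
    return SimGenotypes(
        tuple(n for n, _ in kept), [p for _, p in kept], genotypes
    )


def assign_phenotypes(sim: SimGenotypes, cfg: SimConfig, rng=None) -> np.ndarray:
    """Additive phenotypes y = sum_q a_q s_q (g_q - 1) + e.

    Each QTL maps to the nearest simulated SNP column.  With
    ``cfg.heritability`` set, the residual sd is chosen so the realised
    genetic variance is that fraction of the total; otherwise
    ``cfg.residual_sd`` (default 1) is used.  No QTLs -> pure noise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genetic = np.zeros(sim.n_individuals)
    for q in cfg.qtls:
        col = sim.column_of(q.chrom, q.pos)
        sign = 1.0 if q.source_parent == 1 else -1.0
        genetic += q.effect * sign * (sim.genotypes[:, col].astype(float) - 1.0)
    if cfg.heritability is not None:
        var_g = genetic.var()
        if var_g == 0:
            raise ValueError(
                "heritability specified but no genetic variance (no QTLs?)"
            )
        sd_e = math.sqrt(var_g * (1.0 - cfg.heritability) / cfg.heritability)
    else:
        sd_e = cfg.effective_residual_sd
    return genetic + rng.normal(0.0, sd_e, size=sim.n_individuals)


def select_extreme_pools(
    phenotypes: np.ndarray, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(ES, ET) index sets: the lowest-phenotype n_ES individuals and the
    highest n_ET.  Ties at a cut are broken by stable (ascending) index
    order.  Raises when the two tails would overlap."""
    n_es, n_et = cfg.pool_sizes
    if n_es + n_et > phenotypes.size:
        raise ValueError("pool sizes exceed the population; tails overlap")
    order = np.argsort(phenotypes, kind="stable")
    # stable sort resolves ties by ascending index, so ES takes the
    # smallest-index ties at its cut and ET the largest-index ties at its
    es = np.sort(order[:n_es])
    et = np.sort(order[phenotypes.size - n_et :])
    return es, et


def sequence_pools(
    sim: SimGenotypes,
    es: np.ndarray,
    et: np.ndarray,
    cfg: SimConfig,
    rng=None,
) -> pd.DataFrame:
    """Pooled sequencing of the two bulks -> package-standard count table.

    Per SNP and pool: true pooled parent-1 frequency f = mean(genotype)/2,
    depth ~ NegBin(mean, dispersion) truncated at 1 (Poisson when
    ``depth_dispersion`` is None), parent-1 reads ~ Binomial(depth, f') with
    f' = f(1-e) + (1-f)e for sequencing error rate e.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if len(es) == 0 or len(et) == 0:
        raise ValueError("empty pool")
    n_snps = sim.genotypes.shape[1]
    rows = {}
    for pool_name, idx, mean_depth in (
        ("ES", es, cfg.mean_depth[0]),
        ("ET", et, cfg.mean_depth[1]),
    ):
        f = sim.genotypes[idx].mean(axis=0) / 2.0
        e = cfg.seq_error
        f_obs = f * (1.0 - e) + (1.0 - f) * e
        if cfg.depth_dispersion is None:
            depth = rng.poisson(mean_depth, size=n_snps)
        else:
            k = cfg.depth_dispersion
            depth = rng.poisson(rng.gamma(k, mean_depth / k, size=n_snps))
        depth = np.maximum(depth, 1)
        n1 = rng.binomial(depth, f_obs)
        rows[f"n1_{pool_name}"] = n1
        rows[f"n2_{pool_name}"] = depth - n1
    chrom = np.concatenate(
        [
            np.repeat(name, len(pos))
            for name, pos in zip(sim.chrom_names, sim.positions)
        ]
    )
    pos = np.concatenate(sim.positions) if sim.positions else np.array([], dtype=int)
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, **{c: rows[c] for c in COUNT_COLUMNS}}
    )


@dataclass
class SimResult:
    """Everything one simulated experiment produced."""

    config: SimConfig
    genotypes: SimGenotypes
    phenotypes: np.ndarray
    es: np.ndarray
    et: np.ndarray
    counts: pd.DataFrame


def simulate_pools(cfg: SimConfig, rng=None) -> SimResult:
    """Run the full generator: genotypes, phenotypes, tail selection,
    pooled sequencing.  Deterministic given ``cfg.seed``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sim = simulate_f3_genotypes(cfg, rng)
    phen = assign_phenotypes(sim, cfg, rng)
    es, et = select_extreme_pools(phen, cfg)
    counts = sequence_pools(sim, es, et, cfg, rng)
    return SimResult(cfg, sim, phen, es, et, counts)


def config_to_yaml(cfg: SimConfig, path) -> None:
    """Serialise a SimConfig (QTLs included) to YAML."""
    d = asdict(cfg)
    d["qtls"] = [asdict(q) for q in cfg.qtls]
    if d["snp_positions"] is not None:
        d["snp_positions"] = [list(map(int, p)) for p in d["snp_positions"]]
    d["chrom_lengths"] = list(d["chrom_lengths"])
    d["chrom_names"] = list(d["chrom_names"])
    d["pool_sizes"] = list(d["pool_sizes"])
    d["mean_depth"] = list(d["mean_depth"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    """Load a SimConfig from YAML written by :func:`config_to_yaml`."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["qtls"] = tuple(Qtl(**q) for q in d.get("qtls", ()))
    for key in ("chrom_lengths", "chrom_names", "pool_sizes", "mean_depth"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if d.get("snp_positions") is not None:
        d["snp_positions"] = tuple(
            np.asarray(p, dtype=np.int64) for p in d["snp_positions"]
        )
    return SimConfig(**d)
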