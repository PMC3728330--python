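"""F3 pooled-segregant simulator: meiosis, selection, pooled sequencing."""

import numpy as np
import pandas as pd
import pytest

from bsaqtl.simdata import (
    Qtl,
    SimConfig,
    SimGenotypes,
    _gamete_patterns,
    _recomb_fractions,
    assign_phenotypes,
    config_from_yaml,
    config_to_yaml,
    draw_snp_positions,
    select_extreme_pools,
    sequence_pools,
    simulate_f3_genotypes,
    simulate_pools,
)


class TestConfigValidation:
    def test_defaults_match_study_design(self):
        cfg = SimConfig()
        assert cfg.pop_size == 10_800
        assert cfg.pool_sizes == (430, 385)
        assert cfg.tail_fraction == 0.04
        assert cfg.mean_depth == (70.0, 89.0)
        assert len(cfg.chrom_lengths) == 12

    @pytest.mark.parametrize("tail", [0.0, 0.5, 0.9])
    def test_tail_fraction_bounds(self, tail):
        with pytest.raises(ValueError):
            SimConfig(tail_fraction=tail, pool_sizes=(1, 1), pop_size=100)

    def test_pool_exceeding_tail_capacity_rejected(self):
        with pytest.raises(ValueError, match="tail capacity"):
            SimConfig(pop_size=1000, tail_fraction=0.04, pool_sizes=(41, 40))

    def test_qtl_off_declared_chromosome_rejected(self):
        with pytest.raises(ValueError, match="not declared"):
            SimConfig(qtls=(Qtl("chrXX", 100, 1.0),))

    def test_qtl_beyond_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SimConfig(qtls=(Qtl("chr01", 10**9, 1.0),))

    def test_heritability_and_residual_sd_exclusive(self):
        with pytest.raises(ValueError):
            SimConfig(heritability=0.5, residual_sd=1.0)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            Qtl("chr01", 100, -1.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(
            chrom_lengths=(10**7, 2 * 10**7),
            qtls=(Qtl("chr02", 5_000_000, 0.8, 2),),
            heritability=0.4,
            pop_size=500,
            tail_fraction=0.2,
            pool_sizes=(100, 100),
            seed=3,
        )
        path = tmp_path / "cfg.yaml"
        config_to_yaml(cfg, path)
        assert config_from_yaml(path) == cfg


class TestMeiosis:
    def test_haldane_recombination_fraction_near_one_percent_at_200kb(self, rng):
        """Adjacent SNPs 200 kb apart (~1 cM) recombine in ~1% of meioses."""
        rec = _recomb_fractions(np.array([1, 200_001]), 200_000.0)
        pat = _gamete_patterns(rng, 200_000, rec)
        frac = float((pat[:, 0] != pat[:, 1]).mean())
        assert frac == pytest.approx(0.01, abs=0.002)

    def test_f3_genotype_frequencies(self):
        # selfing an F2 (1/4, 1/2, 1/4) gives F3 (3/8, 1/4, 3/8)
        cfg = SimConfig(
            chrom_lengths=(10**6,) * 3,
            snp_positions=(np.array([500_000]),) * 3,
            pop_size=30_000,
            tail_fraction=0.1,
            pool_sizes=(10, 10),
            seed=1,
        )
        sim = simulate_f3_genotypes(cfg)
        counts = np.array([(sim.genotypes == k).mean() for k in (0, 1, 2)])
        assert counts == pytest.approx([3 / 8, 1 / 4, 3 / 8], abs=0.01)
        assert sim.genotypes.mean() / 2 == pytest.approx(0.5, abs=0.01)

    def test_genotype_codes_in_range(self):
        cfg = SimConfig(
            chrom_lengths=(10**6,),
            pop_size=200,
            tail_fraction=0.1,
            pool_sizes=(10, 10),
            mean_spacing=50_000,
            seed=2,
        )
        sim = simulate_f3_genotypes(cfg)
        assert set(np.unique(sim.genotypes)) <= {0, 1, 2}

    def test_zero_snp_chromosome_contributes_no_columns(self):
        cfg = SimConfig(
            chrom_lengths=(10**6, 10**6),
            snp_positions=(np.array([100, 200]), np.array([], dtype=int)),
            pop_size=50,
            tail_fraction=0.2,
            pool_sizes=(5, 5),
            seed=0,
        )
        with pytest.warns(UserWarning, match="no SNPs"):
            sim = simulate_f3_genotypes(cfg)
        assert sim.genotypes.shape == (50, 2)
        assert sim.chrom_names == ("chr01",)


class TestPhenotypes:
    def _sim(self, cfg):
        return simulate_f3_genotypes(cfg, np.random.default_rng(cfg.seed))

    def test_no_qtls_pure_noise_unit_variance(self):
        cfg = SimConfig(
            chrom_lengths=(10**6,),
            snp_positions=(np.array([100]),),
            pop_size=20_000,
            tail_fraction=0.1,
            pool_sizes=(10, 10),
            seed=4,
        )
        sim = self._sim(cfg)
        phen = assign_phenotypes(sim, cfg)
        assert phen.var() == pytest.approx(1.0, rel=0.05)

    def test_single_qtl_heritability_recovered_by_regression(self):
        cfg = SimConfig(
            chrom_lengths=(10**6,),
            snp_positions=(np.array([500_000]),),
            qtls=(Qtl("chr01", 500_000, 1.0),),
            heritability=0.5,
            pop_size=20_000,
            tail_fraction=0.1,
            pool_sizes=(10, 10),
            seed=5,
        )
        sim = self._sim(cfg)
        phen = assign_phenotypes(sim, cfg, np.random.default_rng(55))
        g = sim.genotypes[:, 0].astype(float)
        r2 = np.corrcoef(g, phen)[0, 1] ** 2
        assert r2 == pytest.approx(0.5, abs=0.03)

    def test_effect_sign_flip_flips_correlation(self):
        base = dict(
            chrom_lengths=(10**6,),
            snp_positions=(np.array([500_000]),),
            pop_size=5_000,
            tail_fraction=0.1,
            pool_sizes=(10, 10),
            residual_sd=0.5,
            seed=6,
        )
        cfg1 = SimConfig(qtls=(Qtl("chr01", 500_000, 1.0, 1),), **base)
        cfg2 = SimConfig(qtls=(Qtl("chr01", 500_000, 1.0, 2),), **base)
        sim = self._sim(cfg1)
        rho1 = np.corrcoef(
            sim.genotypes[:, 0], assign_phenotypes(sim, cfg1, np.random.default_rng(9))
        )[0, 1]
        rho2 = np.corrcoef(
            sim.genotypes[:, 0], assign_phenotypes(sim, cfg2, np.random.default_rng(9))
        )[0, 1]
        assert rho1 > 0.5 and rho2 < -0.5

    def test_heritability_without_qtls_rejected(self):
        cfg = SimConfig(
            chrom_lengths=(10**6,),
            snp_positions=(np.array([100]),),
            heritability=0.5,
            pop_size=100,
            tail_fraction=0.1,
            pool_sizes=(5, 5),
            seed=0,
        )
        sim = self._sim(cfg)
        with pytest.raises(ValueError, match="genetic variance"):
            assign_phenotypes(sim, cfg)


class TestSelection:
    def _cfg(self, pop, pools):
        return SimConfig(
            chrom_lengths=(10**6,),
            snp_positions=(np.array([100]),),
            pop_size=pop,
            tail_fraction=0.45,
            pool_sizes=pools,
        )

    def test_extremes_selected(self):
        phen = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        es, et = select_extreme_pools(phen, self._cfg(5, (1, 1)))
        assert list(es) == [1] and list(et) == [4]

    def test_ties_broken_by_index_order(self):
        phen = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        es, et = select_extreme_pools(phen, self._cfg(6, (2, 2)))
        assert list(es) == [0, 1] and list(et) == [4, 5]

    def test_overlapping_tails_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            select_extreme_pools(np.arange(5.0), self._cfg(7, (3, 3)))


class TestSequencing:
    def _genotypes(self, value, n_ind=40, n_snp=30):
        return SimGenotypes(
            ("chr01",),
            [np.arange(1, n_snp + 1) * 1000],
            np.full((n_ind, n_snp), value, dtype=np.int8),
        )

    def _cfg(self, **kw):
        defaults = dict(
            chrom_lengths=(10**6,),
            snp_positions=(np.arange(1, 31) * 1000,),
            pop_size=40,
            tail_fraction=0.45,
            pool_sizes=(15, 15),
            seed=8,
        )
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_fixed_parent2_pool_yields_zero_parent1_reads(self):
        sim = self._genotypes(0)
        cfg = self._cfg()
        counts = sequence_pools(sim, np.arange(15), np.arange(15, 30), cfg)
        assert (counts["n1_ES"] == 0).all() and (counts["n1_ET"] == 0).all()
        assert (counts["n2_ES"] >= 1).all()

    def test_heterozygous_pool_near_half(self):
        sim = self._genotypes(1, n_snp=2000)
        cfg = self._cfg(
            snp_positions=(np.arange(1, 2001) * 100,), mean_depth=(100.0, 100.0),
            depth_dispersion=None,
        )
        counts = sequence_pools(sim, np.arange(15), np.arange(15, 30), cfg)
        mean_n1 = counts["n1_ES"].mean()
        assert mean_n1 == pytest.approx(50.0, rel=0.03)

    def test_sequencing_error_pulls_fixed_sites_off_zero(self):
        sim = self._genotypes(0, n_snp=2000)
        cfg = self._cfg(
            snp_positions=(np.arange(1, 2001) * 100,),
            seq_error=0.01,
            mean_depth=(100.0, 100.0),
            depth_dispersion=None,
        )
        counts = sequence_pools(sim, np.arange(15), np.arange(15, 30), cfg)
        rate = counts["n1_ES"].sum() / (counts["n1_ES"] + counts["n2_ES"]).sum()
        assert rate == pytest.approx(0.01, rel=0.2)

    def test_empty_pool_rejected(self):
        sim = self._genotypes(1)
        with pytest.raises(ValueError, match="empty pool"):
            sequence_pools(sim, np.array([], dtype=int), np.arange(5), self._cfg())


class TestEndToEnd:
    def _null_cfg(self, seed):
        return SimConfig(
            chrom_lengths=(20_000_000,) * 2,
            mean_spacing=40_000,
            pop_size=1_000,
            tail_fraction=0.25,
            pool_sizes=(200, 200),
            mean_depth=(60.0, 60.0),
            seed=seed,
        )

    def test_same_seed_bitwise_identical_tables(self):
        a = simulate_pools(self._null_cfg(13)).counts
        b = simulate_pools(self._null_cfg(13)).counts
        pd.testing.assert_frame_equal(a, b)

    def test_null_genome_mean_frequency_near_half(self):
        # more chromosomes and individuals than the determinism fixture:
        # the genome-mean is averaging correlated pool-composition drift
        cfg = SimConfig(
            chrom_lengths=(20_000_000,) * 6,
            mean_spacing=40_000,
            pop_size=4_000,
            tail_fraction=0.25,
            pool_sizes=(400, 400),
            mean_depth=(60.0, 60.0),
            seed=14,
        )
        counts = simulate_pools(cfg).counts
        total = sum(counts[c] for c in ("n1_ES", "n2_ES", "n1_ET", "n2_ET"))
        freq = (counts["n1_ES"] + counts["n1_ET"]) / total
        assert 0.48 <= freq.mean() <= 0.52

    def test_strong_qtl_shifts_pools_in_configured_direction(self):
        """With a strong QTL, the high-tail pool is enriched for the
        configured source parent's allele in nearly every replicate."""
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            source = 1 if rep % 2 == 0 else 2
            cfg = SimConfig(
                chrom_lengths=(10_000_000,),
                mean_spacing=100_000,
                qtls=(Qtl("chr01", 5_000_000, 1.0, source),),
                heritability=0.4,
                pop_size=1_000,
                tail_fraction=0.25,
                pool_sizes=(200, 200),
                mean_depth=(60.0, 60.0),
                seed=100 + rep,
            )
            res = simulate_pools(cfg)
            i = int(np.argmin(np.abs(res.counts["pos"].to_numpy() - 5_000_000)))
            row = res.counts.iloc[i]
            f_es = row["n1_ES"] / (row["n1_ES"] + row["n2_ES"])
            f_et = row["n1_ET"] / (row["n1_ET"] + row["n2_ET"])
            expected_sign = 1.0 if source == 1 else -1.0
            hits += int(np.sign(f_et - f_es) == expected_sign)
        assert hits >= int(0.95 * n_reps) - 1  # scaled-down replicate count

    def test_snp_positions_sorted_and_within_bounds(self, rng):
        cfg = self._null_cfg(15)
        positions = draw_snp_positions(cfg, rng)
        for pos, length in zip(positions, cfg.chrom_lengths):
            assert (np.diff(pos) >= 0).all()
            assert pos[0] >= 1 and pos[-1] <= length
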