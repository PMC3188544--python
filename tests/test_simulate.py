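"""Tests of the synthetic panels, admixed cohorts and phenotypes."""

import numpy as np
import pytest
from scipy.stats import kstest, spearmanr

from transheight.association import scan, snp_regression, zscore_transform
from transheight.errors import InvalidConfigError
from transheight.ld import LDCache, fst_two_pop
from transheight.simulate import (
    SimulationConfig,
    expected_admixed_freq,
    simulate_admixed_cohort,
    simulate_panels,
    simulate_phenotype,
)
from conftest import make_panel


def realized_fst(source, target):
    f1, f2 = source.alt_frequency(), target.alt_frequency()
    poly = ((f1 > 0) & (f1 < 1)) | ((f2 > 0) & (f2 < 1))
    return float(np.mean(fst_two_pop(f1[poly], f2[poly])))


class TestPanels:
    def test_deterministic_under_seed(self, small_config):
        a1, b1 = simulate_panels(small_config)
        a2, b2 = simulate_panels(small_config)
        assert np.array_equal(a1.haplotypes, a2.haplotypes)
        assert np.array_equal(b1.haplotypes, b2.haplotypes)
        assert a1.variants.equals(a2.variants)

    def test_panel_invariants(self, panels):
        for p in panels:
            assert p.n_haplotypes % 2 == 0
            assert set(np.unique(p.haplotypes)) <= {0, 1}
            assert (np.diff(p.variants["pos"]) > 0).all()

    def test_realized_fst_matches_target(self):
        # frequency-based oracle over all variants at the calibrated target
        cfg = SimulationConfig(n_variants=10_000, n_haplotypes=400,
                               divergence_F=0.15, seed=3)
        src, tgt = simulate_panels(cfg)
        assert abs(realized_fst(src, tgt) - 0.15) < 0.03

    def test_no_divergence_limit(self):
        cfg = SimulationConfig(n_variants=2_000, n_haplotypes=1_000,
                               divergence_F=1e-6, seed=4)
        src, tgt = simulate_panels(cfg)
        diff = np.abs(src.alt_frequency() - tgt.alt_frequency())
        assert diff.mean() < 0.03
        assert realized_fst(src, tgt) < 0.01

    def test_fst_monotone_in_divergence(self):
        grid = [0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
        vals = []
        for f in grid:
            cfg = SimulationConfig(n_variants=4_000, divergence_F=f, seed=5)
            vals.append(realized_fst(*simulate_panels(cfg)))
        rho = spearmanr(grid, vals).statistic
        assert rho > 0.9

    def test_block_ld_structure(self, panels):
        # near pairs share a founder block, far pairs do not
        src, _ = panels
        ld = LDCache(src)
        poly = np.flatnonzero(src.is_polymorphic())
        near, far = [], []
        rng = np.random.default_rng(0)
        for i in rng.choice(poly, 150, replace=False):
            rows, _, r2 = ld.window_ld(int(i), 300_000)
            dist = np.abs(
                src.variants["pos"].to_numpy()[rows]
                - src.variants["pos"].iat[int(i)]
            )
            ok = ~np.isnan(r2) & (rows != i)
            near.extend(r2[ok & (dist <= 4_000)])
            far.extend(r2[ok & (dist >= 100_000)])
        assert np.mean(near) > np.mean(far)
        assert np.mean(far) < 0.05

    def test_invalid_configs(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_variants=0)
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_variants=10, variant_spacing=100,
                             block_length_mean=1e9)
        with pytest.raises(InvalidConfigError):
            SimulationConfig(heritability_target=1.0)
        with pytest.raises(InvalidConfigError):
            SimulationConfig(divergence_F=0.0)


class TestAdmixedCohort:
    def test_alpha_one_is_fully_african(self):
        cfg = SimulationConfig(n_variants=300, n_haplotypes=60,
                               admixture_alpha=1.0, n_studies=1,
                               per_study_n=80, seed=9)
        cohort = simulate_admixed_cohort(simulate_panels(cfg), cfg)
        assert cohort.local_ancestry.max() == 0  # European count 0 everywhere

    def test_mean_european_dosage(self):
        # binomial expectation over tracts: 2 x (1 - alpha) chromosomes
        cfg = SimulationConfig(n_variants=200, n_haplotypes=100,
                               admixture_alpha=0.8, n_studies=1,
                               per_study_n=5_000, seed=10)
        cohort = simulate_admixed_cohort(simulate_panels(cfg), cfg)
        assert abs(cohort.local_ancestry.mean() - 0.4) < 0.02

    def test_expected_admixed_frequency(self):
        # 8% African ancestry, f_AFR=0.54, f_EUR=1.0
        assert expected_admixed_freq(0.54, 1.0, 0.08) == pytest.approx(0.9632)

    def test_genotype_consistent_with_ancestry_at_fixed_difference(self):
        # EUR fixed for alt, AFR fixed for ref: genotype == European dosage
        n_var, n_hap = 50, 40
        eur = make_panel(np.ones((n_var, n_hap)), population="EUR")
        afr = make_panel(np.zeros((n_var, n_hap)), population="AFR")
        cfg = SimulationConfig(n_variants=n_var, n_haplotypes=n_hap,
                               variant_spacing=1000, block_length_mean=10_000,
                               admixture_alpha=0.5, tract_length_mean=10_000,
                               n_studies=1, per_study_n=200, seed=11)
        cohort = simulate_admixed_cohort((eur, afr), cfg)
        assert np.array_equal(cohort.genotypes, cohort.local_ancestry)

    def test_genotype_equals_haplotype_sum_range(self, cohort):
        assert cohort.genotypes.min() >= 0
        assert cohort.genotypes.max() <= 2
        assert set(np.unique(cohort.local_ancestry)) <= {0, 1, 2}

    def test_deterministic(self, panels, small_config):
        c1 = simulate_admixed_cohort(panels, small_config)
        c2 = simulate_admixed_cohort(panels, small_config)
        assert np.array_equal(c1.genotypes, c2.genotypes)
        assert np.array_equal(c1.local_ancestry, c2.local_ancestry)

    def test_x_linked_male_coding(self):
        cfg = SimulationConfig(n_variants=100, n_haplotypes=60, x_linked=True,
                               chromosome="X", n_studies=1, per_study_n=150,
                               seed=12)
        cohort = simulate_admixed_cohort(simulate_panels(cfg), cfg)
        males = cohort.individuals["sex"].to_numpy() == 1
        assert (cohort.genotypes[males] % 2 == 0).all()  # 0/2 coding
        assert (cohort.local_ancestry[males] % 2 == 0).all()

    def test_missing_rate(self):
        cfg = SimulationConfig(n_variants=200, n_haplotypes=60,
                               missing_rate=0.1, n_studies=1, per_study_n=200,
                               seed=13)
        cohort = simulate_admixed_cohort(simulate_panels(cfg), cfg)
        frac = (cohort.genotypes == -1).mean()
        assert 0.07 < frac < 0.13
        assert np.isnan(cohort.genotype(cohort.variants["id"].iat[0])).any()

    def test_empty_panel_errors(self, small_config):
        import pandas as pd
        from transheight.panels import HaplotypePanel
        with pytest.raises(InvalidConfigError):
            empty = HaplotypePanel.__new__(HaplotypePanel)
            empty.variants = pd.DataFrame(
                columns=["chrom", "pos", "id", "ref", "alt"]
            )
            empty.haplotypes = np.zeros((0, 4), np.uint8)
            empty._index = {}
            simulate_admixed_cohort((empty, empty), small_config)


class TestPhenotype:
    def test_null_phenotype_gives_uniform_p(self):
        # ~1 variant per block and every-5th thinning keep the 2,000
        # retained tests quasi-independent (the KS reference assumes
        # independent P-values; within-block duplicates would break it)
        cfg = SimulationConfig(n_variants=10_000, n_haplotypes=200,
                               block_length_mean=1_000, n_studies=1,
                               per_study_n=600, seed=14)
        cohort = simulate_admixed_cohort(simulate_panels(cfg), cfg)
        cohort = simulate_phenotype(cohort, cfg)
        z = zscore_transform(
            cohort.height,
            covariates=cohort.individuals[["sex", "age", "disease"]].to_numpy(float),
        )
        tab = scan(z, cohort.genotypes.astype(float),
                   covariates=cohort.local_ancestry.mean(axis=1))
        p = tab["P"].dropna().to_numpy()[::5]
        assert p.size >= 1_500
        assert kstest(p, "uniform").pvalue > 0.01

    def test_single_causal_recovery(self):
        # beta = 0.3 Z units, MAF 0.3, n = 4000: estimate within 2 SE
        rng = np.random.default_rng(15)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            g = rng.binomial(2, 0.3, 4_000).astype(float)
            y = 0.3 * g + rng.standard_normal(4_000)
            res = snp_regression(zscore_transform(y), g)
            total_sd = np.sqrt(1.0 + 0.3**2 * 2 * 0.3 * 0.7)
            if abs(res.beta - 0.3 / total_sd) < 2 * res.se:
                hits += 1
        assert hits >= 90

    def test_heritability_scaling(self, panels):
        cfg = SimulationConfig(n_variants=800, n_haplotypes=200, n_studies=2,
                               per_study_n=300, seed=7,
                               causal_effects=[("rs1", 0.5), ("rs30", -0.4)],
                               heritability_target=0.5)
        cohort = simulate_admixed_cohort(panels, cfg)
        cohort = simulate_phenotype(cohort, cfg)
        g = (0.5 * cohort.genotype("rs1") - 0.4 * cohort.genotype("rs30"))
        latent = (cohort.height - 170.0
                  - cfg.sex_effect * cohort.individuals["sex"].to_numpy()
                  - cfg.age_effect * (cohort.individuals["age"].to_numpy() - 45)
                  - cfg.disease_effect * cohort.individuals["disease"].to_numpy()
                  ) / cfg.height_scale
        h2 = np.var(g) / np.var(latent)
        assert abs(h2 - 0.5) < 0.07

    def test_deterministic(self, panels, small_config):
        c1 = simulate_phenotype(simulate_admixed_cohort(panels, small_config),
                                small_config)
        c2 = simulate_phenotype(simulate_admixed_cohort(panels, small_config),
                                small_config)
        assert np.array_equal(c1.height, c2.height)

    def test_errors(self, cohort, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(),
                                  "heritability_target": 0.5})
        with pytest.raises(InvalidConfigError):
            simulate_phenotype(cohort, cfg)  # h2 > 0 without causal effects
        cfg2 = SimulationConfig(**{**small_config.to_dict(),
                                   "causal_effects": [["nope", 0.1]]})
        with pytest.raises(InvalidConfigError):
            simulate_phenotype(cohort, cfg2)
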