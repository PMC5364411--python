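"""Synthetic GWAS generator: LD structure, liability cohorts, permutations."""

import numpy as np
import pytest
from scipy import stats as st

import crosstrait as ct
from crosstrait.types import (
    CohortDesign,
    GenerationError,
    GeneticArchitecture,
    ParameterError,
)


class TestReferencePanel:
    def test_determinism(self):
        a = ct.simulate_reference_panel(80, 120, 20, seed=9)
        b = ct.simulate_reference_panel(80, 120, 20, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.block_bounds == b.block_bounds
        c = ct.simulate_reference_panel(80, 120, 20, seed=10)
        assert not np.array_equal(a.haplotypes, c.haplotypes)

    def test_block_count_and_cross_block_independence(self, small_panel):
        # ~400/25 = 16 blocks expected
        assert 8 <= len(small_panel.block_bounds) <= 32
        # blocks are generated independently: cross-block r2 is pure noise,
        # while within-block neighbours are strongly correlated
        H = small_panel.haplotypes.astype(float)
        X = (H - H.mean(0)) / H.std(0)
        R = (X.T @ X) / H.shape[0]
        (s0, e0), (s1, e1) = small_panel.block_bounds[:2]
        cross = R[s0:e0, s1:e1] ** 2
        assert cross.mean() < 3.0 / H.shape[0]  # E[r2] = 1/n under independence

    def test_ld_decays_with_distance_within_blocks(self, small_panel):
        H = small_panel.haplotypes.astype(float)
        X = (H - H.mean(0)) / H.std(0)
        R = (X.T @ X) / H.shape[0]
        adj, far = [], []
        for s, e in small_panel.block_bounds:
            if e - s < 6:
                continue
            for j in range(s, e - 1):
                adj.append(R[j, j + 1] ** 2)
            for j in range(s, e - 5):
                far.append(R[j, j + 5] ** 2)
        assert np.mean(adj) > np.mean(far)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            ct.simulate_reference_panel(10, 1000, 20, seed=0)
        with pytest.raises(ParameterError):
            ct.simulate_reference_panel(100, 50, 20, seed=0)


class TestEffectSizes:
    def test_independent_traits_uncorrelated_effects(self, small_panel):
        arch = GeneticArchitecture(h2_liab_1=0.3, h2_liab_2=0.3, r_g=0.0,
                                   prop_causal=1.0)
        eff = ct.draw_effect_sizes(arch, small_panel.variants, seed=11)
        b1, b2 = eff["beta1"].to_numpy(), eff["beta2"].to_numpy()
        r = np.corrcoef(b1, b2)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(b1))

    def test_perfect_correlation_equal_scale(self, small_panel):
        arch = GeneticArchitecture(h2_liab_1=0.2, h2_liab_2=0.2, r_g=1.0,
                                   prop_causal=0.5)
        eff = ct.draw_effect_sizes(arch, small_panel.variants, seed=12)
        np.testing.assert_allclose(eff["beta1"], eff["beta2"], atol=1e-12)

    def test_generating_correlation_recovered(self):
        # the study's generating truth: r_g = 0.143 over 5,000 causal variants
        m = 10_000
        variants = ct.simulate_sumstats_direct(
            np.ones(m), 0.01, 0.01, 0.0, 100, 100, seed=0
        )[0].variants
        arch = GeneticArchitecture(h2_liab_1=0.082, h2_liab_2=0.23, r_g=0.143,
                                   prop_causal=0.5)
        eff = ct.draw_effect_sizes(arch, variants, seed=13)
        causal = eff["causal"].to_numpy()
        assert causal.sum() == 5_000
        r = np.corrcoef(eff.loc[causal, "beta1"], eff.loc[causal, "beta2"])[0, 1]
        assert abs(r - 0.143) < 3 / np.sqrt(5_000)

    def test_effect_variance_sums_to_h2(self, small_panel):
        arch = GeneticArchitecture(h2_liab_1=0.3, h2_liab_2=0.1, prop_causal=0.5)
        tot1, tot2 = [], []
        for s in range(30):
            eff = ct.draw_effect_sizes(arch, small_panel.variants, seed=100 + s)
            tot1.append((eff["beta1"] ** 2).sum())
            tot2.append((eff["beta2"] ** 2).sum())
        assert abs(np.mean(tot1) - 0.3) < 0.02
        assert abs(np.mean(tot2) - 0.1) < 0.01


class TestLiabilityCohort:
    def test_median_threshold_gives_half_cases(self, small_panel):
        arch = GeneticArchitecture(h2_liab_1=0.0, h2_liab_2=0.0, r_g=0.0,
                                   K_1=0.5, K_2=0.5)
        eff = ct.draw_effect_sizes(arch, small_panel.variants, seed=20)
        out = ct.sample_unselected(small_panel, eff, arch, 20_000, 1, seed=21)
        assert abs(out["case"].mean() - 0.5) < 3 * np.sqrt(0.25 / 20_000)

    def test_no_genetic_signal_no_case_control_difference(self, small_panel):
        arch = GeneticArchitecture(h2_liab_1=0.0, h2_liab_2=0.0, r_g=0.0,
                                   K_1=0.3, K_2=0.3)
        eff = ct.draw_effect_sizes(arch, small_panel.variants, seed=22)
        out = ct.sample_unselected(small_panel, eff, arch, 5_000, 1, seed=23)
        g = out["genetic_value"]
        assert np.all(g == 0)  # h2 = 0 implies zero effects hence zero values

    def test_unselected_case_count_binomial(self, small_panel):
        arch = GeneticArchitecture(K_1=1 / 100, K_2=1 / 100, h2_liab_1=0.1,
                                   h2_liab_2=0.1, prop_causal=0.2)
        eff = ct.draw_effect_sizes(arch, small_panel.variants, seed=24)
        n = 100_000
        out = ct.sample_unselected(small_panel, eff, arch, n, 1, seed=25)
        count = out["case"].sum()
        assert abs(count - n / 100) < 3 * np.sqrt(n * 0.01 * 0.99)

    def test_heritability_round_trip(self, small_panel):
        # variance of genetic values in an unselected sample recovers h2
        arch = GeneticArchitecture(h2_liab_1=0.3, h2_liab_2=0.3, K_1=0.2,
                                   K_2=0.2, prop_causal=0.2)
        vs = []
        for s in range(10):
            eff = ct.draw_effect_sizes(arch, small_panel.variants, seed=300 + s)
            out = ct.sample_unselected(small_panel, eff, arch, 2_000, 1,
                                       seed=400 + s)
            vs.append(out["genetic_value"].var())
        assert abs(np.mean(vs) - 0.3) < 0.05

    def test_unreachable_case_count_raises(self, small_panel, desk_arch,
                                           desk_effects):
        design = CohortDesign(n_cases_1=500, n_controls_1=10)
        with pytest.raises(GenerationError):
            ct.simulate_liability_cohort(
                small_panel, desk_effects, desk_arch, design, 1, seed=30,
                max_attempt_factor=0.5,
            )

    def test_shared_controls_are_identical_rows(self, small_panel, desk_arch,
                                                desk_effects):
        design = CohortDesign(n_cases_1=50, n_controls_1=80, n_cases_2=50,
                              n_controls_2=80, n_shared_controls=40)
        c1, c2 = ct.simulate_bivariate_cohorts(
            small_panel, desk_effects, desk_arch, design, seed=31
        )
        np.testing.assert_array_equal(
            c1.genotypes[50:90], c2.genotypes[50:90]
        )


class TestSummaryStats:
    def test_null_p_value_calibration(self, small_panel):
        rng = np.random.default_rng(40)
        n = 600
        idx = rng.integers(0, small_panel.n_haplotypes, size=(n, 2))
        G = (small_panel.haplotypes[idx[:, 0]]
             + small_panel.haplotypes[idx[:, 1]]).astype(float)
        y = rng.integers(0, 2, n)
        stats = ct.compute_summary_stats(G, y, small_panel.variants)
        assert abs((stats.p < 0.05).mean() - 0.05) < 0.02

    def test_duplicated_variant_identical_z(self, small_panel):
        rng = np.random.default_rng(41)
        G = rng.binomial(2, 0.3, (300, 10)).astype(float)
        G[:, 5] = G[:, 0]
        y = rng.integers(0, 2, 300)
        vt = ct.VariantTable(small_panel.variants.table.iloc[:10])
        stats = ct.compute_summary_stats(G, y, vt)
        assert stats.z[0] == pytest.approx(stats.z[5], abs=1e-12)

    def test_perfect_association_dominates_null(self, small_panel):
        rng = np.random.default_rng(42)
        G = rng.binomial(2, 0.3, (300, 50)).astype(float)
        y = rng.integers(0, 2, 300)
        G[:, 0] = y  # dosage equal to phenotype
        vt = ct.VariantTable(small_panel.variants.table.iloc[:50])
        stats = ct.compute_summary_stats(G, y, vt)
        assert abs(stats.z[0]) > np.max(np.abs(stats.z[1:]))

    def test_constant_phenotype_rejected(self, small_panel):
        G = np.random.default_rng(43).binomial(2, 0.3, (100, 400)).astype(float)
        with pytest.raises(Exception):
            ct.compute_summary_stats(G, np.ones(100), small_panel.variants)


class TestStructuredPermutation:
    def test_single_cube_preserves_global_count(self):
        rng = np.random.default_rng(50)
        G = rng.binomial(2, 0.3, (200, 20)).astype(float)
        y = rng.integers(0, 2, 200)
        yp = ct.structured_permutation(G, y, n_cubes=1, seed=51)
        assert yp.sum() == y.sum()
        assert not np.array_equal(yp, y)

    def test_singleton_cubes_leave_labels_unchanged(self):
        rng = np.random.default_rng(52)
        G = rng.binomial(2, 0.4, (25, 60)).astype(float)
        y = rng.integers(0, 2, 25)
        yp = ct.structured_permutation(G, y, n_cubes=25**3, seed=53)
        np.testing.assert_array_equal(yp, y)

    def test_strata_are_respected(self, small_panel):
        arch = GeneticArchitecture(h2_liab_1=0.2, h2_liab_2=0.2, K_1=0.3,
                                   K_2=0.3, prop_causal=0.2)
        eff = ct.draw_effect_sizes(arch, small_panel.variants, seed=54)
        design = CohortDesign(n_cases_1=150, n_controls_1=250, n_strata=2,
                              stratum_fst=0.15)
        c = ct.simulate_liability_cohort(small_panel, eff, arch, design, 1,
                                         seed=55)
        yp = ct.structured_permutation(c.genotypes, c.phenotype, n_cubes=8,
                                       seed=56)
        # per-stratum case fractions preserved exactly: two well-separated
        # strata fall in disjoint cube sets, so no label crosses strata
        for s in np.unique(c.strata):
            assert yp[c.strata == s].sum() == c.phenotype[c.strata == s].sum()

    def test_per_cube_counts_preserved(self):
        rng = np.random.default_rng(57)
        G = rng.binomial(2, 0.3, (500, 40)).astype(float)
        y = rng.integers(0, 2, 500)
        # global count preservation holds for any cube partition
        for nc in (8, 27, 64):
            yp = ct.structured_permutation(G, y, n_cubes=nc, seed=58)
            assert yp.sum() == y.sum()


class TestInjectMisdiagnosis:
    def test_boundary_fractions(self):
        rng = np.random.default_rng(60)
        B = rng.binomial(2, 0.3, (50, 30))
        pool = rng.binomial(2, 0.7, (80, 30))
        out0, rows0 = ct.inject_misdiagnosis(B, pool, 0.0, seed=61)
        np.testing.assert_array_equal(out0, B)
        assert len(rows0) == 0
        out1, rows1 = ct.inject_misdiagnosis(B, pool, 1.0, seed=62)
        assert len(rows1) == 50
        pool_rows = {tuple(r) for r in pool}
        assert all(tuple(r) in pool_rows for r in out1)

    def test_exact_replacement_count(self):
        rng = np.random.default_rng(63)
        B = rng.binomial(2, 0.3, (2_000, 5))
        pool = rng.binomial(2, 0.3, (500, 5))
        out, rows = ct.inject_misdiagnosis(B, pool, 0.05, seed=64)
        assert len(rows) == 100
        changed = np.any(out != B, axis=1)
        assert set(np.where(changed)[0]) <= set(rows)

    def test_insufficient_pool(self):
        B = np.zeros((100, 4), int)
        pool = np.ones((3, 4), int)
        with pytest.raises(GenerationError):
            ct.inject_misdiagnosis(B, pool, 0.5, seed=65)


class TestDirectGenerator:
    def test_shared_controls_induce_null_correlation(self):
        # with r_g = 0 the z-score correlation equals N_s / sqrt(N1 N2)
        m = 30_000
        ell = ct.simulate_ld_scores(m, seed=70)
        n1 = n2 = 10_000
        ns = 4_000
        s1, s2 = ct.simulate_sumstats_direct(
            ell, 0.0, 0.0, 0.0, n1, n2, n_shared=ns, seed=71
        )
        r = np.corrcoef(s1.z, s2.z)[0, 1]
        assert abs(r - ns / np.sqrt(n1 * n2)) < 3 / np.sqrt(m)

    def test_mean_chi2_matches_generative_model(self):
        m = 30_000
        ell = ct.simulate_ld_scores(m, seed=72)
        h2o, n = 0.2, 20_000
        s1, _ = ct.simulate_sumstats_direct(ell, h2o, 0.0, 0.0, n, n, seed=73)
        expected = 1 + n * h2o * ell.mean() / m
        assert abs((s1.z**2).mean() - expected) < 0.05 * expected

    def test_bit_reproducibility(self):
        ell = ct.simulate_ld_scores(1_000, seed=74)
        a = ct.simulate_sumstats_direct(ell, 0.1, 0.1, 0.3, 5e3, 5e3, seed=75)
        b = ct.simulate_sumstats_direct(ell, 0.1, 0.1, 0.3, 5e3, 5e3, seed=75)
        assert np.array_equal(a[0].z, b[0].z) and np.array_equal(a[1].z, b[1].z)
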