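"""PRS engine: clumping, scoring, pseudo-R2, deciles, permutation nulls."""

import numpy as np
import pandas as pd
import pytest

import crosstrait as ct
from crosstrait.prs import (
    PrsConfig,
    PrsModel,
    _panel_r2_column,
    clump,
    decile_or,
    delta_nagelkerke,
    nagelkerke_r2,
    permutation_prs,
    score,
    select_pcs,
)
from crosstrait.types import (
    CohortDesign,
    GeneticArchitecture,
    HaplotypePanel,
    SummaryStats,
    VariantTable,
)

# 40-individual fixture for the likelihood oracle (fixed literal values)
FIX_Y = np.array([0, 0, 1, 1, 1, 1, 1, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 1, 1, 1,
                  0, 0, 1, 0, 1, 0, 1, 1, 1, 1, 0, 0, 0, 1, 0, 1, 1, 1, 1, 0],
                 dtype=float)
FIX_SEX = np.array([1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0,
                    1, 0, 0, 0, 1, 0, 1, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1],
                   dtype=float)
FIX_SCORE = np.array([-1.842, -0.235, -1.267, 0.271, 0.157, -0.187, -2.517,
                      -0.539, -0.049, 0.113, -1.53, -0.478, -0.979, -0.809,
                      1.061, -0.808, -0.033, 0.884, -0.584, -0.112, 0.11,
                      0.064, -1.225, 0.076, 1.359, -1.547, 0.859, 0.119,
                      -0.641, 2.0, 0.762, -1.199, 0.075, 0.577, -0.189,
                      0.683, -0.067, 0.667, 1.439, -0.676])


def _newton_logit_ll(y, X, tol=1e-12, max_iter=100):
    """Independent Newton-Raphson logistic MLE returning the log-likelihood."""
    X = np.column_stack([np.ones(len(y)), X]) if X is not None else np.ones((len(y), 1))
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * W[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def _oracle_delta_nagelkerke(y, s, cov):
    n = len(y)
    p = y.mean()
    ll_null = n * (p * np.log(p) + (1 - p) * np.log(1 - p))
    rmax = 1 - np.exp(2 / n * ll_null)
    ll_base = _newton_logit_ll(y, cov)
    ll_full = _newton_logit_ll(y, np.column_stack([cov, s]))
    r2b = (1 - np.exp(2 / n * (ll_null - ll_base))) / rmax
    r2f = (1 - np.exp(2 / n * (ll_null - ll_full))) / rmax
    return r2f - r2b


def _stats_with_beta(variants, p_values, betas, n=10_000):
    from scipy import stats as st

    z = st.norm.isf(np.asarray(p_values) / 2)
    return SummaryStats(
        variants, z, np.asarray(p_values, float), np.full(len(betas), float(n)),
        beta=np.asarray(betas, float),
    )


class TestClump:
    def _dup_panel(self, n_copies, n_hap=200, spacing_bp=50_000):
        rng = np.random.default_rng(5)
        col = rng.binomial(1, 0.4, n_hap)
        H = np.tile(col[:, None], (1, n_copies))
        pos = np.arange(1, n_copies + 1) * spacing_bp
        table = pd.DataFrame(
            {"chrom": 1, "pos": pos, "cm": pos * 1e-6,
             "id": [f"v{j}" for j in range(n_copies)],
             "a1": "A", "a2": "G", "maf": 0.4}
        )
        return HaplotypePanel(VariantTable(table), H, [(0, n_copies)])

    def test_complete_redundancy_keeps_lowest_p(self):
        panel = self._dup_panel(3)
        stats = _stats_with_beta(panel.variants, [1e-8, 1e-4, 1e-2], [0.1] * 3)
        kept = clump(stats, panel, distance_kb=250, r2_cut=0.5)
        assert kept == {"v0"}

    def test_uncorrelated_variants_all_retained(self, small_panel):
        rng = np.random.default_rng(6)
        # one variant per block: mutually independent by construction
        idx = [s for s, e in small_panel.block_bounds]
        vt = VariantTable(small_panel.variants.table.iloc[idx])
        stats = _stats_with_beta(vt, rng.uniform(1e-6, 0.01, len(idx)),
                                 np.ones(len(idx)))
        kept = clump(stats, small_panel, distance_kb=10_000, r2_cut=0.2)
        assert kept == set(vt.ids)

    def test_matches_exhaustive_oracle_and_order_invariance(self, small_panel):
        rng = np.random.default_rng(7)
        vt = VariantTable(small_panel.variants.table.iloc[:20])
        pvals = rng.uniform(1e-8, 0.5, 20)
        stats = _stats_with_beta(vt, pvals, np.ones(20))
        kept = clump(stats, small_panel, distance_kb=50, r2_cut=0.2)

        # independent oracle: explicit greedy over a precomputed r2 matrix
        H = small_panel.haplotypes[:, :20].astype(float)
        R2 = np.corrcoef(H.T) ** 2
        pos = vt.table["pos"].to_numpy()
        order = np.argsort(pvals, kind="stable")
        assigned, oracle = np.zeros(20, bool), set()
        for i in order:
            if assigned[i]:
                continue
            assigned[i] = True
            oracle.add(vt.ids[i])
            for j in range(20):
                if not assigned[j] and abs(pos[j] - pos[i]) <= 50_000 \
                        and R2[i, j] > 0.2:
                    assigned[j] = True
        assert kept == oracle

        # row order invariance
        perm = rng.permutation(20)
        t2 = vt.table.iloc[perm].sort_values("pos").reset_index(drop=True)
        # rebuild with identical content but shuffled construction path
        stats2 = _stats_with_beta(
            VariantTable(t2),
            np.array([pvals[list(vt.ids).index(v)] for v in t2["id"]]),
            np.ones(20),
        )
        assert clump(stats2, small_panel, 50, 0.2) == kept


class TestScore:
    def _mini(self):
        pos = np.array([1_000, 2_000, 3_000])
        table = pd.DataFrame(
            {"chrom": 1, "pos": pos, "cm": pos * 1e-6,
             "id": ["v0", "v1", "v2"], "a1": "A", "a2": "G", "maf": 0.3}
        )
        return VariantTable(table)

    def test_zero_betas_zero_scores(self):
        vt = self._mini()
        stats = _stats_with_beta(vt, [0.01] * 3, [0.0] * 3)
        G = np.array([[0, 1, 2], [2, 1, 0]], float)
        np.testing.assert_array_equal(
            score(G, vt, stats, set(vt.ids), 0.5), [0.0, 0.0]
        )

    def test_single_variant_closed_form(self):
        vt = self._mini()
        stats = _stats_with_beta(vt, [0.01, 1.0, 1.0], [np.log(2), 0, 0])
        G = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        s = score(G, vt, stats, {"v0"}, 0.05)
        np.testing.assert_allclose(s, [0.0, np.log(2), 2 * np.log(2)])

    def test_allele_flip_equivalence(self):
        vt = self._mini()
        rng = np.random.default_rng(8)
        G = rng.binomial(2, 0.4, (30, 3)).astype(float)
        betas = np.array([0.3, -0.2, 0.5])
        base = score(G, vt, _stats_with_beta(vt, [0.01] * 3, betas),
                     set(vt.ids), 0.5)
        # flip variant 1 in the discovery stats: a1<->a2 and beta sign
        t = vt.table.copy()
        t.loc[1, ["a1", "a2"]] = t.loc[1, ["a2", "a1"]].to_numpy()
        flipped_betas = betas * np.array([1, -1, 1])
        flip = score(G, vt, _stats_with_beta(VariantTable(t), [0.01] * 3,
                                             flipped_betas), set(vt.ids), 0.5)
        # score(2-d) with -beta differs from score(d) with beta by 2*beta
        np.testing.assert_allclose(flip, base - 2 * betas[1], atol=1e-12)


class TestSelectPcs:
    def test_alpha_one_retains_all(self):
        rng = np.random.default_rng(9)
        G = rng.binomial(2, 0.3, (200, 50)).astype(float)
        y = rng.integers(0, 2, 200)
        pcs, idx = select_pcs(G, y, n_pcs=10, alpha=1.0)
        assert pcs.shape[1] == 10 and len(idx) == 10

    def test_null_structure_rarely_selected(self):
        rng = np.random.default_rng(10)
        G = rng.binomial(2, 0.3, (2_000, 100)).astype(float)
        y = rng.integers(0, 2, 2_000)
        _, idx = select_pcs(G, y, n_pcs=20, alpha=0.0005)
        assert len(idx) <= 1  # expected count 20 * 0.0005 = 0.01

    def test_stratum_confounding_selects_leading_pc(self, small_panel):
        arch = GeneticArchitecture(h2_liab_1=0.0, h2_liab_2=0.0, r_g=0.0,
                                   K_1=0.3, K_2=0.3)
        eff = ct.draw_effect_sizes(arch, small_panel.variants, seed=11)
        rng = np.random.default_rng(12)
        # two strata, strongly stratum-biased case fraction
        from crosstrait.simulate import _stratum_panels
        panels = _stratum_panels(small_panel, 2, 0.15, rng)
        n_per = 300
        rows, ys = [], []
        for s, frac in ((0, 0.8), (1, 0.2)):
            i1 = rng.integers(0, 200, n_per)
            i2 = rng.integers(0, 200, n_per)
            rows.append(panels[s][i1] + panels[s][i2])
            ys.append(rng.random(n_per) < frac)
        G = np.concatenate(rows).astype(float)
        y = np.concatenate(ys).astype(int)
        _, idx = select_pcs(G, y, n_pcs=10, alpha=0.0005)
        assert 0 in idx


class TestDeltaNagelkerke:
    def test_zero_variance_score(self):
        d, p = delta_nagelkerke(FIX_Y, np.zeros(40), FIX_SEX[:, None])
        assert d == 0.0 and np.isnan(p)

    def test_matches_newton_oracle_to_six_decimals(self):
        d, p = delta_nagelkerke(FIX_Y, FIX_SCORE, FIX_SEX[:, None])
        oracle = _oracle_delta_nagelkerke(FIX_Y, FIX_SCORE, FIX_SEX[:, None])
        assert d == pytest.approx(oracle, abs=1e-6)
        assert 0 < p < 1

    def test_affine_invariance(self):
        d1, _ = delta_nagelkerke(FIX_Y, FIX_SCORE, FIX_SEX[:, None])
        d2, _ = delta_nagelkerke(FIX_Y, 3.7 * FIX_SCORE - 11.0, FIX_SEX[:, None])
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_near_perfect_predictor_approaches_r2_max(self):
        rng = np.random.default_rng(13)
        y = np.repeat([0.0, 1.0], 50)
        s = y + 0.01 * rng.standard_normal(100)  # ridge guard via tiny noise
        r2 = nagelkerke_r2(y, s[:, None])
        assert r2 > 0.95


class TestDecileOr:
    def test_reference_decile_is_unity_and_null_coverage(self):
        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, 600).astype(float)
        s = rng.standard_normal(600)
        table = decile_or(y, s)
        assert table.loc[0, "odds_ratio"] == 1.0
        covers = ((table["ci_low"] <= 1) & (table["ci_high"] >= 1)).iloc[1:]
        assert covers.sum() >= 8

    def test_predictive_scores_monotone_on_average(self):
        from scipy import stats as st

        rng = np.random.default_rng(15)
        liab = rng.standard_normal(2_000)
        y = (liab > 0).astype(float)
        s = liab + rng.standard_normal(2_000)
        table = decile_or(y, s)
        rho = st.spearmanr(table["decile"], table["odds_ratio"]).statistic
        assert rho > 0


class TestPermutationPrs:
    def test_reproducible_and_near_zero(self):
        rng = np.random.default_rng(16)
        liab = rng.standard_normal(500)
        y = (liab > 0.5).astype(float)
        s = liab + 0.5 * rng.standard_normal(500)
        a = permutation_prs(y, s, None, n_perms=1, seed=3)
        b = permutation_prs(y, s, None, n_perms=1, seed=3)
        assert a[0] == b[0]
        null = permutation_prs(y, s, None, n_perms=20, seed=4)
        observed, _ = delta_nagelkerke(y, s, None)
        assert null.mean() < observed


class TestPrsModel:
    def test_end_to_end_fit(self, desk_cohort, marginal_discovery, small_panel):
        res = PrsModel(
            desk_cohort, marginal_discovery, small_panel,
            PrsConfig(), select_pcs_flag=False,
        ).fit()
        assert len(res.table) == 12
        assert (res.table["delta_r2"].dropna() >= -1e-9).all()
        assert res.deciles is not None
        assert res.deciles.loc[0, "odds_ratio"] == 1.0
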