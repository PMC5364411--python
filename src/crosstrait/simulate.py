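"""Synthetic GWAS generator.

Produces every input the cross-trait analysis needs without external data:

* reference haplotype panels with block LD structure whose within-block r^2
  decays with genetic-map distance (a Markov copying process; no coalescent
  machinery),
* bivariate polygenic case-control cohorts under the liability-threshold
  model, with optional population strata (Balding-Nichols frequency
  perturbation), shared controls and injected misdiagnosis,
* per-variant association summary statistics (score-test z),
* structure-preserving label permutations (the PC1-3 "cube" procedure), and
* a fast direct generator that emits two traits' z-scores straight from the
  LD score regression generative model, for cheap regression experiments.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _st

from .types import (
    AnalysisError,
    Cohort,
    CohortDesign,
    GenerationError,
    GeneticArchitecture,
    HaplotypePanel,
    ParameterError,
    SummaryStats,
    VariantTable,
)

logger = logging.getLogger(__name__)

# copying probability decays as exp(-LD_DECAY_RATE * d_cm) between neighbours
LD_DECAY_RATE = 30.0
CM_PER_BP = 1e-6  # 1 cM/Mb


def simulate_reference_panel(
    n_haplotypes: int,
    n_variants: int,
    block_size_mean: int = 50,
    seed: int = 0,
) -> HaplotypePanel:
    """Simulate a haplotype reference panel with independent LD blocks.

    Within a block every variant shares one block allele frequency; each
    haplotype's allele at variant j copies its allele at variant j-1 with
    probability exp(-30 * d_cM), else is drawn fresh from the block frequency.
    This yields monotone LD decay in map distance and exactly zero LD across
    blocks.
    """
    if n_haplotypes < 50 or n_variants < 100:
        raise ParameterError("need n_haplotypes >= 50 and n_variants >= 100")
    if block_size_mean < 1:
        raise ParameterError("block_size_mean must be >= 1")
    rng = np.random.default_rng(seed)

    # block partition
    bounds: list[tuple[int, int]] = []
    start = 0
    while start < n_variants:
        size = max(1, int(rng.poisson(block_size_mean)))
        stop = min(start + size, n_variants)
        bounds.append((start, stop))
        start = stop

    # map: bp increments 500..5000, cm at 1 cM/Mb with a jump between blocks
    bp_steps = rng.integers(500, 5000, size=n_variants)
    pos = np.cumsum(bp_steps)
    block_id = np.zeros(n_variants, int)
    for b, (s, e) in enumerate(bounds):
        block_id[s:e] = b
    cm = np.cumsum(bp_steps * CM_PER_BP) + block_id * 2.0  # 2 cM gaps

    H = np.zeros((n_haplotypes, n_variants), dtype=np.int8)
    for s, e in bounds:
        p = rng.uniform(0.1, 0.9)
        H[:, s] = rng.random(n_haplotypes) < p
        for j in range(s + 1, e):
            c = np.exp(-LD_DECAY_RATE * (cm[j] - cm[j - 1]))
            copy = rng.random(n_haplotypes) < c
            fresh = rng.random(n_haplotypes) < p
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
    # guard monomorphic / near-fixed columns: flip a few haplotypes
    freq = H.mean(axis=0)
    for j in np.where((freq < 0.005) | (freq > 0.995))[0]:
        minor = 1 if freq[j] < 0.5 else 0
        k = max(1, int(np.ceil(0.01 * n_haplotypes)))
        rows = rng.choice(n_haplotypes, size=k, replace=False)
        H[rows, j] = minor
    freq = H.mean(axis=0)

    table = pd.DataFrame(
        {
            "chrom": 1,
            "pos": pos,
            "cm": cm,
            "id": [f"rs{j + 1}" for j in range(n_variants)],
            "a1": "A",
            "a2": "G",
            "maf": np.minimum(freq, 1 - freq),
        }
    )
    return HaplotypePanel(VariantTable(table), H, bounds)


def draw_effect_sizes(
    arch: GeneticArchitecture, variants: VariantTable, seed: int = 0
) -> pd.DataFrame:
    """Draw per-variant standardized-genotype effect pairs.

    Causal variants (a ``prop_causal`` fraction) receive effects from a
    bivariate normal with per-trait variances h2_t / M_causal and covariance
    rho_g / M_causal, so summed effect variances equal the liability h2 in
    expectation.  Non-causal variants get (0, 0).
    """
    rng = np.random.default_rng(seed)
    m = len(variants)
    m_causal = max(1, int(round(arch.prop_causal * m)))
    causal = np.zeros(m, bool)
    causal[rng.choice(m, size=m_causal, replace=False)] = True

    v1 = arch.h2_liab_1 / m_causal
    v2 = arch.h2_liab_2 / m_causal
    cov = arch.rho_g / m_causal
    if cov**2 > v1 * v2 + 1e-18:
        raise ParameterError("effect covariance not positive semi-definite")
    a = rng.standard_normal(m_causal)
    b = rng.standard_normal(m_causal)
    b1 = np.sqrt(v1) * a
    if v1 > 0:
        resid = max(v2 - cov**2 / v1, 0.0)
        b2 = (cov / np.sqrt(v1)) * a + np.sqrt(resid) * b
    else:
        b2 = np.sqrt(v2) * b
    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    beta1[causal] = b1
    beta2[causal] = b2
    return pd.DataFrame(
        {"id": variants.ids, "beta1": beta1, "beta2": beta2, "causal": causal}
    )


def _stratum_panels(
    panel: HaplotypePanel, n_strata: int, fst: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-stratum haplotype matrices via Balding-Nichols frequency shifts.

    Stratum frequencies are drawn from Beta(p(1-F)/F, (1-p)(1-F)/F); panel
    columns are nudged toward the stratum frequency by flipping a random
    subset of haplotypes, which preserves within-block LD approximately.
    """
    if n_strata <= 1 or fst <= 0:
        return [panel.haplotypes]
    p = panel.freqs
    n_hap = panel.n_haplotypes
    out = []
    for _ in range(n_strata):
        a = p * (1 - fst) / fst
        b = (1 - p) * (1 - fst) / fst
        p_s = np.clip(rng.beta(a, b), 0.01, 0.99)
        H = panel.haplotypes.copy()
        for j in range(H.shape[1]):
            delta = int(round((p_s[j] - p[j]) * n_hap))
            if delta > 0:
                zeros = np.where(H[:, j] == 0)[0]
                flip = rng.choice(zeros, size=min(delta, len(zeros)), replace=False)
                H[flip, j] = 1
            elif delta < 0:
                ones = np.where(H[:, j] == 1)[0]
                flip = rng.choice(ones, size=min(-delta, len(ones)), replace=False)
                H[flip, j] = 0
        out.append(H)
    return out


def _standardize(G: np.ndarray, freq: np.ndarray) -> np.ndarray:
    sd = np.sqrt(2 * freq * (1 - freq))
    return (G - 2 * freq) / sd


def _draw_individuals(
    panels: list[np.ndarray],
    beta: np.ndarray,
    beta_other: np.ndarray,
    arch_h2: float,
    arch_h2_other: float,
    freq: np.ndarray,
    n: int,
    rng: np.random.Generator,
):
    """Draw n individuals: genotypes, both traits' liabilities, stratum."""
    n_strata = len(panels)
    strat = rng.integers(0, n_strata, size=n)
    n_hap = panels[0].shape[0]
    i1 = rng.integers(0, n_hap, size=n)
    i2 = rng.integers(0, n_hap, size=n)
    G = np.empty((n, panels[0].shape[1]), dtype=np.int8)
    for s in range(n_strata):
        mask = strat == s
        G[mask] = panels[s][i1[mask]] + panels[s][i2[mask]]
    X = _standardize(G.astype(float), freq)
    g1 = X @ beta
    g2 = X @ beta_other
    e1 = rng.standard_normal(n) * np.sqrt(max(1 - arch_h2, 0.0))
    e2 = rng.standard_normal(n) * np.sqrt(max(1 - arch_h2_other, 0.0))
    return G, g1, g1 + e1, g2 + e2, strat


def sample_unselected(
    panel: HaplotypePanel,
    effects: pd.DataFrame,
    arch: GeneticArchitecture,
    n: int,
    trait_index: int = 1,
    seed: int = 0,
) -> dict:
    """Draw n population (unselected) individuals for one trait.

    Returns genotypes, genetic values, liabilities and case labels; useful
    for checking the generator against closed-form expectations (case counts
    are Binomial(n, K), genetic-value variance is h2 in expectation).
    """
    if trait_index not in (1, 2):
        raise ParameterError("trait_index must be 1 or 2")
    rng = np.random.default_rng(seed)
    h2 = arch.h2_liab_1 if trait_index == 1 else arch.h2_liab_2
    h2o = arch.h2_liab_2 if trait_index == 1 else arch.h2_liab_1
    K = arch.K_1 if trait_index == 1 else arch.K_2
    beta = effects["beta1" if trait_index == 1 else "beta2"].to_numpy()
    betao = effects["beta2" if trait_index == 1 else "beta1"].to_numpy()
    G, g, L, _, strat = _draw_individuals(
        [panel.haplotypes], beta, betao, h2, h2o, panel.freqs, n, rng
    )
    return {
        "genotypes": G,
        "genetic_value": g,
        "liability": L,
        "case": (L > _st.norm.isf(K)).astype(int),
        "strata": strat,
    }


def simulate_liability_cohort(
    panel: HaplotypePanel,
    effects: pd.DataFrame,
    arch: GeneticArchitecture,
    design: CohortDesign,
    trait_index: int,
    seed: int = 0,
    max_attempt_factor: float = 500.0,
    batch: int = 2000,
) -> Cohort:
    """Simulate one case-control cohort under the liability-threshold model.

    Individuals are formed by pairing panel haplotypes (stratum-perturbed when
    ``design.n_strata > 1``); liability = genetic value + N(0, 1-h2); an
    individual is a case iff liability exceeds Phi^-1(1-K_t).  Rejection
    sampling continues until the requested case and control counts are
    reached or the attempt budget is exhausted.
    """
    if trait_index not in (1, 2):
        raise ParameterError("trait_index must be 1 or 2")
    rng = np.random.default_rng(seed)
    h2 = arch.h2_liab_1 if trait_index == 1 else arch.h2_liab_2
    h2o = arch.h2_liab_2 if trait_index == 1 else arch.h2_liab_1
    K = arch.K_1 if trait_index == 1 else arch.K_2
    n_cases = design.n_cases_1 if trait_index == 1 else design.n_cases_2
    n_controls = design.n_controls_1 if trait_index == 1 else design.n_controls_2
    beta = effects["beta1" if trait_index == 1 else "beta2"].to_numpy()
    betao = effects["beta2" if trait_index == 1 else "beta1"].to_numpy()
    thresh = _st.norm.isf(K)
    panels = _stratum_panels(panel, design.n_strata, design.stratum_fst, rng)
    freq = panel.freqs

    budget = int(
        max_attempt_factor * max(max(n_cases, 1) / K, max(n_controls, 1) / (1 - K))
    )
    drawn = 0
    case_rows, ctrl_rows = [], []
    case_strat, ctrl_strat = [], []
    while (sum(len(r) for r in case_rows) < n_cases
           or sum(len(r) for r in ctrl_rows) < n_controls):
        if drawn >= budget:
            have = sum(len(r) for r in case_rows)
            raise GenerationError(
                f"attempt budget exhausted: {have}/{n_cases} cases after {drawn} draws"
            )
        n = min(batch, budget - drawn)
        G, _, L, _, strat = _draw_individuals(panels, beta, betao, h2, h2o, freq, n, rng)
        drawn += n
        is_case = L > thresh
        case_rows.append(G[is_case])
        case_strat.append(strat[is_case])
        ctrl_rows.append(G[~is_case])
        ctrl_strat.append(strat[~is_case])
    cases = np.concatenate(case_rows)[:n_cases]
    ctrls = np.concatenate(ctrl_rows)[:n_controls]
    strata = np.concatenate(
        [np.concatenate(case_strat)[:n_cases], np.concatenate(ctrl_strat)[:n_controls]]
    )
    G = np.concatenate([cases, ctrls])
    y = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    return Cohort(G, y, panel.variants, strata=strata)


def simulate_bivariate_cohorts(
    panel: HaplotypePanel,
    effects: pd.DataFrame,
    arch: GeneticArchitecture,
    design: CohortDesign,
    seed: int = 0,
    **kwargs,
) -> tuple[Cohort, Cohort]:
    """Simulate the two trait cohorts with literally shared control rows."""
    c1 = simulate_liability_cohort(panel, effects, arch, design, 1, seed, **kwargs)
    c2 = simulate_liability_cohort(panel, effects, arch, design, 2, seed + 1, **kwargs)
    ns = design.n_shared_controls
    if ns > 0:
        # overwrite the first ns controls of cohort 2 with cohort 1's controls
        src = np.arange(design.n_cases_1, design.n_cases_1 + ns)
        dst = np.arange(design.n_cases_2, design.n_cases_2 + ns)
        c2.genotypes[dst] = c1.genotypes[src]
        c2.ids[dst] = c1.ids[src]
        if c1.strata is not None and c2.strata is not None:
            c2.strata[dst] = c1.strata[src]
    return c1, c2


def compute_summary_stats(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    variants: VariantTable,
    covariates: np.ndarray | None = None,
) -> SummaryStats:
    """Score-test association z per variant.

    Phenotype and standardized dosages are residualized on the covariates
    (plus an intercept); z_j = sqrt(n_resid) * corr(x_j, y).  Monomorphic
    variants are dropped with a log record.
    """
    y = np.asarray(phenotype, float)
    if np.ptp(y) == 0:
        raise AnalysisError("constant phenotype")
    G = np.asarray(genotypes, float)
    n = len(y)
    sd = G.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d monomorphic variants", int((~keep).sum()))
    Gk = G[:, keep]
    X = (Gk - Gk.mean(axis=0)) / Gk.std(axis=0)
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, float)])
    else:
        C = np.ones((n, 1))
    # residualize on covariates
    Q, _ = np.linalg.qr(C)
    y = y - Q @ (Q.T @ y)
    X = X - Q @ (Q.T @ X)
    df = n - C.shape[1]
    ynorm = np.linalg.norm(y)
    xnorm = np.linalg.norm(X, axis=0)
    r = (X.T @ y) / (xnorm * ynorm)
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.sqrt(df) * r
    vt = VariantTable(variants.table.loc[keep].reset_index(drop=True))
    return SummaryStats.from_z(vt, z, float(n))


def structured_permutation(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    n_cubes: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permute case-control labels within cubes of PC1-3 space.

    The top three principal components of the standardized genotype matrix
    define a 3-D space that is subdivided into equal-width cubes
    (round(n_cubes^(1/3)) bins per axis).  Labels are shuffled only within a
    cube, so the global and per-cube case counts are preserved exactly.
    """
    if n_cubes < 1:
        raise ParameterError("n_cubes must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype).copy()
    n = len(y)
    if n_cubes == 1:
        perm = rng.permutation(n)
        return y[perm]
    G = np.asarray(genotypes, float)
    sd = G.std(axis=0)
    X = (G[:, sd > 0] - G[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    # top 3 PCs via SVD of the (centered) matrix
    k = min(3, min(X.shape) - 1)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :k] * S[:k]
    nz = S[:k] > 1e-10 * S[0]
    if nz.sum() < k:
        logger.warning("degenerate PCs: using %d dimensions", int(nz.sum()))
        pcs = pcs[:, nz]
        k = int(nz.sum())
    bins_per_dim = max(1, int(round(n_cubes ** (1.0 / max(k, 1)))))
    idx = np.zeros(n, dtype=np.int64)
    for d in range(pcs.shape[1]):
        lo, hi = pcs[:, d].min(), pcs[:, d].max()
        width = (hi - lo) or 1.0
        b = np.minimum(((pcs[:, d] - lo) / width * bins_per_dim).astype(int),
                       bins_per_dim - 1)
        idx = idx * bins_per_dim + b
    out = y.copy()
    for cube in np.unique(idx):
        members = np.where(idx == cube)[0]
        out[members] = y[members][rng.permutation(len(members))]
    return out


def inject_misdiagnosis(
    cohort_b_cases: np.ndarray,
    cohort_a_case_pool: np.ndarray,
    fraction: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace a fraction of trait-B case rows with genuine trait-A cases.

    Returns the contaminated case matrix and the indices of replaced rows.
    """
    if not 0 <= fraction <= 1:
        raise ParameterError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_b = cohort_b_cases.shape[0]
    n_swap = int(round(fraction * n_b))
    if n_swap > cohort_a_case_pool.shape[0]:
        raise GenerationError(
            f"pool of {cohort_a_case_pool.shape[0]} cannot supply {n_swap} rows"
        )
    out = cohort_b_cases.copy()
    rows = rng.choice(n_b, size=n_swap, replace=False)
    src = rng.choice(cohort_a_case_pool.shape[0], size=n_swap, replace=False)
    out[rows] = cohort_a_case_pool[src]
    return out, np.sort(rows)


# ---------------------------------------------------------------------------
# direct summary-statistic generator (LDSC generative model)

def simulate_ld_scores(m: int, seed: int = 0, mean_ell: float = 5.0) -> np.ndarray:
    """Draw per-SNP LD scores >= 1 with the requested mean (Gamma excess)."""
    rng = np.random.default_rng(seed)
    return 1.0 + rng.gamma(2.0, (mean_ell - 1.0) / 2.0, size=m)


def simulate_sumstats_direct(
    ell: np.ndarray,
    h2_obs_1: float,
    h2_obs_2: float,
    r_g: float,
    n1: float,
    n2: float,
    n_shared: float = 0.0,
    intercept_1: float = 1.0,
    intercept_2: float = 1.0,
    seed: int = 0,
) -> tuple[SummaryStats, SummaryStats]:
    """Draw two traits' z-scores straight from the LDSC generative model.

    Per SNP j the pair (z1, z2) is bivariate normal with
    ``Var(z_t) = intercept_t + N_t * h2_obs_t * ell_j / M`` and
    ``Cov = sqrt(N1 N2) * rho_g_obs * ell_j / M + N_s / sqrt(N1 N2)``,
    where rho_g_obs = r_g * sqrt(h2_obs_1 * h2_obs_2).  The shared-control
    term is the null correlation induced by N_s overlapping individuals.
    """
    rng = np.random.default_rng(seed)
    ell = np.asarray(ell, float)
    m = len(ell)
    v1 = intercept_1 + n1 * h2_obs_1 * ell / m
    v2 = intercept_2 + n2 * h2_obs_2 * ell / m
    rho_obs = r_g * np.sqrt(h2_obs_1 * h2_obs_2)
    cov = np.sqrt(n1 * n2) * rho_obs * ell / m + n_shared / np.sqrt(n1 * n2)
    if np.any(cov**2 > v1 * v2):
        raise ParameterError("generative covariance exceeds variance bound")
    a = rng.standard_normal(m)
    b = rng.standard_normal(m)
    z1 = np.sqrt(v1) * a
    z2 = (cov / np.sqrt(v1)) * a + np.sqrt(v2 - cov**2 / v1) * b
    variants = _synthetic_variant_table(m)
    return (
        SummaryStats.from_z(variants, z1, float(n1)),
        SummaryStats.from_z(variants, z2, float(n2)),
    )


def _synthetic_variant_table(m: int) -> VariantTable:
    pos = np.arange(1, m + 1) * 1000
    return VariantTable(
        pd.DataFrame(
            {
                "chrom": 1,
                "pos": pos,
                "cm": pos * CM_PER_BP,
                "id": [f"rs{j + 1}" for j in range(m)],
                "a1": "A",
                "a2": "G",
                "maf": 0.3,
            }
        )
    )
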