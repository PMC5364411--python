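"""Polygenic risk scoring of a target cohort from discovery summary statistics.

Stages: variant filtering (MAF, strand-ambiguous A/T and G/C removal),
two-round greedy LD clumping, threshold scoring (sum of per-allele log-odds
times dosage), covariate-adjusted logistic modelling with the Nagelkerke
pseudo-R^2 increment over a baseline model, decile odds ratios, and
label-permutation nulls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st

from .types import AnalysisError, Cohort, HaplotypePanel, ParameterError, SummaryStats

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLDS = (
    5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 5e-3, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass
class PrsConfig:
    """Scoring protocol: thresholds, clumping rounds and variant filters."""

    p_thresholds: tuple[float, ...] = DEFAULT_P_THRESHOLDS
    round1_kb: float = 250.0
    round1_r2: float = 0.5
    round2_kb: float = 5000.0
    round2_r2: float = 0.2
    maf_min: float = 0.01
    info_min: float = 0.3
    drop_ambiguous: bool = True
    n_pcs: int = 100
    pc_alpha: float = 0.0005

    def __post_init__(self) -> None:
        th = list(self.p_thresholds)
        if th != sorted(th) or len(set(th)) != len(th):
            raise ParameterError("p_thresholds must be strictly increasing")
        for r2 in (self.round1_r2, self.round2_r2):
            if not 0 < r2 < 1:
                raise ParameterError("clump r2 cutoffs must lie in (0, 1)")


def _panel_r2_column(panel: HaplotypePanel, j: int, others: np.ndarray) -> np.ndarray:
    H = panel.haplotypes.astype(float)
    x = H[:, j] - H[:, j].mean()
    Y = H[:, others] - H[:, others].mean(axis=0)
    denom = np.sqrt((x @ x) * np.sum(Y * Y, axis=0))
    with np.errstate(invalid="ignore"):
        r = np.where(denom > 0, (x @ Y) / denom, 0.0)
    return r**2


def clump(
    stats: SummaryStats,
    panel: HaplotypePanel,
    distance_kb: float,
    r2_cut: float,
    candidate_ids: set[str] | None = None,
) -> set[str]:
    """Greedy LD clumping: lowest-p index variants absorb correlated neighbours.

    Repeatedly takes the lowest-p unassigned variant as index and removes all
    unassigned variants within ``distance_kb`` whose panel r^2 with the index
    exceeds ``r2_cut``.  Ties in p are broken by (chrom, pos, id), which makes
    the output independent of input row order.
    """
    frame = stats.to_frame()
    if candidate_ids is not None:
        frame = frame[frame["id"].isin(candidate_ids)]
    pv = panel.variants.table
    col_of = {vid: k for k, vid in enumerate(pv["id"])}
    frame = frame[frame["id"].isin(col_of)].copy()
    if frame.empty:
        return set()
    frame = frame.sort_values(["p", "chrom", "pos", "id"], kind="mergesort")
    ids = frame["id"].to_numpy()
    chrom = frame["chrom"].to_numpy()
    pos = frame["pos"].to_numpy(float)
    cols = np.array([col_of[v] for v in ids])

    assigned = np.zeros(len(frame), bool)
    retained: set[str] = set()
    for i in range(len(frame)):
        if assigned[i]:
            continue
        assigned[i] = True
        retained.add(ids[i])
        near = (
            ~assigned
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= distance_kb * 1000)
        )
        idx = np.where(near)[0]
        if len(idx):
            r2 = _panel_r2_column(panel, cols[i], cols[idx])
            assigned[idx[r2 > r2_cut]] = True
    return retained


def two_round_clump(
    stats: SummaryStats, panel: HaplotypePanel, config: PrsConfig,
    candidate_ids: set[str] | None = None,
) -> set[str]:
    first = clump(stats, panel, config.round1_kb, config.round1_r2, candidate_ids)
    return clump(stats, panel, config.round2_kb, config.round2_r2, first)


def filter_variants(stats: SummaryStats, config: PrsConfig,
                    info: np.ndarray | None = None) -> set[str]:
    """Apply MAF / INFO / strand-ambiguity filters; returns surviving ids."""
    t = stats.variants.table
    keep = t["maf"].to_numpy() >= config.maf_min
    if config.drop_ambiguous:
        amb = np.array(
            [(a1, a2) in AMBIGUOUS_PAIRS for a1, a2 in zip(t["a1"], t["a2"])]
        )
        keep &= ~amb
    if info is not None:
        keep &= np.asarray(info, float) >= config.info_min
    return set(t.loc[keep, "id"])


def score(
    genotypes: np.ndarray,
    genotype_variants,
    stats: SummaryStats,
    retained: set[str],
    p_threshold: float,
) -> np.ndarray:
    """Per-individual risk score: sum of beta * dosage over scoring variants.

    Effect alleles are aligned (dosage complemented and beta applied to
    ``2 - d`` when the effect allele matches the target's other allele);
    missing dosages contribute the variant's mean dosage.
    """
    if stats.beta is None:
        raise ParameterError("summary statistics carry no effect sizes (beta)")
    sf = stats.to_frame()
    sf = sf[sf["id"].isin(retained) & (sf["p"] <= p_threshold)]
    gt = genotype_variants.table
    col_of = {vid: k for k, vid in enumerate(gt["id"])}
    n = genotypes.shape[0]
    total = np.zeros(n)
    used = 0
    a1g = gt["a1"].to_numpy()
    a2g = gt["a2"].to_numpy()
    for _, row in sf.iterrows():
        k = col_of.get(row["id"])
        if k is None:
            continue
        d = genotypes[:, k].astype(float)
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)
        if row["a1"] == a1g[k]:
            pass
        elif row["a1"] == a2g[k]:
            d = 2.0 - d
        else:
            continue
        total += row["beta"] * d
        used += 1
    if used == 0:
        logger.warning("no variants passed p <= %g; scores are all zero", p_threshold)
    return total


def select_pcs(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    n_pcs: int = 100,
    alpha: float = 0.0005,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components with a significant joint effect on the phenotype.

    Computes the top ``n_pcs`` PCs of the standardized dosage matrix, fits one
    logistic model of phenotype on all PCs, and retains those with Wald
    p < alpha.  Returns (selected PC matrix, selected indices).
    """
    G = np.asarray(genotypes, float)
    sd = G.std(axis=0)
    X = (G[:, sd > 0] - G[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    k = min(n_pcs, X.shape[0] - 1, X.shape[1])
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    nz = S[:k] > 1e-10 * max(S[0], 1.0)
    if nz.sum() < k:
        logger.warning("rank deficiency: only %d PCs available", int(nz.sum()))
    pcs = (U[:, :k] * S[:k])[:, nz]
    design = sm.add_constant(pcs)
    fit = sm.Logit(np.asarray(phenotype, float), design).fit(disp=0, maxiter=200)
    pvals = np.asarray(fit.pvalues)[1:]
    sel = np.where(pvals < alpha)[0]
    return pcs[:, sel], sel


def _logit_ll(y: np.ndarray, X: np.ndarray | None) -> tuple[float, object | None]:
    """Log-likelihood of a fitted logistic model (intercept-only when X None)."""
    n = len(y)
    if X is None:
        p = y.mean()
        ll = n * (p * np.log(p) + (1 - p) * np.log(1 - p)) if 0 < p < 1 else 0.0
        return ll, None
    design = sm.add_constant(X)
    fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        raise AnalysisError("logistic model did not converge (separation?)")
    return float(fit.llf), fit


def nagelkerke_r2(y: np.ndarray, X: np.ndarray | None) -> float:
    """Nagelkerke pseudo-R^2 of a logistic model against intercept-only."""
    y = np.asarray(y, float)
    n = len(y)
    ll0, _ = _logit_ll(y, None)
    ll1, _ = _logit_ll(y, X)
    cox = 1 - np.exp(2.0 / n * (ll0 - ll1))
    rmax = 1 - np.exp(2.0 / n * ll0)
    return float(cox / rmax)


def delta_nagelkerke(
    phenotype: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Nagelkerke R^2 increment of the score over the covariate baseline.

    Returns (delta_r2, Wald p of the score term).  A zero-variance score
    yields (0, nan) since the regressor is degenerate.
    """
    y = np.asarray(phenotype, float)
    s = np.asarray(scores, float)
    if s.std() == 0:
        return 0.0, float("nan")
    C = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if C is not None and C.shape[0] != len(y):
        C = C.T
    base = nagelkerke_r2(y, C)
    full_X = s[:, None] if C is None else np.column_stack([C, s])
    full = nagelkerke_r2(y, full_X)
    _, fit = _logit_ll(y, full_X)
    p = float(np.asarray(fit.pvalues)[-1])
    return float(full - base), p


def decile_or(
    phenotype: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Odds ratio (with 95% CI) per score decile relative to decile 1.

    Deciles are assigned by score rank with stable tie-breaking by individual
    order; decile 1 is the reference (OR 1 by construction).
    """
    y = np.asarray(phenotype, float)
    s = np.asarray(scores, float)
    n = len(y)
    order = np.argsort(s, kind="stable")
    dec = np.empty(n, int)
    dec[order] = (np.arange(n) * n_bins) // n
    counts = np.bincount(dec, minlength=n_bins)
    if (counts == 0).any():
        logger.warning("empty decile after ties; bins merged")
    dummies = np.zeros((n, n_bins - 1))
    for d in range(1, n_bins):
        dummies[:, d - 1] = dec == d
    X = dummies if covariates is None else np.column_stack([covariates, dummies])
    fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
    k0 = X.shape[1] - (n_bins - 1) + 1  # first dummy coefficient index
    rows = [{"decile": 1, "odds_ratio": 1.0, "ci_low": 1.0, "ci_high": 1.0,
             "n": int(counts[0]),
             "case_control_ratio": _cc_ratio(y, dec == 0)}]
    for d in range(1, n_bins):
        b = fit.params[k0 + d - 1]
        se = fit.bse[k0 + d - 1]
        rows.append(
            {
                "decile": d + 1,
                "odds_ratio": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.96 * se)),
                "ci_high": float(np.exp(b + 1.96 * se)),
                "n": int(counts[d]),
                "case_control_ratio": _cc_ratio(y, dec == d),
            }
        )
    return pd.DataFrame(rows)


def _cc_ratio(y: np.ndarray, mask: np.ndarray) -> float:
    cases = y[mask].sum()
    ctrls = (1 - y[mask]).sum()
    return float(cases / ctrls) if ctrls > 0 else float("inf")


def permutation_prs(
    phenotype: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None,
    n_perms: int,
    seed: int = 0,
) -> np.ndarray:
    """Null delta-R^2 under case-count-preserving label permutation."""
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, float)
    out = np.empty(n_perms)
    for i in range(n_perms):
        yp = y[rng.permutation(len(y))]
        out[i], _ = delta_nagelkerke(yp, scores, covariates)
    return out


@dataclass
class PrsResults:
    """Per-threshold scoring results plus decile ORs at the best threshold."""

    table: pd.DataFrame
    best_threshold: float
    deciles: pd.DataFrame | None
    n_clumped: int
    selected_pcs: np.ndarray = field(default_factory=lambda: np.array([], int))

    def summary(self) -> str:
        lines = [
            "Polygenic risk score analysis",
            f"  clumped scoring set: {self.n_clumped} variants",
            f"  best threshold: P_T = {self.best_threshold:g}",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class PrsModel:
    """Risk-score model of a target cohort given discovery summary statistics.

    ``fit()`` filters and clumps the discovery statistics against the panel,
    scores the target cohort at each p-value threshold, and reports the
    Nagelkerke R^2 increment over a baseline model of the supplied covariates
    plus phenotype-associated principal components.
    """

    def __init__(
        self,
        target: Cohort,
        discovery: SummaryStats,
        panel: HaplotypePanel,
        config: PrsConfig | None = None,
        covariates: np.ndarray | None = None,
        select_pcs_flag: bool = True,
    ) -> None:
        self.target = target
        self.discovery = discovery
        self.panel = panel
        self.config = config or PrsConfig()
        self.covariates = covariates
        self.select_pcs_flag = select_pcs_flag

    def fit(self, compute_deciles: bool = True) -> PrsResults:
        cfg = self.config
        candidates = filter_variants(self.discovery, cfg)
        retained = two_round_clump(self.discovery, self.panel, cfg, candidates)

        sel_idx = np.array([], int)
        cov = self.covariates
        if self.select_pcs_flag:
            pcs, sel_idx = select_pcs(
                self.target.genotypes, self.target.phenotype, cfg.n_pcs, cfg.pc_alpha
            )
            if pcs.shape[1]:
                cov = pcs if cov is None else np.column_stack([cov, pcs])

        rows = []
        scores_by_t = {}
        for pt in cfg.p_thresholds:
            s = score(self.target.genotypes, self.target.variants,
                      self.discovery, retained, pt)
            scores_by_t[pt] = s
            n_used = int(
                ((self.discovery.p <= pt)
                 & pd.Series(self.discovery.variants.ids).isin(retained)).sum()
            )
            try:
                dr2, p = delta_nagelkerke(self.target.phenotype, s, cov)
            except AnalysisError:
                logger.warning("threshold %g skipped: non-convergence", pt)
                dr2, p = float("nan"), float("nan")
            rows.append({"p_threshold": pt, "n_snps": n_used,
                         "delta_r2": dr2, "p_value": p})
        table = pd.DataFrame(rows)
        valid = table.dropna(subset=["delta_r2"])
        best = float(valid.loc[valid["delta_r2"].idxmax(), "p_threshold"])
        deciles = None
        if compute_deciles and scores_by_t[best].std() > 0:
            deciles = decile_or(self.target.phenotype, scores_by_t[best], cov)
        return PrsResults(
            table=table,
            best_threshold=best,
            deciles=deciles,
            n_clumped=len(retained),
            selected_pcs=sel_idx,
        )
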