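"""LD score regression: univariate heritability and bivariate genetic correlation.

The univariate model is ``E[chi2_j] = a + N * h2_obs * ell_j / M``; the slope
recovers the observed-scale SNP heritability, the intercept ``a`` absorbs
confounding that is not proportional to LD score.  The bivariate model
regresses the z-score product of two traits on LD score,
``E[z1 z2] = c + sqrt(N1 N2) * rho_g_obs * ell_j / M``, whose intercept
absorbs sample overlap, which is why the genetic-correlation estimate is
robust to shared controls.  Standard errors come from a leave-one-block-out
jackknife over contiguous variant blocks.

Organised statsmodels-style: :class:`LdscModel` / :class:`BivariateLdscModel`
are built from data and ``fit()`` returns a results object with estimates,
jackknife SEs and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .ldscore import LDScoreTable
from .simulate import compute_summary_stats, structured_permutation
from .types import Cohort, ParameterError, SummaryStats

logger = logging.getLogger(__name__)


def observed_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Convert observed-scale (0/1) heritability to the liability scale.

    ``h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2)`` with
    ``z = phi(Phi^-1(1-K))``; K is the population lifetime risk and P the
    sample case fraction.  Linear in ``h2_obs``.
    """
    if not 0 < K < 1 or not 0 < P < 1:
        raise ParameterError("K and P must lie strictly in (0, 1)")
    z = _st.norm.pdf(_st.norm.isf(K))
    return h2_obs * K**2 * (1 - K) ** 2 / (P * (1 - P) * z**2)


def liability_to_observed(h2_liab: float, K: float, P: float) -> float:
    """Inverse of :func:`observed_to_liability` (used by the generator)."""
    return h2_liab / observed_to_liability(1.0, K, P)


def _block_edges(m: int, n_blocks: int) -> np.ndarray:
    if n_blocks < 2 or n_blocks > m:
        raise ParameterError(f"need 2 <= n_blocks <= {m} variants")
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Weighted least squares of y on x; returns (slope, intercept)."""
    if intercept:
        X = np.column_stack([np.ones_like(x), x])
    else:
        X = x[:, None]
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    return (coef[1], coef[0]) if intercept else (coef[0], None)


def _jackknife(values: np.ndarray) -> float:
    b = len(values)
    return float(np.sqrt((b - 1) / b * np.sum((values - values.mean()) ** 2)))


@dataclass
class LdscResults:
    """Univariate LD score regression fit."""

    slope: float
    intercept: float
    h2_obs: float
    se_h2_obs: float
    mean_chi2: float
    n_blocks: int
    constrained: bool
    n_snps: int
    M: int
    h2_liab: float | None = None
    se_h2_liab: float | None = None
    n_winsorized: int = 0
    _delete_values: np.ndarray = field(default=None, repr=False)  # type: ignore

    def summary(self) -> str:
        lines = [
            "LD score regression (univariate)",
            f"  SNPs: {self.n_snps}   M: {self.M}   mean chi2: {self.mean_chi2:.4f}",
            f"  intercept: {self.intercept:.4f}"
            + ("  (constrained)" if self.constrained else ""),
            f"  h2 (observed): {self.h2_obs:.4f}  (SE {self.se_h2_obs:.4f})",
        ]
        if self.h2_liab is not None:
            lines.append(
                f"  h2 (liability): {self.h2_liab:.4f}  (SE {self.se_h2_liab:.4f})"
            )
        lines.append(f"  jackknife blocks: {self.n_blocks}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "slope", "intercept", "h2_obs", "se_h2_obs", "h2_liab",
                "se_h2_liab", "mean_chi2", "n_blocks", "constrained",
                "n_snps", "M", "n_winsorized",
            )
        }


class LdscModel:
    """Univariate LD score regression model.

    Parameters
    ----------
    stats : SummaryStats
        GWAS summary statistics for one trait.
    scores : LDScoreTable
        Per-variant LD scores; intersected with ``stats`` by variant id.
    M : int, optional
        Number of SNPs the heritability refers to (defaults to the number of
        regression SNPs).
    constrained_intercept : bool
        Fix the intercept at 1 (subtract 1 from chi2 and fit through the
        origin), appropriate when confounding is known to be controlled.
    K, P : float, optional
        Population prevalence and sample case fraction; when given the fit
        also reports the liability-scale heritability.
    """

    def __init__(
        self,
        stats: SummaryStats,
        scores: LDScoreTable,
        M: int | None = None,
        constrained_intercept: bool = False,
        K: float | None = None,
        P: float | None = None,
        min_snps: int = 200,
        winsor_mult: float = 80.0,
    ) -> None:
        merged = pd.merge(
            stats.to_frame()[["id", "z", "n_eff"]],
            pd.DataFrame({"id": scores.variants.ids, "ell": scores.ell}),
            on="id",
        )
        if len(merged) < min_snps:
            raise ParameterError(
                f"only {len(merged)} variants shared between stats and scores"
            )
        self.chi2 = merged["z"].to_numpy() ** 2
        self.ell = merged["ell"].to_numpy()
        self.N = merged["n_eff"].to_numpy()
        self.M = int(M) if M is not None else len(merged)
        if self.M < len(merged):
            raise ParameterError("M must be >= number of regression variants")
        self.constrained = bool(constrained_intercept)
        self.K, self.P = K, P
        self.winsor_mult = winsor_mult

    def _weights(self, slope: float, intercept: float) -> np.ndarray:
        nbar = self.N.mean()
        h2 = max(slope * self.M / nbar, 0.0)
        var = (intercept + nbar * h2 * self.ell / self.M) ** 2
        return 1.0 / (np.maximum(self.ell, 1.0) * np.maximum(var, 1e-6))

    def fit(self, n_blocks: int = 200) -> LdscResults:
        chi2 = self.chi2.copy()
        cap = self.winsor_mult * chi2.mean()
        n_win = int((chi2 > cap).sum())
        if n_win:
            logger.info("winsorizing %d chi2 values above %.1f", n_win, cap)
            chi2 = np.minimum(chi2, cap)
        nbar = self.N.mean()
        y = chi2 - 1.0 if self.constrained else chi2
        free = not self.constrained

        w = 1.0 / np.maximum(self.ell, 1.0)
        for _ in range(2):
            slope, icpt = _wls(self.ell, y, w, intercept=free)
            a = 1.0 if self.constrained else icpt
            w = self._weights(slope, a)
        slope, icpt = _wls(self.ell, y, w, intercept=free)
        intercept = 1.0 if self.constrained else float(icpt)
        h2_obs = slope * self.M / nbar

        edges = _block_edges(len(y), n_blocks)
        deletes = np.empty(n_blocks)
        for b in range(n_blocks):
            mask = np.ones(len(y), bool)
            mask[edges[b]:edges[b + 1]] = False
            s_b, _ = _wls(self.ell[mask], y[mask], w[mask], intercept=free)
            deletes[b] = s_b * self.M / self.N[mask].mean()
        se = _jackknife(deletes)

        res = LdscResults(
            slope=float(slope),
            intercept=intercept,
            h2_obs=float(h2_obs),
            se_h2_obs=se,
            mean_chi2=float(self.chi2.mean()),
            n_blocks=n_blocks,
            constrained=self.constrained,
            n_snps=len(y),
            M=self.M,
            n_winsorized=n_win,
            _delete_values=deletes,
        )
        if self.K is not None and self.P is not None:
            factor = observed_to_liability(1.0, self.K, self.P)
            res.h2_liab = res.h2_obs * factor
            res.se_h2_liab = res.se_h2_obs * factor
        return res


@dataclass
class BivariateResults:
    """Bivariate LD score regression fit (genetic covariance/correlation)."""

    rho_g: float
    r_g: float
    se_rg: float
    p_rg: float
    cross_intercept: float
    cross_slope: float
    fit1: LdscResults
    fit2: LdscResults
    n_snps: int
    M: int
    n_blocks: int
    rg_reason: str | None = None

    def summary(self) -> str:
        lines = [
            "LD score regression (bivariate)",
            f"  SNPs: {self.n_snps}   M: {self.M}",
            f"  genetic covariance (observed): {self.rho_g:.5f}",
            f"  cross-trait intercept: {self.cross_intercept:.4f}",
        ]
        if np.isnan(self.r_g):
            lines.append(f"  r_g: undefined ({self.rg_reason})")
        else:
            lines.append(
                f"  r_g: {self.r_g:.4f}  (SE {self.se_rg:.4f}, P {self.p_rg:.3g})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rho_g": self.rho_g,
            "r_g": self.r_g,
            "se_rg": self.se_rg,
            "p_rg": self.p_rg,
            "cross_intercept": self.cross_intercept,
            "n_snps": self.n_snps,
            "M": self.M,
            "fit1": self.fit1.to_dict(),
            "fit2": self.fit2.to_dict(),
        }


class BivariateLdscModel:
    """Bivariate LD score regression of two traits' z-score products.

    Alleles are aligned across the two studies by variant id: where the
    effect/other alleles are swapped the second trait's z sign is flipped;
    variants with incompatible alleles are dropped.
    """

    def __init__(
        self,
        stats1: SummaryStats,
        stats2: SummaryStats,
        scores: LDScoreTable,
        M: int | None = None,
        constrained_intercept_1: bool = False,
        constrained_intercept_2: bool = False,
        min_snps: int = 200,
    ) -> None:
        f1 = stats1.to_frame()[["id", "a1", "a2", "z", "n_eff"]]
        f2 = stats2.to_frame()[["id", "a1", "a2", "z", "n_eff"]]
        merged = pd.merge(f1, f2, on="id", suffixes=("_1", "_2"))
        same = (merged["a1_1"] == merged["a1_2"]) & (merged["a2_1"] == merged["a2_2"])
        flipped = (merged["a1_1"] == merged["a2_2"]) & (merged["a2_1"] == merged["a1_2"])
        merged = merged[same | flipped].copy()
        sign = np.where(same[same | flipped], 1.0, -1.0)
        merged["z_2"] = merged["z_2"] * sign
        merged = pd.merge(
            merged, pd.DataFrame({"id": scores.variants.ids, "ell": scores.ell}), on="id"
        )
        if len(merged) < min_snps:
            raise ParameterError(
                f"only {len(merged)} aligned variants shared across inputs"
            )
        self.z1 = merged["z_1"].to_numpy()
        self.z2 = merged["z_2"].to_numpy()
        self.n1 = merged["n_eff_1"].to_numpy()
        self.n2 = merged["n_eff_2"].to_numpy()
        self.ell = merged["ell"].to_numpy()
        self.M = int(M) if M is not None else len(merged)
        self._stats = (stats1, stats2)
        self._scores = scores
        self._constrained = (constrained_intercept_1, constrained_intercept_2)
        self._min_snps = min_snps

    def fit(self, n_blocks: int = 200) -> BivariateResults:
        m = len(self.ell)
        n1bar, n2bar = self.n1.mean(), self.n2.mean()
        stats1, stats2 = self._stats

        fit1 = LdscModel(
            stats1, self._scores, M=self.M,
            constrained_intercept=self._constrained[0], min_snps=self._min_snps,
        ).fit(n_blocks)
        fit2 = LdscModel(
            stats2, self._scores, M=self.M,
            constrained_intercept=self._constrained[1], min_snps=self._min_snps,
        ).fit(n_blocks)

        y = self.z1 * self.z2
        w = 1.0 / np.maximum(self.ell, 1.0)
        slope, icpt = _wls(self.ell, y, w, intercept=True)
        for _ in range(2):
            v1 = fit1.intercept + n1bar * max(fit1.h2_obs, 0) * self.ell / self.M
            v2 = fit2.intercept + n2bar * max(fit2.h2_obs, 0) * self.ell / self.M
            c = icpt + slope * self.ell
            var = v1 * v2 + c**2
            w = 1.0 / (np.maximum(self.ell, 1.0) * np.maximum(var, 1e-6))
            slope, icpt = _wls(self.ell, y, w, intercept=True)

        rho_g = slope * self.M / np.sqrt(n1bar * n2bar)
        reason = None
        if fit1.h2_obs <= 0 or fit2.h2_obs <= 0:
            r_g = np.nan
            reason = "a component heritability estimate is non-positive"
        else:
            r_g = rho_g / np.sqrt(fit1.h2_obs * fit2.h2_obs)
            if abs(r_g) > 1:
                logger.warning("r_g estimate %.3f exceeds 1 (estimation noise)", r_g)

        # jackknife the full r_g statistic: refit all three regressions per block
        edges = _block_edges(m, n_blocks)
        h1_del = fit1._delete_values
        h2_del = fit2._delete_values
        rg_del = np.empty(n_blocks)
        for b in range(n_blocks):
            mask = np.ones(m, bool)
            mask[edges[b]:edges[b + 1]] = False
            s_b, _ = _wls(self.ell[mask], y[mask], w[mask], intercept=True)
            rho_b = s_b * self.M / np.sqrt(self.n1[mask].mean() * self.n2[mask].mean())
            denom = h1_del[b] * h2_del[b]
            rg_del[b] = rho_b / np.sqrt(denom) if denom > 0 else np.nan
        valid = np.isfinite(rg_del)
        se = _jackknife(rg_del[valid]) if valid.sum() >= 2 else np.nan
        p = 2 * _st.norm.sf(abs(r_g) / se) if (se and np.isfinite(se) and se > 0
                                               and np.isfinite(r_g)) else np.nan

        return BivariateResults(
            rho_g=float(rho_g),
            r_g=float(r_g),
            se_rg=float(se),
            p_rg=float(p),
            cross_intercept=float(icpt),
            cross_slope=float(slope),
            fit1=fit1,
            fit2=fit2,
            n_snps=m,
            M=self.M,
            n_blocks=n_blocks,
            rg_reason=reason,
        )


def permutation_null_h2(
    cohort: Cohort,
    scores: LDScoreTable,
    n_perms: int,
    n_cubes: int = 64,
    seed: int = 0,
    M: int | None = None,
    constrained_intercept: bool = True,
    n_blocks: int = 50,
    n_pc_covariates: int = 3,
) -> np.ndarray:
    """Null distribution of h2 estimates under structure-preserving permutation.

    For each permutation the case-control labels are shuffled within PC1-3
    cubes, structure-controlled association statistics are recomputed (score
    test with the top ``n_pc_covariates`` principal components as covariates,
    emulating per-stratum association plus meta-analysis) and a univariate
    LD score regression is fitted; the array of observed-scale h2 estimates
    is returned (expected to be indistinguishable from zero).
    """
    rng = np.random.default_rng(seed)
    cov = None
    if n_pc_covariates > 0:
        G = np.asarray(cohort.genotypes, float)
        sd = G.std(axis=0)
        X = (G[:, sd > 0] - G[:, sd > 0].mean(axis=0)) / sd[sd > 0]
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        cov = U[:, :n_pc_covariates] * S[:n_pc_covariates]
    out = np.empty(n_perms)
    for i in range(n_perms):
        y = structured_permutation(
            cohort.genotypes, cohort.phenotype, n_cubes, seed=int(rng.integers(2**31))
        )
        stats = compute_summary_stats(cohort.genotypes, y, cohort.variants, cov)
        fit = LdscModel(
            stats, scores, M=M, constrained_intercept=constrained_intercept
        ).fit(n_blocks)
        out[i] = fit.h2_obs
    return out
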