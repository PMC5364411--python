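"""Bivariate liability-threshold comorbidity model.

Two binary traits are modelled as a standard bivariate normal liability with
correlation equal to the liability-scale genetic covariance
``rho = r_g * sqrt(h2_1 * h2_2)``; a trait manifests when its liability
exceeds ``Phi^-1(1 - K)`` set by the lifetime risk K.  From the upper-orthant
probability follow the joint lifetime risk, the comorbidity odds ratio, the
misdiagnosis rate that would mimic an observed genetic covariance, and the
cohort size needed to detect the comorbidity excess epidemiologically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as _st

from .types import ParameterError


def liability_threshold(K: float) -> float:
    """Liability threshold ``t = Phi^-1(1 - K)`` for lifetime risk K."""
    if not 0 < K < 1:
        raise ParameterError("K must lie in (0, 1)")
    return float(_st.norm.isf(K))


def joint_risk(K1: float, K2: float, rho_liab: float, tol: float = 1e-10) -> float:
    """Upper-orthant probability P(L1 > t1, L2 > t2) of the bivariate normal.

    Computed deterministically via the conditional-normal reduction: a 1-D
    integral of the conditional survival function against the standard normal
    density, evaluated by adaptive Gauss quadrature to absolute tolerance
    ``tol``.
    """
    if not abs(rho_liab) < 1:
        raise ParameterError("|rho_liab| must be < 1")
    t1 = liability_threshold(K1)
    t2 = liability_threshold(K2)
    if rho_liab == 0:
        return K1 * K2
    s = np.sqrt(1 - rho_liab**2)

    def integrand(x):
        return _st.norm.pdf(x) * _st.norm.sf((t2 - rho_liab * x) / s)

    # the integrand is negligible beyond ~13 SD; a finite upper limit keeps
    # the quadrature error estimate sharp
    upper = t1 + 14.0
    val, err = integrate.quad(
        integrand, t1, upper, epsabs=tol / 100, epsrel=1e-12, limit=500
    )
    if err > tol:
        raise ArithmeticError(f"orthant integral error {err:.2e} exceeds {tol:.0e}")
    return float(val)


def comorbidity_or(K1: float, K2: float, rho_liab: float) -> float:
    """Odds ratio of the 2x2 affection table implied by (K1, K2, rho).

    OR = (p11 * p00) / (p10 * p01); symmetric in trait order.
    """
    p11 = joint_risk(K1, K2, rho_liab)
    p10 = K1 - p11
    p01 = K2 - p11
    p00 = 1 - K1 - K2 + p11
    if min(p10, p01, p00, p11) <= 0:
        raise ParameterError("degenerate 2x2 cell probability")
    return float(p11 * p00 / (p10 * p01))


def misdiagnosis_rate(rho_g: float, n_cases_2: int, n_cases_1: int) -> float:
    """Misdiagnosis fraction that would mimic genetic covariance ``rho_g``.

    ``M = C / (C + 1)`` with ``C = rho_g * N_2 / N_1`` where N_2 is the case
    count of the cohort receiving misdiagnosed trait-1 cases.
    """
    if n_cases_1 <= 0 or n_cases_2 <= 0:
        raise ParameterError("case counts must be positive")
    c = rho_g * n_cases_2 / n_cases_1
    return float(c / (c + 1))


def _binomial_power(n: int, p0: float, p1: float, alpha: float, sided: str) -> float:
    """Exact power of the binomial test of p = p0 vs p1 at sample size n."""
    if sided == "one":
        k_crit = _st.binom.isf(alpha, n, p0)  # reject if X > k_crit
        return float(_st.binom.sf(k_crit, n, p1))
    k_crit = _st.binom.isf(alpha / 2, n, p0)
    return float(_st.binom.sf(k_crit, n, p1))


def required_cohort_size(
    p0: float,
    p1: float,
    alpha: float = 0.05,
    power: float = 0.80,
    sided: str = "one",
) -> int:
    """Smallest n giving the target power to detect rate p1 against null p0.

    Starts from the normal-approximation sample-size formula and refines with
    an exact binomial power search (power is non-monotone in n because of
    discreteness, so the search scans a window around the approximation).
    """
    if not 0 < p0 < p1 < 1:
        raise ParameterError("need 0 < p0 < p1 < 1")
    a = alpha if sided == "one" else alpha / 2
    za = _st.norm.isf(a)
    zb = _st.norm.ppf(power)
    if zb <= -za:  # target power at or below the test level
        return 1
    n_approx = int(
        np.ceil(
            ((za * np.sqrt(p0 * (1 - p0)) + zb * np.sqrt(p1 * (1 - p1))) / (p1 - p0))
            ** 2
        )
    )
    if n_approx > 5_000_000:
        # exact refinement is pointless at this scale; the normal
        # approximation is accurate to far better than the discreteness step
        return n_approx
    lo = max(1, int(n_approx * 0.5))
    hi = max(lo + 10, int(n_approx * 2) + 10)
    best = None
    n = lo
    while n <= hi:
        if _binomial_power(n, p0, p1, alpha, sided) >= power:
            # discreteness: require stability over the next few n
            if all(
                _binomial_power(m, p0, p1, alpha, sided) >= power
                for m in range(n + 1, n + 6)
            ):
                best = n
                break
        n += 1
    return int(best if best is not None else n_approx)


@dataclass
class ComorbidityResults:
    """Joint risk, comorbidity odds ratio and derived epidemiology."""

    rho_liab: float
    t1: float
    t2: float
    p_joint: float
    recip_joint: float
    or_comorbid: float
    or_ci: tuple[float, float] | None
    n_required: int | None
    n_required_ci: tuple[int, int] | None
    misdiagnosis: float | None

    def summary(self) -> str:
        lines = [
            "Bivariate liability-threshold comorbidity model",
            f"  liability covariance rho: {self.rho_liab:.5f}",
            f"  thresholds: t1 = {self.t1:.4f}, t2 = {self.t2:.4f}",
            f"  joint lifetime risk: {self.p_joint:.3e}  (1 in {self.recip_joint:,.0f})",
            f"  comorbidity odds ratio: {self.or_comorbid:.3f}"
            + (
                f"  ({self.or_ci[0]:.3f}-{self.or_ci[1]:.3f})"
                if self.or_ci
                else ""
            ),
        ]
        if self.n_required is not None:
            ci = (
                f"  ({self.n_required_ci[0]:,}-{self.n_required_ci[1]:,})"
                if self.n_required_ci
                else ""
            )
            lines.append(f"  required incident cohort: {self.n_required:,}{ci}")
        if self.misdiagnosis is not None:
            lines.append(
                f"  misdiagnosis rate mimicking rho: {100 * self.misdiagnosis:.2f}%"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rho_liab": self.rho_liab,
            "t1": self.t1,
            "t2": self.t2,
            "p_joint": self.p_joint,
            "recip_joint": self.recip_joint,
            "or_comorbid": self.or_comorbid,
            "or_ci": list(self.or_ci) if self.or_ci else None,
            "n_required": self.n_required,
            "n_required_ci": list(self.n_required_ci) if self.n_required_ci else None,
            "misdiagnosis": self.misdiagnosis,
        }


class ComorbidityModel:
    """Comorbidity model parameterized by (h2_1, h2_2, r_g, K1, K2).

    ``rg_ci`` endpoints, when given, are propagated by plug-in (holding the
    heritabilities fixed) into the odds-ratio and cohort-size ranges.
    ``case_counts = (n_cases_1, n_cases_2)`` additionally reports the
    misdiagnosis rate that would mimic the implied genetic covariance.
    """

    def __init__(
        self,
        h2_1: float,
        h2_2: float,
        r_g: float,
        K1: float,
        K2: float,
        rg_ci: tuple[float, float] | None = None,
        case_counts: tuple[int, int] | None = None,
        alpha: float = 0.05,
        power: float = 0.80,
        sided: str = "one",
        compute_n_required: bool = True,
    ) -> None:
        self.h2_1, self.h2_2, self.r_g = h2_1, h2_2, r_g
        self.K1, self.K2 = K1, K2
        self.rg_ci = rg_ci
        self.case_counts = case_counts
        self.alpha, self.power, self.sided = alpha, power, sided
        self.compute_n_required = compute_n_required

    def _rho(self, r_g: float) -> float:
        return r_g * np.sqrt(self.h2_1 * self.h2_2)

    def fit(self) -> ComorbidityResults:
        rho = self._rho(self.r_g)
        p11 = joint_risk(self.K1, self.K2, rho)
        orr = comorbidity_or(self.K1, self.K2, rho)
        or_ci = None
        n_ci = None
        if self.rg_ci is not None:
            lo, hi = (self._rho(r) for r in self.rg_ci)
            or_ci = (comorbidity_or(self.K1, self.K2, lo),
                     comorbidity_or(self.K1, self.K2, hi))
        n_req = None
        if self.compute_n_required:
            # excess of trait 2 within an incident trait-1 cohort; undefined
            # when the model implies no excess (rho <= 0)
            def _n(rho_val):
                p1c = joint_risk(self.K1, self.K2, rho_val) / self.K1
                if p1c <= self.K2 * (1 + 1e-9):
                    return None
                return required_cohort_size(
                    self.K2, p1c, self.alpha, self.power, self.sided
                )

            n_req = _n(rho)
            if self.rg_ci is not None and n_req is not None:
                lo, hi = (self._rho(r) for r in self.rg_ci)
                n_hi, n_lo = _n(lo), _n(hi)
                n_ci = (n_lo, n_hi) if (n_lo and n_hi) else None
        mis = None
        if self.case_counts is not None:
            n1, n2 = self.case_counts
            mis = misdiagnosis_rate(rho, n2, n1)
        return ComorbidityResults(
            rho_liab=float(rho),
            t1=liability_threshold(self.K1),
            t2=liability_threshold(self.K2),
            p_joint=p11,
            recip_joint=1.0 / p11,
            or_comorbid=orr,
            or_ci=or_ci,
            n_required=n_req,
            n_required_ci=n_ci,
            misdiagnosis=mis,
        )
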