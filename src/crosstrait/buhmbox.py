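"""Cohort-heterogeneity (subgroup contamination) test.

Distinguishes genuine pleiotropy from cohort contamination: if a subset of
trait-B cases really has trait A (misdiagnosis), those individuals carry
trait-A risk alleles together, inducing positive pairwise correlations among
independent risk alleles in B cases that are absent in controls.  Under true
pleiotropy the excess risk is spread over all cases and no such correlation
arises, so the statistic stays null-calibrated.

The statistic aggregates case-minus-control dosage correlations over risk
allele pairs with weights increasing in the allele-frequency difference
delta = p_case - p_control:

    y_ij = (r_case,ij - r_control,ij) * sqrt(N_eff)
    S    = sum_{i<j} w_ij y_ij / sqrt(sum w_ij^2),   p = Phi(-S)

with N_eff = 1 / (1/N_case + 1/N_control) and default weights
``w_ij = delta_i delta_j / sqrt(p_i q_i p_j q_j)``; the alternative
``weights="freq"`` uses ``w_ij = delta_i delta_j sqrt(p_i q_i p_j q_j)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .types import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RiskAlleleSet:
    """Independent risk alleles with control and case allele frequencies.

    Variants must be pairwise independent in the reference population (e.g.,
    one per LD block).  Frequencies are oriented so that the risk allele is
    the counted allele: ``p_case >= p_control`` after orientation.
    """

    ids: np.ndarray
    p_control: np.ndarray
    p_case: np.ndarray

    def __post_init__(self) -> None:
        self.p_control = np.asarray(self.p_control, float)
        self.p_case = np.asarray(self.p_case, float)
        if not (len(self.ids) == len(self.p_control) == len(self.p_case)):
            raise ParameterError("risk set columns must align")
        if np.any((self.p_control <= 0) | (self.p_control >= 1)) or np.any(
            (self.p_case <= 0) | (self.p_case >= 1)
        ):
            raise ParameterError("allele frequencies must lie in (0, 1)")

    @classmethod
    def from_odds_ratios(cls, ids, p_control, gamma) -> "RiskAlleleSet":
        """Case frequencies implied by per-allele odds ratios gamma."""
        p = np.asarray(p_control, float)
        g = np.asarray(gamma, float)
        pc = g * p / (g * p + (1 - p))
        return cls(np.asarray(ids), p, pc)

    def oriented(self) -> "RiskAlleleSet":
        """Flip alleles so that delta = p_case - p_control >= 0 everywhere."""
        flip = self.p_case < self.p_control
        pc = np.where(flip, 1 - self.p_control, self.p_control)
        pa = np.where(flip, 1 - self.p_case, self.p_case)
        return RiskAlleleSet(self.ids, pc, pa)

    @property
    def delta(self) -> np.ndarray:
        return self.p_case - self.p_control


@dataclass
class BuhmboxResult:
    statistic: float
    p_value: float
    n_pairs: int
    n_variants: int

    def summary(self) -> str:
        return (
            "Cohort-heterogeneity test\n"
            f"  variants: {self.n_variants}  pairs: {self.n_pairs}\n"
            f"  S = {self.statistic:.4f}   one-sided P = {self.p_value:.4g}"
        )


def _corr(G: np.ndarray) -> np.ndarray:
    X = G - G.mean(axis=0)
    sd = X.std(axis=0)
    X = X / sd
    return (X.T @ X) / G.shape[0]


def buhmbox_statistic(
    case_genotypes: np.ndarray,
    control_genotypes: np.ndarray,
    risk_set: RiskAlleleSet,
    weights: str = "default",
) -> BuhmboxResult:
    """Heterogeneity statistic S (standard normal under the null) and one-sided p.

    ``case_genotypes`` / ``control_genotypes`` are dosage matrices over the
    risk-set variants (columns aligned with ``risk_set.ids``).  Monomorphic
    variants in either group are dropped with a log record.
    """
    Gc = np.asarray(case_genotypes, float)
    Gn = np.asarray(control_genotypes, float)
    if Gc.shape[1] != len(risk_set.ids) or Gn.shape[1] != len(risk_set.ids):
        raise ParameterError("genotype columns must match the risk set")
    # orient so the counted allele is the risk allele everywhere: flip both
    # the frequencies and the dosage coding of flipped variants
    rs = risk_set.oriented()
    flipped = risk_set.p_case < risk_set.p_control
    Gc = np.where(flipped[None, :], 2 - Gc, Gc)
    Gn = np.where(flipped[None, :], 2 - Gn, Gn)
    keep = (Gc.std(axis=0) > 0) & (Gn.std(axis=0) > 0)
    if not keep.all():
        logger.info("dropping %d monomorphic risk variants", int((~keep).sum()))
    Gc, Gn = Gc[:, keep], Gn[:, keep]
    m = Gc.shape[1]
    if m < 2:
        raise ParameterError("need at least 2 polymorphic risk variants")
    delta = rs.delta[keep]
    p = rs.p_control[keep]
    q = 1 - p

    r_case = _corr(Gc)
    r_ctrl = _corr(Gn)
    n_eff = 1.0 / (1.0 / Gc.shape[0] + 1.0 / Gn.shape[0])
    y = (r_case - r_ctrl) * np.sqrt(n_eff)

    if weights == "default":
        w = np.outer(delta, delta) / np.sqrt(np.outer(p * q, p * q))
    elif weights == "freq":
        w = np.outer(delta, delta) * np.sqrt(np.outer(p * q, p * q))
    else:
        raise ParameterError(f"unknown weight scheme {weights!r}")

    iu = np.triu_indices(m, k=1)
    s = float(np.sum(w[iu] * y[iu]) / np.sqrt(np.sum(w[iu] ** 2)))
    return BuhmboxResult(
        statistic=s,
        p_value=float(_st.norm.sf(s)),
        n_pairs=len(iu[0]),
        n_variants=m,
    )


class BuhmboxTest:
    """Model-object wrapper: ``BuhmboxTest(cases, controls, risk_set).fit()``."""

    def __init__(self, case_genotypes, control_genotypes,
                 risk_set: RiskAlleleSet, weights: str = "default") -> None:
        self.case_genotypes = case_genotypes
        self.control_genotypes = control_genotypes
        self.risk_set = risk_set
        self.weights = weights

    def fit(self) -> BuhmboxResult:
        return buhmbox_statistic(
            self.case_genotypes, self.control_genotypes, self.risk_set, self.weights
        )
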