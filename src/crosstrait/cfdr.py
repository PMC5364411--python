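"""Conditional false discovery rate (cFDR) pleiotropy analysis.

The cFDR of a variant for a primary trait, given an auxiliary conditioning
trait, is the empirical-cdf estimator

    cfdr_i = p1_i * #{j : p2_j <= p2_i} / #{j : p1_j <= p1_i and p2_j <= p2_i}

clipped to [p1_i, 1], with ties counted inclusively.  Conditioning statistics
are first residualized on LD score (so enrichment reflects shared signal, not
shared LD) and optionally decorrelated against the primary trait's z-scores
to remove the null correlation induced by shared controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .ldscore import LDScoreTable
from .regression import LdscResults
from .types import HaplotypePanel, ParameterError, SummaryStats, VariantTable

logger = logging.getLogger(__name__)

_EPS = 1e-8


def residualize_on_ldscore(
    stats: SummaryStats, scores: LDScoreTable, fit: LdscResults
) -> SummaryStats:
    """Remove the LD-score-proportional part of the chi-square statistics.

    ``chi2_resid = max(chi2 - slope * ell, eps)``; the residual p-value is the
    chi-square(1) survival probability.  Variants without an LD score are
    dropped (count logged).  Z signs are preserved.
    """
    ell_of = dict(zip(scores.variants.ids, scores.ell))
    ids = stats.variants.ids
    have = np.array([v in ell_of for v in ids])
    if not have.all():
        logger.info("dropping %d variants with no LD score", int((~have).sum()))
    ell = np.array([ell_of[v] for v in ids[have]])
    z = stats.z[have]
    chi2 = np.maximum(z**2 - fit.slope * ell, _EPS)
    z_resid = np.sign(z) * np.sqrt(chi2)
    vt = VariantTable(stats.variants.table.loc[have].reset_index(drop=True))
    return SummaryStats.from_z(vt, z_resid, stats.n_eff[have])


class _Fenwick:
    """Binary indexed tree for prefix counts over ranks 1..n."""

    def __init__(self, n: int) -> None:
        self.n = n
        self.tree = np.zeros(n + 1, dtype=np.int64)

    def add(self, i: int) -> None:
        while i <= self.n:
            self.tree[i] += 1
            i += i & (-i)

    def query(self, i: int) -> int:
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def cfdr(p_primary: np.ndarray, p_conditioning: np.ndarray) -> np.ndarray:
    """Per-variant conditional FDR (empirical-cdf estimator, inclusive ties).

    O(M log M) via a Fenwick tree over conditioning ranks; exactly equal to
    the brute-force double loop.
    """
    p1 = np.asarray(p_primary, float)
    p2 = np.asarray(p_conditioning, float)
    if p1.shape != p2.shape:
        raise ParameterError("p vectors must have equal length")
    if np.any((p1 <= 0) | (p1 > 1)) or np.any((p2 <= 0) | (p2 > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    m = len(p1)
    # dense 1-based ranks of p2 (ties share a rank)
    uniq, inv = np.unique(p2, return_inverse=True)
    key2 = inv.astype(np.int64) + 1
    csum = np.cumsum(np.bincount(inv, minlength=len(uniq)))
    n_cond = csum[inv]  # inclusive #{p2_j <= p2_i}

    # sweep in increasing p1, inserting whole p1 tie-groups before querying
    order1 = np.argsort(p1, kind="mergesort")
    sorted_p1 = p1[order1]
    bit = _Fenwick(len(uniq))
    n_both = np.empty(m, dtype=np.int64)
    k = 0
    while k < m:
        j = k
        while j + 1 < m and sorted_p1[j + 1] == sorted_p1[k]:
            j += 1
        for idx in order1[k:j + 1]:
            bit.add(int(key2[idx]))
        for idx in order1[k:j + 1]:
            n_both[idx] = bit.query(int(key2[idx]))
        k = j + 1
    out = p1 * n_cond / n_both
    return np.clip(out, p1, 1.0)


def shared_control_adjust(
    z_primary: np.ndarray, z_conditioning: np.ndarray, null_corr: float
) -> np.ndarray:
    """Decorrelate conditioning z-scores against the primary trait's under the null.

    ``z_adj = (z_cond - c * z_primary) / sqrt(1 - c^2)`` with ``c`` the null
    correlation induced by shared controls (from the bivariate cross-trait
    intercept, or the design value N_s / sqrt(N1 N2)).  Identity when c = 0.
    """
    if not abs(null_corr) < 1:
        raise ParameterError("|null_corr| must be < 1")
    z1 = np.asarray(z_primary, float)
    z2 = np.asarray(z_conditioning, float)
    return (z2 - null_corr * z1) / np.sqrt(1 - null_corr**2)


@dataclass
class Locus:
    lead: str
    members: list[str]
    min_cfdr: float


@dataclass
class CfdrResult:
    """Per-variant cFDR values and the clumped significant loci."""

    variants: VariantTable
    p_primary: np.ndarray
    p_conditioning: np.ndarray
    cfdr_values: np.ndarray
    loci: list[Locus]
    threshold: float

    def summary(self) -> str:
        lines = [
            "Conditional FDR analysis",
            f"  variants: {len(self.cfdr_values)}   threshold: {self.threshold}",
            f"  significant loci: {len(self.loci)}",
        ]
        for loc in self.loci:
            lines.append(
                f"    lead {loc.lead}  members {len(loc.members)}"
                f"  min cFDR {loc.min_cfdr:.3g}"
            )
        return "\n".join(lines)


def clump_loci(
    cfdr_values: np.ndarray,
    variants: VariantTable,
    panel: HaplotypePanel,
    r2_cut: float = 0.1,
    threshold: float = 0.01,
) -> list[Locus]:
    """Greedily clump sub-threshold variants into LD loci.

    Leads are taken in ascending cFDR order; members are all variants with
    panel r^2 > ``r2_cut`` to the lead.
    """
    vals = np.asarray(cfdr_values, float)
    ids = variants.ids
    pv = panel.variants.table
    col_of = {vid: k for k, vid in enumerate(pv["id"])}
    sub = np.where(vals < threshold)[0]
    sub = sub[np.argsort(vals[sub], kind="mergesort")]
    H = panel.haplotypes.astype(float)
    taken = set()
    loci: list[Locus] = []
    for i in sub:
        if ids[i] in taken or ids[i] not in col_of:
            continue
        x = H[:, col_of[ids[i]]]
        members = [ids[i]]
        taken.add(ids[i])
        for j in sub:
            vid = ids[j]
            if vid in taken or vid not in col_of:
                continue
            y = H[:, col_of[vid]]
            denom = x.std() * y.std()
            r = np.corrcoef(x, y)[0, 1] if denom > 0 else 0.0
            if r**2 > r2_cut:
                members.append(vid)
                taken.add(vid)
        loci.append(Locus(lead=ids[i], members=members, min_cfdr=float(vals[i])))
    return loci


def run_cfdr(
    primary: SummaryStats,
    conditioning: SummaryStats,
    scores: LDScoreTable,
    conditioning_fit: LdscResults,
    panel: HaplotypePanel | None = None,
    null_corr: float = 0.0,
    threshold: float = 0.01,
    r2_cut: float = 0.1,
) -> CfdrResult:
    """Full cFDR pipeline: residualize, overlap-adjust, estimate, clump."""
    cond = residualize_on_ldscore(conditioning, scores, conditioning_fit)
    merged_ids = set(primary.variants.ids) & set(cond.variants.ids)
    keep1 = np.array([v in merged_ids for v in primary.variants.ids])
    keep2_of = {v: i for i, v in enumerate(cond.variants.ids)}
    order2 = np.array([keep2_of[v] for v in primary.variants.ids[keep1]])
    z1 = primary.z[keep1]
    z2 = cond.z[order2]
    if null_corr != 0.0:
        z2 = shared_control_adjust(z1, z2, null_corr)
    p1 = 2 * _st.norm.sf(np.abs(z1))
    p2 = 2 * _st.norm.sf(np.abs(z2))
    p1 = np.clip(p1, 1e-300, 1.0)
    p2 = np.clip(p2, 1e-300, 1.0)
    vals = cfdr(p1, p2)
    vt = VariantTable(primary.variants.table.loc[keep1].reset_index(drop=True))
    loci = clump_loci(vals, vt, panel, r2_cut, threshold) if panel is not None else []
    return CfdrResult(
        variants=vt, p_primary=p1, p_conditioning=p2,
        cfdr_values=vals, loci=loci, threshold=threshold,
    )
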