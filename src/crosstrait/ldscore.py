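"""LD score computation from a haplotype reference panel.

The LD score of variant j is the sum, over all panel variants k within a
genetic-map window, of the adjusted squared correlation
``r2_adj = r2 - (1 - r2)/(n - 2)`` (the finite-panel bias correction), with
the self term included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import HaplotypePanel, ParameterError, VariantTable


@dataclass
class LDScoreTable:
    """Per-variant LD scores aligned 1:1 with a variant table."""

    variants: VariantTable
    ell: np.ndarray

    def __post_init__(self) -> None:
        self.ell = np.asarray(self.ell, float)
        if len(self.ell) != len(self.variants):
            raise ParameterError("ell must align with variants")


def compute_ld_scores(
    panel: HaplotypePanel,
    window_cm: float = 1.0,
    regression_subset: set[str] | None = None,
) -> LDScoreTable:
    """Compute adjusted LD scores in ``window_cm`` centiMorgan windows.

    When ``regression_subset`` is given, scores are reported only for those
    variant ids, but each score still sums over *all* panel variants in the
    window (the tag set and the regression set differ, as in real pipelines).
    """
    if window_cm <= 0:
        raise ParameterError("window_cm must be positive")
    n = panel.n_haplotypes
    table = panel.variants.table
    ell = np.empty(len(table))
    H = panel.haplotypes.astype(float)
    sd = H.std(axis=0)
    X = (H - H.mean(axis=0)) / sd
    for chrom, sub in table.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        cm = sub["cm"].to_numpy()
        R = (X[:, idx].T @ X[:, idx]) / n
        r2 = R**2
        adj = r2 - (1 - r2) / (n - 2)
        within = np.abs(cm[:, None] - cm[None, :]) <= window_cm
        ell[idx] = (adj * within).sum(axis=1)
    if regression_subset is not None:
        keep = table["id"].isin(regression_subset).to_numpy()
        return LDScoreTable(
            VariantTable(table.loc[keep].reset_index(drop=True)), ell[keep]
        )
    return LDScoreTable(panel.variants, ell)
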