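"""Core containers shared by all pipeline stages.

Variant metadata, haplotype reference panels, per-trait association summary
statistics and the generating/assumed genetic architecture are passed between
modules as the lightweight dataclasses defined here.  All of them wrap plain
numpy arrays / pandas DataFrames so they serialize to the text dialects in
:mod:`crosstrait.io` without loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st


class ParameterError(ValueError):
    """Invalid model or generator parameter."""


class GenerationError(RuntimeError):
    """A synthetic cohort could not be produced within the attempt budget."""


class AnalysisError(RuntimeError):
    """An analysis stage received degenerate input."""


VARIANT_COLUMNS = ["chrom", "pos", "cm", "id", "a1", "a2", "maf"]


@dataclass
class VariantTable:
    """Per-variant metadata: position, map position, alleles, frequency.

    Positions are 1-based (PLINK/BIM convention); ``cm`` is the genetic-map
    position in centiMorgans.  ``maf`` is the minor allele frequency.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ParameterError(f"variant table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        if t["id"].duplicated().any():
            raise ParameterError("variant ids must be unique")
        for _, sub in t.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ParameterError("pos must be strictly increasing within chrom")
            if not np.all(np.diff(sub["cm"].to_numpy()) >= 0):
                raise ParameterError("cm must be non-decreasing within chrom")
        maf = t["maf"].to_numpy(float)
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ParameterError("maf must lie in (0, 0.5]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()


@dataclass
class HaplotypePanel:
    """Reference panel: binary haplotype matrix plus LD-block structure.

    ``haplotypes`` is (n_haplotypes, n_variants) with 0/1 entries;
    ``block_bounds`` is a list of half-open ``(start, stop)`` variant-index
    intervals that partition the variant range.  Variants in different blocks
    are generated independently, so cross-block LD is zero by construction.
    """

    variants: VariantTable
    haplotypes: np.ndarray
    block_bounds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.haplotypes.shape[1] != len(self.variants):
            raise ParameterError("haplotype column count must equal variant count")
        freqs = self.haplotypes.mean(axis=0)
        if np.any(freqs < 0.005) or np.any(freqs > 0.995):
            raise ParameterError("panel allele frequencies must lie in [0.005, 0.995]")
        bounds = sorted(self.block_bounds)
        if bounds[0][0] != 0 or bounds[-1][1] != len(self.variants) or any(
            bounds[i][1] != bounds[i + 1][0] for i in range(len(bounds) - 1)
        ):
            raise ParameterError("blocks must partition the variant index range")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def freqs(self) -> np.ndarray:
        """Per-variant allele-1 frequency in the panel."""
        return self.haplotypes.mean(axis=0)


@dataclass
class GeneticArchitecture:
    """Generating (or assumed) parameters of the bivariate polygenic model.

    Defaults are the ALS/schizophrenia study conditions: liability-scale SNP
    heritabilities 8.2% and 23%, genetic correlation 14.3%, lifetime risks
    1/400 and 1/100.
    """

    h2_liab_1: float = 0.082
    h2_liab_2: float = 0.23
    r_g: float = 0.143
    K_1: float = 1 / 400
    K_2: float = 1 / 100
    prop_causal: float = 0.1

    def __post_init__(self) -> None:
        for h in (self.h2_liab_1, self.h2_liab_2):
            if not 0 <= h <= 1:
                raise ParameterError("heritabilities must lie in [0, 1]")
        if not -1 <= self.r_g <= 1:
            raise ParameterError("r_g must lie in [-1, 1]")
        for K in (self.K_1, self.K_2):
            if not 0 < K < 1:
                raise ParameterError("lifetime risks must lie in (0, 1)")
        if not 0 < self.prop_causal <= 1:
            raise ParameterError("prop_causal must lie in (0, 1]")
        # PSD check of the per-variant effect covariance
        rho = self.rho_g
        if rho**2 > self.h2_liab_1 * self.h2_liab_2 + 1e-12:
            raise ParameterError("implied effect covariance is not PSD")

    @property
    def rho_g(self) -> float:
        """Liability-scale genetic covariance r_g * sqrt(h2_1 * h2_2)."""
        return self.r_g * np.sqrt(self.h2_liab_1 * self.h2_liab_2)


@dataclass
class CohortDesign:
    """Cohort sizes for the two case-control studies, including shared controls."""

    n_cases_1: int = 400
    n_controls_1: int = 600
    n_cases_2: int = 400
    n_controls_2: int = 600
    n_shared_controls: int = 0
    n_strata: int = 1
    stratum_fst: float = 0.0

    def __post_init__(self) -> None:
        counts = (self.n_cases_1, self.n_controls_1, self.n_cases_2,
                  self.n_controls_2, self.n_shared_controls, self.n_strata)
        if any(c < 0 for c in counts):
            raise ParameterError("cohort counts must be non-negative")
        if self.n_shared_controls > min(self.n_controls_1, self.n_controls_2):
            raise ParameterError("n_shared_controls exceeds a cohort's control count")


@dataclass
class SummaryStats:
    """Per-variant association results for one trait.

    ``z`` is the association z-score, ``p`` the two-sided p-value
    (p = 2*Phi(-|z|)) and ``n_eff`` the per-variant sample size.  ``beta``
    optionally carries per-allele log-odds effect sizes for risk scoring.
    """

    variants: VariantTable
    z: np.ndarray
    p: np.ndarray
    n_eff: np.ndarray
    beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = len(self.variants)
        self.z = np.asarray(self.z, float)
        self.p = np.asarray(self.p, float)
        self.n_eff = np.asarray(self.n_eff, float)
        if not (len(self.z) == len(self.p) == len(self.n_eff) == m):
            raise ParameterError("summary statistic columns must align with variants")
        if np.any(self.n_eff <= 0):
            raise ParameterError("n_eff must be positive")
        if not np.allclose(self.p, 2 * _st.norm.sf(np.abs(self.z)), atol=1e-6):
            raise ParameterError("p must equal 2*Phi(-|z|)")

    @classmethod
    def from_z(cls, variants: VariantTable, z: np.ndarray, n_eff,
               beta: np.ndarray | None = None) -> "SummaryStats":
        z = np.asarray(z, float)
        n = np.broadcast_to(np.asarray(n_eff, float), z.shape).copy()
        return cls(variants, z, 2 * _st.norm.sf(np.abs(z)), n, beta)

    @property
    def chi2(self) -> np.ndarray:
        return self.z**2

    def to_frame(self) -> pd.DataFrame:
        out = self.variants.table.copy()
        out["z"] = self.z
        out["p"] = self.p
        out["n_eff"] = self.n_eff
        if self.beta is not None:
            out["beta"] = self.beta
        return out


@dataclass
class Cohort:
    """Individual-level genotypes (0/1/2 dosages) with phenotype labels."""

    genotypes: np.ndarray
    phenotype: np.ndarray
    variants: VariantTable
    strata: np.ndarray | None = None
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.genotypes.shape[0]
        if len(self.phenotype) != n:
            raise ParameterError("phenotype length must match genotype rows")
        if self.genotypes.shape[1] != len(self.variants):
            raise ParameterError("genotype columns must match variants")
        if self.ids is None:
            self.ids = np.array([f"ind{i}" for i in range(n)])

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]
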