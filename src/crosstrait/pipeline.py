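"""Config-driven orchestration of the full cross-trait analysis.

``run_pipeline`` executes simulate -> LD scores -> h2 / r_g -> PRS -> cFDR ->
comorbidity -> heterogeneity on synthetic data and writes a consolidated
JSON + text report.  Every artifact carries the config hash; a stage failure
halts with the stage name while partial outputs persist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .buhmbox import BuhmboxTest, RiskAlleleSet
from .cfdr import run_cfdr
from .ldscore import compute_ld_scores
from .liability import ComorbidityModel
from .prs import PrsConfig, PrsModel
from .regression import BivariateLdscModel, LdscModel
from .simulate import (
    compute_summary_stats,
    draw_effect_sizes,
    simulate_bivariate_cohorts,
    simulate_reference_panel,
)
from .types import CohortDesign, GeneticArchitecture, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class PanelConfig:
    n_haplotypes: int = 200
    n_variants: int = 400
    block_size_mean: int = 25


@dataclass
class LdscConfig:
    window_cm: float = 1.0
    n_blocks: int = 50
    constrained_intercept: bool = True


@dataclass
class CfdrConfig:
    threshold: float = 0.01
    r2_cut: float = 0.1


@dataclass
class ComorbidityConfig:
    alpha: float = 0.05
    power: float = 0.80
    sided: str = "one"


@dataclass
class PipelineConfig:
    """Declarative description of one synthetic end-to-end run."""

    seed: int = 0
    outdir: str = "crosstrait_out"
    architecture: GeneticArchitecture = field(default_factory=GeneticArchitecture)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    panel: PanelConfig = field(default_factory=PanelConfig)
    ldsc: LdscConfig = field(default_factory=LdscConfig)
    prs: PrsConfig = field(default_factory=PrsConfig)
    cfdr: CfdrConfig = field(default_factory=CfdrConfig)
    comorbidity: ComorbidityConfig = field(default_factory=ComorbidityConfig)

    _BLOCKS = {
        "architecture": GeneticArchitecture,
        "cohort": CohortDesign,
        "panel": PanelConfig,
        "ldsc": LdscConfig,
        "prs": PrsConfig,
        "cfdr": CfdrConfig,
        "comorbidity": ComorbidityConfig,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for req in ("architecture", "cohort"):
            if req not in d:
                raise ParameterError(f"config is missing the required {req!r} block")
        kwargs = {}
        for key, typ in cls._BLOCKS.items():
            if key in d:
                block = d.pop(key)
                known = {f.name for f in dataclasses.fields(typ)}
                unknown = set(block) - known
                if unknown:
                    raise ParameterError(f"unknown keys in {key!r}: {sorted(unknown)}")
                if key == "prs" and "p_thresholds" in block:
                    block["p_thresholds"] = tuple(block["p_thresholds"])
                kwargs[key] = typ(**block)
        known_top = {"seed", "outdir"}
        unknown = set(d) - known_top
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "outdir": self.outdir}
        for key, _ in self._BLOCKS.items():
            block = dataclasses.asdict(getattr(self, key))
            if key == "prs":
                block["p_thresholds"] = list(block["p_thresholds"])
            out[key] = block
        return out


def run_pipeline(config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.to_dict()
    seed = config.seed
    report: dict = {"config_hash": cio.param_hash(params)}
    stage = "simulate"
    try:
        panel = simulate_reference_panel(
            config.panel.n_haplotypes, config.panel.n_variants,
            config.panel.block_size_mean, seed=seed,
        )
        effects = draw_effect_sizes(config.architecture, panel.variants, seed=seed + 1)
        c1, c2 = simulate_bivariate_cohorts(
            panel, effects, config.architecture, config.cohort, seed=seed + 2
        )
        cio.write_bim(panel.variants, outdir / "panel.bim", seed, params)
        cio.write_raw(c1, outdir / "cohort1.raw", seed, params)
        cio.write_raw(c2, outdir / "cohort2.raw", seed, params)

        stage = "sumstats"
        stats1 = compute_summary_stats(c1.genotypes, c1.phenotype, c1.variants)
        stats2 = compute_summary_stats(c2.genotypes, c2.phenotype, c2.variants)
        # per-allele effect sizes for risk scoring
        stats2.beta = stats2.z / np.sqrt(stats2.n_eff)
        cio.write_summary_stats(stats1, outdir / "trait1.sumstats.txt", seed, params)
        cio.write_summary_stats(stats2, outdir / "trait2.sumstats.txt", seed, params)

        stage = "ldscore"
        scores = compute_ld_scores(panel, config.ldsc.window_cm)
        cio.write_ld_scores(scores, outdir / "panel.l2.ldscore", seed, params)

        stage = "h2"
        P1 = config.cohort.n_cases_1 / (config.cohort.n_cases_1 + config.cohort.n_controls_1)
        fit1 = LdscModel(
            stats1, scores,
            constrained_intercept=config.ldsc.constrained_intercept,
            K=config.architecture.K_1, P=P1,
        ).fit(config.ldsc.n_blocks)
        report["h2_trait1"] = fit1.to_dict()

        stage = "rg"
        biv = BivariateLdscModel(stats1, stats2, scores).fit(config.ldsc.n_blocks)
        report["rg"] = biv.to_dict()

        stage = "prs"
        prs_res = PrsModel(c1, stats2, panel, config.prs).fit()
        report["prs"] = {
            "table": prs_res.table.to_dict(orient="records"),
            "best_threshold": prs_res.best_threshold,
            "n_clumped": prs_res.n_clumped,
        }

        stage = "cfdr"
        fit2_free = LdscModel(stats2, scores, constrained_intercept=False).fit(
            config.ldsc.n_blocks
        )
        ns = config.cohort.n_shared_controls
        n1 = config.cohort.n_cases_1 + config.cohort.n_controls_1
        n2 = config.cohort.n_cases_2 + config.cohort.n_controls_2
        null_corr = ns / np.sqrt(n1 * n2)
        cf = run_cfdr(
            stats1, stats2, scores, fit2_free, panel,
            null_corr=null_corr,
            threshold=config.cfdr.threshold, r2_cut=config.cfdr.r2_cut,
        )
        report["cfdr"] = {
            "n_loci": len(cf.loci),
            "loci": [
                {"lead": l.lead, "n_members": len(l.members), "min_cfdr": l.min_cfdr}
                for l in cf.loci
            ],
        }

        stage = "comorbidity"
        # the comorbidity model is parameterized by the configured (assumed)
        # architecture so the stage is deterministic given the config; the
        # estimated r_g and its jackknife CI are reported alongside in "rg"
        com = ComorbidityModel(
            config.architecture.h2_liab_1, config.architecture.h2_liab_2,
            config.architecture.r_g,
            config.architecture.K_1, config.architecture.K_2,
            case_counts=(config.cohort.n_cases_1, config.cohort.n_cases_2),
            alpha=config.comorbidity.alpha, power=config.comorbidity.power,
            sided=config.comorbidity.sided,
        ).fit()
        report["comorbidity"] = com.to_dict()

        stage = "buhmbox"
        risk = _risk_set_from_cohort(panel, effects, c1)
        col_of = {v: k for k, v in enumerate(panel.variants.ids)}
        cols = [col_of[v] for v in risk.ids]
        bb = BuhmboxTest(
            c2.genotypes[c2.phenotype == 1][:, cols],
            c2.genotypes[c2.phenotype == 0][:, cols],
            risk,
        ).fit()
        report["buhmbox"] = {"S": bb.statistic, "p": bb.p_value}
    except Exception as err:
        cio.write_json(report, outdir / "report.partial.json", seed, params)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    cio.write_json(report, outdir / "report.json", seed, params)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(f"# crosstrait report config={report['config_hash']}\n")
        fh.write(json.dumps(report, indent=2, default=cio._json_default))
    return report


def _risk_set_from_cohort(panel, effects, cohort) -> RiskAlleleSet:
    """One trait-1 risk variant per LD block, frequencies from the cohort."""
    beta1 = effects["beta1"].to_numpy()
    ids = panel.variants.ids
    chosen = []
    for s, e in panel.block_bounds:
        j = s + int(np.argmax(np.abs(beta1[s:e])))
        if beta1[j] != 0:
            chosen.append(j)
    cases = cohort.genotypes[cohort.phenotype == 1]
    ctrls = cohort.genotypes[cohort.phenotype == 0]
    p_case = np.clip(cases[:, chosen].mean(axis=0) / 2, 0.01, 0.99)
    p_ctrl = np.clip(ctrls[:, chosen].mean(axis=0) / 2, 0.01, 0.99)
    return RiskAlleleSet(ids[chosen], p_ctrl, p_case)
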