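"""Text-dialect readers and writers.

Four dialects, all tab-delimited text:

* summary statistics: ``SNP CHR BP A1 A2 Z P N`` (``OR`` accepted in place of
  ``Z``; extra ``CM``/``MAF``/``BETA`` columns are written for lossless
  round-trips and ignored by other tools); missing values as ``NA``;
* variant metadata: PLINK BIM (``chrom id cm pos a1 a2``);
* genotypes: PLINK RAW dosage (``FID IID PAT MAT SEX PHENOTYPE`` then one
  column per counted allele);
* LD scores: LDSC ``.l2.ldscore`` (``CHR SNP BP L2``).

Every artifact written here starts with a ``#`` header line embedding the
seed and a parameter hash, which readers skip.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd
from scipy import stats as _st

from .ldscore import LDScoreTable
from .types import Cohort, ParameterError, SummaryStats, VariantTable

logger = logging.getLogger(__name__)


def param_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _header_line(seed, params: dict | None) -> str:
    return f"# crosstrait seed={seed} params={param_hash(params or {})}\n"


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                       float_precision="round_trip")


def write_summary_stats(stats: SummaryStats, path, seed=0, params=None) -> None:
    t = stats.variants.table
    out = pd.DataFrame(
        {
            "SNP": t["id"], "CHR": t["chrom"], "BP": t["pos"],
            "A1": t["a1"], "A2": t["a2"],
            "Z": stats.z, "P": stats.p, "N": stats.n_eff,
            "CM": t["cm"], "MAF": t["maf"],
        }
    )
    if stats.beta is not None:
        out["BETA"] = stats.beta
    with open(path, "w") as fh:
        fh.write(_header_line(seed, params))
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path) -> SummaryStats:
    """Read the summary-stat dialect; OR is log-converted when Z is absent.

    Malformed rows (missing id/position or no usable effect statistic) are
    counted and skipped.  Strand-ambiguous variants are flagged in the log.
    """
    raw = _read_table(path)
    cols = {c.upper(): c for c in raw.columns}
    for req in ("SNP", "CHR", "BP", "A1", "A2", "P", "N"):
        if req not in cols:
            raise ParameterError(
                f"no recognizable {req} column; found {list(raw.columns)}"
            )
    if "Z" not in cols and "OR" not in cols and "BETA" not in cols:
        raise ParameterError(
            f"no recognizable effect column (Z/OR/BETA); found {list(raw.columns)}"
        )
    n0 = len(raw)
    raw = raw.dropna(subset=[cols[c] for c in ("SNP", "CHR", "BP", "P", "N")])
    beta = None
    if "Z" in cols:
        raw = raw.dropna(subset=[cols["Z"]])
        z = raw[cols["Z"]].to_numpy(float)
        if "BETA" in cols:
            beta = raw[cols["BETA"]].to_numpy(float)
    else:
        if "OR" in cols:
            raw = raw.dropna(subset=[cols["OR"]])
            beta = np.log(raw[cols["OR"]].to_numpy(float))
        else:
            raw = raw.dropna(subset=[cols["BETA"]])
            beta = raw[cols["BETA"]].to_numpy(float)
        # reconstitute z from beta and p (sign from beta)
        p = raw[cols["P"]].to_numpy(float)
        z = np.sign(beta) * _st.norm.isf(np.clip(p, 1e-300, 1) / 2)
        z = np.where(beta == 0, 0.0, z)
    skipped = n0 - len(raw)
    if skipped:
        logger.info("skipped %d malformed rows", skipped)
    amb = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    n_amb = sum(
        (a1, a2) in amb for a1, a2 in zip(raw[cols["A1"]], raw[cols["A2"]])
    )
    if n_amb:
        logger.info("%d strand-ambiguous variants flagged", n_amb)
    pos = raw[cols["BP"]].to_numpy(int)
    table = pd.DataFrame(
        {
            "chrom": raw[cols["CHR"]].to_numpy(int),
            "pos": pos,
            "cm": raw[cols["CM"]].to_numpy(float) if "CM" in cols else pos * 1e-6,
            "id": raw[cols["SNP"]].to_numpy(),
            "a1": raw[cols["A1"]].to_numpy(),
            "a2": raw[cols["A2"]].to_numpy(),
            "maf": raw[cols["MAF"]].to_numpy(float) if "MAF" in cols else 0.25,
        }
    )
    return SummaryStats.from_z(
        VariantTable(table), z, raw[cols["N"]].to_numpy(float), beta
    )


def write_bim(variants: VariantTable, path, seed=0, params=None) -> None:
    t = variants.table
    out = t[["chrom", "id", "cm", "pos", "a1", "a2"]]
    with open(path, "w") as fh:
        fh.write(_header_line(seed, params))
        out.to_csv(fh, sep="\t", index=False, header=False, float_format="%.17g")


def read_bim(path, maf: float | np.ndarray = 0.25) -> VariantTable:
    """Read BIM-dialect variant metadata; the dialect carries no frequency,
    so ``maf`` supplies it (scalar or per-variant)."""
    raw = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        float_precision="round_trip",
    )
    raw["maf"] = maf
    return VariantTable(raw[["chrom", "pos", "cm", "id", "a1", "a2", "maf"]])


def write_raw(cohort: Cohort, path, seed=0, params=None) -> None:
    t = cohort.variants.table
    dosage_cols = [f"{vid}_{a1}" for vid, a1 in zip(t["id"], t["a1"])]
    out = pd.DataFrame(cohort.genotypes, columns=dosage_cols)
    meta = pd.DataFrame(
        {
            "FID": cohort.ids, "IID": cohort.ids,
            "PAT": 0, "MAT": 0, "SEX": 0,
            "PHENOTYPE": np.asarray(cohort.phenotype) + 1,  # PLINK 1/2 coding
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_line(seed, params))
        pd.concat([meta, out], axis=1).to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_raw(path, variants: VariantTable | None = None) -> Cohort:
    raw = _read_table(path)
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    dosage_cols = [c for c in raw.columns if c not in meta_cols]
    G = raw[dosage_cols].to_numpy(float)
    y = raw["PHENOTYPE"].to_numpy(int) - 1
    if variants is None:
        ids = [c.rsplit("_", 1)[0] for c in dosage_cols]
        a1 = [c.rsplit("_", 1)[1] for c in dosage_cols]
        freq = np.clip(G.mean(axis=0) / 2, 1e-3, 1 - 1e-3)
        pos = np.arange(1, len(ids) + 1)
        variants = VariantTable(
            pd.DataFrame(
                {
                    "chrom": 1, "pos": pos, "cm": pos * 1e-6, "id": ids,
                    "a1": a1, "a2": "N",
                    "maf": np.minimum(freq, 1 - freq),
                }
            )
        )
    return Cohort(G, y, variants, ids=raw["IID"].to_numpy())


def write_ld_scores(scores: LDScoreTable, path, seed=0, params=None) -> None:
    t = scores.variants.table
    out = pd.DataFrame(
        {"CHR": t["chrom"], "SNP": t["id"], "BP": t["pos"], "L2": scores.ell}
    )
    with open(path, "w") as fh:
        fh.write(_header_line(seed, params))
        out.to_csv(fh, sep="\t", index=False)


def read_ld_scores(path, variants: VariantTable | None = None) -> LDScoreTable:
    raw = _read_table(path)
    if variants is None:
        pos = raw["BP"].to_numpy(int)
        variants = VariantTable(
            pd.DataFrame(
                {
                    "chrom": raw["CHR"].to_numpy(int), "pos": pos, "cm": pos * 1e-6,
                    "id": raw["SNP"].to_numpy(), "a1": "A", "a2": "G", "maf": 0.25,
                }
            )
        )
    return LDScoreTable(variants, raw["L2"].to_numpy(float))


def write_json(obj: dict, path, seed=0, params=None) -> None:
    payload = {"_meta": {"seed": seed, "params": param_hash(params or {})}, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
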