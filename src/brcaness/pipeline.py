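"""End-to-end orchestration: discover -> score -> stratify -> associate.

Everything here is glue over the library modules; the value added is a
single config object, deterministic outputs (stable row order, no embedded
timestamps) and a flat association report with one row per
(cohort, score, covariate, test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discovery import ScreenParams, ScreenResult, intersect_cohorts, per_gene_screen
from .gsva import GsvaParams, gsva_scores
from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    read_clinical,
    read_expression,
    read_gmt,
    tpm_to_log2,
    write_gmt,
)
from .scores import (
    CytConfig,
    IciConfig,
    cyt_score,
    ici_score,
    load_brcaness_signature,
    load_dna_repair_set,
)
from .stratify import (
    StratifyParams,
    fisher_exact,
    km_logrank,
    kruskal_wallis,
    mann_whitney,
    response_auc,
    spearman,
    tertile_split,
)

logger = logging.getLogger(__name__)

__all__ = ["CohortSpec", "PipelineConfig", "run_discovery", "run_full_analysis"]


@dataclass(frozen=True)
class CohortSpec:
    name: str
    expr: str
    clin: str
    scale: str = "tpm"
    roles: dict = field(default_factory=dict)

    def load(self) -> tuple[ExpressionMatrix, ClinicalTable]:
        matrix = read_expression(self.expr, scale=self.scale, cohort=self.name)
        clinical = read_clinical(self.clin, roles=self.roles or None)
        common = [s for s in matrix.sample_ids if s in set(clinical.sample_ids)]
        if not common:
            raise ValueError(f"cohort {self.name}: no samples shared by matrix and clinical")
        matrix = ExpressionMatrix(matrix.values[common], matrix.scale, matrix.cohort)
        clinical = ClinicalTable(clinical.data.loc[common], clinical.roles)
        return matrix, clinical


@dataclass(frozen=True)
class PipelineConfig:
    cohorts: tuple[CohortSpec, ...]
    out_dir: str
    signature_gmt: str | None = None  # None -> discover (>=2 cohorts) or packaged
    screen: ScreenParams = field(default_factory=ScreenParams)
    gsva: GsvaParams = field(default_factory=GsvaParams)
    stratify: StratifyParams = field(default_factory=StratifyParams)
    with_dna_repair: bool = True
    with_cyt: bool = False
    with_ici: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = tuple(CohortSpec(**c) for c in raw["cohorts"])
        return cls(
            cohorts=cohorts,
            out_dir=raw["out_dir"],
            signature_gmt=raw.get("signature_gmt"),
            screen=ScreenParams(**raw.get("screen", {})),
            gsva=GsvaParams(**raw.get("gsva", {})),
            stratify=StratifyParams(**raw.get("stratify", {})),
            with_dna_repair=bool(raw.get("with_dna_repair", True)),
            with_cyt=bool(raw.get("with_cyt", False)),
            with_ici=bool(raw.get("with_ici", False)),
            seed=int(raw.get("seed", 0)),
        )


def _mutation_labels(clinical: ClinicalTable) -> np.ndarray:
    if "mutation_status" not in clinical.roles:
        raise ValueError("clinical table lacks a mutation_status column mapping")
    return clinical.column("mutation_status").to_numpy(dtype=float).astype(int)


def run_discovery(config: PipelineConfig) -> ScreenResult:
    """Per-gene AUC screen in every cohort, intersected into a signature.

    Persists per-cohort AUC tables and the signature GMT under out_dir.
    """
    if len(config.cohorts) < 2:
        raise ValueError("signature discovery needs at least 2 cohorts")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = []
    for spec in config.cohorts:
        matrix, clinical = spec.load()
        labels = _mutation_labels(clinical)
        table = per_gene_screen(matrix, labels)
        table.rename("auc").to_csv(out / f"auc_{spec.name}.tsv", sep="\t",
                                   index_label="gene")
        logger.info("cohort %s: screened %d genes (%d mutants / %d samples)",
                    spec.name, len(table), int(labels.sum()), len(labels))
        tables.append(table)
    result = intersect_cohorts(tables, config.screen)
    if result.signature is None:
        logger.warning("no gene exceeded AUC %.3f in all %d cohorts; empty signature",
                       config.screen.auc_threshold, len(tables))
    else:
        write_gmt(GeneSetCollection((result.signature,)), out / "signature.gmt")
        logger.info("signature: %d genes above AUC %.3f in all cohorts",
                    len(result.signature), config.screen.auc_threshold)
    return result


def _resolve_signature(config: PipelineConfig) -> GeneSet:
    if config.signature_gmt:
        return read_gmt(config.signature_gmt).sets[0]
    if len(config.cohorts) >= 2:
        result = run_discovery(config)
        if result.signature is not None:
            return result.signature
        logger.warning("discovery yielded an empty signature; falling back to packaged panel")
    return load_brcaness_signature()


def _score_cohort(
    spec: CohortSpec, signature: GeneSet, config: PipelineConfig
) -> tuple[pd.DataFrame, ClinicalTable]:
    matrix, clinical = spec.load()
    tpm = matrix if matrix.scale == "tpm" else None
    log2 = tpm_to_log2(matrix) if matrix.scale == "tpm" else matrix

    # one gsva call for all sets: the kernel-CDF transform dominates runtime
    gene_sets = [GeneSet("brcaness", "signature", signature.genes)]
    if config.with_dna_repair:
        repair = load_dna_repair_set()
        gene_sets.append(GeneSet("dna_repair", "hallmark DNA repair", repair.genes))

    scores = gsva_scores(log2, GeneSetCollection(tuple(gene_sets)), config.gsva)
    scores.index.name = "sample_id"
    if config.with_cyt:
        if tpm is None:
            raise ValueError("CYT requires TPM-scale input")
        scores["cyt"] = cyt_score(tpm, CytConfig())
    if config.with_ici:
        scores["ici"] = ici_score(log2, IciConfig())
    scores["brcaness_high"] = tertile_split(scores["brcaness"].to_numpy(), config.stratify)
    return scores, clinical


def _associate(
    cohort: str, scores: pd.DataFrame, clinical: ClinicalTable
) -> tuple[list[dict], dict[str, pd.DataFrame]]:
    rows: list[dict] = []
    points: dict[str, pd.DataFrame] = {}
    high = scores["brcaness_high"].to_numpy()
    score_cols = [c for c in scores.columns if c != "brcaness_high"]

    def add(score_name, covariate, test, comp):
        rows.append({
            "cohort": cohort, "score": score_name, "covariate": covariate,
            "test": test, "statistic": comp.statistic, "p_value": comp.p_value,
            "n": int(sum(comp.group_sizes)),
        })

    for role, covariate in (("mutation_status", "mutation"), ("response", "response")):
        if role not in clinical.roles:
            continue
        col = clinical.column(role).to_numpy(dtype=float)
        mask = np.isfinite(col)
        y = col[mask].astype(int)
        if y.sum() == 0 or y.sum() == mask.sum():
            logger.warning("%s: %s column single-class; skipped", cohort, covariate)
            continue
        for sc in score_cols:
            v = scores[sc].to_numpy()[mask]
            add(sc, covariate, "mann_whitney", mann_whitney(v[y == 1], v[y == 0]))
            auc, roc = response_auc(v, y)
            rows.append({"cohort": cohort, "score": sc, "covariate": covariate,
                         "test": "roc_auc", "statistic": auc, "p_value": float("nan"),
                         "n": int(mask.sum())})
            points[f"roc_{cohort}_{sc}_{covariate}"] = roc
        table = np.array([
            [int(((high == 1) & mask & (col == 1)).sum()),
             int(((high == 1) & mask & (col == 0)).sum())],
            [int(((high == 0) & mask & (col == 1)).sum()),
             int(((high == 0) & mask & (col == 0)).sum())],
        ])
        add("brcaness_high", covariate, "fisher_exact", fisher_exact(table))

    if "subtype" in clinical.roles:
        sub = clinical.column("subtype")
        groups = [scores["brcaness"].to_numpy()[(sub == lev).to_numpy()]
                  for lev in sorted(sub.dropna().unique())]
        if len(groups) >= 2:
            add("brcaness", "subtype", "kruskal_wallis", kruskal_wallis(groups))

    numeric_cols = [c for c in clinical.data.columns
                    if c not in set(clinical.roles.values())
                    and pd.api.types.is_numeric_dtype(clinical.data[c])]
    for other in [c for c in score_cols if c != "brcaness"] + numeric_cols:
        v = clinical.data[other].to_numpy(dtype=float) if other in numeric_cols \
            else scores[other].to_numpy()
        mask = np.isfinite(v)
        if mask.sum() >= 3 and np.unique(v[mask]).size > 1:
            add("brcaness", other, "spearman",
                spearman(scores["brcaness"].to_numpy()[mask], v[mask]))

    if "survival_time" in clinical.roles and "survival_event" in clinical.roles:
        t = clinical.column("survival_time").to_numpy(dtype=float)
        e = clinical.column("survival_event").to_numpy(dtype=float)
        mask = np.isfinite(t) & np.isfinite(e)
        if mask.sum() >= 4 and len(np.unique(high[mask])) == 2:
            curves, comp = km_logrank(t[mask], e[mask].astype(int), high[mask])
            add("brcaness_high", "survival", "logrank", comp)
            km = pd.concat(
                {str(k): v for k, v in curves.items()}, axis=1
            )
            points[f"km_{cohort}_brcaness_high"] = km

    return rows, points


def run_full_analysis(config: PipelineConfig) -> pd.DataFrame:
    """Score every cohort, stratify, and run the full association battery.

    Writes per-cohort ``scores_<name>.tsv``, a combined
    ``associations.tsv``, and ROC/KM point tables under out_dir.  Output is
    deterministic given the config: rerunning yields byte-identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    signature = _resolve_signature(config)
    all_rows: list[dict] = []
    for spec in config.cohorts:
        scores, clinical = _score_cohort(spec, signature, config)
        scores.to_csv(out / f"scores_{spec.name}.tsv", sep="\t",
                      float_format="%.10g")
        rows, points = _associate(spec.name, scores, clinical)
        all_rows.extend(rows)
        for name, frame in points.items():
            frame.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.10g")
    report = pd.DataFrame(
        all_rows, columns=["cohort", "score", "covariate", "test",
                           "statistic", "p_value", "n"]
    )
    report.to_csv(out / "associations.tsv", sep="\t", index=False,
                  float_format="%.10g")
    logger.info("wrote %d association rows to %s", len(report), out / "associations.tsv")
    return report
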