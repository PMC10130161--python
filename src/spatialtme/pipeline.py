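"""End-to-end pipeline: ingest -> phenotype -> filter -> score -> distances
-> groups -> survival statistics, driven by one config.

``run_pipeline`` executes the full analysis on a cell table + clinical table
and writes tidy TSV result tables (mixing scores per core/subject/phenotype,
distance panel, group assignments and summaries, survival reports) plus a
run manifest.  Outputs are written to a temporary directory and atomically
renamed, so a failed stage leaves no partial final tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distances as dist_mod
from . import groups as group_mod
from . import io as io_mod
from . import spatial as spatial_mod
from . import survival as surv_mod

logger = logging.getLogger("spatialtme")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    cell_table: str
    clinical_table: str | None = None
    rules_file: str | None = None  # None -> packaged default rules
    out_dir: str = "spatialtme_results"
    window_spec: object = "convex_hull"  # or ("circle", diameter_um)
    edge_correction: str = "border"
    r_max: float | None = None
    density_threshold: float = 2.0  # cells/mm2
    min_reference: int = spatial_mod.MIN_REFERENCE
    min_target: int = spatial_mod.MIN_TARGET
    anchor_phenotype: str = "CD3+"
    pairs: list | None = None  # None -> the default 128-pair panel
    dichotomize_by_histology: bool = False
    seed: int = 0
    schema: dict = field(default_factory=dict)

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = PipelineConfig(**raw)
        if isinstance(cfg.window_spec, list):
            cfg.window_spec = tuple(cfg.window_spec)
        if cfg.pairs is not None:
            cfg.pairs = [tuple(p) for p in cfg.pairs]
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    if not config.cell_table or not Path(config.cell_table).exists():
        problems.append(f"cell table not found: {config.cell_table!r}")
    if config.clinical_table and not Path(config.clinical_table).exists():
        problems.append(f"clinical table not found: {config.clinical_table!r}")
    if config.rules_file and not Path(config.rules_file).exists():
        problems.append(f"rules file not found: {config.rules_file!r}")
    if config.r_max is not None and config.r_max <= 0:
        problems.append(f"r_max must be positive, got {config.r_max}")
    if config.density_threshold < 0:
        problems.append("density threshold must be non-negative")
    if config.min_reference < 1 or config.min_target < 1:
        problems.append("min reference/target counts must be >= 1")
    if config.edge_correction not in ("none", "border"):
        problems.append(f"unknown edge correction {config.edge_correction!r}")
    return problems


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def compute_densities(cells: pd.DataFrame, phenotype_matrix: pd.DataFrame,
                      window_spec="convex_hull") -> pd.DataFrame:
    """Per-core density of every phenotype (cells/mm2), one shared window per
    core."""
    rows = []
    for (subject, core), idx in cells.groupby(["subject_id", "core_id"]).groups.items():
        core_cells = cells.loc[idx]
        pm = phenotype_matrix.loc[idx]
        try:
            base = io_mod.build_point_pattern(core_cells, pm.columns[0],
                                              window_spec, phenotype_matrix=pm)
        except ValueError as err:
            logger.warning("core %s skipped for densities: %s", core, err)
            continue
        area = base.window.area_mm2
        counts = pm.sum(axis=0)
        for pheno, n in counts.items():
            rows.append({"subject_id": subject, "core_id": core,
                         "phenotype": pheno, "n_cells": int(n),
                         "density": n / area})
    return pd.DataFrame(rows)


def _subject_densities(core_densities: pd.DataFrame) -> pd.DataFrame:
    return (core_densities.groupby(["subject_id", "phenotype"], as_index=False)
            ["density"].median())


def _survival_reports(clinical: pd.DataFrame,
                      assignments: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate KM/log-rank and a Cox model of group vs OS, adjusted for
    available clinical covariates."""
    df = clinical.merge(assignments[["subject_id", "pattern", "distance_class",
                                     "group"]], on="subject_id", how="inner")
    uni_rows = []
    for feat in ("pattern", "distance_class", "group"):
        sub = df.dropna(subset=[feat, "os_months", "os_event"])
        levels = sub[feat].dropna().unique()
        if len(levels) >= 2 and sub.groupby(feat)["os_event"].sum().min() >= 1:
            res = surv_mod.km_logrank(sub["os_months"], sub["os_event"],
                                      sub[feat], fit_curves=False)
            uni_rows.append({"feature": feat, "outcome": "os",
                             "logrank_statistic": res.logrank_statistic,
                             "logrank_p": res.logrank_p,
                             "n": int(sub.shape[0])})
    univariate = pd.DataFrame(uni_rows, columns=["feature", "outcome",
                                                 "logrank_statistic",
                                                 "logrank_p", "n"])

    model = df.dropna(subset=["group", "os_months", "os_event"]).copy()
    cox_table = pd.DataFrame(columns=["covariate", "B", "SE", "Wald", "HR",
                                      "CI_lower", "CI_upper", "p"])
    if len(model) >= 10 and model["os_event"].sum() >= 5:
        for g in (2, 3, 4):
            model[f"group{g}"] = (model["group"] == g).astype(float)
        covs = [f"group{g}" for g in (2, 3, 4) if model[f"group{g}"].nunique() > 1]
        if "histology" in model.columns:
            model["adc"] = surv_mod.encode_binary(model["histology"], "ADC")
            if model["adc"].nunique() > 1:
                covs.append("adc")
        for bin_col in ("smoker",):
            if bin_col in model.columns and model[bin_col].nunique() > 1:
                covs.append(bin_col)
        for mut_col in ("kras", "egfr"):
            if mut_col in model.columns:
                model[f"{mut_col}_mut"] = surv_mod.encode_binary(model[mut_col], "mut")
                if model[f"{mut_col}_mut"].nunique() > 1:
                    covs.append(f"{mut_col}_mut")
        if covs:
            try:
                fit = surv_mod.cox_ph(model, covs)
                cox_table = fit.table.reset_index(names="covariate")
            except Exception as err:  # noqa: BLE001 - reported, not fatal
                logger.warning("Cox stage skipped: %s", err)
    return univariate, cox_table


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the result bundle to
    ``config.out_dir``; returns the result tables in memory."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))

    cells = io_mod.read_cell_table(config.cell_table, schema=config.schema)
    clinical = (io_mod.read_clinical_table(config.clinical_table)
                if config.clinical_table else None)
    rules = (io_mod.load_rules(config.rules_file) if config.rules_file
             else io_mod.default_rules())
    pheno = io_mod.assign_phenotypes(cells, rules)

    core_densities = compute_densities(cells, pheno, config.window_spec)
    subject_densities = _subject_densities(core_densities)
    included = io_mod.filter_phenotypes_by_median_density(
        subject_densities, config.density_threshold) if len(subject_densities) else []
    targets = [p for p in included if not p.startswith("CK+")]

    core_scores = spatial_mod.score_all(
        cells, pheno, targets, reference_phenotype=io_mod.MALIGNANT,
        window_spec=config.window_spec, edge_correction=config.edge_correction,
        r_max=config.r_max, min_reference=config.min_reference,
        min_target=config.min_target)
    subject_scores = spatial_mod.aggregate_scores_by_subject(core_scores)
    phenotype_scores = spatial_mod.summarize_scores_by_phenotype(
        subject_scores, clinical)

    pairs = config.pairs if config.pairs is not None else dist_mod.default_pair_list()
    pairs = [(r, t) for r, t in pairs if r in pheno.columns and t in pheno.columns]
    subject_distances = dist_mod.distance_panel(cells, pheno, pairs)
    if len(subject_distances):
        subject_distances = dist_mod.classify_distances(
            subject_distances, clinical,
            by_histology=config.dichotomize_by_histology)
    else:
        subject_distances["distance_class"] = pd.Series(dtype=object)

    if len(subject_scores) and len(subject_distances):
        assignments = group_mod.assign_groups(
            subject_scores, subject_distances,
            anchor_phenotype=config.anchor_phenotype)
    else:
        assignments = pd.DataFrame(columns=["subject_id", "pattern",
                                            "distance_class", "phenotype",
                                            "group"])
    if len(assignments) and len(assignments.dropna(subset=["group"])):
        group_summary = group_mod.densities_by_group(subject_densities, assignments)
    else:
        group_summary = pd.DataFrame(columns=["phenotype", "kruskal_stat",
                                              "kruskal_p"])

    univariate = pd.DataFrame(columns=["feature", "outcome", "logrank_statistic",
                                       "logrank_p", "n"])
    cox_table = pd.DataFrame(columns=["covariate", "B", "SE", "Wald", "HR",
                                      "CI_lower", "CI_upper", "p"])
    if clinical is not None and "os_months" in clinical.columns and len(assignments):
        univariate, cox_table = _survival_reports(clinical, assignments)

    results = {
        "densities_by_core": core_densities,
        "densities_by_subject": subject_densities,
        "scores_by_core": core_scores,
        "scores_by_subject": subject_scores,
        "scores_by_phenotype": phenotype_scores,
        "distances_by_subject": subject_distances,
        "group_assignments": assignments,
        "group_summary": group_summary,
        "survival_univariate": univariate,
        "survival_cox": cox_table,
    }

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".spatialtme-", dir=out_dir))
    try:
        for name, table in results.items():
            table.to_csv(tmp / f"{name}.tsv", sep="\t", index=False)
        manifest = {
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "included_phenotypes": included,
            "n_subjects": int(cells["subject_id"].nunique()),
            "n_cores": int(cells["core_id"].nunique()),
            "n_cells": int(len(cells)),
        }
        with open(tmp / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        for f in tmp.iterdir():
            os.replace(f, out_dir / f.name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    return results
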