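"""Discovery and validation pipeline orchestration.

``run_discovery`` chains the discovery arm per tissue compartment —
read/collapse/harmonize the expression datasets, random-effects
meta-analysis with permutation FDR, significant-gene selection, consensus
target mapping and per-miRNA enrichment — and unions the candidate miRNA
lists across compartments.  ``run_validation`` computes the clinical
statistics (group comparisons, correlations with eGFR/uPCR, MEST-C lesion
comparisons, univariate Cox, ROC AUC) from a cohort table and qPCR
measurement file.  Both write deterministic TSV outputs plus a JSON
manifest that records inputs, seed, thresholds and stage counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clinical_validation as cv
from . import expression_io as eio
from . import meta_analysis as ma
from . import synthetic_data as sd
from . import target_enrichment as te

logger = logging.getLogger(__name__)

TSV_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration for a discovery and/or validation run."""

    out_dir: str = "results"
    seed: int = 1
    permutations: int = ma.DEFAULT_PERMUTATIONS
    fdr_gene: float = 0.05
    fc: float = 1.5
    fdr_mirna: float = 0.05
    min_support: int = 2
    direction: str = "combined"  # or "split"
    # per-compartment expression inputs:
    #   {compartment: {"expression": {dataset_id: path}, "annotation": path,
    #                  "probe_map": optional path}}
    compartments: dict[str, dict[str, Any]] = field(default_factory=dict)
    target_dbs: list[str] = field(default_factory=list)
    cohort: str | None = None
    measurements: str | None = None
    roc_outcome: str = "label"  # "label" (progressor) or "event5"
    simulate: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for thr in (self.fdr_gene, self.fc, self.fdr_mirna):
            if thr <= 0:
                raise ValueError("thresholds must be positive")
        if self.direction not in ("combined", "split"):
            raise ValueError("direction must be 'combined' or 'split'")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=TSV_FLOAT_FORMAT)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-22s %6.2fs", name, t1 - t0)
    return t1


def load_compartment(spec: dict[str, Any]) -> eio.DatasetCollection:
    """Read, optionally probe-collapse, and harmonize one compartment's inputs."""
    annotation = eio.read_sample_annotation(spec["annotation"])
    probe_map = eio.read_probe_map(spec["probe_map"]) if spec.get("probe_map") else None
    expr = spec["expression"]
    items = expr.items() if isinstance(expr, dict) else [
        (Path(p).stem, p) for p in expr
    ]
    matrices = []
    for ds_id, path in items:
        pm, report = eio.read_expression_tsv(path, ds_id)
        if report.n_dropped_all_missing:
            logger.info("%s: %d all-missing rows dropped", ds_id,
                        report.n_dropped_all_missing)
        if probe_map is not None:
            pm = eio.ProbesetMatrix(ds_id, pm.values, probe_map)
            matrices.append(eio.collapse_probesets(pm))
        else:
            # rows already are gene symbols: identity provenance
            matrices.append(eio.GeneMatrix(ds_id, pm.values,
                                           {g: g for g in pm.values.index}))
    return eio.harmonize(matrices, annotation)


def discover_collection(collection: eio.DatasetCollection,
                        consensus: te.ConsensusTargetMap,
                        config: RunConfig) -> dict[str, Any]:
    """Meta-analysis + enrichment for one harmonized collection."""
    t0 = time.perf_counter()
    results = ma.meta_analyze(collection, n_permutations=config.permutations,
                              seed=config.seed, fdr_threshold=config.fdr_gene,
                              fc_threshold=config.fc)
    t0 = _stage("meta_analysis", t0)
    sig, report = ma.select_significant(results, config.fdr_gene, config.fc)

    universe = collection.gene_universe
    enrichments: dict[str, pd.DataFrame] = {}
    candidates: list[str] = []
    notices: list[str] = []
    if not sig:
        notices.append("no significant genes: enrichment skipped")
    else:
        if config.direction == "split":
            subsets = {
                "up": {g for g in sig if results.loc[g, "fc"] > 1.0},
                "down": {g for g in sig if results.loc[g, "fc"] <= 1.0},
            }
        else:
            subsets = {"combined": sig}
        for label, genes in subsets.items():
            if not genes:
                notices.append(f"empty {label} gene set: enrichment skipped")
                continue
            records = te.enrich_all(consensus, genes, universe)
            table, cand = te.rank_and_select(records, config.fdr_mirna)
            enrichments[label] = table
            candidates.extend(cand)
        _stage("enrichment", t0)
    return {
        "results": results,
        "significant": sig,
        "selection_report": report,
        "enrichments": enrichments,
        "candidates": sorted(set(candidates)),
        "notices": notices,
    }


def run_discovery(config: RunConfig) -> dict[str, Any]:
    """Run the full discovery arm and write per-compartment outputs.

    Returns the manifest; TSV tables and ``discovery_manifest.json`` are
    written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(config.target_dbs) < 2:
        raise ValueError("discovery needs >=2 target databases")
    t0 = time.perf_counter()
    consensus = te.build_consensus(config.target_dbs, config.min_support)
    t0 = _stage("consensus_map", t0)

    manifest: dict[str, Any] = {
        "seed": config.seed,
        "permutations": config.permutations,
        "thresholds": {"fdr_gene": config.fdr_gene, "fc": config.fc,
                       "fdr_mirna": config.fdr_mirna,
                       "min_support": config.min_support},
        "direction": config.direction,
        "target_dbs": [str(p) for p in config.target_dbs],
        "consensus": {"n_mirnas": consensus.n_mirnas,
                      "n_pairs_retained": consensus.n_pairs_retained},
        "compartments": {},
    }
    union: list[str] = []
    for comp, spec in config.compartments.items():
        collection = spec if isinstance(spec, eio.DatasetCollection) else load_compartment(spec)
        t0 = _stage(f"load[{comp}]", t0)
        res = discover_collection(collection, consensus, config)
        _write_tsv(res["results"].reset_index(), out / f"meta_{comp}.tsv")
        for label, table in res["enrichments"].items():
            suffix = "" if label == "combined" else f"_{label}"
            _write_tsv(table, out / f"enrichment_{comp}{suffix}.tsv")
        manifest["compartments"][comp] = {
            "n_datasets": len(collection.datasets),
            "universe_size": collection.n_genes,
            "selection": res["selection_report"],
            "n_candidates": len(res["candidates"]),
            "candidates": res["candidates"],
            "notices": res["notices"],
        }
        union.extend(res["candidates"])
    manifest["candidate_union"] = sorted(set(union))
    manifest["n_candidate_union"] = len(manifest["candidate_union"])
    _write_tsv(pd.DataFrame({"mirna": manifest["candidate_union"]}),
               out / "candidates.tsv")
    (out / "discovery_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# validation arm

def compute_levels(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-patient creatinine-normalized log10 levels, wide (patient x assay).

    Measurements with a missing Ct or non-positive creatinine are excluded
    and logged.
    """
    rows = []
    n_excluded = 0
    for rec in measurements.itertuples(index=False):
        try:
            level = cv.relative_level(rec.ct_target, rec.ct_reference,
                                      rec.urine_creatinine)
        except ValueError as exc:
            n_excluded += 1
            logger.info("measurement excluded (%s %s): %s", rec.patient_id,
                        rec.assay, exc)
            continue
        rows.append({"patient_id": rec.patient_id, "assay": rec.assay,
                     "level": level})
    if n_excluded:
        logger.info("excluded %d unusable measurements", n_excluded)
    long = pd.DataFrame(rows)
    return long.pivot(index="patient_id", columns="assay", values="level")


def run_validation(config: RunConfig) -> dict[str, Any]:
    """Run the validation arm: group comparisons, correlations, Cox, ROC."""
    if not config.cohort or not config.measurements:
        raise ValueError("validation needs cohort and measurements paths")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(config.cohort, sep="\t", comment="#")
    measurements = pd.read_csv(config.measurements, sep="\t", comment="#")
    levels = compute_levels(measurements)
    data = cohort.merge(levels, left_on="patient_id", right_index=True, how="left")

    assays = [a for a in levels.columns]
    usable_assays = []
    for a in assays:
        n_measured = int(data[a].notna().sum())
        if n_measured < 3:
            logger.warning("assay %s excluded: only %d measured patients", a,
                           n_measured)
        else:
            usable_assays.append(a)

    igan = data[data["group"] == "IgAN"]
    group_order = ["IgAN", "disease_control", "normal_control"]
    present_groups = [g for g in group_order if (data["group"] == g).any()]

    # three-group Kruskal-Wallis + unadjusted pairwise Mann-Whitney
    group_rows = []
    for a in usable_assays:
        row: dict[str, Any] = {"assay": a}
        series = {g: data.loc[data["group"] == g, a].dropna() for g in present_groups}
        if len(present_groups) >= 2:
            if len(present_groups) > 2:
                stat, p = cv.group_compare(*(series[g] for g in present_groups))
                row["kw_stat"], row["kw_p"] = stat, p
            for i in range(len(present_groups)):
                for j in range(i + 1, len(present_groups)):
                    gi, gj = present_groups[i], present_groups[j]
                    _, p = cv.group_compare(series[gi], series[gj])
                    row[f"p_{gi}_vs_{gj}"] = p
        else:
            raise ValueError("group comparisons need at least two groups")
        group_rows.append(row)
    groups_df = pd.DataFrame(group_rows)

    # Spearman correlations vs eGFR and uPCR among disease patients
    corr_rows = []
    for a in usable_assays:
        row = {"assay": a}
        for var in ("egfr", "upcr"):
            try:
                rho, p = cv.spearman(igan[var], igan[a])
            except ValueError:
                rho, p = np.nan, np.nan
            row[f"rho_{var}"], row[f"p_{var}"] = rho, p
        corr_rows.append(row)
    corr_df = pd.DataFrame(corr_rows)

    # per-lesion MEST-C comparisons (score 0 vs >=1)
    mest_rows = []
    for a in usable_assays:
        row = {"assay": a}
        for lesion in ("mest_m", "mest_e", "mest_s", "mest_t", "mest_c"):
            if lesion not in igan.columns:
                continue
            g0 = igan.loc[igan[lesion] == 0, a].dropna()
            g1 = igan.loc[igan[lesion] >= 1, a].dropna()
            if len(g0) and len(g1):
                _, p = cv.group_compare(g0, g1)
                row[f"p_{lesion}"] = p
            else:
                row[f"p_{lesion}"] = np.nan
        mest_rows.append(row)
    mest_df = pd.DataFrame(mest_rows)

    # univariate Cox for clinical covariates and assays
    time_col = "time_years" if "time_years" in igan.columns else "followup_years"
    cox_rows = []
    clinical_vars = [c for c in ("age", "htn", "dm", "bmi", "egfr", "upcr",
                                 "ras_blocker", "immunosuppressant", "mest_m",
                                 "mest_e", "mest_s", "mest_t", "mest_c")
                     if c in igan.columns]
    for var in clinical_vars + usable_assays:
        sub = igan[[time_col, "event", var]].dropna()
        try:
            res = cv.cox_univariate(sub[time_col], sub["event"], sub[var])
        except ValueError as exc:
            logger.info("cox skipped for %s: %s", var, exc)
            continue
        cox_rows.append({"variable": var, "hr": res.hr, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p": res.p,
                         "converged": res.converged, "n": res.n,
                         "n_events": res.n_events})
    cox_df = pd.DataFrame(cox_rows)

    # ROC for progression outcome
    if config.roc_outcome == "event5":
        roc_sub = igan.copy()
        roc_sub["outcome"] = ((roc_sub["event"] == 1)
                              & (roc_sub[time_col] <= 5.0)).astype(int)
    else:
        roc_sub = igan[igan["progression_label"].isin(
            [cv.PROGRESSOR, cv.NON_PROGRESSOR])].copy()
        roc_sub["outcome"] = (roc_sub["progression_label"] == cv.PROGRESSOR).astype(int)
    auc_rows = []
    for a in usable_assays:
        sub = roc_sub[[a, "outcome"]].dropna()
        try:
            auc, lo, hi = cv.roc_auc(sub[a], sub["outcome"])
        except ValueError as exc:
            logger.info("roc skipped for %s: %s", a, exc)
            continue
        auc_rows.append({"assay": a, "auc": auc, "ci_low": lo, "ci_high": hi,
                         "n": len(sub), "n_outcome": int(sub["outcome"].sum())})
    auc_df = pd.DataFrame(auc_rows)

    _write_tsv(groups_df, out / "group_comparisons.tsv")
    _write_tsv(corr_df, out / "correlations.tsv")
    _write_tsv(mest_df, out / "mestc_comparisons.tsv")
    _write_tsv(cox_df, out / "cox_univariate.tsv")
    _write_tsv(auc_df, out / "roc_auc.tsv")

    manifest = {
        "cohort": str(config.cohort),
        "measurements": str(config.measurements),
        "n_patients": int(len(cohort)),
        "n_igan": int((cohort["group"] == "IgAN").sum()),
        "assays": usable_assays,
        "roc_outcome": config.roc_outcome,
        "tables": ["group_comparisons.tsv", "correlations.tsv",
                   "mestc_comparisons.tsv", "cox_univariate.tsv",
                   "roc_auc.tsv"],
    }
    (out / "validation_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_simulate(config: RunConfig) -> dict[str, Any]:
    """Generate synthetic inputs under ``out_dir`` as configured.

    The ``simulate`` config section may hold ``expression`` (a mapping of
    compartment name to generator parameters), ``targets`` and ``cohort``
    parameter mappings; omitted sections are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = dict(config.simulate)
    manifest: dict[str, Any] = {"seed": config.seed, "outputs": {}}
    de_union: set[str] = set()
    universe: list[str] | None = None
    for comp, params in (spec.get("expression") or {}).items():
        params = dict(params)
        params.setdefault("compartment", comp)
        params.setdefault("seed", config.seed)
        coll, truth = sd.gen_expression_collection(outdir=out / comp, **params)
        de_union |= set(truth.de_genes)
        universe = coll.gene_universe
        manifest["outputs"][f"expression/{comp}"] = {
            "dir": str(out / comp), "n_genes": coll.n_genes,
            "n_de": len(truth.de_genes),
        }
    if "targets" in spec:
        params = dict(spec["targets"])
        params.setdefault("seed", config.seed)
        if universe is not None:
            params.setdefault("gene_universe", universe)
            params.setdefault("de_genes", sorted(de_union))
        _, truth = sd.gen_target_databases(outdir=out / "targets", **params)
        manifest["outputs"]["targets"] = {
            "dir": str(out / "targets"),
            "enriched": sorted(truth.enriched_mirnas),
        }
    if "cohort" in spec:
        params = dict(spec["cohort"])
        params.setdefault("seed", config.seed)
        cohort, _, _ = sd.gen_cohort(outdir=out / "cohort", **params)
        manifest["outputs"]["cohort"] = {
            "dir": str(out / "cohort"), "n_patients": int(len(cohort)),
        }
    (out / "simulate_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
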