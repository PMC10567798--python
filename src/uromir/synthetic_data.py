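"""Ground-truthed synthetic fixtures for every pipeline stage.

Three generators emulate the statistical structure of the real inputs:

* :func:`gen_expression_collection` — multi-dataset case/control log2
  expression with differentially expressed (DE) genes implanted under the
  random-effects model (per-dataset true effect theta_gi ~ N(mu_g, tau^2));
  group means are offset by theta_gi * noise_sd / 2 on either side so the
  population standardized mean difference equals theta_gi exactly.
* :func:`gen_target_databases` — multi-source miRNA-target pair files with
  highly variable target-set sizes; selected miRNAs draw their targets
  from the DE set with an odds multiplier, and cross-source agreement
  controls how often a pair is shared between databases.
* :func:`gen_cohort` — a three-group patient cohort (disease, disease
  control, normal control) with creatinine-derived eGFR, proteinuria,
  Oxford MEST-C lesions, urinary miRNA qPCR measurements whose levels
  correlate negatively with eGFR and positively with uPCR, and
  proportional-hazards event times driven by per-assay log hazard ratios.

All generators are pure functions of their parameters and seed: the same
call yields byte-identical files.  Default parameters mirror the shape of
the emulated study (five datasets per compartment, ~10,000 shared genes,
tens of samples per group, ~1,800 miRNAs, a 93/11/19 cohort).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical_validation import (INDETERMINATE, classify_progression,
                                  ckd_epi_egfr, invert_ckd_epi)
from .expression_io import DatasetCollection, HarmonizedDataset

TSV_FLOAT_FORMAT = "%.10g"

# per-assay defaults: log hazard ratios for the three progression-associated
# markers, and common negative-eGFR / positive-uPCR level couplings
DEFAULT_ASSAY_EFFECTS: dict[str, dict[str, float]] = {
    name: {
        "log_hr": log_hr,
        "egfr_beta": -0.30,
        "upcr_beta": 0.25,
        "base_level": 5.5,
        "noise_sd": 0.8,
    }
    for name, log_hr in {
        "miR-16-5p": math.log(2.13),
        "miR-26b-3p": 0.0,
        "miR-29a-3p": 0.0,
        "miR-29c-3p": 0.0,
        "miR-124-3p": 0.0,
        "miR-126-3p": 0.0,
        "miR-199a-3p": math.log(2.76),
        "miR-199b-5p": 0.0,
        "miR-335-3p": math.log(1.31),
        "miR-615-3p": 0.0,
        "miR-29b-3p": 0.0,
    }.items()
}


@dataclass
class SimTruth:
    """Ground truth recorded alongside every generated fixture."""

    seed: int
    params: dict = field(default_factory=dict)
    de_genes: dict = field(default_factory=dict)   # gene -> signed true mu
    tau: float = 0.0
    enriched_mirnas: dict = field(default_factory=dict)  # mirna -> overlap odds
    cohort_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=TSV_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# expression

def gen_expression_collection(n_datasets: int = 5, n_genes: int = 10_000,
                              n_case: int = 20, n_control: int = 20,
                              de_fraction: float = 0.05, mu: float = 1.0,
                              tau: float = 0.3, noise_sd: float = 1.0,
                              compartment: str = "glomerulus", seed: int = 1,
                              outdir: str | Path | None = None,
                              ) -> tuple[DatasetCollection, SimTruth]:
    """Simulate a harmonized multi-dataset expression collection.

    A ``de_fraction`` of genes carries a signed true pooled effect of
    magnitude ``mu`` (up/down split evenly at random) with between-study SD
    ``tau``; remaining genes are null.  When ``outdir`` is given, one
    expression TSV per dataset, the sample annotation, and a truth JSON are
    written in the dialects the readers consume.
    """
    if min(n_datasets, n_genes, n_case, n_control) <= 0:
        raise ValueError("all sizes must be positive")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    mu_g = np.zeros(n_genes)
    mu_g[de_idx] = signs * mu

    datasets: list[HarmonizedDataset] = []
    ann_rows = []
    for d in range(n_datasets):
        ds_id = f"DS{d + 1:02d}"
        theta = rng.normal(mu_g, tau)
        baseline = rng.normal(8.0, 1.0, size=n_genes)
        shift = theta * noise_sd / 2.0
        case = rng.normal((baseline + shift)[:, None], noise_sd,
                          size=(n_genes, n_case))
        control = rng.normal((baseline - shift)[:, None], noise_sd,
                             size=(n_genes, n_control))
        case_ids = [f"{ds_id}_case{j + 1:02d}" for j in range(n_case)]
        control_ids = [f"{ds_id}_ctrl{j + 1:02d}" for j in range(n_control)]
        values = pd.DataFrame(np.hstack([case, control]),
                              index=pd.Index(genes, name="id"),
                              columns=case_ids + control_ids)
        datasets.append(HarmonizedDataset(ds_id, values, case_ids, control_ids))
        for s in case_ids:
            ann_rows.append((s, ds_id, "case", compartment))
        for s in control_ids:
            ann_rows.append((s, ds_id, "control", compartment))

    collection = DatasetCollection(compartment=compartment,
                                   gene_universe=genes, datasets=datasets)
    truth = SimTruth(
        seed=seed,
        params={"n_datasets": n_datasets, "n_genes": n_genes, "n_case": n_case,
                "n_control": n_control, "de_fraction": de_fraction, "mu": mu,
                "tau": tau, "noise_sd": noise_sd, "compartment": compartment},
        de_genes={genes[i]: float(mu_g[i]) for i in sorted(de_idx)},
        tau=tau,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ds in collection.datasets:
            _write_tsv(ds.values, outdir / f"{ds.dataset_id}.tsv", seed, index=True)
        ann = pd.DataFrame(ann_rows, columns=["sample_id", "dataset_id",
                                              "group", "compartment"])
        _write_tsv(ann, outdir / "annotation.tsv", seed)
        (outdir / "truth.json").write_text(truth.to_json())
    return collection, truth


# ---------------------------------------------------------------------------
# target databases

def gen_target_databases(n_mirnas: int = 1800,
                         gene_universe: list[str] | int = 10_000,
                         n_sources: int = 3,
                         baseline_target_rate: float = 0.06,
                         enriched_mirnas: list[str] | int = 0,
                         overlap_odds: float = 5.0,
                         agreement: float = 0.6,
                         de_genes: list[str] | None = None,
                         seed: int = 1,
                         outdir: str | Path | None = None,
                         ) -> tuple[list[pd.DataFrame], SimTruth]:
    """Simulate multi-source miRNA-target databases with implanted enrichment.

    Each miRNA draws a log-normally dispersed number of targets (mean
    ``baseline_target_rate`` of the universe).  Enriched miRNAs sample DE
    genes with ``overlap_odds``-fold weight.  Every pair gets one primary
    source and is replicated into each other source independently with
    probability ``agreement``; the consensus filter therefore removes a
    pair with probability (1-agreement)^(n_sources-1).
    """
    if overlap_odds < 1.0:
        raise ValueError("overlap_odds must be >= 1")
    if not 0.0 < agreement <= 1.0:
        raise ValueError("agreement must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(gene_universe, int):
        gene_universe = [f"G{i:05d}" for i in range(gene_universe)]
    genes = np.asarray(gene_universe)
    n_genes = len(genes)
    mirnas = [f"miR-{i + 1:04d}" for i in range(n_mirnas)]

    if isinstance(enriched_mirnas, int):
        enriched = list(rng.choice(mirnas, size=enriched_mirnas, replace=False))
    else:
        enriched = list(enriched_mirnas)
        unknown = set(enriched) - set(mirnas)
        if unknown:
            raise ValueError(f"enriched miRNAs not in miRNA list: {sorted(unknown)}")
    enriched_set = set(enriched)

    de_mask = np.zeros(n_genes, dtype=bool)
    if de_genes:
        de_mask = np.isin(genes, list(de_genes))

    base_weights = np.ones(n_genes)
    enr_weights = np.where(de_mask, overlap_odds, 1.0)

    mean_size = max(2.0, baseline_target_rate * n_genes)
    min_size = max(5, n_genes // 100)
    rows_by_source: dict[str, list[tuple[str, str]]] = {
        f"DB{s + 1}": [] for s in range(n_sources)
    }
    source_names = list(rows_by_source)
    for mirna in mirnas:
        size = int(np.clip(round(rng.lognormal(math.log(mean_size), 0.8)),
                           min_size, max(min_size, n_genes // 3)))
        w = enr_weights if mirna in enriched_set else base_weights
        targets = rng.choice(genes, size=size, replace=False, p=w / w.sum())
        for gene in targets:
            primary = int(rng.integers(n_sources))
            present = rng.random(n_sources) < agreement
            present[primary] = True
            for s in range(n_sources):
                if present[s]:
                    rows_by_source[source_names[s]].append((mirna, gene))

    frames = []
    for source in source_names:
        df = pd.DataFrame(rows_by_source[source], columns=["mirna", "gene"])
        df["source"] = source
        frames.append(df)

    truth = SimTruth(
        seed=seed,
        params={"n_mirnas": n_mirnas, "n_genes": n_genes,
                "n_sources": n_sources,
                "baseline_target_rate": baseline_target_rate,
                "overlap_odds": overlap_odds, "agreement": agreement},
        enriched_mirnas={m: overlap_odds for m in sorted(enriched_set)},
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for source, df in zip(source_names, frames):
            _write_tsv(df, outdir / f"{source}.tsv", seed)
        (outdir / "targets_truth.json").write_text(truth.to_json())
    return frames, truth


# ---------------------------------------------------------------------------
# cohort

def gen_cohort(n_igan: int = 93, n_disease_control: int = 11,
               n_normal: int = 19,
               assay_effects: dict[str, dict[str, float]] | None = None,
               baseline_hazard: float = 0.055, seed: int = 1,
               outdir: str | Path | None = None,
               ) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a patient cohort with urinary miRNA qPCR measurements.

    Covariates are drawn from group-specific ranges typical of a
    glomerulonephritis biopsy cohort (disease patients with reduced eGFR
    and overt proteinuria, near-normal controls).  Serum creatinine is
    obtained by inverting the CKD-EPI equation from a target eGFR so the
    two are mutually consistent.  Per-assay log10 levels couple negatively
    to eGFR and positively to uPCR; progression event times follow an
    exponential proportional-hazards model whose linear predictor sums the
    per-assay ``log_hr`` terms over standardized levels.  eGFR trajectories
    consistent with each outcome are generated and the progression label is
    derived from them by the classification rule itself.
    """
    if min(n_igan, n_disease_control, n_normal) < 0:
        raise ValueError("group sizes must be >= 0")
    effects = assay_effects if assay_effects is not None else DEFAULT_ASSAY_EFFECTS
    rng = np.random.default_rng(seed)

    groups = (["IgAN"] * n_igan + ["disease_control"] * n_disease_control
              + ["normal_control"] * n_normal)
    n = len(groups)
    rows = []
    for i, group in enumerate(groups):
        sex = "male" if rng.random() < 0.55 else "female"
        if group == "IgAN":
            age = float(np.clip(rng.normal(44.5, 16.4), 18, 85))
            egfr_t = float(np.clip(rng.normal(69.7, 37.3), 8, 130))
            htn, dm = rng.random() < 0.46, rng.random() < 0.054
            ras, imm = rng.random() < 0.80, rng.random() < 0.78
        elif group == "disease_control":
            age = float(np.clip(rng.normal(49.9, 18.1), 18, 85))
            egfr_t = float(np.clip(rng.normal(109.3, 15.7), 60, 140))
            htn, dm = rng.random() < 0.36, False
            ras, imm = rng.random() < 0.5, rng.random() < 0.3
        else:
            age = float(np.clip(rng.normal(34.3, 17.6), 18, 85))
            egfr_t = float(np.clip(rng.normal(114.1, 22.8), 60, 150))
            htn, dm = rng.random() < 0.053, False
            ras, imm = False, False
        scr = invert_ckd_epi(egfr_t, age, sex)
        egfr = ckd_epi_egfr(scr, age, sex)
        bmi = float(np.clip(rng.normal(23.7, 2.9), 16, 38))
        rows.append({"patient_id": f"P{i + 1:03d}", "group": group, "age": age,
                     "sex": sex, "htn": int(htn), "dm": int(dm), "bmi": bmi,
                     "serum_creatinine": scr, "egfr": egfr,
                     "ras_blocker": int(ras), "immunosuppressant": int(imm)})
    cohort = pd.DataFrame(rows)

    egfr = cohort["egfr"].to_numpy()
    egfr_z = (egfr - egfr.mean()) / egfr.std()
    upcr = np.empty(n)
    for i, group in enumerate(groups):
        if group == "IgAN":
            upcr[i] = np.clip(np.exp(0.45 - 0.8 * egfr_z[i] + rng.normal(0, 0.6)),
                              0.05, 15.0)
        elif group == "disease_control":
            upcr[i] = np.clip(np.exp(0.8 + rng.normal(0, 0.5)), 0.1, 15.0)
        else:
            upcr[i] = np.clip(np.exp(-2.3 + rng.normal(0, 0.3)), 0.01, 0.4)
    cohort["upcr"] = upcr
    upcr_z = (np.log(upcr) - np.log(upcr).mean()) / np.log(upcr).std()

    # Oxford MEST-C for disease patients only; controls carry zeros
    is_igan = cohort["group"].to_numpy() == "IgAN"
    cohort["mest_m"] = np.where(is_igan, rng.random(n) < 0.645, 0).astype(int)
    cohort["mest_e"] = np.where(is_igan, rng.random(n) < 0.215, 0).astype(int)
    cohort["mest_s"] = np.where(is_igan, rng.random(n) < 0.355, 0).astype(int)
    cohort["mest_t"] = np.where(
        is_igan, rng.choice([0, 1, 2], size=n, p=[0.69, 0.21, 0.10]), 0)
    cohort["mest_c"] = np.where(
        is_igan, rng.choice([0, 1, 2], size=n, p=[0.75, 0.18, 0.07]), 0)

    # assay levels: higher with worse kidney function and heavier proteinuria
    assay_names = sorted(effects)
    levels = pd.DataFrame(index=cohort["patient_id"], columns=assay_names,
                          dtype=float)
    for assay in assay_names:
        e = effects[assay]
        levels[assay] = (e.get("base_level", 5.5)
                         + e.get("egfr_beta", -0.3) * egfr_z
                         + e.get("upcr_beta", 0.25) * upcr_z
                         + rng.normal(0, e.get("noise_sd", 0.8), size=n))

    # proportional-hazards event times from standardized levels
    lp = np.zeros(n)
    for assay in assay_names:
        log_hr = effects[assay].get("log_hr", 0.0)
        if log_hr:
            col = levels[assay].to_numpy()
            lp += log_hr * (col - col.mean()) / col.std()
    event_time = rng.exponential(1.0 / (baseline_hazard * np.exp(lp)))
    followup = rng.uniform(3.0, 10.0, size=n)
    observed_event = (event_time <= followup) & is_igan
    time_obs = np.where(observed_event, event_time, followup)

    labels, traj_store = [], {}
    for i in range(n):
        if not is_igan[i]:
            labels.append(INDETERMINATE)
            continue
        base = egfr[i]
        fup = followup[i]
        points = []
        if observed_event[i] and event_time[i] <= 5.0:
            t_ev = max(event_time[i], 0.5)
            for t in np.arange(1.0, math.floor(fup) + 1.0):
                frac = min(t / t_ev, 1.1)
                points.append((float(t), float(base * max(1.0 - 0.55 * frac, 0.2))))
            points.append((float(t_ev), float(base * 0.45)))
        elif not observed_event[i] and fup > 5.0:
            for t in np.arange(1.0, math.floor(fup) + 1.0):
                points.append((float(t), float(base * (1.0 + rng.uniform(-0.08, 0.08)))))
        else:
            for t in np.arange(1.0, math.floor(fup) + 1.0):
                points.append((float(t), float(base * (1.0 - 0.05 * t))))
        rrt = bool(observed_event[i] and event_time[i] <= 5.0
                   and rng.random() < 0.3)
        labels.append(classify_progression(base, points, rrt, fup))
        traj_store[cohort.loc[i, "patient_id"]] = points

    cohort["followup_years"] = followup
    cohort["event"] = observed_event.astype(int)
    cohort["time_years"] = time_obs
    cohort["progression_label"] = labels

    # qPCR measurements that round-trip through the ddCt transformation
    urine_cr = rng.uniform(0.5, 2.5, size=n)
    meas_rows = []
    ct_cal = 25.0
    for i, pid in enumerate(cohort["patient_id"]):
        for assay in assay_names:
            level = levels.loc[pid, assay]
            ct_target = ct_cal - math.log2(urine_cr[i] * 10.0 ** level)
            meas_rows.append({"patient_id": pid, "assay": assay,
                              "ct_target": ct_target, "ct_reference": ct_cal,
                              "urine_creatinine": urine_cr[i]})
    measurements = pd.DataFrame(meas_rows)

    truth = SimTruth(
        seed=seed,
        params={"n_igan": n_igan, "n_disease_control": n_disease_control,
                "n_normal": n_normal, "baseline_hazard": baseline_hazard},
        cohort_params={"assay_effects": {a: dict(effects[a]) for a in assay_names}},
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tsv(cohort, outdir / "cohort.tsv", seed)
        _write_tsv(measurements, outdir / "measurements.tsv", seed)
        (outdir / "cohort_truth.json").write_text(truth.to_json())
    return cohort, measurements, truth
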