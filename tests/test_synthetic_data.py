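import hashlib
from pathlib import Path

import numpy as np
import pytest

from uromir.clinical_validation import ckd_epi_egfr, cox_univariate
from uromir.meta_analysis import collection_effects
from uromir.synthetic_data import (gen_cohort, gen_expression_collection,
                                   gen_target_databases)
from uromir.target_enrichment import (build_consensus, enrich_all,
                                      rank_and_select)


def dir_digest(path: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(path.rglob("*")) if p.is_file()}


class TestExpressionGenerator:
    def test_zero_de_fraction_has_empty_truth(self):
        _, truth = gen_expression_collection(n_datasets=2, n_genes=50,
                                             n_case=4, n_control=4,
                                             de_fraction=0.0, seed=1)
        assert truth.de_genes == {}

    def test_same_seed_byte_identical_files(self, tmp_path):
        kw = dict(n_datasets=2, n_genes=40, n_case=4, n_control=4,
                  de_fraction=0.2, seed=11)
        gen_expression_collection(outdir=tmp_path / "a", **kw)
        gen_expression_collection(outdir=tmp_path / "b", **kw)
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        kw = dict(n_datasets=2, n_genes=40, n_case=4, n_control=4)
        gen_expression_collection(outdir=tmp_path / "a", seed=1, **kw)
        gen_expression_collection(outdir=tmp_path / "b", seed=2, **kw)
        assert dir_digest(tmp_path / "a") != dir_digest(tmp_path / "b")

    def test_sample_smd_calibrated_to_mu(self):
        # population SMD of an implanted gene equals mu when tau = 0
        coll, truth = gen_expression_collection(
            n_datasets=5, n_genes=600, n_case=20, n_control=20,
            de_fraction=5 / 6, mu=0.8, tau=0.0, seed=3)
        y, _, _ = collection_effects(coll)
        genes = list(coll.gene_universe)
        idx = [genes.index(g) for g in truth.de_genes]
        signs = np.sign(list(truth.de_genes.values()))
        aligned = y[idx] * signs[:, None]
        assert abs(np.nanmean(aligned) - 0.8) < 0.05

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            gen_expression_collection(n_datasets=0)
        with pytest.raises(ValueError):
            gen_expression_collection(de_fraction=1.5)

    def test_files_round_trip_through_readers(self, tmp_path):
        from uromir.expression_io import (GeneMatrix, harmonize,
                                          read_expression_tsv,
                                          read_sample_annotation)
        coll, _ = gen_expression_collection(n_datasets=2, n_genes=30,
                                            n_case=4, n_control=4, seed=5,
                                            outdir=tmp_path)
        ann = read_sample_annotation(tmp_path / "annotation.tsv")
        gms = []
        for ds in coll.datasets:
            pm, _ = read_expression_tsv(tmp_path / f"{ds.dataset_id}.tsv",
                                        ds.dataset_id)
            gms.append(GeneMatrix(ds.dataset_id, pm.values,
                                  {g: g for g in pm.values.index}))
        rebuilt = harmonize(gms, ann)
        assert rebuilt.gene_universe == coll.gene_universe
        np.testing.assert_allclose(rebuilt.datasets[0].values.to_numpy(),
                                   coll.datasets[0].values.to_numpy(),
                                   rtol=1e-9)


class TestTargetGenerator:
    def test_full_agreement_keeps_every_pair(self):
        frames, _ = gen_target_databases(n_mirnas=20, gene_universe=200,
                                         agreement=1.0, seed=2)
        union = set(map(tuple, frames[0][["mirna", "gene"]].to_numpy()))
        for f in frames[1:]:
            assert set(map(tuple, f[["mirna", "gene"]].to_numpy())) == union
        cmap = build_consensus(frames)
        assert cmap.n_pairs_retained == len(union)

    def test_low_agreement_empties_consensus(self):
        frames, _ = gen_target_databases(n_mirnas=20, gene_universe=200,
                                         agreement=0.01, seed=2)
        total = sum(len(f) for f in frames)
        cmap = build_consensus(frames)
        assert cmap.n_pairs_retained < 0.1 * total

    def test_unknown_enriched_mirna_rejected(self):
        with pytest.raises(ValueError, match="not in"):
            gen_target_databases(n_mirnas=5, gene_universe=50,
                                 enriched_mirnas=["miR-nope"], seed=1)

    def test_unit_odds_implant_is_null(self):
        # with overlap_odds = 1 the "enriched" miRNAs carry no signal
        de = [f"G{i:05d}" for i in range(40)]
        quiet = 0
        for seed in range(1, 11):
            frames, truth = gen_target_databases(
                n_mirnas=40, gene_universe=400, enriched_mirnas=3,
                overlap_odds=1.0, agreement=0.8, de_genes=de, seed=seed)
            cmap = build_consensus(frames)
            table, _ = rank_and_select(
                enrich_all(cmap, set(de), [f"G{i:05d}" for i in range(400)]))
            qs = table.set_index("mirna")["q"]
            if all(qs.get(m, 1.0) > 0.05 for m in truth.enriched_mirnas):
                quiet += 1
        assert quiet >= 8

    def test_determinism(self, tmp_path):
        kw = dict(n_mirnas=10, gene_universe=100, seed=4)
        gen_target_databases(outdir=tmp_path / "a", **kw)
        gen_target_databases(outdir=tmp_path / "b", **kw)
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")


class TestCohortGenerator:
    def test_determinism(self, tmp_path):
        kw = dict(n_igan=30, n_disease_control=5, n_normal=5, seed=8)
        gen_cohort(outdir=tmp_path / "a", **kw)
        gen_cohort(outdir=tmp_path / "b", **kw)
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_egfr_consistent_with_creatinine(self):
        cohort, _, _ = gen_cohort(n_igan=20, n_disease_control=3, n_normal=3,
                                  seed=1)
        for row in cohort.itertuples():
            assert ckd_epi_egfr(row.serum_creatinine, row.age,
                                row.sex) == pytest.approx(row.egfr, rel=1e-6)

    def test_labels_and_invariants(self):
        cohort, meas, _ = gen_cohort(n_igan=60, n_disease_control=5,
                                     n_normal=10, seed=2)
        assert set(cohort["progression_label"]) <= {
            "progressor", "non_progressor", "indeterminate"}
        controls = cohort[cohort["group"] != "IgAN"]
        assert (controls["progression_label"] == "indeterminate").all()
        assert (meas["urine_creatinine"] > 0).all()
        assert (cohort["egfr"] > 0).all()

    def test_measurements_round_trip_to_levels(self):
        from uromir.clinical_validation import relative_level
        cohort, meas, _ = gen_cohort(n_igan=10, n_disease_control=2,
                                     n_normal=2, seed=3)
        lv = [relative_level(r.ct_target, r.ct_reference, r.urine_creatinine)
              for r in meas.itertuples()]
        assert np.isfinite(lv).all()
        # levels vary across patients (not a degenerate constant)
        assert np.std(lv) > 0.1

    def test_null_assay_effects_give_unit_hazard_ratios(self):
        effects = {f"m{i}": {"log_hr": 0.0} for i in range(4)}
        betas = []
        for seed in (1, 2, 3):
            cohort, meas, _ = gen_cohort(n_igan=150, n_disease_control=0,
                                         n_normal=0, assay_effects=effects,
                                         seed=seed)
            from uromir.pipeline import compute_levels
            levels = compute_levels(meas)
            data = cohort.merge(levels, left_on="patient_id",
                                right_index=True)
            for a in effects:
                res = cox_univariate(data["time_years"], data["event"],
                                     data[a])
                if res.converged:
                    betas.append(res.beta)
        assert abs(np.mean(betas)) < 0.12

    def test_strong_assay_effect_detected(self):
        effects = {"hot": {"log_hr": 1.0}, "cold": {"log_hr": 0.0}}
        wins = 0
        n_runs = 30
        for seed in range(1, n_runs + 1):
            cohort, meas, _ = gen_cohort(n_igan=200, n_disease_control=0,
                                         n_normal=0, assay_effects=effects,
                                         seed=seed)
            from uromir.pipeline import compute_levels
            data = cohort.merge(compute_levels(meas), left_on="patient_id",
                                right_index=True)
            res = cox_univariate(data["time_years"], data["event"],
                                 data["hot"])
            if res.converged and res.hr > 1.0:
                wins += 1
        assert wins >= int(0.95 * n_runs)
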