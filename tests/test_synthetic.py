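"""Generator determinism, planted-truth consistency and config validation."""

import numpy as np
import pandas as pd
import pytest

from crcpanel.somatic import carrier_matrix, filter_somatic
from crcpanel.synthetic import (
    CohortConfig,
    generate_clinical,
    generate_cnv_segments,
    generate_drug_screen_db,
    generate_germline_genotypes,
    generate_reference_with_indels,
    generate_somatic_variants,
)


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = CohortConfig(n_patients=40, seed=5)
        a, ta = generate_clinical(cfg)
        b, tb = generate_clinical(CohortConfig(n_patients=40, seed=5))
        pd.testing.assert_frame_equal(a, b)
        assert ta == tb

    def test_different_seed_differs(self):
        a, _ = generate_clinical(CohortConfig(n_patients=40, seed=1))
        b, _ = generate_clinical(CohortConfig(n_patients=40, seed=2))
        assert not a["os_months"].equals(b["os_months"])

    def test_somatic_draw_independent_of_clinical_call_order(self):
        # child seeds: regenerating somatic twice gives the same table
        cfg = CohortConfig(n_patients=30, seed=9)
        clinical, _ = generate_clinical(cfg)
        v1, _ = generate_somatic_variants(cfg, clinical)
        v2, _ = generate_somatic_variants(cfg, clinical)
        pd.testing.assert_frame_equal(v1, v2)


class TestClinical:
    def test_schema_and_invariants(self, small_cohort):
        clin = small_cohort["clinical"]
        assert len(clin) == 150
        assert clin["patient_id"].is_unique
        assert (clin["rfs_months"] <= clin["os_months"] + 1e-9).all()
        assert clin["stage"].isin(["I", "II", "III", "IV"]).all()
        assert clin["os_months"].between(0, 120).all()

    def test_treatment_restricted_to_stage_ii_plus(self, small_cohort):
        clin = small_cohort["clinical"]
        assert (clin.loc[clin["stage"] == "I", "regimen"] == "none").all()
        treated = clin["regimen"] != "none"
        assert abs(treated.mean() - 0.62) < 0.12

    def test_stage_marginals_near_configured(self):
        clin, _ = generate_clinical(CohortConfig(n_patients=2000, seed=3))
        props = clin["stage"].value_counts(normalize=True)
        assert props["III"] == pytest.approx(0.47, abs=0.04)
        assert props["I"] == pytest.approx(0.12, abs=0.03)

    def test_planted_set_shortens_survival(self):
        cfg = CohortConfig(n_patients=1500, seed=4)
        clin, truth = generate_clinical(cfg)
        genes = set(cfg.planted_prognostic_sets["os5"]["genes"])
        in_set = np.array([bool(genes & set(truth["carriers"][p]))
                           for p in clin["patient_id"]])
        # restricted mean over the follow-up window
        assert clin.loc[in_set, "os_months"].mean() < clin.loc[~in_set, "os_months"].mean() - 5

    def test_planted_stage_gene_marginal_preserved(self):
        cfg = CohortConfig(n_patients=4000, seed=6)
        _, truth = generate_clinical(cfg)
        freq = np.mean([("APC" in truth["carriers"][p]) for p in truth["carriers"]])
        assert freq == pytest.approx(0.64, abs=0.03)

    def test_planted_stage_gene_enriched_in_advanced(self):
        cfg = CohortConfig(n_patients=4000, seed=6)
        _, truth = generate_clinical(cfg)
        adv, early = [], []
        for p, info in truth["patients"].items():
            (adv if info["stage"] in ("III", "IV") else early).append(
                "APC" in truth["carriers"][p])
        assert np.mean(adv) > np.mean(early) + 0.05

    def test_empty_cohort(self):
        clin, truth = generate_clinical(CohortConfig(n_patients=0))
        assert len(clin) == 0 and truth["carriers"] == {}


class TestConfigValidation:
    def test_bad_distribution(self):
        with pytest.raises(ValueError):
            CohortConfig(stage_distribution={"I": 0.5, "II": 0.2})

    def test_unknown_planted_gene(self):
        with pytest.raises(ValueError, match="NOTAGENE"):
            CohortConfig(planted_stage_genes={"NOTAGENE": 2.0})

    def test_unknown_set_gene(self):
        with pytest.raises(ValueError):
            CohortConfig(planted_prognostic_sets={"s": {"genes": ["NOPE"], "hr": 2.0}})

    def test_negative_hr(self):
        with pytest.raises(ValueError):
            CohortConfig(planted_prognostic_sets={"s": {"genes": ["APC"], "hr": -1.0}})


class TestSomaticTruth:
    def test_carriers_realized_after_filtering(self, small_cohort):
        clin = small_cohort["clinical"]
        variants = small_cohort["variants"]
        truth = small_cohort["variant_truth"]
        kept = filter_somatic(variants)
        cm = carrier_matrix(kept, clin["patient_id"])
        for pid, genes in truth["carriers"].items():
            for g in genes:
                assert cm.loc[pid, g] >= 1, f"{pid} lost carriage of {g}"
        # and no spurious carriage
        for pid in clin["patient_id"]:
            called = set(cm.columns[cm.loc[pid] > 0])
            assert called <= set(truth["carriers"][pid])

    def test_subthreshold_rows_all_rejected(self, small_cohort):
        variants = small_cohort["variants"]
        sub = variants.iloc[small_cohort["variant_truth"]["subthreshold_rows"]]
        assert len(sub) > 0
        assert len(filter_somatic(sub)) == 0

    def test_kras_carriers_have_hotspot(self, small_cohort):
        variants = small_cohort["variants"]
        truth = small_cohort["variant_truth"]
        kras_carriers = {p for p, gs in truth["carriers"].items() if "KRAS" in gs}
        with_hotspot = set(
            variants.loc[(variants["gene"] == "KRAS")
                         & (variants["protein_change"] != ""), "sample_id"])
        assert kras_carriers <= with_hotspot


class TestReferenceGenerator:
    def test_background_has_no_spurious_runs(self):
        from crcpanel.instability import find_homopolymers

        ref = generate_reference_with_indels(3000, [(500, "C", 7)], {}, seed=1)
        runs = find_homopolymers(ref["sequence"])
        assert [(r.start, r.end, r.base) for r in runs] == [(500, 507, "C")]

    def test_indel_flags_match_positions(self):
        ref = generate_reference_with_indels(
            2000, [(100, "A", 6)], {"n_inside": 4, "n_outside": 3}, seed=2)
        ind = ref["indels"]
        inside = ind["in_homopolymer"]
        assert inside.sum() == 4 and (~inside).sum() == 3
        for _, r in ind.iterrows():
            p0 = r["pos"] - 1
            assert (100 <= p0 < 106) == r["in_homopolymer"]

    def test_oversubscribed_indels_raise(self):
        with pytest.raises(ValueError):
            generate_reference_with_indels(100, [(10, "A", 5)], {"n_inside": 6})


class TestCnvGenerator:
    def test_bin_means_near_expectations(self):
        seg, truth = generate_cnv_segments(
            0.8, 1.0, ["deletion", "duplication", "neutral"],
            bins_per_segment=500, noise_sd=0.05, seed=2)
        f = 0.8
        means = [np.mean(b) for b in seg["bin_log2"]]
        assert means[0] == pytest.approx(np.log2((2 - f) / 2), abs=0.02)
        assert means[1] == pytest.approx(np.log2((2 + f) / 2), abs=0.02)
        assert means[2] == pytest.approx(0.0, abs=0.02)
        assert truth == ["deletion", "duplication", "neutral"]

    def test_deletion_baf_shifted_duplication_balanced(self):
        seg, _ = generate_cnv_segments(
            0.8, 1.0, ["deletion", "duplication"], seed=3)
        f = 0.8
        assert abs(seg["baf"].iloc[0] - 0.5) == pytest.approx(abs(1 / (2 - f) - 0.5), abs=0.05)
        assert seg["baf"].iloc[1] == pytest.approx(0.5, abs=0.05)

    def test_invalid_state_or_purity(self):
        with pytest.raises(ValueError):
            generate_cnv_segments(0.8, 1.0, ["weird"])
        with pytest.raises(ValueError):
            generate_cnv_segments(0.0, 1.0, ["neutral"])


class TestGermlineGenerator:
    def test_matrix_shape_and_codes(self):
        cfg = CohortConfig(n_patients=50, seed=8, n_germline_variants=15)
        clin, _ = generate_clinical(cfg)
        geno, ann = generate_germline_genotypes(cfg, clin)
        assert geno.shape == (15, 50)
        assert geno.isin([0, 1, 2]).all().all()
        assert list(ann.index) == list(geno.index)

    def test_planted_variant_prepended_and_consistent(self):
        cfg = CohortConfig(
            n_patients=50, seed=8, n_germline_variants=5,
            planted_germline_effects={"rsX": {"maf": 0.2, "hr_os": 2.0}})
        clin, _ = generate_clinical(cfg)
        geno, _ = generate_germline_genotypes(cfg, clin)
        assert geno.index[0] == "rsX"

    def test_mismatched_effects_rejected(self):
        cfg = CohortConfig(n_patients=20, seed=8)
        clin, _ = generate_clinical(cfg)
        with pytest.raises(ValueError, match="must match"):
            generate_germline_genotypes(
                cfg, clin, planted_variant_effects={"rsY": {"maf": 0.1}})

    def test_hwe_marginals(self):
        cfg = CohortConfig(
            n_patients=3000, seed=10, n_germline_variants=0,
            planted_germline_effects={"rsH": {"maf": 0.3}})
        geno = generate_germline_genotypes(cfg, generate_clinical(cfg)[0])[0]
        g = geno.loc["rsH"].to_numpy()
        assert (g == 1).mean() == pytest.approx(2 * 0.3 * 0.7, abs=0.03)
        assert (g == 2).mean() == pytest.approx(0.09, abs=0.02)


class TestDrugScreen:
    def test_planted_gene_saturates_resistant_tail(self):
        db = generate_drug_screen_db(planted_resistance_genes={"RES1": {}}, seed=6)
        mut = db["mutations"]
        tail = set(db["resistant_tail"])
        with_gene = set(mut.loc[mut["gene"] == "RES1", "cell_line_id"])
        assert tail <= with_gene

    def test_background_catalog_below_threshold(self):
        db = generate_drug_screen_db(seed=6)
        bg = {g: f for g, f in db["catalog"].mutated_freq.items() if g.startswith("BG")}
        assert max(bg.values()) < 0.05

    def test_too_few_lines(self):
        with pytest.raises(ValueError):
            generate_drug_screen_db(n_cell_lines=10, k=20)
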