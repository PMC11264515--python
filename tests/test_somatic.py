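"""Somatic filtering, impact classing and cohort mutation summaries."""

import numpy as np
import pandas as pd
import pytest

from crcpanel.somatic import (
    apc_truncating_flags,
    carrier_matrix,
    classify_impact,
    compute_tmb,
    comutation_flags,
    filter_somatic,
    gene_frequency,
    kras_allele_annotate,
    oncoplot_summary,
    sample_variant_counts,
)


def make_variants(rows):
    defaults = {
        "sample_id": "P1", "gene": "APC", "chrom": "chr5", "pos": 100,
        "ref": "A", "alt": "T", "variant_class": "missense",
        "vaf": 0.3, "alt_reads": 30, "filter_status": "PASS", "protein_change": "",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestFilter:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ({"filter_status": "PASS", "vaf": 0.05, "alt_reads": 3}, True),   # inclusive floor
            ({"filter_status": "PASS", "vaf": 0.04, "alt_reads": 10}, False),
            ({"filter_status": "PASS", "vaf": 0.30, "alt_reads": 2}, False),
            ({"filter_status": "germline_risk", "vaf": 0.5, "alt_reads": 50}, False),
            ({"filter_status": "PASS", "vaf": 0.051, "alt_reads": 4}, True),
        ],
    )
    def test_boundary_semantics(self, row, kept):
        out = filter_somatic(make_variants([row]))
        assert len(out) == (1 if kept else 0)

    def test_conservation_and_reasons(self):
        v = make_variants([
            {"vaf": 0.5}, {"vaf": 0.01}, {"alt_reads": 1},
            {"filter_status": "weak_evidence"}, {"vaf": np.nan},
        ])
        kept, reasons = filter_somatic(v, return_rejections=True)
        assert len(kept) + sum(reasons.values()) == len(v)
        assert reasons == {"missing_field": 1, "non_pass": 1, "low_vaf": 1, "low_alt_reads": 1}

    def test_idempotent(self):
        v = make_variants([{"vaf": 0.5}, {"vaf": 0.01}, {"alt_reads": 0}])
        once = filter_somatic(v)
        twice = filter_somatic(once)
        pd.testing.assert_frame_equal(once, twice)


class TestImpact:
    @pytest.mark.parametrize("vclass,impact", [
        ("missense", "MODERATE"), ("inframe_deletion", "MODERATE"),
        ("inframe_insertion", "MODERATE"), ("nonsense", "HIGH"),
        ("frameshift_deletion", "HIGH"), ("frameshift_insertion", "HIGH"),
        ("splice_site", "HIGH"), ("tss", "HIGH"),
        ("synonymous", "LOW"), ("other", "MODIFIER"),
    ])
    def test_classing_map(self, vclass, impact):
        assert classify_impact(vclass) == impact

    def test_unknown_class_named_in_error(self):
        with pytest.raises(ValueError, match="startloss"):
            classify_impact("startloss")


class TestCarrierAndFrequency:
    def test_carrier_counts_and_indicator(self):
        v = make_variants([
            {"sample_id": "P1", "gene": "APC"},
            {"sample_id": "P1", "gene": "APC", "pos": 200},
            {"sample_id": "P2", "gene": "TP53", "variant_class": "synonymous"},
        ])
        cm = carrier_matrix(v, ["P1", "P2", "P3"])
        assert cm.loc["P1", "APC"] == 2
        # synonymous is LOW: does not qualify
        assert "TP53" not in cm.columns or cm.loc["P2"].get("TP53", 0) == 0
        assert (cm.loc["P3"] == 0).all()

    def test_row_order_invariance(self):
        v = make_variants([
            {"sample_id": "P2", "gene": "KRAS"}, {"sample_id": "P1", "gene": "APC"},
            {"sample_id": "P1", "gene": "KRAS"},
        ])
        a = carrier_matrix(v, ["P1", "P2"])
        b = carrier_matrix(v.iloc[::-1].reset_index(drop=True), ["P2", "P1"])
        pd.testing.assert_frame_equal(a, b)

    def test_gene_frequency_rounding_to_cohort_values(self):
        cm = pd.DataFrame({"APC": [1] * 53 + [0] * 30}, index=[f"P{i}" for i in range(83)])
        freq = gene_frequency(cm)
        assert freq.loc["APC", "frequency"] == pytest.approx(53 / 83)
        assert round(freq.loc["APC", "frequency"] * 100) == 64

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            gene_frequency(pd.DataFrame(columns=["APC"]))

    def test_extremes(self):
        cm = pd.DataFrame({"A": [1, 1], "B": [0, 0]}, index=["P1", "P2"])
        freq = gene_frequency(cm)
        assert freq.loc["A", "frequency"] == 1.0
        assert freq.loc["B", "frequency"] == 0.0


class TestCounts:
    def test_median_of_even_cohort(self):
        v = make_variants(
            [{"sample_id": "P1", "pos": i} for i in range(18)]
            + [{"sample_id": "P2", "pos": i} for i in range(19)]
        )
        out = sample_variant_counts(v)
        assert out["median_total"] == 18.5

    def test_zero_variant_sample_included(self):
        v = make_variants([{"sample_id": "P1"}])
        out = sample_variant_counts(v, patients=["P1", "P2"])
        assert out["per_sample"].loc["P2", "total"] == 0
        assert out["range_total"][0] == 0

    def test_single_sample_median(self):
        v = make_variants([{"sample_id": "P1"}, {"sample_id": "P1", "pos": 2}])
        out = sample_variant_counts(v)
        assert out["median_total"] == 2.0


class TestTmb:
    @pytest.mark.parametrize("n,mb,expected", [(36, 10.0, 3.6), (0, 10.0, 0.0), (7, 2.0, 3.5)])
    def test_arithmetic(self, n, mb, expected):
        v = make_variants([{"sample_id": "P1", "pos": i} for i in range(n)])
        tmb = compute_tmb(v, mb, patients=["P1"])
        assert tmb.loc["P1"] == pytest.approx(expected)

    def test_bad_panel_size(self):
        with pytest.raises(ValueError):
            compute_tmb(make_variants([{}]), 0.0)


class TestKrasFlags:
    def test_hotspot_alleles(self):
        v = make_variants([
            {"sample_id": "P1", "gene": "KRAS", "protein_change": "p.G12D"},
            {"sample_id": "P2", "gene": "KRAS", "protein_change": "p.G13D"},
            {"sample_id": "P3", "gene": "KRAS", "protein_change": "p.Q61H"},
            {"sample_id": "P4", "gene": "KRAS", "protein_change": "p.Gly12Asp"},
        ])
        flags = kras_allele_annotate(v)
        assert flags.loc["P1"].tolist() == [True, True, True]
        assert flags.loc["P2"].tolist() == [True, True, False]
        assert flags.loc["P3"].tolist() == [True, False, False]
        assert flags.loc["P4", "KRAS_12D"]  # three-letter HGVS accepted

    def test_unparseable_leaves_codon_flags_false(self):
        v = make_variants([{"sample_id": "P1", "gene": "KRAS", "protein_change": "p.?"}])
        flags = kras_allele_annotate(v)
        assert flags.loc["P1", "KRAS_any"]
        assert not flags.loc["P1", "KRAS_codon12_13"]


class TestComutation:
    def test_combinations(self):
        v = make_variants([
            {"sample_id": "P1", "gene": "KRAS", "protein_change": "p.G12D"},
            {"sample_id": "P1", "gene": "TP53"},
            {"sample_id": "P1", "gene": "APC", "variant_class": "missense"},
            {"sample_id": "P2", "gene": "KRAS", "protein_change": "p.G12D"},
            {"sample_id": "P2", "gene": "TP53"},
            {"sample_id": "P2", "gene": "APC", "variant_class": "nonsense"},
        ])
        cm = carrier_matrix(v, ["P1", "P2", "P3"])
        kras = kras_allele_annotate(v, ["P1", "P2", "P3"])
        apc = apc_truncating_flags(v, ["P1", "P2", "P3"])
        flags = comutation_flags(cm, kras, apc)
        assert flags.loc["P1", "KRAS12D_TP53"] and flags.loc["P1", "KRAS1213_TP53"]
        # APC missense does not qualify for the triple
        assert not flags.loc["P1", "APCtrunc_KRAS_TP53"]
        assert flags.loc["P2", "APCtrunc_KRAS_TP53"]
        assert not flags.loc["P3"].any()


class TestOncoplot:
    def test_modal_class_and_ordering(self):
        rows = []
        for i in range(5):
            rows.append({"sample_id": f"P{i}", "gene": "APC", "variant_class": "missense"})
        rows.append({"sample_id": "P0", "gene": "ZZZ", "variant_class": "nonsense"})
        rows.append({"sample_id": "P0", "gene": "AAA", "variant_class": "nonsense"})
        out = oncoplot_summary(make_variants(rows), top_n=3)
        assert out["gene"].tolist() == ["APC", "AAA", "ZZZ"]  # tie broken lexically
        assert out.loc[0, "missense"] == 5

    def test_top_n_larger_than_gene_count(self):
        v = make_variants([{"gene": "APC"}])
        assert len(oncoplot_summary(v, top_n=50)) == 1
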