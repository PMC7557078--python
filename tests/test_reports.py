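"""Ranked report tables: published-table reproduction and structural
invariants (ranking, shares, summary rows, stratum comparisons)."""

import math

import pytest

from dietrisk.core import summarize_samples
from dietrisk.reports import (
    CrfcTable,
    DriContext,
    EmptyReportWarning,
    StratumTotals,
    compare_strata,
    compare_strata_records,
    report_all_foods,
    report_all_pesticides_from_rows,
    report_by_type,
    report_food,
    report_filename,
    sigfig,
)
from dietrisk.filters import SelectionSpec
from dietrisk.tables import table_fixtures

from conftest import make_sample


@pytest.fixture(scope="module")
def fx():
    return table_fixtures()


class TestPeachesTable(object):
    """1996 US-grown conventional peaches, recomputed from printed inputs."""

    def test_row_values_match_printed_columns(self, fx):
        report = fx["peaches_1996"].report()
        top = report.frame.iloc[0]
        assert top.analyte_id == "parathion-methyl"
        assert top.dri_m == pytest.approx(1.756, abs=5e-4)
        assert top.fs_dri == pytest.approx(0.727, abs=5e-4)
        assert top.pct_fs_dri == pytest.approx(69.5, abs=0.1)

    def test_summary_row(self, fx):
        s = fx["peaches_1996"].report().summary
        assert s["n_analytes"] == 23
        assert s["total_positives"] == 591
        assert s["aggregate_fs_dri"] == pytest.approx(1.047, abs=1e-3)
        assert s["aggregate_dri_m"] == pytest.approx(4.092, abs=2e-3)
        assert s["average_n_samples"] == pytest.approx(195, abs=0.5)
        assert s["residues_per_sample"] == pytest.approx(3.03, abs=0.01)

    def test_skewed_tail(self, fx):
        """15 of the 23 analytes sit below FS-DRI 0.01 and together carry
        only a small share of the aggregate."""
        frame = fx["peaches_1996"].report().frame
        small = frame[frame.fs_dri < 0.01]
        assert len(small) == 15
        assert small.pct_fs_dri.sum() < 3.0


class TestChlorpyrifosTable:
    """Chlorpyrifos across 11 foods, 1999 US domestic conventional."""

    def test_shape_and_top_row(self, fx):
        report = fx["chlorpyrifos_1999"].report()
        assert len(report) == 11 and report.summary["n_foods"] == 11
        top = report.frame.iloc[0]
        assert top.food_label == "Apples-Single Servings"
        assert top.dri_m == pytest.approx(0.774, abs=5e-4)
        assert top.pct_fs_dri == pytest.approx(52.9, abs=0.1)

    def test_totals(self, fx):
        s = fx["chlorpyrifos_1999"].report().summary
        assert s["aggregate_fs_dri"] == pytest.approx(0.449, abs=1e-3)
        assert s["total_samples"] == 5574
        assert s["total_positives"] == 603
        assert s["residues_per_sample"] == pytest.approx(0.108, abs=1e-3)


class TestSpringOnionsTable:
    def test_low_risk_aggregates(self, fx):
        s = fx["spring_onions_2016"].report().summary
        assert s["aggregate_fs_dri"] == pytest.approx(0.000867, abs=1e-6)
        assert s["aggregate_dri_m"] == pytest.approx(0.0170, abs=1e-4)
        assert s["n_analytes"] == 13 and s["total_positives"] == 47

    def test_fungicides_dominate_residue_counts(self, fx):
        """The packaged type map classes 36 of the 47 residues (~77%) as
        fungicides, in line with the published near-80% fungicide share."""
        tab = fx["spring_onions_2016"]
        report = report_by_type(tab.summaries(), tab.crfc_table())
        row = report.frame.set_index("ptype").loc["fungicide"]
        assert row.residues == 36
        assert 100.0 * row.residues / report.summary["total_residues"] == pytest.approx(
            79, abs=3
        )


class TestAllFoodsTable:
    def test_2016_us_totals_and_spinach_share(self, fx):
        report = fx["us_all_foods_2016"].report()
        s = report.summary
        assert s["aggregate_fs_dri"] == pytest.approx(2.40, abs=0.01)
        assert s["residues_per_sample"] == pytest.approx(3.12, abs=0.01)
        assert s["n_foods"] == 21 and s["total_positives"] == 24658
        assert s["avg_fs_dri_per_food"] == pytest.approx(0.114, abs=1e-3)
        top = report.frame.iloc[0]
        assert top.food_id == "Spinach"
        assert top.pct_fs_dri == pytest.approx(31.8, abs=0.1)

    def test_top_three_foods_share(self, fx):
        frame = fx["us_all_foods_2016"].report().frame
        assert frame.pct_fs_dri.iloc[:3].sum() == pytest.approx(59.8, abs=0.1)
        assert list(frame.food_id.iloc[:3]) == [
            "Spinach",
            "Green Beans",
            "Cherries, Frozen",
        ]


class TestTopKPesticidesTable:
    def test_ranking_and_others_block(self, fx):
        report = fx["uk_top20_2016"].report()
        assert len(report) == 20
        assert report.frame.iloc[0].analyte_id == "pirimiphos-methyl"
        assert report.summary["others_count"] == 82
        assert report.summary["total_positives"] == 1624
        # published share 49.6% of total FS-DRI; printed-rounding envelope
        assert report.frame.iloc[0].pct_fs_dri == pytest.approx(49.6, rel=0.02)

    def test_topk_equal_to_row_count_leaves_others_empty(self, fx):
        frame = fx["uk_top20_2016"].frame
        report = report_all_pesticides_from_rows(frame, top_k=len(frame))
        assert report.summary["others_count"] == 0
        assert len(report) == len(frame)

    def test_topk_and_others_shares_total_100(self, fx):
        report = fx["uk_top20_2016"].report()
        share = report.frame.pct_fs_dri.sum() + (
            100.0 * report.summary["others_fs_dri"] / report.summary["aggregate_fs_dri"]
        )
        assert share == pytest.approx(100.0, abs=1e-9)


class TestGlyphosateTable:
    def test_oats_rank_first(self, fx):
        report = fx["glyphosate_2016"].report()
        assert len(report) == 10
        top = report.frame.iloc[0]
        assert top.food_label == "Breakfast Cereal: Oats"
        # printed-rounding envelope targets (raw samples unavailable)
        assert top.dri_m == pytest.approx(0.000549, rel=0.02)
        assert top.pct_fs_dri == pytest.approx(38.24, rel=0.02)


class TestComparisons:
    def test_conventional_vs_organic_apples(self, fx):
        table = compare_strata(*fx["apples_2009"])
        assert table.summary["fs_dri_ratio"] == pytest.approx(255, abs=1)

    def test_domestic_vs_imported_potatoes(self, fx):
        with pytest.warns(EmptyReportWarning, match="pct_zero_residue"):
            table = compare_strata(*fx["us_potatoes_2015"])
        assert table.summary["fs_dri_ratio"] == pytest.approx(2.06, abs=0.01)
        assert table.summary["dri_m_ratio"] == pytest.approx(6.99, abs=0.01)
        # imported stratum has 0% zero-residue samples: that ratio is absent
        assert math.isnan(table.frame.iloc[2].pct_zero_residue)

    def test_identical_strata_ratio_one(self):
        a = StratumTotals("a", 10.0, 5, 20.0, 0.5, 1.0, 0.25)
        b = StratumTotals("b", 10.0, 5, 20.0, 0.5, 1.0, 0.25)
        table = compare_strata(a, b)
        ratios = table.frame.iloc[2]
        for f in ("avg_samples", "residues", "dri_m", "fs_dri"):
            assert ratios[f] == pytest.approx(1.0)

    def test_from_records_by_claim(self, thresholds, servings):
        records = [
            make_sample(sample_id=f"C{i}", concs={"captan": 0.5}, claim="none")
            for i in range(10)
        ] + [
            make_sample(sample_id=f"O{i}", concs={"captan": 0.0}, claim="organic")
            for i in range(10)
        ]
        ctx = DriContext(thresholds, servings)
        with pytest.warns(EmptyReportWarning):
            table = compare_strata_records(records, "claim", ctx)
        conv = table.frame.iloc[0]
        assert conv.stratum == "conventional" and conv.residues == 10


class TestStructuralInvariants:
    def test_aggregate_equals_sum_of_rows_exactly(self, fx):
        for name in ("peaches_1996", "chlorpyrifos_1999", "spring_onions_2016"):
            report = fx[name].report()
            assert report.summary["aggregate_fs_dri"] == report.frame.fs_dri.sum()
            assert report.summary["aggregate_dri_m"] == report.frame.dri_m.sum()

    def test_ranking_is_a_permutation_sorted_descending(self, fx):
        report = fx["peaches_1996"].report()
        assert sorted(report.frame.analyte_id) == sorted(
            r.label for r in fx["peaches_1996"].rows
        )
        assert list(report.frame.fs_dri) == sorted(report.frame.fs_dri, reverse=True)

    def test_shares_sum_to_100(self, fx):
        for name in ("peaches_1996", "chlorpyrifos_1999", "glyphosate_2016"):
            assert fx[name].report().frame.pct_fs_dri.sum() == pytest.approx(
                100.0, abs=1e-9
            )

    def test_single_analyte_food_share_is_100(self, thresholds, servings):
        samples = [
            make_sample(sample_id=f"S{i}", concs={"captan": 0.2}) for i in range(5)
        ]
        report = report_food(
            summarize_samples(samples), "peaches", DriContext(thresholds, servings)
        )
        assert report.frame.pct_fs_dri.iloc[0] == pytest.approx(100.0)

    def test_tie_break_is_deterministic_by_name(self):
        rows = [
            make_sample(sample_id=f"S{i}", concs={"b-analyte": 0.1, "a-analyte": 0.1},
                        loq=0.01)
            for i in range(3)
        ]
        ctx = CrfcTable({("a-analyte",): (1.0, 100.0), ("b-analyte",): (1.0, 100.0)})
        report = report_food(summarize_samples(rows), "peaches", ctx)
        assert list(report.frame.analyte_id) == ["a-analyte", "b-analyte"]

    def test_one_food_dataset_all_foods_matches_food_report(
        self, thresholds, servings
    ):
        samples = [
            make_sample(sample_id=f"S{i}", concs={"captan": 0.3, "iprodione": 0.1})
            for i in range(6)
        ]
        summaries = summarize_samples(samples)
        ctx = DriContext(thresholds, servings)
        all_foods = report_all_foods(summaries, ctx)
        one_food = report_food(summaries, "peaches", ctx)
        assert all_foods.summary["aggregate_fs_dri"] == pytest.approx(
            one_food.summary["aggregate_fs_dri"], rel=1e-12
        )
        assert all_foods.summary["total_positives"] == one_food.summary["total_positives"]

    def test_empty_selection_warns_and_returns_empty(self, thresholds, servings):
        with pytest.warns(EmptyReportWarning):
            report = report_food([], "peaches", DriContext(thresholds, servings))
        assert len(report) == 0

    def test_missing_threshold_rows_excluded_and_counted(self, servings):
        samples = [
            make_sample(sample_id=f"S{i}", concs={"unlisted": 0.2}) for i in range(3)
        ]
        ctx = DriContext({}, servings)
        with pytest.warns(EmptyReportWarning):
            report_food(summarize_samples(samples), "peaches", ctx)
        assert ctx.diagnostics.missing_threshold["unlisted"] == 1


class TestRendering:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.75625, 1.76), (0.0008671, 0.000867), (0.2575, 0.258), (15.625, 15.6)],
    )
    def test_sigfig_three(self, value, expected):
        assert sigfig(value, 3) == expected

    def test_filename_encodes_kind_and_selection(self):
        spec = SelectionSpec("domestic_us", "conventional", True, False)
        name = report_filename(5, spec, 2016, "us")
        assert name == "r05_us_domestic_us_conventional_r10_noOC_2016.csv"

    def test_csv_round_trip_full_precision(self, fx, tmp_path):
        report = fx["peaches_1996"].report()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        report.to_csv(p1, full_precision=True)
        fx["peaches_1996"].report().to_csv(p2, full_precision=True)
        assert p1.read_bytes() == p2.read_bytes()  # byte-identical reruns
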