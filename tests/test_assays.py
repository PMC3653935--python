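"""Plate statistics: growth folds, false-negative scoring, Z', ANOVA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import table_from_ratios
from nucbarcode.assays import (
    count_per_well,
    coculture_equivalence_test,
    growth_false_negative_rate,
    growth_fold,
    growth_table,
    nuclear_reporter_summary,
    z_prime,
)
from nucbarcode.barcode import EXCLUDED
from nucbarcode.model import Channel, NucleusRecord, ObjectTable, ValidationError


def _counts(rows):
    return pd.DataFrame(rows, columns=["well_id", "day", "line", "count"])


class TestCountPerWell:
    def test_line_counts_and_total(self):
        table = table_from_ratios([0.5] * 6, well_id="B01")
        assignments = ["A", "A", "A", "B", "B", "other"]
        counts = count_per_well([(table, assignments)])
        by_line = counts.set_index("line")["count"]
        assert by_line["A"] == 3
        assert by_line["B"] == 2
        assert by_line["other"] == 1
        assert by_line["total"] == 6

    def test_excluded_not_in_total(self):
        table = table_from_ratios([0.5] * 4, well_id="B01")
        counts = count_per_well([(table, ["A", "A", EXCLUDED, EXCLUDED])])
        by_line = counts.set_index("line")["count"]
        assert by_line["total"] == 2
        assert by_line[EXCLUDED] == 2

    def test_empty_input_gives_empty_table(self):
        assert count_per_well([]).empty

    def test_fields_of_same_well_summed(self):
        t0 = table_from_ratios([0.5] * 2, well_id="B01", field_index=0)
        t1 = table_from_ratios([0.5] * 3, well_id="B01", field_index=1)
        counts = count_per_well([(t0, ["A", "A"]), (t1, ["A", "A", "A"])])
        assert counts.set_index("line")["count"]["A"] == 5


class TestGrowthFold:
    def test_printed_day4_over_day0_folds(self):
        """638/359 -> 1.78 and 591/314 -> 1.88 at two decimals."""
        counts = _counts(
            [
                ("w1", 0, "a", 359), ("w1", 4, "a", 638),
                ("w2", 0, "b", 314), ("w2", 4, "b", 591),
            ]
        )
        assert round(growth_fold(counts, "w1", "a", 4), 2) == 1.78
        assert round(growth_fold(counts, "w2", "b", 4), 2) == 1.88

    def test_no_growth_gives_unity(self):
        counts = _counts([("w", 0, "a", 100), ("w", 4, "a", 100)])
        assert growth_fold(counts, "w", "a", 4) == 1.0

    def test_zero_baseline_flagged_undefined(self):
        counts = _counts([("w", 0, "a", 0), ("w", 4, "a", 10)])
        with pytest.raises(ValidationError, match="undefined"):
            growth_fold(counts, "w", "a", 4)

    def test_growth_table_skips_undefined_wells(self):
        counts = _counts(
            [
                ("w1", 0, "a", 100), ("w1", 3, "a", 150),
                ("w2", 0, "a", 0), ("w2", 3, "a", 10),
            ]
        )
        out = growth_table(counts, day_t=3)
        assert list(out.well_id) == ["w1"]
        assert out.fold.iloc[0] == pytest.approx(1.5)


class TestFalseNegativeRate:
    def test_all_treated_far_above_threshold(self):
        frac, _ = growth_false_negative_rate([100, 110, 120], [1, 2, 3])
        assert frac == 0.0

    def test_all_treated_below_threshold(self):
        frac, _ = growth_false_negative_rate([1, 2, 3], [100, 110, 120])
        assert frac == 1.0

    def test_degenerate_reference_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            frac, tau = growth_false_negative_rate([5.0], [2.0, 2.0, 2.0])
        assert tau == 2.0
        assert frac == 0.0

    def test_reference_too_small_rejected(self):
        with pytest.raises(ValidationError):
            growth_false_negative_rate([1.0], [1.0])

    def test_longitudinal_scoring_beats_cross_well_scoring(self):
        """Per-well fold normalization wins when plating cv >> assay cv.

        Day-0 counts ~ Normal(1000, 15% cv); every well truly grows
        1.5-fold with 5% measurement noise.  Scoring Day-4 counts against
        the Day-0 cross-well distribution misses many growing wells;
        scoring per-well folds against a no-growth fold reference misses
        far fewer.
        """
        rng = np.random.default_rng(2024)
        n = 10_000
        day0_true = rng.normal(1000, 150, size=n)
        meas0 = day0_true * rng.normal(1, 0.05, size=n)
        meas4 = day0_true * 1.5 * rng.normal(1, 0.05, size=n)
        # cross-well: compare Day-4 counts to 3sd above the Day-0 spread
        fn_cross, _ = growth_false_negative_rate(meas4, meas0)
        # longitudinal: per-well folds vs the no-growth fold distribution
        null_folds = rng.normal(1, 0.05 * np.sqrt(2), size=n)
        folds = meas4 / meas0
        fn_long, _ = growth_false_negative_rate(folds, null_folds)
        assert fn_long < fn_cross


class TestZPrime:
    def test_hand_computed_value(self):
        pos = [1.9, 2.0, 2.1]
        neg = [0.9, 1.0, 1.1]
        q = z_prime(pos, neg)
        assert q.z_prime == pytest.approx(1 - 3 * (0.1 + 0.1) / 1.0)

    def test_perfect_assay_limit(self):
        q = z_prime([2.0, 2.0], [1.0, 1.0])
        assert q.z_prime == 1.0

    def test_equal_means_undefined(self):
        with pytest.raises(ValidationError, match="equal"):
            z_prime([1.0, 1.2], [1.2, 1.0])

    def test_converges_to_closed_form_at_12_sigma_separation(self):
        """mu gap of 12 sigma gives Z' -> 1 - 6/12 = 0.5."""
        rng = np.random.default_rng(7)
        sigma = 0.4
        pos = rng.normal(12 * sigma, sigma, size=4000)
        neg = rng.normal(0.0, sigma, size=4000)
        assert z_prime(pos, neg).z_prime == pytest.approx(0.5, abs=0.02)


def _reporter_table(well, field, yfp_by_line):
    records = []
    oid = 0
    for line, vals in yfp_by_line.items():
        for v in vals:
            oid += 1
            records.append(
                NucleusRecord(
                    object_id=oid, well_id=well, field_index=field, day=0,
                    centroid=(0.0, 0.0), area_px=100,
                    intensity={
                        Channel.EM1: 1.0, Channel.EM2: 1.0,
                        Channel.YFP: v * 100,
                    },
                    ratio_em1_em2=1.0,
                )
            )
    assignments = [
        line for line, vals in yfp_by_line.items() for _ in vals
    ]
    return ObjectTable(records=records), assignments


class TestReporterSummary:
    def test_uniform_intensity_gives_mean_no_spread(self):
        pairs = [
            _reporter_table("w1", 0, {"A": [100.0] * 5}),
            _reporter_table("w1", 1, {"A": [100.0] * 5}),
        ]
        out = nuclear_reporter_summary(pairs, {"w1": "veh"})
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(100.0)
        assert row["sd"] == pytest.approx(0.0)
        assert row["n_fields"] == 2

    def test_demultiplexed_lines_keep_distinct_means(self):
        pairs = [
            _reporter_table("w1", 0, {"A": [100.0] * 5, "B": [200.0] * 5}),
        ]
        out = nuclear_reporter_summary(pairs, {"w1": "veh"}).set_index("line")
        assert out.loc["A", "mean"] == pytest.approx(100.0)
        assert out.loc["B", "mean"] == pytest.approx(200.0)

    def test_empty_field_contributes_missing_not_zero(self):
        pairs = [_reporter_table("w1", 0, {"A": [50.0] * 3})]
        out = nuclear_reporter_summary(pairs, {"w1": "veh"})
        assert set(out.line) == {"A"}


class TestEquivalenceTest:
    def _panel(self, rng, shift=0.0, n_rep=6):
        rows = []
        for treat in ("veh", "dht", "e2", "actd"):
            base = {"veh": 1.0, "dht": 5.0, "e2": 3.0, "actd": 0.5}[treat]
            for mode in ("mono", "co"):
                for _ in range(n_rep):
                    val = base + (shift if mode == "co" else 0.0)
                    rows.append(
                        {
                            "treatment": treat,
                            "mode": mode,
                            "value": val + rng.normal(0, 0.2),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_values_in_both_modes_give_f_zero_p_one(self):
        rng = np.random.default_rng(1)
        rows = []
        for treat in ("veh", "dht", "e2"):
            vals = rng.normal({"veh": 1, "dht": 5, "e2": 3}[treat], 0.2, 5)
            for mode in ("mono", "co"):  # exact copies in both modes
                rows += [
                    {"treatment": treat, "mode": mode, "value": v} for v in vals
                ]
        f, p = coculture_equivalence_test(pd.DataFrame(rows))
        assert f == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_constant_shift_detected(self):
        df = self._panel(np.random.default_rng(2), shift=2.0)
        f, p = coculture_equivalence_test(df)
        assert p < 1e-6

    def test_single_treatment_rejected(self):
        df = pd.DataFrame(
            {"treatment": ["veh"] * 4, "mode": ["mono", "mono", "co", "co"],
             "value": [1.0, 1.1, 1.0, 1.2]}
        )
        with pytest.raises(ValidationError, match="two treatments"):
            coculture_equivalence_test(df)
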