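"""Ratio measurement, window calibration, classification and spectral model."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from conftest import table_from_ratios
from nucbarcode.barcode import (
    AMBIGUOUS,
    CalibrationError,
    EXCLUDED,
    FPSpectrum,
    LineCalibration,
    OTHER,
    band_integral,
    calibrate_line,
    classify_objects,
    classify_ratios,
    make_windows,
    measure_objects,
    predict_em_ratio_from_spectrum,
    predict_mixture_ratio,
)
from nucbarcode.barcode import BarcodeCalibration
from nucbarcode.model import Channel, LOW_SIGNAL, SATURATED
from nucbarcode.simulate import render_nucleus


class TestMeasureObjects:
    def _disk_label(self, shape=(64, 64), radius=10):
        labels = np.zeros(shape, dtype=int)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        labels[(rr - 32) ** 2 + (cc - 32) ** 2 <= radius**2] = 1
        return labels

    def test_ratio_is_summed_em1_over_summed_em2(self):
        labels = self._disk_label()
        area = (labels == 1).sum()
        em1 = np.where(labels == 1, 100.0 / area, 0.0)
        em2 = np.where(labels == 1, 200.0 / area, 0.0)
        table = measure_objects(labels, {"em1": em1, "em2": em2})
        rec = table.records[0]
        assert rec.ratio_em1_em2 == pytest.approx(0.5, rel=1e-12)
        assert rec.intensity[Channel.EM1] == pytest.approx(100.0)

    def test_zero_em2_sum_flags_low_signal(self):
        labels = self._disk_label()
        em1 = np.where(labels == 1, 1.0, 0.0)
        table = measure_objects(labels, {"em1": em1, "em2": np.zeros_like(em1)})
        rec = table.records[0]
        assert rec.ratio_em1_em2 is None
        assert LOW_SIGNAL in rec.flags

    def test_low_signal_floor_scales_with_noise_and_area(self):
        labels = self._disk_label()
        area = (labels == 1).sum()
        em2_total = 4.9 * 2.0 * math.sqrt(area)  # just below 5*sd*sqrt(area)
        em2 = np.where(labels == 1, em2_total / area, 0.0)
        table = measure_objects(
            labels, {"em1": em2, "em2": em2}, noise_sd=2.0
        )
        assert LOW_SIGNAL in table.records[0].flags

    def test_saturated_flag_from_raw_frames(self):
        labels = self._disk_label()
        em = np.where(labels == 1, 10.0, 0.0)
        raw = np.where(labels == 1, 4095, 0).astype(np.uint16)
        table = measure_objects(
            labels, {"em1": em, "em2": em}, raw={"em1": raw, "em2": raw}
        )
        assert SATURATED in table.records[0].flags

    def test_empty_label_image_gives_empty_table(self):
        table = measure_objects(np.zeros((16, 16), dtype=int), {"em1": np.zeros((16, 16)), "em2": np.zeros((16, 16))})
        assert len(table) == 0

    def test_noise_free_nucleus_ratio_recovered_to_1e6(self):
        em1 = np.zeros((64, 64))
        em2 = np.zeros((64, 64))
        footprint = render_nucleus(em1, em2, (32, 32), 6.0, 5.0e4, 0.737)
        labels = footprint.astype(int)
        table = measure_objects(labels, {"em1": em1, "em2": em2})
        assert table.records[0].ratio_em1_em2 == pytest.approx(0.737, rel=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_ratio_scale_invariance(self, scale):
        """Multiplying both corrected grids by c > 0 leaves R unchanged."""
        em1 = np.zeros((48, 48))
        em2 = np.zeros((48, 48))
        footprint = render_nucleus(em1, em2, (24, 24), 5.0, 3.0e4, 0.88)
        labels = footprint.astype(int)
        base = measure_objects(labels, {"em1": em1, "em2": em2})
        scaled = measure_objects(labels, {"em1": em1 * scale, "em2": em2 * scale})
        assert scaled.records[0].ratio_em1_em2 == pytest.approx(
            base.records[0].ratio_em1_em2, rel=1e-9
        )


class TestCalibrateLine:
    def test_hand_computed_mean_and_sample_sd(self):
        table = table_from_ratios([0.5, 0.6, 0.7])
        cal = calibrate_line([table], "x", min_n=3)
        assert cal.mu == pytest.approx(0.6)
        assert cal.sigma == pytest.approx(0.1)
        assert cal.n == 3

    def test_degenerate_zero_sd_fails_window_construction(self):
        table = table_from_ratios([0.7] * 10)
        cal = calibrate_line([table], "x", min_n=5)
        assert cal.sigma == 0.0
        with pytest.raises(CalibrationError, match="sigma"):
            make_windows([cal], k=3)

    def test_insufficient_objects_named_in_error(self):
        table = table_from_ratios([0.5, 0.6])
        with pytest.raises(CalibrationError, match="only 2"):
            calibrate_line([table], "x", min_n=500)

    def test_flagged_objects_excluded_from_calibration(self):
        table = table_from_ratios([0.5, 0.6, 0.7])
        table.records[0].flags = frozenset({SATURATED})
        cal = calibrate_line([table], "x", min_n=2)
        assert cal.n == 2
        assert cal.mu == pytest.approx(0.65)

    def test_large_sample_recovers_parameters(self):
        """1e4 draws from Normal(0.560, 0.025): mu and sigma within 3 se."""
        rng = np.random.default_rng(99)
        draws = rng.normal(0.560, 0.025, size=10_000)
        cal = calibrate_line([table_from_ratios(draws)], "x")
        assert cal.mu == pytest.approx(0.560, abs=0.00075)
        assert cal.sigma == pytest.approx(0.025, abs=0.0006)


class TestMakeWindows:
    def test_three_sd_window_matches_printed_bounds(self):
        cal = LineCalibration("mCherry2", mu=0.5544, sigma=0.0236, n=1000)
        windows = make_windows([cal], k=3)
        lo, hi = windows.window("mCherry2")
        assert round(lo, 4) == 0.4836
        assert round(hi, 4) == 0.6252

    def test_half_sd_window_arithmetic(self):
        cal = LineCalibration("x", mu=1.0, sigma=0.1, n=10)
        lo, hi = make_windows([cal], k=0.5).window("x")
        assert (lo, hi) == (pytest.approx(0.95), pytest.approx(1.05))

    def test_adjacent_three_line_windows_disjoint_at_k3(self):
        cals = [
            LineCalibration("a", 0.560, 0.025, 100),
            LineCalibration("b", 0.737, 0.031, 100),
        ]
        windows = make_windows(cals, k=3)
        assert windows.window("a")[1] < windows.window("b")[0]  # 0.635 < 0.644

    def test_overlap_reports_pair_and_max_k(self):
        cals = [
            LineCalibration("a", 0.560, 0.025, 100),
            LineCalibration("b", 0.737, 0.031, 100),
        ]
        with pytest.raises(CalibrationError, match="largest non-overlapping k"):
            make_windows(cals, k=4)
        # max non-overlapping k = (0.737-0.560)/(0.025+0.031) = 3.16
        try:
            make_windows(cals, k=4)
        except CalibrationError as exc:
            assert "3.16" in str(exc)

    def test_csv_round_trip(self, tmp_path):
        cals = [
            LineCalibration("a", 0.560, 0.025, 100),
            LineCalibration("b", 0.737, 0.031, 100),
        ]
        windows = make_windows(cals, k=3)
        path = tmp_path / "cal.csv"
        windows.write_csv(path)
        back = BarcodeCalibration.read_csv(path)
        assert back.k == 3
        for line in windows.lines:
            assert back.window(line.label) == pytest.approx(
                windows.window(line.label)
            )


class TestClassify:
    @pytest.fixture()
    def two_line_windows(self):
        return make_windows(
            [
                LineCalibration("mCherry2", 0.5544, 0.0236, 1000),
                LineCalibration("mPlum2", 1.0626, 0.0539, 1000),
            ],
            k=3,
        )

    def test_ratio_inside_window_assigned_to_line(self, two_line_windows):
        assert classify_ratios([0.55], two_line_windows)[0] == "mCherry2"

    def test_ratio_between_windows_is_other(self, two_line_windows):
        assert classify_ratios([0.80], two_line_windows)[0] == OTHER

    def test_flagged_objects_excluded(self, two_line_windows):
        table = table_from_ratios([0.55, 0.55])
        table.records[0].flags = frozenset({SATURATED})
        assignments, counts = classify_objects(table, two_line_windows)
        assert assignments == [EXCLUDED, "mCherry2"]
        assert counts[EXCLUDED] == 1
        assert counts["mCherry2"] == 1

    def test_every_object_lands_in_exactly_one_category(self, two_line_windows):
        rng = np.random.default_rng(5)
        table = table_from_ratios(rng.uniform(0.3, 1.5, size=500))
        assignments, counts = classify_objects(table, two_line_windows)
        assert len(assignments) == 500
        assert sum(counts.values()) == 500

    def test_overlapping_windows_flag_straddlers_ambiguous(self):
        windows = make_windows(
            [
                LineCalibration("a", 0.5, 0.1, 10),
                LineCalibration("b", 0.7, 0.1, 10),
            ],
            k=2,
            allow_overlap=True,
        )
        out = classify_ratios([0.6, 0.35, 0.85], windows)
        assert list(out) == [AMBIGUOUS, "a", "b"]


class TestSpectralPrediction:
    def test_flat_spectrum_equal_width_filters_unity(self):
        wl = np.arange(550.0, 751.0)
        flat = FPSpectrum("flat", wl, np.ones_like(wl))
        assert predict_em_ratio_from_spectrum(flat, detector_factor=1.0) == (
            pytest.approx(1.0, rel=1e-12)
        )

    def test_detector_factor_passes_through_for_flat_spectrum(self):
        wl = np.arange(550.0, 751.0)
        flat = FPSpectrum("flat", wl, np.ones_like(wl))
        assert predict_em_ratio_from_spectrum(flat) == pytest.approx(0.893, rel=1e-12)

    def test_gaussian_spectrum_matches_fine_quadrature_oracle(self):
        """Trapezoid engine vs adaptive quadrature on an analytic spectrum."""
        center, sd = 649.0, 30.0

        def spectrum(l):
            return math.exp(-((l - center) ** 2) / (2 * sd**2))

        num, _ = quad(spectrum, 635.0, 675.0, epsabs=1e-12)
        den, _ = quad(spectrum, 608.0, 648.0, epsabs=1e-12)
        oracle = 0.893 * num / den

        wl = np.arange(560.0, 760.0, 0.25)
        fp = FPSpectrum("g", wl, np.exp(-((wl - center) ** 2) / (2 * sd**2)))
        assert predict_em_ratio_from_spectrum(fp) == pytest.approx(oracle, abs=1e-4)

    def test_band_outside_spectrum_support_rejected(self):
        wl = np.arange(620.0, 660.0)
        fp = FPSpectrum("x", wl, np.ones_like(wl))
        with pytest.raises(Exception, match="support"):
            band_integral(fp.wavelength_nm, fp.intensity, (635.0, 675.0))

    def test_spectrum_csv_round_trip(self, tmp_path):
        wl = np.arange(600.0, 700.0)
        inten = np.exp(-((wl - 649.0) ** 2) / 800.0)
        path = tmp_path / "spec.csv"
        path.write_text(
            "wavelength_nm,relative_intensity\n"
            + "\n".join(f"{w},{i}" for w, i in zip(wl, inten))
        )
        fp = FPSpectrum.from_csv(path, name="mPlum")
        np.testing.assert_allclose(fp.intensity, inten)


class TestMixturePrediction:
    def test_identical_constituents_return_homogeneous_ratio(self):
        assert predict_mixture_ratio(0.74, 0.74) == pytest.approx(0.74, rel=1e-12)

    def test_hand_computed_equal_weight_mixture(self):
        # (1/3 + 1/2) / (2/3 + 1/2) = 5/7
        assert predict_mixture_ratio(0.5, 1.0) == pytest.approx(5.0 / 7.0, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        r_n=st.floats(0.1, 3.0),
        r_c=st.floats(0.1, 3.0),
        w_n=st.floats(0.1, 10.0),
        w_c=st.floats(0.1, 10.0),
    )
    def test_mixture_ratio_between_constituents(self, r_n, r_c, w_n, w_c):
        mixed = predict_mixture_ratio(r_n, r_c, w_n, w_c)
        lo, hi = sorted((r_n, r_c))
        assert lo - 1e-12 <= mixed <= hi + 1e-12

    def test_mixture_monotone_toward_weighted_constituent(self):
        base = predict_mixture_ratio(0.5, 1.2, 1.0, 1.0)
        heavier_c = predict_mixture_ratio(0.5, 1.2, 1.0, 3.0)
        heavier_n = predict_mixture_ratio(0.5, 1.2, 3.0, 1.0)
        assert heavier_n < base < heavier_c
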