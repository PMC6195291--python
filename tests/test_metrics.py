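import numpy as np
import pytest

from arspl.core import EcgRecord, PeakList, RegionBoundaries
from arspl.metrics import (amplitude_gaps, correlation_coefficient,
                           detection_metrics_from_counts, evaluate_detection,
                           rmse, st_level, st_report)


class TestCorrelation:
    def test_perfect_and_anti_correlation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlation_coefficient(a, a) == pytest.approx(1.0)
        assert correlation_coefficient(a, -a) == pytest.approx(-1.0)
        assert correlation_coefficient(a, 2 * a) == pytest.approx(1.0)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=500), rng.normal(size=500)
        cc = correlation_coefficient(a, b)
        assert correlation_coefficient(3 * a + 7, b) == pytest.approx(cc)
        assert correlation_coefficient(-2 * a, b) == pytest.approx(-cc)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlation_coefficient(np.ones(10), np.arange(10.0))


class TestRmse:
    def test_zero_for_identical_and_hand_value(self):
        a = np.array([0.0, 1.0, 2.0, 3.0])
        assert rmse(a, a) == 0.0
        b = np.array([0.0, 1.0, 2.0, 7.0])
        assert rmse(a, b) == pytest.approx(2.0)   # sqrt(16/4)

    def test_symmetry_and_translation_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=100), rng.normal(size=100)
        assert rmse(a, b) == rmse(b, a) >= 0.0
        assert rmse(a + 5.0, b + 5.0) == pytest.approx(rmse(a, b))


class TestStLevel:
    def test_flat_cycle_and_known_difference(self):
        y = np.zeros(1000)
        assert st_level(y, 1000.0, 500, 100) == 0.0
        y[560] = 150.0  # 60 ms after the J-point at 500
        assert st_level(y, 1000.0, 500, 100) == pytest.approx(0.15)

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            st_level(np.zeros(100), 1000.0, 90, 10)


class TestStReport:
    def _setup(self, n_cycles=10):
        # M = n_cycles+2 peaks -> exactly n_cycles scorable cycles (2..M-1)
        m = n_cycles + 2
        px = 1000 * np.arange(1, m + 1)
        n = int(px[-1] + 500)
        b = RegionBoundaries(b_se=px[:-1] + 40, b_te=px[:-1] + 370,
                             b_qs=px[1:] - 30, n_samples=n)
        ori = EcgRecord(1000.0, {"V1": np.zeros(n)})
        return b, ori, n

    def test_identical_records_give_zero_ratios(self):
        b, ori, n = self._setup()
        rep = st_report(ori, ori, b, 1000.0)
        assert rep.cdr == rep.er == rep.dr == 0.0
        assert np.all(rep.stse_mv == 0.0)

    def test_single_elevated_cycle_counts_once(self):
        b, ori, n = self._setup(10)
        syn = EcgRecord(1000.0, {"V1": np.zeros(n)})
        # elevate one cycle's ST point by +0.15 mV (150 µV)
        j = int(b.b_se[3]) + 60
        syn.leads["V1"][j] = 150.0
        rep = st_report(syn, ori, b, 1000.0)
        assert rep.n_cycles == 10
        assert rep.er == pytest.approx(10.0)
        assert rep.dr == 0.0
        assert rep.cdr == pytest.approx(10.0)

    def test_cdr_is_er_plus_dr(self):
        b, ori, n = self._setup(10)
        rng = np.random.default_rng(2)
        syn = EcgRecord(1000.0, {"V1": rng.normal(0, 120.0, size=n)})
        rep = st_report(syn, ori, b, 1000.0)
        assert rep.cdr == pytest.approx(rep.er + rep.dr)
        assert 0.0 <= rep.dr <= rep.cdr <= 100.0


class TestEvaluateDetection:
    def test_published_count_worked_example(self):
        m = detection_metrics_from_counts(tp=11916, fn=119, fp=37)
        assert round(m.se, 2) == 99.01
        assert round(m.p_plus, 2) == 99.69
        assert round(m.acc, 2) == 98.71

    def test_perfect_detection(self):
        m = detection_metrics_from_counts(tp=10, fn=0, fp=0)
        assert m.se == m.p_plus == m.acc == 100.0

    def test_hand_matched_example(self):
        m = evaluate_detection(np.array([102, 1100, 3000]),
                               np.array([100, 1100, 2100]), 1000.0, tol_s=0.05)
        assert (m.tp, m.fn, m.fp) == (2, 1, 1)
        assert m.se == pytest.approx(66.67, abs=0.01)
        assert m.p_plus == pytest.approx(66.67, abs=0.01)
        assert m.acc == pytest.approx(50.0)

    def test_order_invariance(self):
        truth = np.array([500, 1500, 2500, 3500])
        det = np.array([498, 1503, 2499, 3600])
        m1 = evaluate_detection(det, truth, 1000.0)
        m2 = evaluate_detection(det[::-1].copy(), truth, 1000.0)
        assert (m1.tp, m1.fn, m1.fp) == (m2.tp, m2.fn, m2.fp)

    def test_one_to_one_matching(self):
        # two detections near one truth: only one may match
        m = evaluate_detection(np.array([995, 1005]), np.array([1000]),
                               1000.0, tol_s=0.05)
        assert (m.tp, m.fn, m.fp) == (1, 0, 1)


class TestAmplitudeGaps:
    def _boundaries(self):
        px = np.array([1000, 2000, 3000, 4000])
        return RegionBoundaries(b_se=px[:-1] + 40, b_te=px[:-1] + 370,
                                b_qs=px[1:] - 30, n_samples=4500)

    def test_continuous_record_has_zero_gaps(self):
        b = self._boundaries()
        rec = EcgRecord(1000.0, {"V1": np.sin(np.arange(4500) / 100.0)})
        g = amplitude_gaps(rec, b)
        step = 0.01  # max slope of the sine per sample
        assert g.g1 <= step and g.g2 <= step and g.g3 <= step

    def test_constructed_step_at_qrs_stt_junction(self):
        b = self._boundaries()
        y = np.zeros(4500)
        y[int(b.b_se[1]):] += 40.0  # step exactly at one QRS->ST-T junction
        g = amplitude_gaps(EcgRecord(1000.0, {"V1": y}), b)
        assert g.g2 == pytest.approx(20.0)  # mean over the two scored junctions

    def test_mean_over_cycles_at_rp_qrs_junctions(self):
        b = self._boundaries()
        y = np.zeros(4500)
        y[int(b.b_qs[0])] = 10.0
        y[int(b.b_qs[1])] = 30.0
        g = amplitude_gaps(EcgRecord(1000.0, {"V1": y}), b)
        assert g.g1 == pytest.approx(20.0)
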