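"""Detection metrics, the sigmoid delay penalty and the composite score."""

import math

import numpy as np
import pytest

from pbrtqc import (
    AnalyteSeries,
    InputError,
    MEWeights,
    SegmentLayout,
    aggregate,
    detect_alarms,
    false_positive_rate,
    inject_step_bias,
    me_score,
    mnped,
    score_scenario,
    segment_detections,
    sensitivity,
    sigmoid_penalty,
)
from pbrtqc.metrics import SegmentDetection
from pbrtqc.monitors import ControlLimits


def _limits(lcl=-1.0, ucl=1.0):
    return ControlLimits(center=0.0, stat_sd=1.0, ucl=ucl, lcl=lcl)


def _scenario(n=40, segments=((10, 10), (30, 5))):
    series = AnalyteSeries(values=np.full(n, 10.0))
    layout = SegmentLayout(n_total=n, segments=segments)
    return inject_step_bias(series, layout, 0.5, +1)


def _trace_from_outside(outside, k=1):
    stat = np.where(outside, 5.0, 0.0).astype(float)
    return detect_alarms(stat, _limits(), k)


class TestSegmentDetections:
    def test_run_at_segment_start_has_zero_delay(self):
        scenario = _scenario()
        outside = np.zeros(40, dtype=bool)
        outside[10:15] = True
        det = segment_detections(_trace_from_outside(outside, k=3), scenario)
        assert det[0].detected and det[0].delay == 0
        assert not det[1].detected and det[1].delay is None

    def test_delay_is_run_start_minus_segment_start(self):
        scenario = _scenario(segments=((10, 20),))
        outside = np.zeros(40, dtype=bool)
        outside[15:22] = True
        det = segment_detections(_trace_from_outside(outside, k=3), scenario)
        assert det[0].delay == 5

    def test_run_starting_in_gap_does_not_detect(self):
        scenario = _scenario(segments=((10, 10),))
        outside = np.zeros(40, dtype=bool)
        outside[8:18] = True  # run starts before the segment
        det = segment_detections(_trace_from_outside(outside, k=3), scenario)
        assert not det[0].detected

    def test_length_mismatch_is_an_input_error(self):
        scenario = _scenario()
        with pytest.raises(InputError):
            segment_detections(_trace_from_outside(np.zeros(30, dtype=bool)), scenario)


class TestSensitivityAndFPR:
    def test_all_biased_alarmed_gives_one_in_both_modes(self):
        scenario = _scenario()
        outside = scenario.error_flag.copy()
        trace = _trace_from_outside(outside, k=1)
        assert sensitivity(trace, scenario, "observation") == 1.0
        assert sensitivity(trace, scenario, "segment") == 1.0

    def test_observation_mode_is_a_count_ratio(self):
        scenario = _scenario(segments=((10, 10),))
        outside = np.zeros(40, dtype=bool)
        outside[10:18] = True  # 8 of 10 biased observations alarmed
        trace = _trace_from_outside(outside, k=1)
        assert sensitivity(trace, scenario, "observation") == pytest.approx(0.8)

    def test_segment_mode_is_a_segment_ratio(self):
        scenario = _scenario(n=100, segments=((10, 10), (40, 10), (70, 10)))
        outside = np.zeros(100, dtype=bool)
        outside[10:13] = True
        outside[40:43] = True
        trace = _trace_from_outside(outside, k=3)
        assert sensitivity(trace, scenario, "segment") == pytest.approx(2 / 3)

    def test_fpr_counts_unbiased_alarms_only(self):
        scenario = _scenario(n=1000, segments=((100, 50),))
        outside = np.zeros(1000, dtype=bool)
        outside[500:502] = True  # 2 of 950 unbiased observations
        trace = _trace_from_outside(outside, k=1)
        assert false_positive_rate(trace, scenario) == pytest.approx(2 / 950)

    def test_no_alarms_gives_zero_fpr_and_sensitivity(self):
        scenario = _scenario()
        trace = _trace_from_outside(np.zeros(40, dtype=bool))
        assert false_positive_rate(trace, scenario) == 0.0
        assert sensitivity(trace, scenario) == 0.0


class TestMnped:
    def _dets(self, delays, missed=0):
        out = [
            SegmentDetection(i, 0, 100, True, d) for i, d in enumerate(delays)
        ]
        out += [
            SegmentDetection(len(delays) + j, 0, 120, False, None)
            for j in range(missed)
        ]
        return out

    def test_median_of_delays(self):
        assert mnped(self._dets([0, 0, 0, 5, 7])) == 0.0
        assert mnped(self._dets([5, 7])) == 6.0

    def test_no_detection_is_undefined(self):
        assert mnped(self._dets([], missed=3)) is None

    def test_penalize_missed_substitutes_segment_length(self):
        assert mnped(self._dets([0], missed=1), policy="penalize_missed") == 60.0


class TestCompositeScore:
    def test_sigmoid_center_is_exactly_half(self):
        assert sigmoid_penalty(101.0) == 0.5

    def test_sigmoid_small_delay(self):
        assert sigmoid_penalty(5.0) == pytest.approx(1.0 / (1.0 + math.exp(4.8)))

    def test_sigmoid_monotone(self):
        assert sigmoid_penalty(5) < sigmoid_penalty(50) < sigmoid_penalty(101)

    def test_limit_case_perfect_detection_slow(self):
        assert me_score(1.0, 0.0, 1e9) == pytest.approx(0.999)
        assert me_score(1.0, 0.0, None) == pytest.approx(0.999)

    def test_direct_evaluation(self):
        # 0.0005*0.7677 + 0.999*(1-0.0016) - 0.0005*sigmoid(5)
        value = me_score(0.7677, 0.0016, 5.0)
        assert value == pytest.approx(0.997778, abs=1e-5)

    def test_monotone_in_each_argument(self):
        base = me_score(0.8, 0.001, 10.0)
        assert me_score(0.9, 0.001, 10.0) > base
        assert me_score(0.8, 0.002, 10.0) < base
        assert me_score(0.8, 0.001, 50.0) < base

    def test_output_bounds(self):
        for sens in (0.0, 1.0):
            for fpr in (0.0, 1.0):
                for m in (0.0, 101.0, None):
                    v = me_score(sens, fpr, m)
                    # the lower bound is attained only in the worst case
                    # (fpr = 1, nothing detected); otherwise strict
                    assert -0.0005 <= v <= 0.9995
                    if m is not None:
                        assert v > -0.0005


class TestAggregate:
    def _metrics(self, sens, fpr, delays, name="s"):
        trace_free = None
        from pbrtqc.metrics import ScenarioMetrics

        return ScenarioMetrics(
            name=name,
            sensitivity=sens,
            fpr=fpr,
            mnped=float(np.median(delays)) if delays else None,
            detected_segments=len(delays),
            total_segments=max(len(delays), 1),
            delays=tuple(delays),
            missed_lengths=(),
            me_score=me_score(sens, fpr, float(np.median(delays)) if delays else None),
        )

    def test_identical_scenarios_are_idempotent(self):
        m = self._metrics(0.9, 0.001, [2, 4])
        summary = aggregate([m, m, m])
        assert summary.sensitivity == pytest.approx(0.9)
        assert summary.fpr == pytest.approx(0.001)
        assert summary.mnped == 3.0

    def test_means_and_pooled_median(self):
        a = self._metrics(1.0, 0.0, [0, 0])
        b = self._metrics(0.5, 0.002, [3, 7])
        summary = aggregate([a, b])
        assert summary.sensitivity == pytest.approx(0.75)
        assert summary.fpr == pytest.approx(0.001)
        assert summary.mnped == 1.5  # median of pooled [0, 0, 3, 7]

    def test_aggregate_lies_between_scenario_extremes(self):
        a = self._metrics(1.0, 0.0005, [1])
        b = self._metrics(0.6, 0.0020, [9])
        summary = aggregate([a, b])
        assert 0.6 <= summary.sensitivity <= 1.0
        assert 0.0005 <= summary.fpr <= 0.0020

    def test_both_scoring_paths_exposed(self):
        a = self._metrics(1.0, 0.0, [0])
        b = self._metrics(0.5, 0.01, [])
        summary = aggregate([a, b])
        assert summary.me_score != summary.me_score_scenario_mean


def test_infinite_limits_give_all_zero_metrics(small_suite):
    scenario = small_suite[0]
    limits = ControlLimits(center=0.0, stat_sd=1.0, ucl=np.inf, lcl=-np.inf)
    stat = np.asarray(scenario.values, dtype=float)
    trace = detect_alarms(stat, limits, 1)
    metrics = score_scenario(trace, scenario)
    assert metrics.sensitivity == 0.0
    assert metrics.fpr == 0.0
    assert metrics.mnped is None
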