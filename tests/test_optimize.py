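"""Grid construction, configuration evaluation and two-stage selection."""

import dataclasses
import random

import numpy as np
import pytest

from pbrtqc import (
    ConfigurationError,
    MonitorConfig,
    OptimizationError,
    build_grid,
    evaluate_config,
    make_training_context,
    reduced_grid,
    run_grid,
    two_stage_select,
    validate,
)
from pbrtqc.metrics import PerformanceSummary, me_score
from pbrtqc.optimize import GridResult, FittedMonitor


@pytest.fixture(scope="module")
def context(pt_train):
    return make_training_context(pt_train)


@pytest.fixture(scope="module")
def ranked(pt_train, small_suite, context):
    grid = reduced_grid("EWMA", smoothings=(0.5, 0.9), consecutive_ks=(5,))
    return run_grid(grid, small_suite, context)


class TestBuildGrid:
    def test_ewma_default_grid_size(self):
        assert len(build_grid("EWMA")) == 9 * 4 * 4 * 4 * 4  # 2304

    def test_override_shrinks_product(self):
        full = build_grid("EWMA")
        small = build_grid("EWMA", consecutive_ks=(5,))
        assert len(small) == len(full) // 4

    def test_ma_grid_contains_recurrent_optimum_shape(self):
        configs = list(build_grid("MA").configs())
        assert any(c.window == 3 and c.consecutive_k == 5 for c in configs)

    def test_empty_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            build_grid("MA", windows=())

    def test_configs_are_algorithm_valid(self):
        for c in reduced_grid("MQ").configs():
            assert c.algorithm == "MQ" and c.quantile is not None


class TestEvaluateConfig:
    def test_deterministic(self, small_suite, context):
        cfg = MonitorConfig(
            algorithm="EWMA", smoothing=0.9, upper_multiplier=3.0,
            lower_multiplier=3.0, consecutive_k=5,
        )
        a = evaluate_config(cfg, small_suite, context)
        b = evaluate_config(cfg, small_suite, context)
        assert a.training == b.training

    def test_degenerate_config_recorded_not_dropped(self, small_suite):
        from pbrtqc import AnalyteSeries
        from pbrtqc.preprocessing import TransformSpec

        flat = AnalyteSeries(values=np.full(200, 5.0))
        ctx = make_training_context(flat, transform=TransformSpec(lam=1.0))
        cfg = MonitorConfig(algorithm="MA", window=3, consecutive_k=1)
        result = evaluate_config(cfg, small_suite, ctx)
        assert result.failed and result.error

    def test_strong_corner_detects_large_biases(self, small_suite, context):
        cfg = MonitorConfig(
            algorithm="EWMA", smoothing=0.9, upper_multiplier=3.0,
            lower_multiplier=3.0, consecutive_k=5,
        )
        result = evaluate_config(cfg, small_suite, context)
        assert result.training.fpr <= 0.002


class TestRunGridAndSelection:
    def test_ranks_are_a_permutation_with_max_first(self, ranked):
        ranks = sorted(r.rank for r in ranked)
        assert ranks == list(range(1, len(ranked) + 1))
        scores = [r.training.me_score for r in ranked if not r.failed]
        assert scores[0] == max(scores)

    def test_order_invariance(self, small_suite, context, ranked):
        grid = reduced_grid("EWMA", smoothings=(0.5, 0.9), consecutive_ks=(5,))
        configs = list(grid.configs())
        random.Random(0).shuffle(configs)
        shuffled = [evaluate_config(c, small_suite, context) for c in configs]
        by_config = {r.config: r for r in shuffled}
        for r in ranked:
            assert by_config[r.config].training == r.training

    def test_stage1_never_discards_global_maximum(self, ranked):
        best = max(
            (r for r in ranked if not r.failed), key=lambda r: r.training.me_score
        )
        selected = two_stage_select(ranked, retain=0.05, min_retain=1)
        # with min_retain=1 only the ME_Score maximum survives stage 1
        assert selected.config == best.config

    def test_single_candidate_returned_unchanged(self, ranked):
        only = [ranked[0]]
        assert two_stage_select(only).config == ranked[0].config

    def test_all_failed_is_an_optimization_error(self, ranked):
        failed = [dataclasses.replace(r, failed=True, training=None) for r in ranked]
        with pytest.raises(OptimizationError):
            two_stage_select(failed)


def _result(cfg, sens, fpr, mnped_value):
    summary = PerformanceSummary(
        sensitivity=sens, fpr=fpr, mnped=mnped_value,
        me_score=me_score(sens, fpr, mnped_value),
        me_score_scenario_mean=me_score(sens, fpr, mnped_value),
    )
    return GridResult(config=cfg, training=summary, fitted=None)


class TestStageTwoOrdering:
    def _cfg(self, k):
        return MonitorConfig(algorithm="MA", window=3, consecutive_k=k)

    def test_clearly_lower_fpr_wins_regardless_of_sensitivity(self):
        a = _result(self._cfg(1), 0.70, 0.001, 1.0)
        b = _result(self._cfg(3), 0.99, 0.002, 1.0)
        assert two_stage_select([a, b], min_retain=2).config == a.config

    def test_equal_fpr_higher_sensitivity_wins(self):
        a = _result(self._cfg(1), 0.9, 0.001, 1.0)
        b = _result(self._cfg(3), 0.8, 0.001, 1.0)
        assert two_stage_select([a, b], min_retain=2).config == a.config

    def test_fpr_below_resolution_treated_as_tied(self):
        # one false alarm in 35k observations cannot be distinguished from
        # zero at operational granularity; sensitivity breaks the tie
        a = _result(self._cfg(1), 0.50, 0.0, 0.0)
        b = _result(self._cfg(3), 0.99, 4e-5, 0.0)
        assert two_stage_select([a, b], min_retain=2).config == b.config

    def test_equal_fpr_and_sensitivity_shorter_mnped_wins(self):
        a = _result(self._cfg(1), 0.9, 0.001, 9.0)
        b = _result(self._cfg(3), 0.9, 0.001, 2.0)
        assert two_stage_select([a, b], min_retain=2).config == b.config


class TestValidate:
    def test_validation_on_training_suite_matches_training_summary(
        self, small_suite, context, ranked
    ):
        selected = two_stage_select(ranked)
        summary = validate(selected, small_suite)
        assert summary.sensitivity == pytest.approx(selected.training.sensitivity)
        assert summary.fpr == pytest.approx(selected.training.fpr)
        assert summary.me_score == pytest.approx(selected.training.me_score)

    def test_empty_scenario_list_rejected(self, ranked):
        with pytest.raises(OptimizationError):
            validate(two_stage_select(ranked), [])


def test_selected_config_detects_large_biases(pt_train, small_suite, context):
    # parameter recovery: the selected monitor must catch nearly every
    # segment whose bias is at least half the measurement scale
    ranked = run_grid(
        reduced_grid("EWMA", smoothings=(0.7, 0.9)), small_suite, context
    )
    selected = two_stage_select(ranked)
    big = [
        s
        for s in selected.training.per_scenario
        if "50" in s.name or "70" in s.name or "90" in s.name
    ]
    assert big, "suite contains large-bias scenarios"
    detected = sum(s.detected_segments for s in big)
    total = sum(s.total_segments for s in big)
    assert detected / total >= 0.9
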