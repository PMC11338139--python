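import numpy as np
import pandas as pd
import pytest

from slidecorr.correlation import classify_significance, pearson
from slidecorr.sweep import (
    PATTERN_NONE,
    PATTERN_OTHER,
    PATTERN_POS_NS,
    PATTERN_POS_NS_NEG,
    SweepResult,
    TransitionReport,
    WindowResult,
    detect_transition,
    run_sweep,
)
from slidecorr.data_model import NormalizationParams
from slidecorr.windowing import WindowSpec


def make_sweep(rps, norm_params=None):
    """Build a SweepResult from (r, p) pairs, one defined window per pair."""
    windows = tuple(
        WindowResult(
            window_id=k, nominal_lower=5.0 * k, nominal_upper=5.0 * k + 40.0,
            sample_min=5.0 * k + 0.3, sample_max=5.0 * k + 39.1,
            sample_mean=5.0 * k + 20.0, n=50, controls=(),
            r=r, p=p, level=None if r is None else classify_significance(p),
        )
        for k, (r, p) in enumerate(rps)
    )
    return SweepResult(driver="d", response="y", controls=(), spec=WindowSpec(40, 5),
                       windows=windows, norm_params=norm_params)


class TestRunSweep:
    def test_single_window_reduces_to_pearson(self):
        table = pd.DataFrame({"d": [1.0, 2.0, 3.0], "y": [2.0, 3.9, 6.1]})
        sweep = run_sweep(table, "d", "y", spec=WindowSpec(w=10, l=5))
        assert len(sweep.windows) == 1
        win = sweep.windows[0]
        ref = pearson(table["d"], table["y"])
        assert win.r == pytest.approx(ref.r, abs=1e-15)
        assert win.p == pytest.approx(ref.p, abs=1e-15)
        assert win.n == 3

    def test_uniform_driver_reference_window_layout(self):
        rng = np.random.default_rng(21)
        table = pd.DataFrame({"d": rng.uniform(0, 100, 400)})
        table.loc[0, "d"] = 99.99  # ensure max close to 100 but below
        table["y"] = rng.standard_normal(400)
        sweep = run_sweep(table, "d", "y", spec=WindowSpec(w=40, l=5))
        assert len(sweep.windows) == 13
        assert sweep.windows[0].nominal_lower == 0.0
        assert sweep.windows[-1].nominal_lower == 60.0

    def test_descriptive_fields_bounded_by_nominal_range(self, piecewise_table):
        table, _ = piecewise_table
        sweep = run_sweep(table, "driver", "response", spec=WindowSpec(w=25, l=10))
        for w in sweep.windows:
            if w.n >= 1:
                assert w.nominal_lower <= w.sample_min <= w.sample_mean
                assert w.sample_mean <= w.sample_max <= w.nominal_upper
                assert w.x_coord == w.sample_mean and w.y_coord == w.r

    def test_sparse_window_reported_undefined_not_dropped(self):
        # all mass at low driver values; high windows stay nearly empty
        d = np.concatenate([np.linspace(0, 20, 50), [90.0, 95.0]])
        rng = np.random.default_rng(22)
        table = pd.DataFrame({"d": d, "y": rng.standard_normal(d.size)})
        sweep = run_sweep(table, "d", "y", spec=WindowSpec(w=10, l=10))
        undefined = [w for w in sweep.windows if not w.defined]
        assert undefined, "expected low-membership windows to stay in the output"
        for w in undefined:
            assert w.r is None and w.p is None and w.level is None
            assert w.n < 3

    def test_determinism(self, piecewise_table):
        table, _ = piecewise_table
        a = run_sweep(table, "driver", "response", ("conf1",), WindowSpec(w=20, l=5))
        b = run_sweep(table, "driver", "response", ("conf1",), WindowSpec(w=20, l=5))
        assert a == b

    def test_bad_column_roles_raise(self):
        table = pd.DataFrame({"d": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(KeyError):
            run_sweep(table, "d", "missing")
        with pytest.raises(ValueError):
            run_sweep(table, "d", "d")
        with pytest.raises(ValueError):
            run_sweep(table, "d", "y", controls=("y",))


class TestDetectTransition:
    def test_pos_then_ns_then_neg_sequence(self):
        """A positive significant run losing significance marks the transition;
        a later strongly negative window upgrades the pattern."""
        sweep = make_sweep([(0.8, 0.001), (0.7, 0.002), (0.2, 0.2), (-0.6, 0.0001)])
        rep = detect_transition(sweep)
        assert rep.transition_window_id == 2
        assert rep.pattern == PATTERN_POS_NS_NEG
        assert rep.threshold_normalized == sweep.windows[2].sample_min
        assert rep.transition_range == (sweep.windows[2].sample_min,
                                        sweep.windows[2].sample_max)

    def test_pos_then_ns_without_negative_tail(self):
        rep = detect_transition(make_sweep([(0.8, 0.001), (0.1, 0.5), (0.05, 0.8)]))
        assert rep.pattern == PATTERN_POS_NS
        assert rep.transition_window_id == 1

    def test_sustained_positive_run_reports_no_transition(self):
        rep = detect_transition(make_sweep([(0.9, 1e-5), (0.8, 1e-4), (0.7, 1e-3)]))
        assert rep.transition_window_id is None
        assert rep.threshold_normalized is None
        assert rep.pattern == PATTERN_OTHER

    def test_no_positive_run_gives_none_pattern(self):
        rep = detect_transition(make_sweep([(-0.2, 0.4), (0.1, 0.9), (-0.5, 0.01)]))
        assert rep.transition_window_id is None
        assert rep.pattern == PATTERN_NONE

    def test_weakly_negative_significant_window_resets_run(self):
        # transition requires loss of significance, not a mere sign change
        rep = detect_transition(
            make_sweep([(0.8, 0.001), (-0.4, 0.01), (0.1, 0.6)]))
        assert rep.transition_window_id is None

    def test_undefined_windows_are_skipped(self):
        rps = [(0.8, 0.001), (None, None), (0.1, 0.6)]
        rep = detect_transition(make_sweep(rps))
        assert rep.transition_window_id == 2

    def test_threshold_mapped_to_original_units(self):
        params = NormalizationParams(ranges={"d": (0.0, 2.0e15)})
        sweep = make_sweep([(0.8, 0.001), (0.1, 0.5)], norm_params=params)
        rep = detect_transition(sweep)
        expected = sweep.windows[1].sample_min / 100.0 * 2.0e15
        assert rep.threshold_original == pytest.approx(expected)

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            detect_transition(make_sweep([(None, None)]))


class TestBreakpointRecovery:
    def test_recovers_known_breakpoint(self, piecewise_table):
        """On a piecewise system (+1 / 0 / -1 slopes, breaks at 40 and 60) the
        threshold lands within one window width of the first breakpoint."""
        table, truth = piecewise_table
        sweep = run_sweep(table, "driver", "response",
                          controls=("conf1", "conf2"), spec=WindowSpec(w=10, l=2))
        rep = detect_transition(sweep)
        assert rep.pattern == PATTERN_POS_NS_NEG
        assert abs(rep.threshold_normalized - truth.breakpoints[0]) <= 10.0
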