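"""Step detection, P(u) kinetics, yields, bootstrap and curve fits."""

import numpy as np
import pandas as pd
import pytest

from chapfold import (ForceProtocol, QCSettings, RefoldingDataset,
                      SimulationConfig, detect_steps, fit_yield_curve,
                      refolding_yield, unfolding_kinetics)
from chapfold.kinetics import Segment
from chapfold.simulate import Trajectory, simulate_staircase_traces
from chapfold.traces import (EmptySelectionError, bootstrap_sem,
                             per_recording_yields)


def _staircase_trace(step_times, step_size=20.0, duration=10.0, rate=1000.0,
                     noise=0.0, seed=0):
    t = np.arange(int(duration * rate) + 1) / rate
    ext = np.zeros_like(t)
    for st in step_times:
        ext[t >= st] += step_size
    if noise:
        ext = ext + np.random.default_rng(seed).normal(0, noise, t.shape)
    return Trajectory(t, np.full_like(t, 120.0), ext,
                      metadata={"segments": [{"label": "unfold", "t0": 0.0,
                                              "t1": duration, "force_pn": 120.0}]})


class TestDetectSteps:
    def test_noiseless_staircase_recovers_all_steps_at_true_times(self):
        truth = [1.0, 2.5, 4.0, 6.2, 8.8]
        ev = detect_steps(_staircase_trace(truth), expected_step_nm=20.0)
        assert len(ev) == 5
        assert np.allclose(ev.times_s, truth, atol=1e-3)
        assert np.allclose(ev.sizes_nm, 20.0, atol=1e-6)
        assert ev.pulse_labels == ["unfold"] * 5

    def test_flat_trace_yields_no_events(self):
        ev = detect_steps(_staircase_trace([]), expected_step_nm=20.0)
        assert len(ev) == 0

    def test_double_step_resolved_as_two_events(self):
        # two domains unfolding within one dwell window -> one 40-nm jump
        ev = detect_steps(_staircase_trace([3.0, 3.001]), expected_step_nm=20.0)
        assert len(ev) == 2

    def test_off_size_jump_rejected(self):
        ev = detect_steps(_staircase_trace([2.0], step_size=9.0),
                          expected_step_nm=20.0)
        assert len(ev) == 0

    def test_too_short_trace_raises(self):
        tr = _staircase_trace([], duration=0.005)
        with pytest.raises(ValueError, match="short"):
            detect_steps(tr, expected_step_nm=20.0, min_dwell_s=0.01)

    def test_detection_skips_quench_regions(self, ubiquitin_scheme):
        proto = ForceProtocol.force_quench(unfold_s=4.0, t_q_s=2.0, test_s=4.0)
        traces = simulate_staircase_traces(
            ubiquitin_scheme.replace(fold_competence=1.0), proto,
            SimulationConfig(seed=2, n_recordings=1, noise_sd_nm=0.5))
        ev = detect_steps(traces[0], expected_step_nm=20.0)
        labels = set(ev.pulse_labels)
        assert labels <= {"unfold", "test"}

    def test_precision_and_recall_on_simulated_staircases(self, ubiquitin_scheme):
        """>= 99% of true unfolding events recovered, >= 99% of detections
        real, at 1-nm noise / 1 kHz / 20-nm steps (detector benchmark at
        reduced trace count; the full 500-trace benchmark runs in the
        acceptance suite)."""
        proto = ForceProtocol((Segment("unfold", 120.0, 10.0),))
        traces = simulate_staircase_traces(
            ubiquitin_scheme, proto,
            SimulationConfig(seed=4, n_recordings=60, noise_sd_nm=1.0))
        tp = fp = fn = 0
        for tr in traces:
            truth = np.sort([t for (_, t, src, dst) in tr.events
                             if src == "folded" and dst == "ext_free"])
            det = np.sort(detect_steps(tr, expected_step_nm=20.0).times_s)
            used = np.zeros(len(truth), bool)
            for d in det:
                ok = np.flatnonzero(~used & (np.abs(truth - d) < 0.025))
                if len(ok):
                    used[ok[0]] = True
                    tp += 1
                else:
                    fp += 1
            fn += int((~used).sum())
        assert tp / (tp + fn) >= 0.99
        assert tp / (tp + fp) >= 0.99


class TestUnfoldingKinetics:
    def test_rate_recovered_from_exponential_dwells(self):
        """Monte-Carlo oracle: single-exponential dwells at k, n = 10,000
        events, fitted rate within 2 SE of k."""
        k = 0.93
        rng = np.random.default_rng(8)
        trace_times = [np.sort(rng.exponential(1 / k, size=7))
                       for _ in range(1430)]  # ~10,000 events
        curve, fit = unfolding_kinetics(trace_times, min_events=6)
        assert fit.success
        assert abs(fit.rate - k) <= max(2 * fit.rate_se, 0.05 * k)

    def test_curve_is_monotone_and_normalized(self):
        rng = np.random.default_rng(1)
        times = [np.sort(rng.exponential(1.0, size=8)) for _ in range(50)]
        curve, _ = unfolding_kinetics(times)
        assert curve.p_unfold[0] == 0.0
        assert curve.p_unfold[-1] == pytest.approx(1.0)
        assert np.all(np.diff(curve.p_unfold) >= -1e-12)

    def test_min_events_filter_and_empty_selection(self):
        with pytest.raises(EmptySelectionError):
            unfolding_kinetics([np.array([0.1, 0.2])], min_events=6)

    def test_degenerate_all_steps_at_time_zero_reports_failure(self):
        times = [np.zeros(7) for _ in range(10)]
        _, fit = unfolding_kinetics(times)
        assert not fit.success
        assert fit.rate is None


def _dataset(rows, step_size=20.0, n_max=9):
    rec = []
    for i, (si, st, e0, e1) in enumerate(rows):
        rec.append((i, "c", 5.0, 0.0, 120.0, max(si, 1), si, st, e0, e1))
    df = pd.DataFrame(rec, columns=RefoldingDataset.COLUMNS)
    return RefoldingDataset(df, step_size, n_max)


class TestRefoldingYield:
    def test_every_domain_refolds(self):
        ds = _dataset([(5, 5, 100.0, 100.0), (6, 6, 120.0, 120.0)])
        y, _ = refolding_yield(ds)
        assert y == 1.0

    def test_no_domain_refolds(self):
        ds = _dataset([(5, 0, 100.0, 100.0), (7, 0, 140.0, 140.0)])
        y, _ = refolding_yield(ds)
        assert y == 0.0

    def test_hand_built_qc_example(self):
        """5/5 passes, 4/6 fails the extension-equality QC, 0/5 passes:
        pooled yield (5+0)/(5+5) = 0.5."""
        ds = _dataset([(5, 5, 100.0, 100.0),
                       (6, 4, 120.0, 80.0),     # 33% extension mismatch
                       (5, 0, 100.0, 101.0)])
        y, _ = refolding_yield(ds)
        assert y == 0.5

    def test_min_steps_filter(self):
        ds = _dataset([(4, 4, 80.0, 80.0), (5, 0, 100.0, 100.0)])
        y, _ = refolding_yield(ds, QCSettings(min_steps_initial=5))
        assert y == 0.0

    def test_all_failing_qc_raises(self):
        ds = _dataset([(2, 1, 40.0, 40.0)])
        with pytest.raises(EmptySelectionError):
            refolding_yield(ds)

    def test_pooled_vs_per_recording_mean_differ_for_unequal_sizes(self):
        ds = _dataset([(9, 9, 180.0, 180.0), (5, 0, 100.0, 100.0)])
        y, _ = refolding_yield(ds)
        assert y == pytest.approx(9 / 14)
        assert per_recording_yields(ds).mean() == pytest.approx(0.5)


class TestBootstrap:
    @staticmethod
    def _pooled(df):
        return df.steps_test.sum() / df.steps_initial.sum()

    def test_identical_recordings_have_zero_sem(self):
        ds = _dataset([(6, 3, 120.0, 120.0)] * 8)
        assert bootstrap_sem(ds, self._pooled, B=200, seed=0) == 0.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        ds = _dataset([(7, int(rng.integers(0, 8)), 140.0, 140.0)
                       for _ in range(30)])
        a = bootstrap_sem(ds, self._pooled, B=300, seed=5)
        assert a == bootstrap_sem(ds, self._pooled, B=300, seed=5)
        assert a != bootstrap_sem(ds, self._pooled, B=300, seed=6)

    def test_matches_binomial_se_on_binomial_data(self):
        """~300 domains with per-domain refolding probability p: bootstrap
        SEM within 25% of sqrt(p(1-p)/n)."""
        p, rng = 0.6, np.random.default_rng(13)
        rows = []
        for _ in range(50):  # 50 recordings x 6 domains = 300
            st = rng.binomial(6, p)
            rows.append((6, st, 120.0, 120.0))
        ds = _dataset(rows)
        n = 300
        sem = bootstrap_sem(ds, self._pooled, B=500, seed=2)
        analytic = np.sqrt(p * (1 - p) / n)
        assert sem == pytest.approx(analytic, rel=0.25)

    def test_sem_scales_with_inverse_sqrt_recordings(self):
        rng = np.random.default_rng(3)
        rows = [(6, int(rng.binomial(6, 0.5)), 120.0, 120.0)
                for _ in range(160)]
        small = _dataset(rows[:40])
        large = _dataset(rows)
        s_small = bootstrap_sem(small, self._pooled, B=400, seed=1)
        s_large = bootstrap_sem(large, self._pooled, B=400, seed=1)
        assert s_small / s_large == pytest.approx(2.0, rel=0.35)

    def test_too_few_resamples_rejected(self):
        ds = _dataset([(5, 2, 100.0, 100.0)] * 3)
        with pytest.raises(ValueError):
            bootstrap_sem(ds, self._pooled, B=1)


class TestFitYieldCurve:
    TQ_GRID = np.array([0.5, 1, 2, 5, 10, 15])
    TEXT_GRID = np.array([1, 2, 3, 5, 10, 15, 30], dtype=float)

    def test_noiseless_saturating_inversion(self):
        y = 0.75 * (1 - np.exp(-0.52 * self.TQ_GRID))
        fit = fit_yield_curve(self.TQ_GRID, y, form="saturating")
        assert fit.rate == pytest.approx(0.52, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.75, abs=1e-6)

    def test_noiseless_decaying_inversion(self):
        y = 0.10 + 0.55 * np.exp(-0.27 * self.TEXT_GRID)
        fit = fit_yield_curve(self.TEXT_GRID, y, form="decaying")
        assert fit.rate == pytest.approx(0.27, abs=1e-6)
        assert fit.offset == pytest.approx(0.10, abs=1e-6)

    def test_equal_weights_match_unweighted_estimates(self):
        rng = np.random.default_rng(4)
        y = 0.7 * (1 - np.exp(-0.5 * self.TQ_GRID)) + rng.normal(0, 0.02, 6)
        a = fit_yield_curve(self.TQ_GRID, y, np.full(6, 0.03), "saturating")
        b = fit_yield_curve(self.TQ_GRID, y, None, "saturating")
        assert a.rate == pytest.approx(b.rate, rel=1e-6)
        assert a.amplitude == pytest.approx(b.amplitude, rel=1e-6)

    def test_flat_data_reports_failure_not_nan(self):
        fit = fit_yield_curve(self.TQ_GRID, np.full(6, 0.4), form="saturating")
        assert not fit.success
        assert fit.rate is None

    def test_zero_sems_replaced_by_median(self):
        y = 0.75 * (1 - np.exp(-0.52 * self.TQ_GRID))
        sems = np.array([0.0, 0.02, 0.02, 0.02, 0.02, 0.02])
        fit = fit_yield_curve(self.TQ_GRID, y, sems, "saturating")
        assert fit.success and fit.rate == pytest.approx(0.52, abs=1e-4)


class TestPipelineConsistency:
    def test_detected_yield_equals_count_yield_without_noise(self, ubiquitin_scheme):
        """simulate -> detect -> yield reproduces the simulator's own
        count-based yield exactly at zero noise."""
        from chapfold import simulate_experiment
        proto = ForceProtocol.force_quench(unfold_s=6.0, t_q_s=5.0, test_s=6.0)
        cfg = SimulationConfig(seed=6, n_recordings=25, noise_sd_nm=0.0)
        ds, traces = simulate_experiment(ubiquitin_scheme, proto, cfg)
        for tr, (_, rec) in zip(traces, ds.records.iterrows()):
            ev = detect_steps(tr, expected_step_nm=20.0)
            n_init = sum(1 for lab in ev.pulse_labels if lab == "unfold")
            n_test = sum(1 for lab in ev.pulse_labels if lab == "test")
            assert n_init == rec.steps_initial
            assert n_test == rec.steps_test
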