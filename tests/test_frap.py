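"""FRAP quantification: correction, normalization, fitting, half-life and
fraction conventions, with generator round trips as the oracle."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import frapquant as fq
from frapquant.config import POSTBLEACH, PREBLEACH
from frapquant.errors import DataError
from frapquant.synthetic import ideal_frap_signal

from conftest import make_trace


def bisect_half_time(tau, lo=1e-12, hi=1e9, iters=200):
    """Independent oracle: solve exp(-tau*t) = 0.5 by bisection."""
    f = lambda t: math.exp(-tau * t) - 0.5
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestCorrectPhotofading:
    def test_constant_cell_signal_is_identity(self):
        tr = make_trace([-10, 0, 5, 15], [900, 200, 300, 400])
        out = fq.correct_photofading(tr)
        np.testing.assert_allclose(out.roi_values, tr.roi_values)

    def test_faded_trace_recovers_ideal_up_to_prebleach_fade_constant(self, noiseless_frap_config):
        # Correction references the prebleach-mean whole-cell signal, so the
        # corrected ROI equals the unfaded ideal times the (constant) mean
        # prebleach fade factor; the constant cancels at normalization.
        cfg = noiseless_frap_config
        traces, _ = fq.simulate_frap_traces(cfg)
        tr = traces[0]
        out = fq.correct_photofading(tr)
        ideal = ideal_frap_signal(cfg, tr.times, tr.phase)
        pre = tr.phase == PREBLEACH
        const = np.exp(-cfg.photofade_rate * (tr.times[pre] - tr.times[0])).mean()
        np.testing.assert_allclose(out.roi_values, ideal * const, rtol=1e-12)
        norm = fq.normalize_to_prebleach(out)
        np.testing.assert_allclose(norm.roi_values, 100.0 * ideal / cfg.prebleach_mean, rtol=1e-12)

    def test_nonpositive_cell_values_rejected(self):
        tr = make_trace([-10, 0, 5, 15], [900, 200, 300, 400], cell=[1000, 0, 900, 900])
        with pytest.raises(DataError, match="non-positive"):
            fq.correct_photofading(tr)

    def test_no_prebleach_frames_rejected(self):
        tr = make_trace([0, 5, 15, 30], [200, 300, 350, 400])
        with pytest.raises(DataError, match="prebleach"):
            fq.correct_photofading(tr)


class TestNormalizeToPrebleach:
    def test_percent_conversion(self):
        tr = make_trace([-20, -10, -5, 0], [200, 200, 200, 100])
        out = fq.normalize_to_prebleach(tr)
        assert out.roi_values[-1] == pytest.approx(50.0)

    @given(scale=st.floats(1e-3, 1e6), bleach=st.floats(0.01, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_prebleach_mean_is_100_for_any_valid_input(self, scale, bleach):
        roi = np.array([1.02, 0.98, 1.0, bleach, bleach + 0.01]) * scale
        tr = make_trace([-20, -10, -5, 0, 5], roi)
        out = fq.normalize_to_prebleach(tr)
        assert out.roi_values[:3].mean() == pytest.approx(100.0, rel=1e-12)

    def test_zero_prebleach_mean_rejected(self):
        tr = make_trace([-10, -5, -1, 0], [0, 0, 0, 10])
        with pytest.raises(DataError, match="positive"):
            fq.normalize_to_prebleach(tr)


class TestFitSingleExponential:
    def test_noiseless_fit_recovers_generator_truth_to_1e6(self):
        cfg = fq.SimFrapConfig(bleach_depth=0.2, mobile_fraction_true=0.625, tau_true=0.05)
        # plateau in percent: 20 + 0.625*80 = 70, post-bleach 20
        traces, _ = fq.simulate_frap_traces(cfg)
        fit = fq.fit_single_exponential(fq.normalize_to_prebleach(fq.correct_photofading(traces[0])))
        assert fit.converged
        assert fit.tau == pytest.approx(0.05, rel=1e-6)
        assert fit.plateau_pct == pytest.approx(70.0, rel=1e-6)
        assert fit.post_bleach_pct == pytest.approx(20.0, rel=1e-6)

    def test_flat_postbleach_trace_flagged_not_converged(self):
        times = [-20, -10, -5] + [0, 5, 15, 30, 45]
        roi = [100, 100, 100] + [40.0] * 5
        fit = fq.fit_single_exponential(make_trace(times, roi))
        assert not fit.converged
        assert abs(fit.plateau_pct - fit.post_bleach_pct) < 1e-3

    def test_mean_tau_over_noisy_traces_within_5pct(self):
        cfg = fq.SimFrapConfig(tau_true=0.05, mobile_fraction_true=0.5, noise_sd_frac=0.02,
                               photofade_rate=0.002, n_traces=12, seed=21)
        traces, _ = fq.simulate_frap_traces(cfg)
        taus = [fq.process_trace(t).tau for t in traces]
        assert np.mean(taus) == pytest.approx(0.05, rel=0.05)

    def test_too_few_postbleach_frames_rejected(self):
        tr = make_trace([-10, -5, -1, 0, 5], [100, 100, 100, 20, 30])
        with pytest.raises(DataError, match=">=3 postbleach"):
            fq.fit_single_exponential(tr)


class TestHalfLife:
    def test_log2_tau_gives_unit_half_life(self):
        assert fq.compute_half_life(math.log(2.0)) == pytest.approx(1.0, rel=1e-12)

    def test_doubling_tau_halves_half_life(self):
        assert fq.compute_half_life(0.1) == pytest.approx(2 * fq.compute_half_life(0.2), rel=1e-12)

    @pytest.mark.parametrize("tau", [1e-4, 1e-3, 0.0231049, 0.05, 0.5, 1.0, 10.0])
    def test_agrees_with_bisection_oracle(self, tau):
        assert fq.compute_half_life(tau) == pytest.approx(bisect_half_time(tau), rel=1e-9)

    def test_tau_0231049_is_30_seconds(self):
        # frozen from the bisection oracle: ln 2 / 0.0231049 = 30.0000...
        assert fq.compute_half_life(0.0231049) == pytest.approx(30.0, abs=1e-3)

    @given(st.floats(1e-4, 10.0), st.floats(1e-4, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_tau(self, a, b):
        if a == b:
            return
        lo, hi = min(a, b), max(a, b)
        assert fq.compute_half_life(hi) < fq.compute_half_life(lo)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(DataError):
            fq.compute_half_life(0.0)


class TestFractions:
    @pytest.mark.parametrize(
        "plateau,post,convention,mobile",
        [
            (60.0, 20.0, "full_scale", 50.0),
            (20.0, 20.0, "full_scale", 0.0),
            (100.0, 20.0, "full_scale", 100.0),
            (100.0, 20.0, "percent_of_prebleach", 100.0),
            (60.0, 20.0, "percent_of_prebleach", 60.0),
        ],
    )
    def test_conventions(self, plateau, post, convention, mobile):
        fit = fq.FrapFit(trace_id="x", tau=0.05, post_bleach_pct=post, plateau_pct=plateau,
                         rss=0.0, converged=True, n_points=10)
        m, im = fq.compute_fractions(fit, convention)
        assert m == pytest.approx(mobile)
        assert m + im == 100.0

    @given(st.floats(0.0, 99.0), st.floats(0.0, 150.0))
    @settings(max_examples=100, deadline=None)
    def test_immobile_is_exact_complement_of_mobile(self, post, plateau):
        fit = fq.FrapFit(trace_id="x", tau=0.05, post_bleach_pct=post, plateau_pct=plateau,
                         rss=0.0, converged=True, n_points=10)
        m, im = fq.compute_fractions(fit)
        assert im == 100.0 - m  # conservation: immobile is the exact complement
        assert m + im == pytest.approx(100.0, abs=1e-10)

    def test_unbleached_trace_rejected(self):
        fit = fq.FrapFit(trace_id="x", tau=0.05, post_bleach_pct=100.0, plateau_pct=110.0,
                         rss=0.0, converged=True, n_points=10)
        with pytest.raises(DataError, match="no bleach"):
            fq.compute_fractions(fit)


class TestAnalyzeExperiment:
    def test_identical_noiseless_traces_have_zero_sem(self):
        cfg = fq.SimFrapConfig(n_traces=12, mobile_fraction_true=0.5)
        traces, _ = fq.simulate_frap_traces(cfg)
        _, summaries = fq.analyze_frap_experiment(traces)
        s = summaries[0]
        assert s.n_cells == 12
        for metric in ("t_half", "mobile_pct", "immobile_pct"):
            assert s.metrics[metric]["sem"] == pytest.approx(0.0, abs=1e-9)

    def test_two_condition_experiment_recovers_truth(self):
        conds = {}
        all_traces = []
        for m, seed, label in [(0.5, 5, "low_mobility"), (0.9, 6, "high_mobility")]:
            cfg = fq.SimFrapConfig(mobile_fraction_true=m, noise_sd_frac=0.02,
                                   photofade_rate=0.002, n_traces=12, seed=seed)
            traces, _ = fq.simulate_frap_traces(cfg)
            for tr in traces:
                tr = fq.FrapTrace(trace_id=f"{label}_{tr.trace_id}", times=tr.times,
                                  roi_values=tr.roi_values, cell_values=tr.cell_values, phase=tr.phase)
                conds[tr.trace_id] = label
                all_traces.append(tr)
        fits, summaries = fq.analyze_frap_experiment(all_traces, conds)
        by_label = {s.condition: s for s in summaries}
        assert by_label["low_mobility"].metrics["mobile_pct"]["mean"] == pytest.approx(50.0, abs=3.0)
        assert by_label["high_mobility"].metrics["mobile_pct"]["mean"] == pytest.approx(90.0, abs=3.0)
        # t_half truth = ln2/0.05 = 13.86 s for both conditions
        assert by_label["low_mobility"].metrics["t_half"]["mean"] == pytest.approx(math.log(2) / 0.05, rel=0.10)

    def test_nonconverged_trace_reported_but_excluded_from_summary(self, caplog):
        cfg = fq.SimFrapConfig(n_traces=12, mobile_fraction_true=0.5, noise_sd_frac=0.01, seed=3)
        traces, _ = fq.simulate_frap_traces(cfg)
        flat = make_trace([-30, -20, -10] + [0, 5, 15, 30, 45],
                          [1000, 1000, 1000] + [200.0] * 5, trace_id="flat")
        with caplog.at_level(logging.WARNING, logger="frapquant.frap"):
            fits, summaries = fq.analyze_frap_experiment(traces + [flat])
        assert len(fits) == 13
        assert not fits.loc[fits.trace_id == "flat", "converged"].item()
        assert summaries[0].n_cells == 12
        assert not caplog.records  # 12 converged cells: no under-pooling warning
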