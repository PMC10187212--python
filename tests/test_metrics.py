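"""Behavioral metrics: cross-correlation, RMS measures, psychometric fit,
state-space summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cstcontrol.metrics import (
    SuccessTable,
    bin_success_rate,
    fit_psychometric,
    meanstate_correlation,
    psychometric_curve,
    rms_ratio,
    rms_slope,
    trial_summary,
    xcorr_peak_lag,
)
from cstcontrol.model import TaskConfig
from cstcontrol.simulate import Trial, TrialSet


def _trial(x, p=None, xdot=None, dt=0.01, lam=2.0, success=True):
    x = np.asarray(x, float)
    n = x.size
    p = np.zeros(n) if p is None else np.asarray(p, float)
    xdot = np.zeros(n) if xdot is None else np.asarray(xdot, float)
    return Trial(lam=lam, objective="position", t=np.arange(n) * dt, x=x,
                 xdot=xdot, p=p, pdot=np.zeros(n), u=np.zeros(n - 1),
                 success=success)


class TestXcorr:
    def test_antiphase_identity(self):
        rng = np.random.default_rng(0)
        cursor = rng.standard_normal(600)
        r, lag = xcorr_peak_lag(-cursor, cursor, dt=0.01)
        assert r == pytest.approx(-1.0)
        assert lag == 0.0

    def test_constructed_shift_recovered(self):
        """hand(t) = -cursor(t - 0.1): peak r ~ -1 at lag ~ +0.1 s."""
        t = np.arange(0, 6, 0.01)
        cursor = np.sin(2 * np.pi * t)
        hand = -np.sin(2 * np.pi * (t - 0.1))
        r, lag = xcorr_peak_lag(hand, cursor, dt=0.01)
        assert r == pytest.approx(-1.0, abs=1e-3)
        assert lag == pytest.approx(0.1, abs=0.011)

    def test_independent_noise_below_permutation_null(self):
        rng = np.random.default_rng(1)
        hand = rng.standard_normal(600)
        cursor = rng.standard_normal(600)
        r, _ = xcorr_peak_lag(hand, cursor, dt=0.01)
        null = []
        for _ in range(200):
            perm = rng.permutation(hand)
            rp, _ = xcorr_peak_lag(perm, cursor, dt=0.01)
            null.append(abs(rp))
        assert abs(r) < np.quantile(null, 0.99) * 1.5

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            xcorr_peak_lag(np.ones(100), np.arange(100.0), dt=0.01)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        cursor = np.cumsum(rng.standard_normal(600)) * 0.01
        hand = -cursor + 0.05 * rng.standard_normal(600)
        r1, l1 = xcorr_peak_lag(hand, cursor, dt=0.01)
        r2, l2 = xcorr_peak_lag(-hand, -cursor, dt=0.01)
        assert r1 == pytest.approx(r2) and l1 == l2


@given(scale=st.floats(0.05, 20.0), seed=st.integers(0, 2**16))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_metrics_scale_invariance(scale, seed):
    """Correlation, lag, and the RMS ratio are invariant under a common
    rescaling of hand and cursor (unit changes must not move them)."""
    rng = np.random.default_rng(seed)
    cursor = np.cumsum(rng.standard_normal(400)) * 0.01
    hand = -cursor + 0.05 * rng.standard_normal(400)
    r1, l1 = xcorr_peak_lag(hand, cursor, dt=0.01)
    r2, l2 = xcorr_peak_lag(scale * hand, scale * cursor, dt=0.01)
    assert r1 == pytest.approx(r2, rel=1e-9) and l1 == l2
    t1 = _trial(np.pad(cursor, (0, 401), mode="edge"),
                p=np.pad(hand, (0, 401), mode="edge"))
    t2 = _trial(scale * np.pad(cursor, (0, 401), mode="edge"),
                p=scale * np.pad(hand, (0, 401), mode="edge"))
    assert rms_ratio(t1) == pytest.approx(rms_ratio(t2), rel=1e-9)


class TestRmsRatio:
    def test_scaling(self):
        t = np.arange(0, 8.01, 0.01)
        x = np.sin(t)
        assert rms_ratio(_trial(x, p=2 * x)) == pytest.approx(2.0)
        assert rms_ratio(_trial(x, p=x)) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(801)
        p = rng.standard_normal(801)
        cfg = TaskConfig(lam=2.0)
        expected = np.sqrt(np.mean(p[:601] ** 2)) / np.sqrt(np.mean(x[:601] ** 2))
        assert rms_ratio(_trial(x, p=p), cfg) == pytest.approx(expected)

    def test_zero_cursor_rejected(self):
        with pytest.raises(ValueError, match="RMS"):
            rms_ratio(_trial(np.zeros(801), p=np.ones(801)))


class TestBinSuccessRate:
    def _set(self, lam_success):
        trials = [
            Trial(lam=lam, objective="o", t=np.zeros(2), x=np.zeros(2),
                  xdot=np.zeros(2), p=np.zeros(2), pdot=np.zeros(2),
                  u=np.zeros(1), success=s)
            for lam, s in lam_success
        ]
        return TrialSet(trials=trials)

    def test_all_successful(self):
        table = bin_success_rate(self._set([(1.6, True), (2.0, True), (3.1, True)]))
        assert np.all(table.rates == 100.0)

    def test_bin_placement(self):
        table = bin_success_rate(self._set([(1.6, True)]))
        assert table.bin_centers[0] == pytest.approx(1.65)

    def test_counting(self):
        table = bin_success_rate(
            self._set([(1.6, True), (1.6, True), (1.7, True), (1.6, False)])
        )
        assert table.rates[0] == pytest.approx(75.0)
        assert table.counts[0] == 4


class TestPsychometricFit:
    def test_noiseless_self_consistency(self):
        lam = np.arange(1.65, 7.0, 0.3)
        rates = psychometric_curve(lam, 4.0, 0.5)
        fit = fit_psychometric(SuccessTable(lam, rates, np.full(lam.size, 100)))
        assert fit.lam_c == pytest.approx(4.0, abs=1e-8)
        assert fit.sigma == pytest.approx(0.5, abs=1e-8)
        assert psychometric_curve(fit.lam_c, fit.lam_c, fit.sigma) == pytest.approx(50.0)

    def test_degenerate_rejected(self):
        lam = np.arange(1.65, 4.0, 0.3)
        high = np.full(lam.size, 98.0)
        with pytest.raises(ValueError, match="50"):
            fit_psychometric(SuccessTable(lam, high, np.full(lam.size, 100)))

    def test_bernoulli_recovery(self):
        """Parameter recovery from sampled success counts (small version of
        the full recovery study in the acceptance suite)."""
        rng = np.random.default_rng(4)
        lam = np.arange(1.65, 7.0, 0.3)
        p = psychometric_curve(lam, 3.5, 0.6) / 100.0
        ok = 0
        for _ in range(50):
            rates = 100.0 * rng.binomial(200, p) / 200.0
            fit = fit_psychometric(SuccessTable(lam, rates, np.full(lam.size, 200)))
            ok += abs(fit.lam_c - 3.5) <= 0.1
        assert ok >= 45


class TestTrialSummary:
    def test_constant_cursor(self):
        f = trial_summary(_trial(np.full(801, 3.0)), include_xcorr=False)
        assert f.mean_x == pytest.approx(3.0)
        assert f.rms_x == pytest.approx(3.0)
        assert f.mean_xdot == 0.0 and f.rms_xdot == 0.0

    def test_sine_closed_form(self):
        t = np.arange(0, 8.01, 0.01)
        x = np.sin(2 * np.pi * t)
        f = trial_summary(_trial(x), include_xcorr=False)
        assert f.mean_x == pytest.approx(0.0, abs=1e-2)
        assert f.rms_x == pytest.approx(1 / np.sqrt(2), abs=1e-2)
        assert f.rms_x >= abs(f.mean_x)


class TestStateSpaceSummaries:
    def _df(self, mean_x, mean_xdot, rms_x=None, rms_xdot=None):
        n = len(mean_x)
        return pd.DataFrame(
            {
                "mean_x": mean_x,
                "mean_xdot": mean_xdot,
                "rms_x": rms_x if rms_x is not None else np.abs(mean_x),
                "rms_xdot": rms_xdot if rms_xdot is not None else np.abs(mean_xdot),
                "success": True,
                "lam": 2.0,
            }
        )

    def test_collinear_points_give_unit_correlation(self):
        x = np.linspace(-1, 1, 20)
        assert meanstate_correlation(self._df(x, 2 * x)) == pytest.approx(1.0)

    def test_isotropic_cloud_uncorrelated(self):
        rng = np.random.default_rng(5)
        assert abs(
            meanstate_correlation(self._df(rng.standard_normal(500), rng.standard_normal(500)))
        ) < 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            meanstate_correlation(self._df([1.0, 2.0], [1.0, 2.0]))

    def test_exact_slope(self):
        x = np.linspace(0.1, 2.0, 10)
        df = self._df(x, x, rms_x=x, rms_xdot=3 * x)
        assert rms_slope(df) == pytest.approx(3.0)

    def test_two_points_exact_line(self):
        df = self._df([1.0, 2.0], [0, 0], rms_x=[1.0, 2.0], rms_xdot=[2.0, 5.0])
        assert rms_slope(df) == pytest.approx(3.0)

    def test_zero_variance_rejected(self):
        df = self._df([1.0] * 5, [0.0] * 5, rms_x=[1.0] * 5, rms_xdot=[1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="variance"):
            rms_slope(df)

    def test_through_origin_variant(self):
        x = np.array([1.0, 2.0, 3.0])
        df = self._df(x, x, rms_x=x, rms_xdot=2 * x + 0.0)
        assert rms_slope(df, through_origin=True) == pytest.approx(2.0)
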