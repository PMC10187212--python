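"""Per-trial and aggregate behavioral metrics for CST performance.

Four aggregate quantities characterize performance as a function of difficulty:
the λ-binned success rate (with a cumulative-Gaussian psychometric fit locating
the critical instability λ_c), the signed peak hand–cursor cross-correlation,
the lag at that peak, and the hand/cursor RMS ratio.  Two per-trial state-space
features support strategy inference: the trial means of cursor position and
velocity (drift signature) and their RMS values (movement-magnitude signature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .model import TaskConfig
from .simulate import Trial, TrialSet

__all__ = [
    "TrialFeatures",
    "SuccessTable",
    "PsychometricFit",
    "xcorr_peak_lag",
    "rms_ratio",
    "bin_success_rate",
    "fit_psychometric",
    "psychometric_curve",
    "trial_summary",
    "summarize_trials",
    "aggregate_by_lambda",
    "meanstate_correlation",
    "rms_slope",
]

BIN_WIDTH = 0.3
BIN_START = 1.5


@dataclass
class TrialFeatures:
    """Scalar features of one trial (computed over the analyzed window)."""

    r_peak: float
    lag_s: float
    rms_ratio: float
    mean_x: float
    mean_xdot: float
    rms_x: float
    rms_xdot: float
    lam: float = np.nan
    success: bool = False
    objective: str = "unknown"


@dataclass
class SuccessTable:
    """Success percentage per λ bin (half-open bins of width 0.3 from λ=1.5)."""

    bin_centers: np.ndarray
    rates: np.ndarray
    counts: np.ndarray


@dataclass
class PsychometricFit:
    """Cumulative-Gaussian psychometric fit: success crosses 50% at lam_c."""

    lam_c: float
    sigma: float
    rss: float
    n_bins: int


def xcorr_peak_lag(
    hand: np.ndarray,
    cursor: np.ndarray,
    dt: float,
    max_lag_s: float = 1.0,
) -> tuple[float, float]:
    """Signed peak normalized cross-correlation and the lag at the peak.

    At each integer lag within ±``max_lag_s`` the Pearson correlation of the
    overlapping (mean-subtracted) segments is computed; the peak is the lag
    maximizing |r|.  Positive lag means the hand lags the cursor.
    """
    hand = np.asarray(hand, float)
    cursor = np.asarray(cursor, float)
    if hand.shape != cursor.shape or hand.ndim != 1:
        raise ValueError("hand and cursor must be equal-length 1-D series")
    n = hand.size
    max_k = min(int(round(max_lag_s / dt)), n - 2)
    if np.ptp(hand) == 0 or np.ptp(cursor) == 0:
        raise ValueError("correlation undefined for a constant series")
    lags = np.arange(-max_k, max_k + 1)
    rs = np.zeros(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:  # hand delayed by k samples relative to cursor
            a, b = cursor[: n - k], hand[k:]
        else:
            a, b = cursor[-k:], hand[: n + k]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        rs[i] = np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb)
    peak = np.max(np.abs(rs))
    # among (numerically) tied peaks, prefer the smallest |lag|
    tied = np.flatnonzero(np.abs(rs) >= peak - 1e-12)
    best = tied[np.argmin(np.abs(lags[tied]))]
    return float(rs[best]), float(lags[best] * dt)


def rms_ratio(trial: Trial, config: TaskConfig | None = None) -> float:
    """RMS(hand position) / RMS(cursor position) over the analyzed window (raw,
    not mean-subtracted)."""
    sl = trial.analyzed_slice(config or TaskConfig(lam=trial.lam))
    x, p = trial.x[sl], trial.p[sl]
    rms_x = float(np.sqrt(np.mean(x**2)))
    if rms_x == 0:
        raise ValueError("cursor RMS is zero; ratio undefined")
    return float(np.sqrt(np.mean(p**2))) / rms_x


def bin_success_rate(tset: TrialSet) -> SuccessTable:
    """Success percentage per half-open λ bin [1.5, 1.8), [1.8, 2.1), ...

    Empty bins are omitted.
    """
    if len(tset) == 0:
        raise ValueError("empty trial set")
    lams = np.array([tr.lam for tr in tset])
    succ = np.array([tr.success for tr in tset], dtype=float)
    idx = np.floor((lams - BIN_START) / BIN_WIDTH + 1e-9).astype(int)
    centers, rates, counts = [], [], []
    for i in np.unique(idx):
        m = idx == i
        centers.append(BIN_START + (i + 0.5) * BIN_WIDTH)
        rates.append(100.0 * succ[m].mean())
        counts.append(int(m.sum()))
    return SuccessTable(
        bin_centers=np.array(centers), rates=np.array(rates), counts=np.array(counts)
    )


def psychometric_curve(lam, lam_c: float, sigma: float):
    """% success = 50 * [1 - erf((λ - λ_c) / (sqrt(2) σ))], i.e. 100·(1 - Φ)."""
    return 50.0 * (1.0 - special.erf((np.asarray(lam, float) - lam_c) / (np.sqrt(2.0) * sigma)))


def fit_psychometric(table: SuccessTable) -> PsychometricFit:
    """Weighted least-squares fit of the cumulative-Gaussian psychometric curve.

    Bins are weighted by trial count.  Requires at least three bins with rates
    on both sides of 50% (otherwise λ_c is not identifiable).
    """
    lam = np.asarray(table.bin_centers, float)
    rates = np.asarray(table.rates, float)
    counts = np.asarray(table.counts, float)
    if lam.size < 3:
        raise ValueError("need at least 3 bins to fit the psychometric curve")
    if rates.min() >= 50.0 or rates.max() <= 50.0:
        raise ValueError("success rates do not span 50%; lam_c not identifiable")
    # initial guess: linear interpolation of the 50% crossing
    above = np.flatnonzero(rates >= 50.0)
    lam_c0 = lam[above[-1]] if above.size else lam[lam.size // 2]
    popt, _ = optimize.curve_fit(
        psychometric_curve,
        lam,
        rates,
        p0=[lam_c0, 0.5],
        sigma=1.0 / np.sqrt(np.maximum(counts, 1.0)),
        absolute_sigma=False,
        maxfev=10000,
        bounds=([0.0, 1e-6], [np.inf, np.inf]),
    )
    lam_c, sigma = float(popt[0]), float(popt[1])
    rss = float(np.sum(counts * (rates - psychometric_curve(lam, lam_c, sigma)) ** 2))
    return PsychometricFit(lam_c=lam_c, sigma=sigma, rss=rss, n_bins=int(lam.size))


def trial_summary(
    trial: Trial,
    config: TaskConfig | None = None,
    max_lag_s: float = 1.0,
    include_xcorr: bool = True,
) -> TrialFeatures:
    """All per-trial features over the analyzed (first 6 s) window."""
    config = config or TaskConfig(lam=trial.lam)
    sl = trial.analyzed_slice(config)
    x, xdot, p = trial.x[sl], trial.xdot[sl], trial.p[sl]
    if include_xcorr:
        try:
            r_peak, lag_s = xcorr_peak_lag(p, x, config.dt, max_lag_s)
        except ValueError:
            r_peak, lag_s = np.nan, np.nan
    else:
        r_peak, lag_s = np.nan, np.nan
    rms_x = float(np.sqrt(np.mean(x**2)))
    ratio = float(np.sqrt(np.mean(p**2))) / rms_x if rms_x > 0 else np.nan
    return TrialFeatures(
        r_peak=r_peak,
        lag_s=lag_s,
        rms_ratio=ratio,
        mean_x=float(np.mean(x)),
        mean_xdot=float(np.mean(xdot)),
        rms_x=rms_x,
        rms_xdot=float(np.sqrt(np.mean(xdot**2))),
        lam=trial.lam,
        success=trial.success,
        objective=trial.objective,
    )


def summarize_trials(
    tset: TrialSet,
    config: TaskConfig | None = None,
    max_lag_s: float = 1.0,
    include_xcorr: bool = True,
) -> pd.DataFrame:
    """One TrialFeatures row per trial (``include_xcorr=False`` skips the
    cross-correlation scan when only state-space features are needed)."""
    rows = [
        trial_summary(tr, config, max_lag_s, include_xcorr).__dict__ for tr in tset
    ]
    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", np.arange(len(df)))
    return df


def aggregate_by_lambda(df: pd.DataFrame) -> pd.DataFrame:
    """Per-λ-bin averages of the four aggregate metrics (success rate, peak
    correlation, lag, RMS ratio) in the style of difficulty-curve summaries."""
    idx = np.floor((df["lam"].to_numpy() - BIN_START) / BIN_WIDTH + 1e-9).astype(int)
    g = df.assign(_bin=idx).groupby("_bin")
    out = g.agg(
        lam_center=("lam", lambda s: BIN_START + (np.floor((s.iloc[0] - BIN_START) / BIN_WIDTH + 1e-9) + 0.5) * BIN_WIDTH),
        success_rate=("success", lambda s: 100.0 * s.mean()),
        r_peak=("r_peak", "mean"),
        lag_s=("lag_s", "mean"),
        rms_ratio=("rms_ratio", "mean"),
        n=("success", "size"),
    )
    return out.reset_index(drop=True)


def _qualifying(df: pd.DataFrame, success_only: bool, lam_max: float | None) -> pd.DataFrame:
    q = df
    if success_only:
        q = q[q["success"]]
    if lam_max is not None:
        q = q[q["lam"] <= lam_max]
    return q


def meanstate_correlation(
    df: pd.DataFrame, success_only: bool = True, lam_max: float | None = None
) -> float:
    """Pearson correlation of per-trial mean cursor position vs mean velocity,
    over qualifying trials (successful, λ up to the critical value)."""
    q = _qualifying(df, success_only, lam_max)
    if len(q) < 3:
        raise ValueError("need at least 3 qualifying trials")
    r, _ = stats.pearsonr(q["mean_x"], q["mean_xdot"])
    return float(r)


def rms_slope(
    df: pd.DataFrame,
    success_only: bool = True,
    lam_max: float | None = None,
    through_origin: bool = False,
) -> float:
    """OLS slope of RMS cursor velocity on RMS cursor position across
    qualifying trials (intercept included unless ``through_origin``)."""
    q = _qualifying(df, success_only, lam_max)
    if len(q) < 2:
        raise ValueError("need at least 2 qualifying trials")
    x = q["rms_x"].to_numpy()
    y = q["rms_xdot"].to_numpy()
    if through_origin:
        den = float(np.dot(x, x))
        if den == 0:
            raise ValueError("zero variance in rms_x")
        return float(np.dot(x, y) / den)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in rms_x")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
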