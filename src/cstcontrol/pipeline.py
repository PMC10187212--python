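"""End-to-end experiment: simulate -> metrics -> classifier -> confusion rates.

The protocol mirrors the simulation study: for each control objective, batches
of trials are generated over the λ grid (1.5 to 6.9 in steps of 0.2); the
λ-binned success curve is fitted with the cumulative-Gaussian psychometric
function to locate λ_c; successful trials with λ up to λ_c enter the RMS-space
feature pool; a linear SVM with Platt calibration is trained on a fixed number
of trials per class and evaluated on trials from an independent random stream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import (
    StrategyClassifier,
    confusion_rates,
    select_training_features,
    train_classifier,
)
from .metrics import (
    aggregate_by_lambda,
    bin_success_rate,
    fit_psychometric,
    meanstate_correlation,
    rms_slope,
    summarize_trials,
)
from .model import NoiseSpec, PlantParams, TaskConfig
from .simulate import TrialSet, default_lam_grid, run_batch
from .solver import GainCache

__all__ = ["run_strategy_experiment", "reproduce_targets", "OBJECTIVES"]

OBJECTIVES = ("position", "velocity")
TRAIN_STREAM, TEST_STREAM = 0, 1


def run_strategy_experiment(
    base_seed: int = 0,
    n_per_lam: int = 500,
    n_train: int = 2250,
    n_test: int = 2500,
    lam_grid: np.ndarray | None = None,
    task: TaskConfig | None = None,
    plant: PlantParams | None = None,
    noise: NoiseSpec | None = None,
    weight: float = 1e4,
    U: float = 10.0,
    delay_steps: int = 5,
    gain_cache: GainCache | None = None,
    compute_xcorr: bool = False,
    keep_trials: bool = False,
) -> dict:
    """Run the full strategy-inference experiment and return its artifacts.

    Returns a dict with, per objective: the fitted λ_c and σ, the training and
    test feature tables, plus the trained classifier and both cross-class
    misclassification percentages.  ``compute_xcorr`` additionally fills the
    correlation/lag features (needed for difficulty-curve summaries but not for
    classification).
    """
    lam_grid = default_lam_grid() if lam_grid is None else np.asarray(lam_grid, float)
    gain_cache = gain_cache or GainCache()
    out: dict = {"objectives": {}, "base_seed": int(base_seed)}
    train_pool = []
    test_pool = []
    for objective in OBJECTIVES:
        batches = {}
        for stream, n_lam in ((TRAIN_STREAM, n_per_lam), (TEST_STREAM, n_per_lam)):
            batches[stream] = run_batch(
                objective,
                lam_grid=lam_grid,
                n_per_lam=n_lam,
                base_seed=base_seed,
                task=task,
                plant=plant,
                noise=noise,
                weight=weight,
                U=U,
                delay_steps=delay_steps,
                stream=stream,
                gain_cache=gain_cache,
            )
        feats_train = summarize_trials(batches[TRAIN_STREAM], include_xcorr=compute_xcorr)
        feats_test = summarize_trials(batches[TEST_STREAM], include_xcorr=False)
        fit = fit_psychometric(bin_success_rate(batches[TRAIN_STREAM]))
        train_sel = select_training_features(
            feats_train, fit.lam_c, n_train, seed=base_seed + 101
        )
        test_sel = select_training_features(
            feats_test, fit.lam_c, n_test, seed=base_seed + 202
        )
        train_pool.append(train_sel)
        test_pool.append(test_sel)
        entry = {
            "lam_c": fit.lam_c,
            "sigma": fit.sigma,
            "features_train": feats_train,
            "features_test": feats_test,
        }
        if keep_trials:
            entry["train_batch"] = batches[TRAIN_STREAM]
            entry["test_batch"] = batches[TEST_STREAM]
        out["objectives"][objective] = entry

    train_df = pd.concat(train_pool, ignore_index=True)
    test_df = pd.concat(test_pool, ignore_index=True)
    model = train_classifier(train_df, seed=base_seed)
    pos_as_vel, vel_as_pos = confusion_rates(model, test_df)
    out.update(
        model=model,
        train_features=train_df,
        test_features=test_df,
        pos_as_vel_pct=pos_as_vel,
        vel_as_pos_pct=vel_as_pos,
    )
    return out


def reproduce_targets(
    base_seed: int = 0,
    n_per_lam: int = 500,
    n_train: int = 2250,
    n_test: int = 2500,
    **kwargs,
) -> dict:
    """Full pipeline at configured scale; emits a JSON-serializable report.

    The report carries both confusion rates, per-objective λ_c/σ, the
    difficulty-curve metric tables (success rate, peak correlation, lag, RMS
    ratio per λ bin), the mean-state correlations, and the RMS-space regression
    slopes, each alongside the qualitative expectation for the two objectives.
    """
    res = run_strategy_experiment(
        base_seed=base_seed,
        n_per_lam=n_per_lam,
        n_train=n_train,
        n_test=n_test,
        compute_xcorr=True,
        **kwargs,
    )
    report: dict = {
        "base_seed": int(base_seed),
        "n_per_lam": int(n_per_lam),
        "confusion": {
            "position_as_velocity_pct": res["pos_as_vel_pct"],
            "velocity_as_position_pct": res["vel_as_pos_pct"],
        },
        "objectives": {},
        "expectations": {
            "lag": "position >= velocity in most bins",
            "rms_ratio": "position >= velocity in most bins",
            "meanstate_r": "velocity > position",
            "rms_slope": "position > velocity",
            "success_rate": "non-increasing in lambda",
            "r_peak": "|r| increasing in lambda, toward -1",
        },
    }
    for objective, entry in res["objectives"].items():
        feats = entry["features_train"]
        lam_c = entry["lam_c"]
        table = aggregate_by_lambda(feats)
        report["objectives"][objective] = {
            "lam_c": lam_c,
            "sigma": entry["sigma"],
            "metric_table": table.to_dict(orient="list"),
            "meanstate_r": meanstate_correlation(feats, lam_max=lam_c),
            "rms_slope": rms_slope(feats, lam_max=lam_c),
        }
    return report
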