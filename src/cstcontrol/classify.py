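"""Inference of the control objective from RMS-space features.

A linear-kernel support vector machine is trained on simulated trials
represented by their (RMS cursor position, RMS cursor velocity) pair — the
plane in which Position Control and Velocity Control separate along a slope
threshold.  Features are standardized before fitting and the decision values
are calibrated to posterior probabilities (Platt scaling).  A trial with
posterior P(position) >= 0.95 is labeled Position Control, < 0.05 Velocity
Control, and anything in between Uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FEATURES",
    "P_UPPER",
    "P_LOWER",
    "StrategyClassifier",
    "TrialLabel",
    "train_classifier",
    "classify_trial",
    "classify_trials",
    "subject_probability",
    "confusion_rates",
    "select_training_features",
]

FEATURES = ("rms_x", "rms_xdot")
P_UPPER = 0.95  # >= : Position Control
P_LOWER = 0.05  # <  : Velocity Control
CLASSES = ("position", "velocity")


@dataclass
class TrialLabel:
    """Posterior probability of Position Control and the three-way label."""

    p_pos: float
    label: str


@dataclass(eq=False)
class StrategyClassifier:
    """Standardizer + linear SVM + Platt posterior calibration, with training
    provenance."""

    pipeline: Pipeline
    provenance: dict = field(default_factory=dict)

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """P(position) for an (n, 2) array of (rms_x, rms_xdot) features."""
        X = np.atleast_2d(np.asarray(X, float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        proba = self.pipeline.predict_proba(X)
        i_pos = list(self.pipeline.classes_).index("position")
        return proba[:, i_pos]

    @property
    def boundary_normal(self) -> np.ndarray:
        """Normal of the linear decision boundary in standardized feature space
        (points toward the side the raw SVM scores positively)."""
        calibrated = self.pipeline.named_steps["svm"]
        return calibrated.calibrated_classifiers_[0].estimator.coef_[0].copy()


def _feature_matrix(df: pd.DataFrame) -> np.ndarray:
    return df.loc[:, list(FEATURES)].to_numpy(dtype=float)


def train_classifier(features: pd.DataFrame, seed: int = 0) -> StrategyClassifier:
    """Fit the strategy classifier on labeled trial features.

    ``features`` needs columns ``rms_x``, ``rms_xdot`` and ``objective``
    (both classes present).  Deterministic given ``seed`` (the Platt
    calibration uses internal cross-validation).
    """
    present = set(features["objective"].unique())
    if not set(CLASSES) <= present:
        raise ValueError(f"training set must contain both classes, got {sorted(present)}")
    X = _feature_matrix(features)
    y = features["objective"].to_numpy()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    calibrated = CalibratedClassifierCV(
        SVC(kernel="linear", random_state=seed),
        method="sigmoid",  # Platt scaling on cross-validated decision values
        cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
        ensemble=False,
    )
    pipe = Pipeline([("scale", StandardScaler()), ("svm", calibrated)])
    pipe.fit(X, y)
    provenance = {
        "n_per_class": {c: int((y == c).sum()) for c in CLASSES},
        "lam_range": [float(features["lam"].min()), float(features["lam"].max())]
        if "lam" in features
        else None,
        "seed": int(seed),
        "features": list(FEATURES),
    }
    return StrategyClassifier(pipeline=pipe, provenance=provenance)


def _label(p_pos: float) -> str:
    if p_pos >= P_UPPER:
        return "position"
    if p_pos < P_LOWER:
        return "velocity"
    return "uncertain"


def classify_trial(model: StrategyClassifier, features) -> TrialLabel:
    """Posterior and three-way label for one trial.

    ``features`` may be a TrialFeatures-like object (attributes rms_x,
    rms_xdot), a mapping, or a length-2 array.
    """
    if hasattr(features, "rms_x"):
        X = np.array([[features.rms_x, features.rms_xdot]], float)
    elif isinstance(features, dict):
        X = np.array([[features["rms_x"], features["rms_xdot"]]], float)
    else:
        X = np.atleast_2d(np.asarray(features, float))
    p = float(model.posterior(X)[0])
    return TrialLabel(p_pos=p, label=_label(p))


def classify_trials(model: StrategyClassifier, df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification: adds ``p_pos`` and ``label`` columns."""
    p = model.posterior(_feature_matrix(df))
    out = df.copy()
    out["p_pos"] = p
    out["label"] = [_label(v) for v in p]
    return out


def subject_probability(labels) -> float:
    """Mean P(position) across all of a subject's trials (uncertain included)."""
    if isinstance(labels, pd.DataFrame):
        p = labels["p_pos"].to_numpy(dtype=float)
    else:
        p = np.array([lab.p_pos for lab in labels], dtype=float)
    if p.size == 0:
        raise ValueError("no trials to average")
    return float(p.mean())


def confusion_rates(model: StrategyClassifier, test: pd.DataFrame) -> tuple[float, float]:
    """Cross-class misclassification percentages on a labeled test set.

    Returns ``(position->velocity %, velocity->position %)``: the fraction of
    position-generated trials labeled velocity (p_pos < 0.05) and of
    velocity-generated trials labeled position (p_pos >= 0.95).  Uncertain
    trials count in the denominators only.
    """
    present = set(test["objective"].unique())
    if not set(CLASSES) <= present:
        raise ValueError(f"test set must contain both classes, got {sorted(present)}")
    labeled = classify_trials(model, test)
    pos = labeled[labeled["objective"] == "position"]
    vel = labeled[labeled["objective"] == "velocity"]
    pos_as_vel = 100.0 * float((pos["p_pos"] < P_LOWER).mean())
    vel_as_pos = 100.0 * float((vel["p_pos"] >= P_UPPER).mean())
    return pos_as_vel, vel_as_pos


def select_training_features(
    df: pd.DataFrame,
    lam_c: float,
    n_trials: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ``n_trials`` successful trials with λ up to ``lam_c`` (the
    figure-style inclusion rule) from one objective's feature table."""
    q = df[(df["success"]) & (df["lam"] <= lam_c)]
    if len(q) < n_trials:
        raise ValueError(
            f"only {len(q)} qualifying trials available, need {n_trials}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(q), size=n_trials, replace=False)
    return q.iloc[np.sort(idx)]
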