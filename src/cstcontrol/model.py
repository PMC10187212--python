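"""State-space model of the hand–muscle–cursor system in the Critical Stability Task.

The CST couples a first-order unstable cursor, ``xdot = lam * (x + p)``, to the
lateral hand position ``p``.  The hand is a point mass driven through a
muscle-like first-order low-pass actuator, ``tau * Fdot = -F + u`` and
``pddot = F / M``.  Differentiating the cursor law once brings the cursor
velocity into the state vector, giving the five-state linear system

    state = [x, xdot, p, pdot, F]

whose continuous dynamics matrix is assembled by :func:`build_continuous_system`
and discretized (forward Euler, ``Ad = I + dt*A``) by :func:`discretize`.
Sensory delay is represented by state augmentation: stacked copies of the five
physical states, one per delay step, with the observation reading the oldest
copy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STATE_LABELS",
    "N_PHYSICAL",
    "TaskConfig",
    "PlantParams",
    "NoiseSpec",
    "ContinuousSystem",
    "DiscreteSystem",
    "build_continuous_system",
    "discretize",
    "cursor_from_hand",
    "read_hand_traces",
    "resample_series",
    "system_to_json",
    "system_from_json",
]

STATE_LABELS = ("x", "xdot", "p", "pdot", "F")
N_PHYSICAL = 5


@dataclass(frozen=True)
class TaskConfig:
    """Task constants: difficulty, workspace and timing.

    Parameters
    ----------
    lam : float
        Instability gain λ of the cursor dynamics (1/s). Larger is harder.
    c : float
        Workspace half-width in cm; the trial fails when ``|x| > c``.
    trial_duration : float
        Analyzed duration in s (success window).
    sim_duration : float
        Simulated horizon in s (the controller plans over this horizon).
    dt : float
        Integration/control step in s.
    """

    lam: float
    c: float = 10.0
    trial_duration: float = 6.0
    sim_duration: float = 8.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not 0 < self.trial_duration <= self.sim_duration:
            raise ValueError(
                "need 0 < trial_duration <= sim_duration, got "
                f"{self.trial_duration} / {self.sim_duration}"
            )

    @property
    def n_steps(self) -> int:
        """Number of control steps over the simulated horizon."""
        return int(round(self.sim_duration / self.dt))

    @property
    def n_analyzed(self) -> int:
        """Number of samples inside the analyzed (success) window, inclusive of t=0."""
        return int(round(self.trial_duration / self.dt)) + 1


@dataclass(frozen=True)
class PlantParams:
    """Hand mass M (kg) and muscle low-pass time constant tau (s)."""

    M: float = 1.0
    tau: float = 0.06

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError(f"M must be positive, got {self.M}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model of the discrete dynamics.

    ``C`` scales the multiplicative (signal-dependent) motor noise: the control
    enters the plant as ``u * (1 + C * eps)`` with ``eps ~ N(0, 1)``.
    ``motor_scale`` sets the additive motor noise covariance
    ``Sigma = motor_scale * Bd @ Bd.T``.  ``sensory_sd`` is the standard
    deviation of the additive observation noise per channel.
    """

    C: float = 1.5
    motor_scale: float = 0.4
    sensory_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 0 or self.motor_scale < 0 or self.sensory_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass(eq=False)
class ContinuousSystem:
    """Continuous-time plant ``xdot = A x + B u`` for the five physical states."""

    A: np.ndarray
    B: np.ndarray
    lam: float
    plant: PlantParams
    state_labels: tuple = STATE_LABELS


@dataclass(eq=False)
class DiscreteSystem:
    """Discrete (optionally delay-augmented) plant.

    ``Ad``/``Bd`` act on the augmented state of ``n_states = 5*(delay_steps+1)``
    entries: the newest copy of the physical states occupies the first five
    slots and each transition shifts copies one step older.  ``H`` reads the
    oldest copy, so the observation is ``delay_steps`` steps stale.
    """

    Ad: np.ndarray
    Bd: np.ndarray
    H: np.ndarray
    delay_steps: int
    n_states: int
    dt: float
    lam: float
    plant: PlantParams


def build_continuous_system(lam: float, plant: PlantParams | None = None) -> ContinuousSystem:
    """Assemble the continuous five-state dynamics for difficulty ``lam``.

    Rows: cursor position, cursor velocity (``xddot = lam^2 x + lam^2 p +
    lam pdot``), hand position, hand velocity (``pddot = F/M``) and actuator
    force (``Fdot = (-F + u)/tau``).
    """
    plant = plant or PlantParams()
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam}")
    A = np.array(
        [
            [0.0, 1.0, 0.0, 0.0, 0.0],
            [lam**2, 0.0, lam**2, lam, 0.0],
            [0.0, 0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.0 / plant.M],
            [0.0, 0.0, 0.0, 0.0, -1.0 / plant.tau],
        ]
    )
    B = np.array([[0.0], [0.0], [0.0], [0.0], [1.0 / plant.tau]])
    return ContinuousSystem(A=A, B=B, lam=lam, plant=plant)


def discretize(sys: ContinuousSystem, dt: float, delay_steps: int = 5) -> DiscreteSystem:
    """Forward-Euler discretization ``Ad = I + dt*A``, ``Bd = dt*B``, with
    optional sensory-delay augmentation.

    With ``delay_steps = d > 0`` the augmented state stacks d+1 copies of the
    physical states (newest first); the observation matrix selects the oldest.
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if delay_steps < 0:
        raise ValueError(f"delay_steps must be >= 0, got {delay_steps}")
    n = N_PHYSICAL
    Ad0 = np.eye(n) + dt * sys.A
    Bd0 = dt * sys.B
    if delay_steps == 0:
        return DiscreteSystem(
            Ad=Ad0, Bd=Bd0, H=np.eye(n), delay_steps=0, n_states=n,
            dt=dt, lam=sys.lam, plant=sys.plant,
        )
    k = delay_steps + 1
    nx = n * k
    Ad = np.zeros((nx, nx))
    Ad[:n, :n] = Ad0
    for i in range(1, k):  # copy i becomes last step's copy i-1
        Ad[i * n : (i + 1) * n, (i - 1) * n : i * n] = np.eye(n)
    Bd = np.zeros((nx, 1))
    Bd[:n] = Bd0
    H = np.zeros((n, nx))
    H[:, delay_steps * n :] = np.eye(n)
    return DiscreteSystem(
        Ad=Ad, Bd=Bd, H=H, delay_steps=delay_steps, n_states=nx,
        dt=dt, lam=sys.lam, plant=sys.plant,
    )


def cursor_from_hand(
    hand: np.ndarray,
    lam: float,
    dt: float,
    x0: float = 0.0,
    scheme: str = "euler",
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct cursor position and velocity from a hand-position series.

    Integrates ``xdot = lam * (x + p)`` from ``x0`` over a uniformly sampled
    hand trace ``p`` (cm).  Two schemes:

    - ``"euler"`` (default): forward Euler at ``dt``, the same update the
      simulator uses, so reconstruction of simulated trials round-trips exactly;
    - ``"exact"``: exact integration of the linear ODE assuming ``p`` is held
      constant over each step (zero-order hold), preferable for external
      recordings.

    Returns ``(x, xdot)`` with ``xdot = lam * (x + p)`` evaluated pointwise.
    """
    hand = np.asarray(hand, dtype=float)
    if hand.ndim != 1 or hand.size < 2:
        raise ValueError("hand must be a 1-D series with at least 2 samples")
    bad = np.flatnonzero(~np.isfinite(hand))
    if bad.size:
        raise ValueError(f"non-finite hand sample at index {bad[0]}")
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    x = np.empty_like(hand)
    x[0] = x0
    if scheme == "euler":
        g = lam * dt
        for k in range(hand.size - 1):
            x[k + 1] = x[k] + g * (x[k] + hand[k])
    elif scheme == "exact":
        e = np.exp(lam * dt)
        for k in range(hand.size - 1):
            x[k + 1] = e * (x[k] + hand[k]) - hand[k]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    xdot = lam * (x + hand)
    return x, xdot


def resample_series(t: np.ndarray, values: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample an (irregular or differently sampled) series to step ``dt``."""
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size != values.size:
        raise ValueError("t and values must be 1-D and equal length")
    t_new = np.arange(t[0], t[-1] + 1e-12, dt)  # never extrapolate past the data
    return t_new, np.interp(t_new, t, values)


def read_hand_traces(path, dt: float | None = None) -> pd.DataFrame:
    """Read recorded hand traces from a delimited text table.

    Requires columns ``time_s`` and ``hand_cm``; ``trial_id`` and ``lambda``
    are optional.  If ``dt`` is given, each trial is linearly resampled to that
    step.  Returns a tidy frame with columns ``trial_id, time_s, hand_cm`` and,
    when present in the input, ``lambda``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"time_s", "hand_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"hand-trace table missing required columns: {sorted(missing)}")
    if "trial_id" not in df.columns:
        df = df.assign(trial_id=0)
    if dt is None:
        return df
    out = []
    for tid, g in df.groupby("trial_id", sort=True):
        t_new, p_new = resample_series(g["time_s"].to_numpy(), g["hand_cm"].to_numpy(), dt)
        rec = pd.DataFrame({"trial_id": tid, "time_s": t_new, "hand_cm": p_new})
        if "lambda" in g.columns:
            rec["lambda"] = g["lambda"].iloc[0]
        out.append(rec)
    return pd.concat(out, ignore_index=True)


def system_to_json(sys: DiscreteSystem) -> str:
    """Serialize a discrete system description to a JSON document."""
    doc = {
        "Ad": sys.Ad.tolist(),
        "Bd": sys.Bd.tolist(),
        "H": sys.H.tolist(),
        "delay_steps": sys.delay_steps,
        "n_states": sys.n_states,
        "dt": sys.dt,
        "lam": sys.lam,
        "plant": asdict(sys.plant),
    }
    return json.dumps(doc)


def system_from_json(doc: str) -> DiscreteSystem:
    """Inverse of :func:`system_to_json`."""
    d = json.loads(doc)
    return DiscreteSystem(
        Ad=np.asarray(d["Ad"], dtype=float),
        Bd=np.asarray(d["Bd"], dtype=float),
        H=np.asarray(d["H"], dtype=float),
        delay_steps=int(d["delay_steps"]),
        n_states=int(d["n_states"]),
        dt=float(d["dt"]),
        lam=float(d["lam"]),
        plant=PlantParams(**d["plant"]),
    )
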