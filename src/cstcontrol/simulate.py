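"""Synthetic CST trial generation under an optimal feedback controller.

A trial forward-simulates the delay-augmented plant with signal-dependent and
additive motor noise, feeds the (delayed, noisy) observation to the state
estimator, and applies the time-varying control law.  Success is decided
post hoc: a trial fails iff the cursor leaves the workspace (|x| > c) within
the analyzed window.

Per-trial randomness is counter-based: each trial draws from
``SeedSequence(base_seed, spawn_key=(stream, lam_index, trial_index))`` so
batches are reproducible and order-independent, and different ``stream``
values give provably disjoint train/test sets.

Units: the plant is simulated in SI units (m, m/s, N) — the scale on which the
noise magnitudes (motor covariance 0.4*Bd@Bd.T, signal-dependent scalar 1.5)
and effort weight are defined — and trial kinematics are reported in cm
against the +/-10 cm workspace.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    DiscreteSystem,
    N_PHYSICAL,
    NoiseSpec,
    PlantParams,
    TaskConfig,
    build_continuous_system,
    discretize,
)
from ._version import __version__
from .solver import CostSpec, GainCache, GainSchedule, make_objective

__all__ = [
    "Trial",
    "TrialSet",
    "FORMAT_VERSION",
    "default_lam_grid",
    "simulate_trial",
    "evaluate_success",
    "run_batch",
    "export_trials",
    "import_trials",
    "trials_from_hand_traces",
]

FORMAT_VERSION = 1

M_TO_CM = 100.0  # plant simulated in meters; trials reported in cm


def default_lam_grid() -> np.ndarray:
    """Difficulty grid 1.5, 1.7, ..., 6.9 (28 levels)."""
    return np.round(np.arange(1.5, 7.0, 0.2), 10)


@dataclass(eq=False)
class Trial:
    """One simulated (or reconstructed) trial of hand/cursor kinematics."""

    lam: float
    objective: str
    t: np.ndarray
    x: np.ndarray
    xdot: np.ndarray
    p: np.ndarray
    pdot: np.ndarray
    u: np.ndarray
    success: bool
    seed: tuple = ()

    def analyzed_slice(self, config: TaskConfig) -> slice:
        return slice(0, min(config.n_analyzed, self.t.size))


@dataclass(eq=False)
class TrialSet:
    """A collection of trials plus the provenance needed to regenerate them."""

    trials: list
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def evaluate_success(trial: Trial, config: TaskConfig) -> bool:
    """Failure iff |x| exceeds the workspace half-width within the analyzed
    window (excursions after ``trial_duration`` are ignored).  A trial whose
    series end (divergence truncation) before the analyzed window is a failure.
    """
    n_needed = config.n_analyzed
    if trial.x.size < n_needed:
        return False
    xa = trial.x[:n_needed]
    if not np.all(np.isfinite(xa)):
        return False
    return bool(np.all(np.abs(xa) <= config.c))


def _initial_state(sys: DiscreteSystem, lam: float, x_offset_cm: float) -> np.ndarray:
    """Augmented initial state: all delayed copies at the same physical state.
    A nonzero cursor offset (given in cm, stored in plant units) initializes
    xdot = lam*(x + p) so the cursor law holds at t = 0."""
    phys = np.zeros(N_PHYSICAL)
    if x_offset_cm:
        phys[0] = x_offset_cm / M_TO_CM
        phys[1] = lam * x_offset_cm / M_TO_CM
    k = sys.n_states // N_PHYSICAL
    return np.tile(phys, k)


def _simulate_level(
    sys: DiscreteSystem,
    gains: GainSchedule,
    noise: NoiseSpec,
    config: TaskConfig,
    seed_keys: list,
    base_seed: int,
    x_offsets: np.ndarray,
) -> list:
    """Vectorized forward simulation of many trials at one difficulty level."""
    A, B, H = sys.Ad, sys.Bd, sys.H
    n = config.n_steps
    n_tr = len(seed_keys)
    ny = H.shape[0]
    sd_motor = np.sqrt(noise.motor_scale)

    # Per-trial noise streams (counter-based, order-independent).
    eps = np.empty((n_tr, n))
    eta = np.empty((n_tr, n))
    omega = np.empty((n_tr, n, ny))
    for i, key in enumerate(seed_keys):
        rng = np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=key))
        eps[i] = rng.standard_normal(n)
        eta[i] = rng.standard_normal(n)
        omega[i] = noise.sensory_sd * rng.standard_normal((n, ny))

    z = np.tile(_initial_state(sys, sys.lam, 0.0), (n_tr, 1))
    if np.any(x_offsets):
        for i, off in enumerate(x_offsets):
            z[i] = _initial_state(sys, sys.lam, off)
    xh = z.copy()  # estimator initialized at the true initial state

    phys = np.empty((n_tr, n + 1, N_PHYSICAL))
    uu = np.empty((n_tr, n))
    phys[:, 0] = z[:, :N_PHYSICAL]
    Bv = B[:, 0]
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(n):
            L = gains.L[t]
            K = gains.K[t]
            u = -(xh @ L[0])  # (n_tr,)
            y = z @ H.T + omega[:, t]
            innov = y - xh @ H.T
            xh = xh @ (A - B @ L).T + innov @ K.T
            u_exec = u * (1.0 + noise.C * eps[:, t]) + sd_motor * eta[:, t]
            z = z @ A.T + u_exec[:, None] * Bv[None, :]
            phys[:, t + 1] = z[:, :N_PHYSICAL]
            uu[:, t] = u

    t_vec = np.arange(n + 1) * config.dt
    phys[:, :, :4] *= M_TO_CM  # report kinematics in cm (force/control stay SI)
    trials = []
    for i, key in enumerate(seed_keys):
        xi = phys[i, :, 0]
        finite = np.isfinite(xi)
        if finite.all():
            end = n + 1
        else:
            end = int(np.argmin(finite))  # truncate at first non-finite step
        tr = Trial(
            lam=sys.lam,
            objective="unknown",
            t=t_vec[:end],
            x=phys[i, :end, 0].copy(),
            xdot=phys[i, :end, 1].copy(),
            p=phys[i, :end, 2].copy(),
            pdot=phys[i, :end, 3].copy(),
            u=uu[i, : max(end - 1, 0)].copy(),
            success=False,
            seed=key,
        )
        tr.success = evaluate_success(tr, config)
        trials.append(tr)
    return trials


def simulate_trial(
    sys: DiscreteSystem,
    gains: GainSchedule,
    noise: NoiseSpec,
    config: TaskConfig,
    seed: int,
    x_init_offset: float = 0.0,
) -> Trial:
    """Simulate a single trial; the seed fully determines the noise streams.

    ``x_init_offset`` (cm) optionally starts the cursor away from the center,
    with the cursor velocity initialized consistently with the cursor law.
    """
    if gains.n != config.n_steps:
        raise ValueError(
            f"gain schedule horizon {gains.n} != config horizon {config.n_steps}"
        )
    return _simulate_level(
        sys, gains, noise, config,
        seed_keys=[(int(seed),)], base_seed=noise.seed,
        x_offsets=np.array([x_init_offset]),
    )[0]


def run_batch(
    objective: str,
    lam_grid: np.ndarray | None = None,
    n_per_lam: int = 500,
    base_seed: int = 0,
    task: TaskConfig | None = None,
    plant: PlantParams | None = None,
    noise: NoiseSpec | None = None,
    weight: float = 1e4,
    U: float = 10.0,
    delay_steps: int = 5,
    stream: int = 0,
    x_offset_sd: float = 0.0,
    gain_cache: GainCache | None = None,
) -> TrialSet:
    """Simulate ``n_per_lam`` trials per difficulty level under one objective.

    Gains are solved once per (lambda, objective) and cached.  ``stream``
    enters every per-trial spawn key, so batches with different streams share
    no random numbers even at the same base seed (train/test bookkeeping).
    ``x_offset_sd`` > 0 draws a Gaussian random initial cursor offset per trial.
    """
    lam_grid = default_lam_grid() if lam_grid is None else np.asarray(lam_grid, float)
    if lam_grid.size == 0:
        raise ValueError("lam_grid must be nonempty")
    plant = plant or PlantParams()
    noise = noise or NoiseSpec()
    task = task or TaskConfig(lam=float(lam_grid[0]))
    gain_cache = gain_cache or GainCache()

    trials: list = []
    for li, lam in enumerate(lam_grid):
        cfg = replace(task, lam=float(lam))
        dsys = discretize(build_continuous_system(float(lam), plant), cfg.dt, delay_steps)
        cost = make_objective(objective, weight, U, cfg.n_steps)
        try:
            gains = gain_cache.get_or_solve(dsys, cost, noise)
        except Exception as err:
            raise RuntimeError(f"gain solve failed at lambda={lam}: {err}") from err
        if n_per_lam == 0:
            continue
        keys = [(stream, li, ti) for ti in range(n_per_lam)]
        offsets = np.zeros(n_per_lam)
        if x_offset_sd > 0:
            off_rng = np.random.default_rng(
                np.random.SeedSequence(base_seed, spawn_key=(stream, li, 2**20))
            )
            offsets = x_offset_sd * off_rng.standard_normal(n_per_lam)
        level_trials = _simulate_level(dsys, gains, noise, cfg, keys, base_seed, offsets)
        for tr in level_trials:
            tr.objective = objective
        trials.extend(level_trials)

    provenance = {
        "format_version": FORMAT_VERSION,
        "package_version": __version__,
        "objective": objective,
        "lam_grid": [float(v) for v in lam_grid],
        "n_per_lam": int(n_per_lam),
        "base_seed": int(base_seed),
        "stream": int(stream),
        "weight": float(weight),
        "U": float(U),
        "delay_steps": int(delay_steps),
        "x_offset_sd": float(x_offset_sd),
        "task": asdict(replace(task, lam=float(lam_grid[0]))),
        "plant": asdict(plant),
        "noise": asdict(noise),
    }
    return TrialSet(trials=trials, provenance=provenance)


def trials_from_hand_traces(
    df: pd.DataFrame,
    task: TaskConfig | None = None,
    lam: float | None = None,
    scheme: str = "exact",
) -> TrialSet:
    """Reconstruct cursor kinematics from recorded hand traces.

    ``df`` is the tidy table produced by :func:`cstcontrol.model.read_hand_traces`
    (already resampled to the model step): columns ``trial_id``, ``time_s``,
    ``hand_cm`` and, unless ``lam`` is given, a per-trial ``lambda`` column.
    The cursor is integrated from x(0) = 0 via the cursor law (exact
    zero-order-hold scheme by default, appropriate for external recordings) and
    success is evaluated against the workspace bound.
    """
    from .model import cursor_from_hand  # local import avoids cycle at module load

    trials = []
    for tid, g in df.groupby("trial_id", sort=True):
        if lam is not None:
            lam_i = float(lam)
        elif "lambda" in g.columns:
            lam_i = float(g["lambda"].iloc[0])
        else:
            raise ValueError(f"trial {tid}: no lambda column and no lam argument")
        t = g["time_s"].to_numpy(dtype=float)
        p = g["hand_cm"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(t)))
        cfg = task or TaskConfig(lam=lam_i)
        x, xdot = cursor_from_hand(p, lam=lam_i, dt=dt, scheme=scheme)
        pdot = np.gradient(p, dt)
        tr = Trial(
            lam=lam_i, objective="unknown", t=t - t[0], x=x, xdot=xdot,
            p=p, pdot=pdot, u=np.full(max(t.size - 1, 0), np.nan),
            success=False, seed=(),
        )
        tr.success = evaluate_success(tr, replace(cfg, lam=lam_i))
        trials.append(tr)
    return TrialSet(
        trials=trials,
        provenance={
            "format_version": FORMAT_VERSION,
            "package_version": __version__,
            "source": "reconstructed-from-hand-traces",
            "scheme": scheme,
        },
    )


def export_trials(tset: TrialSet, path) -> None:
    """Write a TrialSet as a tidy per-step table plus a JSON sidecar.

    ``path`` is a directory that will contain ``trials.csv`` (columns
    trial_id, t_s, x_cm, xdot_cms, p_cm, pdot_cms, u) and ``meta.json``
    (per-trial lambda/objective/seed/success and the global provenance).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = []
    meta_trials = []
    for tid, tr in enumerate(tset.trials):
        n = tr.t.size
        u_pad = np.append(tr.u, np.nan) if tr.u.size == n - 1 else tr.u[:n]
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": tid,
                    "t_s": tr.t,
                    "x_cm": tr.x,
                    "xdot_cms": tr.xdot,
                    "p_cm": tr.p,
                    "pdot_cms": tr.pdot,
                    "u": u_pad,
                }
            )
        )
        meta_trials.append(
            {
                "trial_id": tid,
                "lam": tr.lam,
                "objective": tr.objective,
                "seed": list(tr.seed),
                "success": bool(tr.success),
            }
        )
    pd.concat(frames, ignore_index=True).to_csv(path / "trials.csv", index=False)
    meta = {
        "format_version": FORMAT_VERSION,
        "provenance": tset.provenance,
        "trials": meta_trials,
    }
    (path / "meta.json").write_text(json.dumps(meta))


def import_trials(path) -> TrialSet:
    """Inverse of :func:`export_trials`; raises on version mismatch."""
    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"corrupt meta.json at byte offset {err.pos}: {err.msg}") from err
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"trial-set format version {version} does not match reader version {FORMAT_VERSION}"
        )
    df = pd.read_csv(path / "trials.csv")
    trials = []
    grouped = dict(iter(df.groupby("trial_id", sort=True)))
    for rec in meta["trials"]:
        g = grouped[rec["trial_id"]]
        n = len(g)
        u = g["u"].to_numpy()
        if n and np.isnan(u[-1]):
            u = u[:-1]
        trials.append(
            Trial(
                lam=float(rec["lam"]),
                objective=rec["objective"],
                t=g["t_s"].to_numpy(),
                x=g["x_cm"].to_numpy(),
                xdot=g["xdot_cms"].to_numpy(),
                p=g["p_cm"].to_numpy(),
                pdot=g["pdot_cms"].to_numpy(),
                u=u,
                success=bool(rec["success"]),
                seed=tuple(rec["seed"]),
            )
        )
    return TrialSet(trials=trials, provenance=meta["provenance"])
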