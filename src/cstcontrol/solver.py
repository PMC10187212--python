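"""Finite-horizon LQG gains under signal-dependent motor noise.

The controller minimizes ``J = sum_t (x_t' Q x_t + u_t' U u_t)`` for the
discrete plant

    x_{t+1} = Ad x_t + Bd (1 + C eps_t) u_t + xi_t,     xi ~ N(0, motor_scale Bd Bd')
    y_t     = H x_t + omega_t,                          omega ~ N(0, sensory_sd^2 I)

with control ``u_t = -L_t xhat_t`` and estimator
``xhat_{t+1} = (Ad - Bd L_t) xhat_t + K_t (y_t - H xhat_t)``.

Because the noise scales with the control signal, the classical separation
principle no longer holds: the optimal control gains depend on the estimation
error covariance and the optimal filter gains depend on the control gains.
``solve_gains`` therefore alternates a backward control-gain recursion with a
forward filter recursion (exact propagation of the estimate, error, and cross
second moments) until the gain schedules reach a fixed point.  In the limit
``C = 0`` with no delay, the interior gains coincide with the steady-state
solutions of the standard discrete algebraic Riccati equations, which is the
independent oracle the tests check against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import DiscreteSystem, N_PHYSICAL, NoiseSpec

__all__ = ["CostSpec", "GainSchedule", "SolverError", "make_objective", "solve_gains", "GainCache"]


class SolverError(RuntimeError):
    """Gain iteration failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(eq=False)
class CostSpec:
    """Quadratic objective: state weight matrix Q (on the five physical
    states), scalar effort weight U, and horizon n in steps."""

    kind: str
    q: float
    v: float
    U: float
    n: int
    Q: np.ndarray = field(repr=False, default=None)

    def lifted_Q(self, sys: DiscreteSystem) -> np.ndarray:
        """Lift Q to the delay-augmented space: the cost acts on the newest copy."""
        Qa = np.zeros((sys.n_states, sys.n_states))
        Qa[:N_PHYSICAL, :N_PHYSICAL] = self.Q
        return Qa


@dataclass(eq=False)
class GainSchedule:
    """Time-indexed control gains L[t] (1 x n_states) and filter gains
    K[t] (n_states x n_obs), t = 0..n-1, with convergence diagnostics."""

    L: np.ndarray
    K: np.ndarray
    iterations: int
    converged: bool
    residual: float

    @property
    def n(self) -> int:
        return self.L.shape[0]


def make_objective(kind: str, weight: float = 1e4, U: float = 10.0, n: int = 800) -> CostSpec:
    """Build the state-cost matrix for a control objective.

    ``position`` penalizes cursor position (Q[0,0] = weight); ``velocity``
    penalizes cursor velocity (Q[1,1] = weight); ``custom`` with a
    (q, v) tuple as ``weight`` sets both diagonal entries.
    """
    if weight is None:
        weight = 0.0
    Q = np.zeros((N_PHYSICAL, N_PHYSICAL))
    if kind == "position":
        if np.ndim(weight) != 0 or weight < 0:
            raise ValueError("position objective needs a scalar weight >= 0")
        Q[0, 0] = weight
        q, v = float(weight), 0.0
    elif kind == "velocity":
        if np.ndim(weight) != 0 or weight < 0:
            raise ValueError("velocity objective needs a scalar weight >= 0")
        Q[1, 1] = weight
        q, v = 0.0, float(weight)
    elif kind == "custom":
        q, v = (float(w) for w in np.atleast_1d(weight)[:2])
        if q < 0 or v < 0:
            raise ValueError("custom weights must be >= 0")
        Q[0, 0], Q[1, 1] = q, v
    else:
        raise ValueError(f"unknown objective kind {kind!r}")
    if not U > 0:
        raise ValueError(f"effort weight U must be positive, got {U}")
    return CostSpec(kind=kind, q=q, v=v, U=float(U), n=int(n), Q=Q)


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def solve_gains(
    sys: DiscreteSystem,
    cost: CostSpec,
    noise: NoiseSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GainSchedule:
    """Alternate backward control and forward filter recursions to a fixed point.

    Backward (given K):
        L_t  = (U + B'Sx B + Cs'(Sx + Se)Cs)^-1 B'Sx A
        Sx_t = Q + A'Sx(A - B L_t)
        Se_t = A'Sx B L_t + (A - K_t H)' Se (A - K_t H)
    with Sx_n = Q, Se_n = 0 and Cs = C * Bd the signal-dependent noise matrix.

    Forward (given L), propagating Se = Cov(error), Sx^ = E[xhat xhat'] and the
    cross moment exactly from xhat_0 = x_0 (zero error at trial start):
        K_t = A Se H' (H Se H' + E)^-1

    Deterministic given inputs.  Raises :class:`SolverError` if the maximum
    relative gain change has not fallen below ``tol`` within ``max_iter``
    alternations.
    """
    A, B, H = sys.Ad, sys.Bd, sys.H
    nx, ny = sys.n_states, H.shape[0]
    n = cost.n
    Qa = cost.lifted_Q(sys)
    R = np.array([[cost.U]])
    Cs = noise.C * B
    Omega = noise.motor_scale * (B @ B.T)
    E = noise.sensory_sd**2 * np.eye(ny)
    E_reg = E if noise.sensory_sd > 0 else 1e-12 * np.eye(ny)

    L = np.zeros((n, 1, nx))
    K = np.zeros((n, nx, ny))
    I = np.eye(nx)

    def forward(L):
        Knew = np.empty_like(K)
        Se = np.zeros((nx, nx))   # Cov(x - xhat): estimator starts at the true state
        Sx = np.zeros((nx, nx))   # E[xhat xhat']: trials start at the origin
        Sxe = np.zeros((nx, nx))  # E[xhat (x - xhat)']
        for t in range(n):
            Sy = H @ Se @ H.T + E_reg
            Kt = np.linalg.solve(Sy.T, (A @ Se @ H.T).T).T
            Knew[t] = Kt
            AmBL = A - B @ L[t]
            AmKH = A - Kt @ H
            u_cov = L[t] @ Sx @ L[t].T  # scalar E[u^2]
            sdn = Cs @ u_cov @ Cs.T
            KEK = Kt @ E @ Kt.T
            Se_n = _sym(AmKH @ Se @ AmKH.T + Omega + KEK + sdn)
            Sx_n = _sym(
                AmBL @ Sx @ AmBL.T
                + Kt @ H @ Se @ H.T @ Kt.T
                + KEK
                + AmBL @ Sxe @ H.T @ Kt.T
                + Kt @ H @ Sxe.T @ AmBL.T
            )
            Sxe = AmBL @ Sxe @ AmKH.T + Kt @ H @ Se @ AmKH.T - KEK
            Se, Sx = Se_n, Sx_n
        return Knew

    def backward(K):
        Lnew = np.empty_like(L)
        Sx = Qa.copy()
        Se = np.zeros((nx, nx))
        for t in range(n - 1, -1, -1):
            BtS = B.T @ Sx
            denom = R + BtS @ B + Cs.T @ (Sx + Se) @ Cs
            Lt = np.linalg.solve(denom, BtS @ A)
            Lnew[t] = Lt
            AmKH = A - K[t] @ H
            Sx_new = _sym(Qa + A.T @ Sx @ (A - B @ Lt))
            Se = _sym(A.T @ Sx @ B @ Lt + AmKH.T @ Se @ AmKH)
            Sx = Sx_new
        return Lnew

    residual = np.inf
    for it in range(1, max_iter + 1):
        Knew = forward(L)
        Lnew = backward(Knew)
        dL = np.max(np.abs(Lnew - L)) / (np.max(np.abs(Lnew)) + 1e-300)
        dK = np.max(np.abs(Knew - K)) / (np.max(np.abs(Knew)) + 1e-300)
        residual = max(dL, dK)
        L, K = Lnew, Knew
        if residual < tol:
            return GainSchedule(L=L, K=K, iterations=it, converged=True, residual=residual)
    raise SolverError(
        f"gain iteration did not converge in {max_iter} alternations "
        f"(residual {residual:.3e})",
        residual,
    )


class GainCache:
    """In-memory cache of gain schedules keyed by the full parameter tuple, so
    batch simulation solves once per (lambda, objective)."""

    def __init__(self):
        self._store: dict = {}

    @staticmethod
    def _key(sys: DiscreteSystem, cost: CostSpec, noise: NoiseSpec):
        return (
            round(sys.lam, 12), sys.dt, sys.delay_steps, sys.plant.M, sys.plant.tau,
            cost.kind, cost.q, cost.v, cost.U, cost.n,
            noise.C, noise.motor_scale, noise.sensory_sd,
        )

    def get_or_solve(self, sys: DiscreteSystem, cost: CostSpec, noise: NoiseSpec, **kw) -> GainSchedule:
        key = self._key(sys, cost, noise)
        if key not in self._store:
            self._store[key] = solve_gains(sys, cost, noise, **kw)
        return self._store[key]

    def __len__(self) -> int:
        return len(self._store)

    def save(self, path) -> None:
        """Persist all solved schedules to an .npz artifact keyed by the
        (lambda, objective, parameter) tuples, so batch jobs can re-use them."""
        arrays = {}
        index = []
        for i, (key, g) in enumerate(self._store.items()):
            index.append(
                {
                    "key": list(key),
                    "iterations": g.iterations,
                    "converged": bool(g.converged),
                    "residual": g.residual,
                }
            )
            arrays[f"L{i}"] = g.L
            arrays[f"K{i}"] = g.K
        arrays["index_json"] = np.frombuffer(
            json.dumps(index).encode("utf-8"), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "GainCache":
        """Inverse of :meth:`save`."""
        data = np.load(path)
        index = json.loads(bytes(data["index_json"]).decode("utf-8"))
        cache = cls()
        for i, rec in enumerate(index):
            cache._store[tuple(rec["key"])] = GainSchedule(
                L=data[f"L{i}"],
                K=data[f"K{i}"],
                iterations=int(rec["iterations"]),
                converged=bool(rec["converged"]),
                residual=float(rec["residual"]),
            )
        return cache
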