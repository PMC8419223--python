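"""Numerical least-action toolkit: action integrals, Euler–Lagrange residuals,
stationarity probes and conservation (Noether) checks.

A system is specified by a Lagrangian ``L(q, qdot, t)`` over m generalized
coordinates; trajectories are sampled on a uniform time grid.  Everything
is finite-difference numerics — the package deliberately carries no
symbolic algebra — so all identities hold to O(Δt²) quadrature/central
difference accuracy, and the tests phrase them that way.

The central scientific content is Noether pairing: a Lagrangian
independent of a coordinate conserves that coordinate's conjugate momentum
``∂L/∂qdot``; a Lagrangian independent of time conserves the energy
``Σ qdot ∂L/∂qdot − L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

#: relative step for finite-difference derivatives of L; chosen near the
#: central-difference optimum (~eps^(1/3)) so that rounding noise in the
#: conjugate momentum is not amplified by the subsequent time derivative
FD_REL_STEP = 1e-5


@dataclass
class LagrangianSystem:
    """Scalar Lagrangian ``L(q, qdot, t)`` with q, qdot of dimension m.

    For mechanical systems use :func:`mechanical_lagrangian` to build
    ``L = K - V`` from a mass and a potential.
    """

    L: Callable[[np.ndarray, np.ndarray, float], float]
    dim: int = 1
    mass: float | None = None
    potential: Callable[[np.ndarray], float] | None = None

    def __call__(self, q, qdot, t) -> float:
        return float(self.L(np.asarray(q, dtype=float), np.asarray(qdot, dtype=float), t))


def mechanical_lagrangian(mass: float, potential: Callable[[np.ndarray], float],
                          dim: int = 1) -> LagrangianSystem:
    """L = ½ m |qdot|² − V(q)."""

    def L(q, qdot, t):
        return 0.5 * mass * float(qdot @ qdot) - float(potential(q))

    return LagrangianSystem(L, dim=dim, mass=mass, potential=potential)


@dataclass
class Trajectory:
    """Uniformly sampled trajectory q(t) on [t1, t2]."""

    t: np.ndarray          # (n,)
    q: np.ndarray          # (n, m)
    qdot: np.ndarray | None = None  # optional analytic velocities

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        if self.q.shape[0] != self.t.shape[0]:
            self.q = self.q.T
        if self.t.ndim != 1 or self.t.shape[0] < 3:
            raise ValueError("need at least 3 strictly increasing time samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.qdot is not None:
            self.qdot = np.atleast_2d(np.asarray(self.qdot, dtype=float))
            if self.qdot.shape[0] != self.t.shape[0]:
                self.qdot = self.qdot.T

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def velocities(self) -> np.ndarray:
        """Analytic velocities when supplied, else central differences
        (one-sided at the endpoints)."""
        if self.qdot is not None:
            return self.qdot
        return np.gradient(self.q, self.t, axis=0)


def sample_trajectory(fun: Callable[[float], np.ndarray], t1: float, t2: float,
                      n: int, vel: Callable[[float], np.ndarray] | None = None) -> Trajectory:
    """Sample an analytic trajectory (and optionally its velocity) on n points."""
    t = np.linspace(t1, t2, n)
    q = np.array([np.atleast_1d(fun(ti)) for ti in t], dtype=float)
    qdot = None
    if vel is not None:
        qdot = np.array([np.atleast_1d(vel(ti)) for ti in t], dtype=float)
    return Trajectory(t, q, qdot)


def action(system: LagrangianSystem, traj: Trajectory) -> float:
    """Action S = ∫ L dt by trapezoidal quadrature (O(Δt²) accurate)."""
    v = traj.velocities()
    Lvals = np.array([system(traj.q[i], v[i], traj.t[i]) for i in range(len(traj.t))])
    return float(np.trapezoid(Lvals, traj.t))


def _dL_dq(system: LagrangianSystem, q, v, t) -> np.ndarray:
    out = np.empty(len(q))
    for k in range(len(q)):
        h = FD_REL_STEP * max(abs(q[k]), 1.0)
        qp, qm = q.copy(), q.copy()
        qp[k] += h
        qm[k] -= h
        out[k] = (system(qp, v, t) - system(qm, v, t)) / (2 * h)
    return out


def _dL_dqdot(system: LagrangianSystem, q, v, t) -> np.ndarray:
    out = np.empty(len(v))
    for k in range(len(v)):
        h = FD_REL_STEP * max(abs(v[k]), 1.0)
        vp, vm = v.copy(), v.copy()
        vp[k] += h
        vm[k] -= h
        out[k] = (system(q, vp, t) - system(q, vm, t)) / (2 * h)
    return out


def el_residual(system: LagrangianSystem, traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Lagrange residual ∂L/∂q − d/dt(∂L/∂qdot) on the interior grid.

    Zero (to discretization error) on true trajectories of the dynamics.
    Returns ``(t_interior, residuals)`` with residuals of shape
    ``(n_interior, m)``.
    """
    if len(traj.t) < 5:
        raise ValueError("need at least 5 samples for central differences")
    v = traj.velocities()
    n, m = traj.q.shape
    dLdq = np.array([_dL_dq(system, traj.q[i], v[i], traj.t[i]) for i in range(n)])
    p = np.array([_dL_dqdot(system, traj.q[i], v[i], traj.t[i]) for i in range(n)])
    dpdt = np.gradient(p, traj.t, axis=0)
    res = dLdq - dpdt
    return traj.t[2:-2], res[2:-2]


def stationarity_check(system: LagrangianSystem, traj: Trajectory,
                       perturbation: Callable[[np.ndarray], np.ndarray] | None = None,
                       epsilons=None) -> dict:
    """Probe δS around a trajectory with an endpoint-vanishing perturbation.

    Evaluates S(ε) for q + ε δq, fits a quadratic near ε = 0, and reports
    the first derivative (≈0 certifies stationarity) and the curvature
    sign (minimum / maximum / saddle).  The default perturbation is a
    half-sine bump, which vanishes at both endpoints.
    """
    t = traj.t
    if perturbation is None:
        span = t[-1] - t[0]

        def perturbation(tt):
            bump = np.sin(np.pi * (tt - t[0]) / span)
            return np.repeat(bump[:, None], traj.q.shape[1], axis=1)

    dq = np.atleast_2d(np.asarray(perturbation(t), dtype=float))
    if dq.shape[0] != len(t):
        dq = dq.T
    if abs(dq[0]).max() > 1e-12 or abs(dq[-1]).max() > 1e-12:
        raise ValueError("perturbation must vanish at both endpoints")
    if epsilons is None:
        epsilons = np.linspace(-0.05, 0.05, 9)
    epsilons = np.asarray(epsilons, dtype=float)
    S = np.array([action(system, Trajectory(t, traj.q + e * dq)) for e in epsilons])
    coeffs = np.polyfit(epsilons, S, 2)  # S(ε) ≈ c2 ε² + c1 ε + c0
    c2, c1, c0 = coeffs
    kind = "minimum" if c2 > 0 else ("maximum" if c2 < 0 else "saddle")
    return {"S0": float(c0), "dS_deps": float(c1), "curvature": float(2 * c2),
            "kind": kind, "epsilons": epsilons, "S": S}


def is_stationary(report: dict, rel_tol: float = 1e-6) -> bool:
    """Stationarity criterion |dS/dε| < rel_tol · |S| at ε = 0."""
    return abs(report["dS_deps"]) < rel_tol * max(abs(report["S0"]), 1e-30)


def conserved_quantity(system: LagrangianSystem, traj: Trajectory,
                       kind: str = "energy", coordinate: int = 0) -> tuple[np.ndarray, float]:
    """Time series of a candidate conserved quantity and its drift (max − min).

    ``kind="momentum"``: conjugate momentum ∂L/∂qdot of one coordinate —
    conserved when L does not depend on that coordinate.
    ``kind="energy"``: Σ qdot ∂L/∂qdot − L — conserved when L does not
    depend explicitly on time.  Drift is measured on the interior grid
    (endpoint finite differences are one-sided and less accurate).
    """
    v = traj.velocities()
    n = len(traj.t)
    if kind == "momentum":
        series = np.array([_dL_dqdot(system, traj.q[i], v[i], traj.t[i])[coordinate]
                           for i in range(n)])
    elif kind == "energy":
        series = np.empty(n)
        for i in range(n):
            p = _dL_dqdot(system, traj.q[i], v[i], traj.t[i])
            series[i] = float(v[i] @ p) - system(traj.q[i], v[i], traj.t[i])
    else:
        raise ValueError(f"unknown conserved quantity kind: {kind!r}")
    interior = series[1:-1] if n > 4 else series
    return series, float(interior.max() - interior.min())


def integrate_trajectory(system: LagrangianSystem, q0, v0, t1: float, t2: float,
                         n: int) -> Trajectory:
    """RK4 integration of the mechanical equations of motion m qddot = −∇V.

    Requires the system to be in mechanical form (mass and potential set).
    """
    if system.mass is None or system.potential is None:
        raise ValueError("integration requires a mechanical-form system (mass, potential)")
    m = system.mass
    V = system.potential
    dim = system.dim

    def grad_V(q):
        g = np.empty(dim)
        for k in range(dim):
            h = FD_REL_STEP * max(abs(q[k]), 1.0)
            qp, qm = q.copy(), q.copy()
            qp[k] += h
            qm[k] -= h
            g[k] = (V(qp) - V(qm)) / (2 * h)
        return g

    def deriv(state):
        q, v = state[:dim], state[dim:]
        return np.concatenate([v, -grad_V(q) / m])

    t = np.linspace(t1, t2, n)
    dt = t[1] - t[0]
    state = np.concatenate([np.atleast_1d(np.asarray(q0, dtype=float)),
                            np.atleast_1d(np.asarray(v0, dtype=float))])
    qs = np.empty((n, dim))
    vs = np.empty((n, dim))
    for i in range(n):
        qs[i], vs[i] = state[:dim], state[dim:]
        if i == n - 1:
            break
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return Trajectory(t, qs, vs)
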