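"""The cost functional E(X) = ||A(X) - Y|| + λ ||P(X)|| and its MAP reading.

A candidate interpretation X is a set of 3D point pairs (P_i, Q_i); A is
perspective projection onto the image; Y is the observed image pair set;
P(X) measures the departure of X from perfect mirror symmetry (minimized
over all candidate symmetry planes); λ trades data fidelity against the
symmetry prior.  With squared Euclidean norms the minimizer of E is the
maximum-a-posteriori estimate under Gaussian image noise and a Gaussian
symmetry prior, with λ equal to the variance ratio σ_data²/σ_prior².

In the noiseless case the minimum of E coincides with the closed-form
recovery of :mod:`mirrorshape.recovery` — the energy view and the
constructive view are two routes to the same interpretation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .geometry import Camera, Plane3D, mirror_reflect, project_perspective
from .recovery import ImageCorrespondenceSet, RecoveredShape, recover_shape

logger = logging.getLogger(__name__)


@dataclass
class EnergyModel:
    """Configuration of the cost functional for a given image pair set."""

    data: ImageCorrespondenceSet
    lam: float = 1.0
    squared_norms: bool = True  # squared norms enable the exact MAP identity

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("λ must be non-negative")

    @property
    def camera(self) -> Camera:
        return self.data.camera


def reprojection_residual(P, Q, data: ImageCorrespondenceSet, squared: bool = True) -> float:
    """||A(X) - Y||: image distance between projected candidate and data.

    Sum of squared image distances by default; points moved along their
    projecting rays leave this term unchanged (depth is invisible to it).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape[0] != len(data) or Q.shape[0] != len(data):
        raise ValueError("candidate and data cardinality mismatch")
    cam = data.camera
    dp = project_perspective(P, cam) - data.p
    dq = project_perspective(Q, cam) - data.q
    ss = float(np.sum(dp**2) + np.sum(dq**2))
    return ss if squared else float(np.sqrt(ss))


def _penalty_for_plane(P, Q, normal: np.ndarray) -> float:
    """Sum of squared |reflect(P_i) - Q_i| for the optimal offset at this normal.

    For a fixed unit normal the optimal plane passes through the centroid
    of the pair midpoints (closed form for the offset).
    """
    n = normal / np.linalg.norm(normal)
    mid = 0.5 * (P + Q)
    d = -float(n @ mid.mean(axis=0))
    plane = Plane3D(n[0], n[1], n[2], d)
    return float(np.sum((mirror_reflect(P, plane) - Q) ** 2))


def best_symmetry_plane(P, Q) -> tuple[Plane3D, float]:
    """Symmetry plane minimizing Σ|reflect(P_i) - Q_i|² and the minimum value.

    The chord directions P_i - Q_i of a truly symmetric pair set are all
    parallel to the plane normal, so the dominant eigenvector of the chord
    scatter matrix is the natural starting point; a short spherical
    optimization refines it for asymmetric input.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape != Q.shape or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    mid = 0.5 * (P + Q)
    if P.shape[0] < 3 or np.linalg.matrix_rank(mid - mid.mean(axis=0), tol=1e-12) < 2:
        warnings.warn("fewer than 3 non-collinear pairs: symmetry plane underdetermined",
                      stacklevel=2)
    u = P - Q
    scatter = u.T @ u
    w, vecs = np.linalg.eigh(scatter)
    n0 = vecs[:, -1]

    def objective(angles):
        th, ph = angles
        n = np.array([np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph), np.sin(th)])
        return _penalty_for_plane(P, Q, n)

    th0 = np.arcsin(np.clip(n0[2], -1, 1))
    ph0 = np.arctan2(n0[1], n0[0])
    best = (np.array([th0, ph0]), objective((th0, ph0)))
    if best[1] > 1e-18:  # refine only when not already exact
        rng = np.random.default_rng(0)
        starts = [best[0]] + [rng.uniform([-np.pi / 2, -np.pi], [np.pi / 2, np.pi])
                              for _ in range(3)]
        for x0 in starts:
            res = _scipy_minimize(objective, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 400})
            if res.fun < best[1]:
                best = (res.x, float(res.fun))
    th, ph = best[0]
    n = np.array([np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph), np.sin(th)])
    d = -float((n / np.linalg.norm(n)) @ mid.mean(axis=0))
    return Plane3D.from_coefficients(n[0], n[1], n[2], d), best[1]


def asymmetry_penalty(P, Q, squared: bool = True) -> float:
    """||P(X)||: departure of the candidate pairs from perfect mirror symmetry.

    Minimum over candidate mirror planes of the sum of squared distances
    between the reflected first half and the second half; exactly 0 iff
    the pairs are mirror-symmetric about some plane.
    """
    _, val = best_symmetry_plane(P, Q)
    return val if squared else float(np.sqrt(val))


def energy(P, Q, model: EnergyModel) -> float:
    """E(X) = ||A(X) - Y|| + λ ||P(X)||."""
    sq = model.squared_norms
    return (reprojection_residual(P, Q, model.data, squared=sq)
            + model.lam * asymmetry_penalty(P, Q, squared=sq))


def map_log_posterior(P, Q, model: EnergyModel, sigma_data: float, sigma_prior: float) -> float:
    """Log-posterior (up to an additive constant) of candidate X.

    Gaussian likelihood on the reprojection residual and Gaussian prior on
    the asymmetry: −½||A(X)−Y||²/σ_d² − ½||P(X)||²/σ_p².  Its argmax equals
    the argmin of E with λ = σ_d²/σ_p² under squared norms.
    """
    if sigma_data <= 0 or sigma_prior <= 0:
        raise ValueError("σ_data and σ_prior must be positive")
    ll = -0.5 * reprojection_residual(P, Q, model.data, squared=True) / sigma_data**2
    lp = -0.5 * asymmetry_penalty(P, Q, squared=True) / sigma_prior**2
    return ll + lp


def lambda_from_sigmas(sigma_data: float, sigma_prior: float) -> float:
    """Variance-matched constraint weight λ = σ_data² / σ_prior²."""
    if sigma_data <= 0 or sigma_prior <= 0:
        raise ValueError("σ_data and σ_prior must be positive")
    return sigma_data**2 / sigma_prior**2


@dataclass
class MinimizeResult:
    P: np.ndarray
    Q: np.ndarray
    energy: float
    reprojection: float
    penalty: float
    converged: bool
    n_iterations: int
    message: str = ""

    def to_dict(self) -> dict:
        return {"energy": self.energy, "reprojection": self.reprojection,
                "penalty": self.penalty, "converged": self.converged,
                "n_iterations": self.n_iterations, "message": self.message}


def minimize_energy(model: EnergyModel, init: RecoveredShape | None = None,
                    max_iter: int = 500, tol: float = 1e-10,
                    n_restarts: int = 3, seed: int = 0) -> MinimizeResult:
    """Numerical minimizer of E over unconstrained 3D point pairs.

    The decision vector holds all 6n point coordinates plus the symmetry
    plane direction (two angles; the plane offset is closed-form), so the
    inner minimization over planes rides along with the outer one.  The
    default initialization is the closed-form recovery applied to the data
    (forced through the residual check, since noisy data never passes it
    exactly), which on noiseless data already sits at the global minimum.
    Seeded jittered restarts guard against local minima.
    """
    data = model.data
    n = len(data)
    if init is None:
        init = recover_shape(data, force=True)
    P0, Q0 = init.P, init.Q
    plane0, _ = best_symmetry_plane(P0, Q0)
    n0 = plane0.normal
    th0 = float(np.arcsin(np.clip(n0[2], -1, 1)))
    ph0 = float(np.arctan2(n0[1], n0[0]))
    x0 = np.concatenate([P0.ravel(), Q0.ravel(), [th0, ph0]])

    sq = model.squared_norms

    def unpack(x):
        P = x[: 3 * n].reshape(n, 3)
        Q = x[3 * n: 6 * n].reshape(n, 3)
        th, ph = x[6 * n], x[6 * n + 1]
        normal = np.array([np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph), np.sin(th)])
        return P, Q, normal

    def objective(x):
        P, Q, normal = unpack(x)
        rep = reprojection_residual(P, Q, data, squared=True)
        pen = _penalty_for_plane(P, Q, normal)
        if not sq:
            return np.sqrt(rep) + model.lam * np.sqrt(pen)
        return rep + model.lam * pen

    rng = np.random.default_rng(seed)
    best = None
    scale = max(np.abs(np.concatenate([P0.ravel(), Q0.ravel()])).max(), 1.0)
    for r in range(max(1, n_restarts)):
        x_start = x0 if r == 0 else x0 + rng.normal(0, 1e-3 * scale, x0.shape)
        res = _scipy_minimize(objective, x_start, method="L-BFGS-B",
                              options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun <= tol:
            break

    P, Q, normal = unpack(best.x)
    rep = reprojection_residual(P, Q, data, squared=sq)
    pen = asymmetry_penalty(P, Q, squared=sq)
    converged = bool(best.success) or best.fun <= tol
    if not converged:
        logger.warning("energy minimization did not converge: %s", best.message)
    return MinimizeResult(P=P, Q=Q, energy=float(rep + model.lam * pen),
                          reprojection=float(rep), penalty=float(pen),
                          converged=converged, n_iterations=int(best.nit),
                          message=str(best.message))
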