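"""Sampled verification of group axioms, invariants, and law/transform commutation.

Transformation groups are generally infinite, so every check here is a
*sampled falsification*: it can demonstrate that a set of transformations
violates an axiom or fails to preserve a feature, but a pass only certifies
the property on the sample.  Reports carry the sample sizes so no claim of
exhaustive proof is made.

Also includes the classic inverse-square worked example: the Moon's
centripetal fall over one second, scaled by the square of the distance
ratio to predict free fall at the Earth's surface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

DAY_SECONDS = 86_400.0
FALL_INTERVAL_S = 1.0


@dataclass
class TransformationSet:
    """A finite sample of transformations with a composition rule.

    Elements act on *instances* (arbitrary objects, typically arrays of
    points) through ``act(element, instance)``.  Equality of two elements is
    decided by comparing their action on ``probes`` within a tolerance,
    which keeps the machinery agnostic of how elements are represented
    (numbers, matrices, callables ...).

    ``in_window`` optionally restricts closure checking to a compact window:
    compositions falling outside it are excluded rather than counted as
    closure failures (translations on a sampled window cannot be closed).
    """

    elements: Sequence
    compose: Callable
    act: Callable
    probes: Sequence = field(default_factory=list)
    in_window: Callable | None = None

    def _signature(self, element) -> np.ndarray:
        out = [np.ravel(np.asarray(self.act(element, p), dtype=float)) for p in self.probes]
        return np.concatenate(out) if out else np.zeros(0)

    def find_equal(self, element, tol: float):
        """Index of a sampled element acting identically on the probes, or None."""
        sig = self._signature(element)
        for j, other in enumerate(self.elements):
            if np.max(np.abs(self._signature(other) - sig), initial=0.0) <= tol:
                return j
        return None


@dataclass
class AxiomReport:
    closure: bool
    identity: bool
    inverse: bool
    associativity: bool
    worst_deviation: dict
    n_elements: int
    n_pairs_checked: int
    excluded_out_of_window: int
    notes: str = "sampled check on a finite element set; a pass is not an exhaustive proof"

    @property
    def is_group(self) -> bool:
        return self.closure and self.identity and self.inverse and self.associativity

    def to_dict(self) -> dict:
        return {
            "closure": self.closure,
            "identity": self.identity,
            "inverse": self.inverse,
            "associativity": self.associativity,
            "is_group": self.is_group,
            "worst_deviation": self.worst_deviation,
            "n_elements": self.n_elements,
            "n_pairs_checked": self.n_pairs_checked,
            "excluded_out_of_window": self.excluded_out_of_window,
            "notes": self.notes,
        }


def check_group_axioms(tset: TransformationSet, tol: float = 1e-9) -> AxiomReport:
    """Check the four group axioms (closure, identity, inverse, associativity)
    on the sampled elements.

    A composition that raises is recorded as a closure failure rather than
    propagating; out-of-window compositions (when ``in_window`` is given)
    are excluded from the closure count.
    """
    els = list(tset.elements)
    if len(els) < 2:
        raise ValueError("need at least 2 sampled elements")

    worst = {"closure": 0.0, "identity": math.inf, "inverse": math.inf, "associativity": 0.0}
    excluded = 0
    n_pairs = 0
    closure_ok = True

    def sig_dist(a, b) -> float:
        return float(np.max(np.abs(tset._signature(a) - tset._signature(b)), initial=0.0))

    composed = {}
    for i, j in itertools.product(range(len(els)), repeat=2):
        n_pairs += 1
        try:
            c = tset.compose(els[i], els[j])
        except Exception:
            closure_ok = False
            worst["closure"] = math.inf
            continue
        if tset.in_window is not None and not tset.in_window(c):
            excluded += 1
            continue
        composed[(i, j)] = c
        k = tset.find_equal(c, tol)
        if k is None:
            closure_ok = False
            dev = min(sig_dist(c, e) for e in els)
            worst["closure"] = max(worst["closure"], dev)

    # identity: some element acting as identity on the probes
    identity_idx = None
    for j, e in enumerate(els):
        dev = max(
            (float(np.max(np.abs(np.ravel(np.asarray(tset.act(e, p), dtype=float))
                                 - np.ravel(np.asarray(p, dtype=float))), initial=0.0))
             for p in tset.probes),
            default=math.inf,
        )
        if dev < worst["identity"]:
            worst["identity"] = dev
            if dev <= tol:
                identity_idx = j
    identity_ok = identity_idx is not None

    # inverse: for each element, some sampled element undoing it on the probes
    inverse_ok = identity_ok
    if identity_ok:
        ident = els[identity_idx]
        for e in els:
            best = math.inf
            for f in els:
                try:
                    c = tset.compose(e, f)
                except Exception:
                    continue
                best = min(best, sig_dist(c, ident))
            worst["inverse"] = min(worst["inverse"], math.inf) if best is math.inf else best
            if best > tol:
                inverse_ok = False
                worst["inverse"] = max(best, 0.0 if worst["inverse"] is math.inf else worst["inverse"])
                break
        else:
            worst["inverse"] = 0.0 if worst["inverse"] is math.inf else worst["inverse"]

    # associativity on sampled triples (capped for cost)
    assoc_ok = True
    triples = list(itertools.product(range(len(els)), repeat=3))[:200]
    for i, j, k in triples:
        try:
            left = tset.compose(tset.compose(els[i], els[j]), els[k])
            right = tset.compose(els[i], tset.compose(els[j], els[k]))
        except Exception:
            continue
        if tset.in_window is not None and not (tset.in_window(left) and tset.in_window(right)):
            continue
        dev = sig_dist(left, right)
        worst["associativity"] = max(worst["associativity"], dev)
        if dev > tol:
            assoc_ok = False

    worst = {k: (None if v is math.inf else v) for k, v in worst.items()}
    return AxiomReport(closure_ok, identity_ok, inverse_ok, assoc_ok, worst,
                       len(els), n_pairs, excluded)


def invariant_deviation(tset: TransformationSet, feature: Callable, instances: Sequence) -> float:
    """Max ``|feature(T(x)) - feature(x)|`` over sampled transforms and instances.

    A value ~0 certifies invariance of the feature on the sample; a large
    value quantifies how badly the feature fails to be invariant.
    """
    if len(instances) == 0:
        raise ValueError("empty instance list")
    worst = 0.0
    for x in instances:
        base = float(feature(x))
        for t in tset.elements:
            worst = max(worst, abs(float(feature(tset.act(t, x))) - base))
    return worst


def law_transform_commutator(evolve: Callable, transform: Callable, state) -> float:
    """Deviation ``||N(Θ(u)) - Θ(N(u))||`` of a law N from commuting with Θ.

    Zero (to numerical tolerance) certifies that Θ is a symmetry of the law
    at this state: the transformed experiment gives the transformed result.
    """
    u = np.asarray(state, dtype=float)
    a = np.asarray(evolve(transform(u)), dtype=float)
    b = np.asarray(transform(np.asarray(evolve(u), dtype=float)), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch between N(Θ(u)) {a.shape} and Θ(N(u)) {b.shape}")
    return float(np.linalg.norm(a - b))


def inverse_square_fall(period_s: float, radius_m: float, distance_ratio: float) -> tuple[float, float]:
    """One-second fall of a circularly orbiting body, and its inverse-square
    rescaling to a distance closer by ``distance_ratio``.

    For a circular orbit of period T and radius r the centripetal
    acceleration is ``(2π/T)² r``, so in one second the body falls
    ``½ (2π/T)² r`` below its tangent line.  Under an inverse-square force,
    gravity ``distance_ratio`` times closer is ``distance_ratio²`` stronger,
    so the predicted one-second fall there is the orbital fall times the
    squared ratio.

    Returns ``(fall_at_orbit, fall_scaled)`` in meters per 1 s.
    """
    if period_s <= 0 or radius_m <= 0 or distance_ratio <= 0:
        raise ValueError("period, radius and distance ratio must be positive")
    omega = 2.0 * math.pi / period_s
    fall_at_orbit = 0.5 * omega**2 * radius_m * FALL_INTERVAL_S**2
    return fall_at_orbit, fall_at_orbit * distance_ratio**2


def moon_fall_example() -> tuple[float, float]:
    """The Moon/Earth worked example with standard lunar constants:
    sidereal period 27.3 days, orbital radius 3.84e8 m, distance ratio 60.
    """
    return inverse_square_fall(27.3 * DAY_SECONDS, 3.84e8, 60.0)
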