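"""Synthetic 16-vertex stimuli for the shape-constancy experiment.

Six stimulus classes, mirroring the classic same/different shape
discrimination design:

  A  symmetric polyhedron with planar lateral structure (each half of the
     vertex set is coplanar);
  B  the vertices of an A-type object with all edges removed;
  C  a polygonal line: A-type vertices connected in seeded random order,
     destroying the symmetry correspondence carried by the structure;
  D  symmetric but partially non-planar (halves are not coplanar);
  E  planar and asymmetric: one half of a larger A-type object;
  F  non-planar and asymmetric.

All stimuli are generated in an object frame whose symmetry plane (when
one exists) is x = 0, with vertices in a unit-scale box.  The vertex pair
structure that the object's connectivity makes visible to an observer is
recorded in ``pairs``: for symmetric classes these are the true mirror
pairs; for C they are pairs of consecutive vertices along the random
polyline (an asymmetric pairing of a symmetric vertex *set*); for E and F
they are nominal pairings with no consistent mirror interpretation.
Generation is deterministic per (class, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STIMULUS_CLASSES = ("A", "B", "C", "D", "E", "F")
N_VERTICES = 16


@dataclass
class Stimulus:
    """A 16-vertex object plus the pair structure its connectivity exposes."""

    stimulus_class: str
    vertices: np.ndarray           # (16, 3)
    pairs: np.ndarray              # (8, 2) vertex index pairs
    edges: list = field(default_factory=list)  # index pairs, [] for class B
    seed: int = 0

    @property
    def paired_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices[self.pairs[:, 0]], self.vertices[self.pairs[:, 1]]


def _planar_half(rng: np.random.Generator, n: int) -> np.ndarray:
    """n points with x > 0, coplanar within a random tilted plane."""
    # in-plane coordinates, then embed in a random plane with nonzero x offset
    uv = rng.uniform(-1.0, 1.0, (n, 2))
    origin = np.array([rng.uniform(0.55, 0.85), 0.0, 0.0])
    # small x-components keep every point clear of the symmetry plane x = 0
    e1 = np.array([rng.uniform(-0.15, 0.15), 1.0, 0.0])
    e2 = np.array([rng.uniform(-0.15, 0.15), 0.0, 1.0])
    return origin + uv[:, :1] * e1 + uv[:, 1:] * e2


def _nonplanar_half(rng: np.random.Generator, n: int) -> np.ndarray:
    """n points with x > 0, in general (non-coplanar) position."""
    pts = np.empty((n, 3))
    pts[:, 0] = rng.uniform(0.25, 1.0, n)
    pts[:, 1] = rng.uniform(-1.0, 1.0, n)
    pts[:, 2] = rng.uniform(-1.0, 1.0, n)
    return pts


def _mirror_pairs(half: np.ndarray):
    """Stack a half with its x = 0 mirror image; return vertices and pair index."""
    n = half.shape[0]
    mirrored = half.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    vertices = np.vstack([half, mirrored])
    pairs = np.column_stack([np.arange(n), np.arange(n) + n])
    return vertices, pairs


def _ring_edges(n_half: int) -> list:
    """Edges of a simple polyhedral frame: a ring around each half plus the
    rungs joining mirror mates."""
    edges = []
    for i in range(n_half):
        edges.append((i, (i + 1) % n_half))
        edges.append((i + n_half, (i + 1) % n_half + n_half))
        edges.append((i, i + n_half))
    return edges


def generate_stimulus(stimulus_class: str, seed: int) -> Stimulus:
    """Deterministic 16-vertex stimulus of the requested class."""
    if stimulus_class not in STIMULUS_CLASSES:
        raise ValueError(f"unknown stimulus class {stimulus_class!r}; "
                         f"expected one of {STIMULUS_CLASSES}")
    rng = np.random.default_rng(seed)
    n_half = N_VERTICES // 2

    if stimulus_class in ("A", "B", "C"):
        half = _planar_half(rng, n_half)
        vertices, pairs = _mirror_pairs(half)
        if stimulus_class == "A":
            edges = _ring_edges(n_half)
        elif stimulus_class == "B":
            edges = []
        else:  # C: random polyline through the same kind of vertex set
            order = rng.permutation(N_VERTICES)
            vertices = vertices[order]
            edges = [(i, i + 1) for i in range(N_VERTICES - 1)]
            # the pairing suggested by the polyline: consecutive vertices
            pairs = np.arange(N_VERTICES).reshape(n_half, 2)
        return Stimulus(stimulus_class, vertices, pairs, edges, seed)

    if stimulus_class == "D":
        half = _nonplanar_half(rng, n_half)
        vertices, pairs = _mirror_pairs(half)
        return Stimulus("D", vertices, pairs, _ring_edges(n_half), seed)

    if stimulus_class == "E":
        # one half of a 32-vertex planar symmetric object: 16 vertices, all x > 0
        big_half = _planar_half(rng, N_VERTICES)
        vertices = big_half
        pairs = np.arange(N_VERTICES).reshape(n_half, 2)
        edges = [(i, (i + 1) % N_VERTICES) for i in range(N_VERTICES)]
        return Stimulus("E", vertices, pairs, edges, seed)

    # F: non-planar asymmetric — symmetric scaffold destroyed by independent
    # per-vertex displacement
    half = _nonplanar_half(rng, n_half)
    vertices, pairs = _mirror_pairs(half)
    vertices = vertices + rng.uniform(-0.35, 0.35, vertices.shape)
    return Stimulus("F", vertices, pairs, _ring_edges(n_half), seed)


def is_symmetric_class(stimulus_class: str) -> bool:
    return stimulus_class in ("A", "B", "D")


def random_symmetric_pairs(n_pairs: int, rng: np.random.Generator,
                           depth: float = 3.0, size: float = 1.0,
                           max_tilt: float = 0.9):
    """Random mirror-symmetric 3D point pairs in camera-frame position.

    Places midpoints on a random symmetry plane whose normal is tilted away
    from the optical axis (so the vanishing point is finite), at depths
    around ``-depth``, with chord half-lengths of order ``size``.  Returns
    ``(P, Q, plane_normal, plane_offset)`` with the plane in the form
    n·x + d = 0, |n| = 1.
    """
    from .geometry import Plane3D  # local import to avoid cycles at module load

    # normal with a guaranteed z component and a substantial transverse part
    tilt = rng.uniform(0.25, max_tilt)  # angle magnitude of transverse part
    azim = rng.uniform(0, 2 * np.pi)
    n = np.array([np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim), np.cos(tilt)])
    center = np.array([0.0, 0.0, -depth])
    d = -float(n @ center)
    plane = Plane3D.from_coefficients(n[0], n[1], n[2], d)
    # in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    uv = rng.uniform(-0.5 * size, 0.5 * size, (n_pairs, 2))
    mid = center + uv[:, :1] * e1 + uv[:, 1:] * e2
    t = rng.uniform(0.15 * size, 0.6 * size, n_pairs)
    P = mid + t[:, None] * n
    Q = mid - t[:, None] * n
    return P, Q, plane
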