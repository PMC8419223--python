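"""Shared fixtures: seeded RNGs, random symmetric scenes, and the
ray-intersection oracle used to validate the closed-form recovery."""

import numpy as np
import pytest

from mirrorshape.geometry import Camera, project_perspective
from mirrorshape.recovery import ImageCorrespondenceSet, canonical_plane_parameters
from mirrorshape.stimuli import random_symmetric_pairs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def symmetric_scene(rng):
    """Factory: a random mirror-symmetric 3D scene, its projection and the
    true canonical-frame recovery parameters."""

    def make(n_pairs=8, z_F=2.0, noise=0.0, local_rng=None):
        r = local_rng if local_rng is not None else rng
        camera = Camera(z_F)
        P, Q, plane = random_symmetric_pairs(n_pairs, r)
        x_v, d_c, theta = canonical_plane_parameters(plane, camera)
        p = project_perspective(P, camera)
        q = project_perspective(Q, camera)
        if noise > 0:
            p = p + r.normal(0, noise, p.shape)
            q = q + r.normal(0, noise, q.shape)
        corr = ImageCorrespondenceSet(p, q, camera)
        return {"P": P, "Q": Q, "plane": plane, "camera": camera,
                "corr": corr, "x_v": x_v, "d_c": d_c, "theta": theta}

    return make


def ray_mirror_oracle(p, q, camera, plane):
    """Independent geometric recovery: intersect the two projecting rays with
    the mirror constraint by solving a small linear system per pair.

    Unknowns per pair: ray parameters t_p, t_q and the chord half-length s
    in  P = F + t_p (p̂ - F),  Q = F + t_q (q̂ - F),  P - Q = s n,
    midpoint on the plane.  Four linear equations, three unknowns,
    consistent exactly when the image pair is the projection of a mirror
    pair.  Entirely independent of the closed-form depth formulas.
    """
    F = camera.center
    n = plane.normal
    d = plane.d
    P_out = np.empty((len(p), 3))
    Q_out = np.empty((len(p), 3))
    for i in range(len(p)):
        ph = np.array([p[i][0], p[i][1], 0.0])
        qh = np.array([q[i][0], q[i][1], 0.0])
        dp = ph - F
        dq = qh - F
        A = np.zeros((4, 3))
        b = np.zeros(4)
        # P - Q - s n = 0
        A[:3, 0] = dp
        A[:3, 1] = -dq
        A[:3, 2] = -n
        # n . midpoint + d = 0
        A[3, 0] = 0.5 * (n @ dp)
        A[3, 1] = 0.5 * (n @ dq)
        b[3] = -(n @ F) - d
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        t_p, t_q, _s = sol
        P_out[i] = F + t_p * dp
        Q_out[i] = F + t_q * dq
    return P_out, Q_out
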