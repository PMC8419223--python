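"""The cost-functional view of 3D recovery: E(X) = ||A(X)-Y|| + λ||P(X)||.

A noisy image is interpreted by minimizing reprojection error plus a
weighted asymmetry penalty.  With the weight matched to the noise
variances the minimizer is the MAP estimate; the printout compares the raw
closed-form construction on the noisy points with the regularized
minimizer against the ground truth.
"""

import logging

import numpy as np

logging.basicConfig(level=logging.ERROR)  # quiet the forced-recovery notice

from mirrorshape import (Camera, EnergyModel, ImageCorrespondenceSet,
                         lambda_from_sigmas, minimize_energy,
                         project_perspective, recover_shape,
                         similarity_procrustes_distance)
from mirrorshape.stimuli import random_symmetric_pairs

rng = np.random.default_rng(3)
camera = Camera(2.0)
sigma = 0.005

P, Q, _ = random_symmetric_pairs(8, rng)
p = project_perspective(P, camera) + rng.normal(0, sigma, (8, 2))
q = project_perspective(Q, camera) + rng.normal(0, sigma, (8, 2))
image = ImageCorrespondenceSet(p, q, camera)

closed = recover_shape(image, force=True)
lam = lambda_from_sigmas(sigma, 0.05)
model = EnergyModel(image, lam=lam)
refined = minimize_energy(model, init=closed, n_restarts=1)

truth = np.vstack([P, Q])
err_closed = similarity_procrustes_distance(truth, closed.points)
err_refined = similarity_procrustes_distance(truth, np.vstack([refined.P, refined.Q]))

print(f"image noise sigma = {sigma}, constraint weight lambda = {lam:.3g}")
print(f"closed form on noisy points : shape error {err_closed:.4f}")
print(f"energy minimizer (MAP)      : shape error {err_refined:.4f}")
print(f"final energy {refined.energy:.3g} "
      f"(reprojection {refined.reprojection:.3g}, penalty {refined.penalty:.3g})")
print("The symmetry prior regularizes the noisy inverse problem: the MAP")
print("interpretation is closer to the true 3D shape than the raw construction.")
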