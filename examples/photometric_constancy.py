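"""Lightness and color constancy: ratio invariance and von Kries gains.

The lightness ratio of two surfaces cancels the illuminant exactly, which
is why chalk looks brighter than coal under moonlight and sunlight alike.
Spectrally, when reflectances lie in a matched 3-dimensional linear model,
an illuminant change acts on cone absorptions as an exact channel-wise
(von Kries) rescaling; outside the model the diagonal fit leaves a
residual.
"""

import numpy as np

from mirrorshape import (blackbody_spectrum, cone_absorptions,
                         fit_von_kries_gains, lightness_ratio,
                         von_kries_exact_basis)
from mirrorshape.photometry import reflectance_basis, reflectances_in_linear_model

# scalar lightness: the ratio invariant
for ill in (1.0, 1e6):
    r = lightness_ratio(0.9, 0.05, ill)
    print(f"chalk (0.9) vs coal (0.05) under illuminant {ill:g}: ratio = {r:g}")

# spectral color: two daylight-like (blackbody) illuminants
rng = np.random.default_rng(5)
e1, e2 = blackbody_spectrum(5000.0), blackbody_spectrum(8000.0)
basis, gains = von_kries_exact_basis(e1, e2)
w = np.column_stack([rng.uniform(0.35, 0.55, 6),
                     rng.uniform(-0.04, 0.04, 6), rng.uniform(-0.04, 0.04, 6)])
inside = reflectances_in_linear_model(w, basis)
a1 = np.array([cone_absorptions(e1, s) for s in inside])
a2 = np.array([cone_absorptions(e2, s) for s in inside])
fit, res_in = fit_von_kries_gains(a1, a2)
print(f"matched 3-basis reflectances: gains {np.round(fit, 4)}, residual {res_in:.2g}")

w2 = np.column_stack([rng.uniform(0.35, 0.55, 6),
                      rng.uniform(-0.15, 0.15, 6), rng.uniform(-0.15, 0.15, 6)])
outside = reflectances_in_linear_model(w2, reflectance_basis(3))
b1 = np.array([cone_absorptions(e1, s) for s in outside])
b2 = np.array([cone_absorptions(e2, s) for s in outside])
_, res_out = fit_von_kries_gains(b1, b2)
print(f"generic reflectances: diagonal-fit residual {res_out:.2g} (model violated)")
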