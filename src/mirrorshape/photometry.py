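"""Lightness and color constancy models.

The scalar (Lambertian) lightness model: reflected light is the product of
illuminant intensity and surface albedo, ``L_R = L_I · S``.  Illumination
acts as a multiplicative group on reflected light, so the ratio of the
light reflected from two surfaces is an invariant — it equals the albedo
ratio regardless of illumination level (chalk looks brighter than coal
under moonlight and sunlight alike).

The spectral generalization: reflectance S(λ) sampled on 400–700 nm,
daylight-like illuminants modelled as Planck blackbody spectra, and three
cone channels.  When reflectances live in a 3-dimensional linear model,
the change of cone absorptions between two illuminants is *exactly* a
diagonal (von Kries) gain: each cone channel is independently rescaled.
Outside the 3-basis model the diagonal map is only approximate and the fit
residual is reported.

The shipped cone fundamentals are synthetic Gaussian sensitivity curves
(three fixed positive, linearly independent functions); they are a stand-in
basis, not measured human fundamentals.
"""

from __future__ import annotations

import numpy as np

#: spectral sampling grid, nm
WAVELENGTHS = np.arange(400.0, 701.0, 10.0)  # 31 samples

# Planck constants (SI)
_H = 6.62607015e-34
_C = 2.99792458e8
_KB = 1.380649e-23


def synthetic_cone_fundamentals(grid: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Three Gaussian sensitivity curves peaking at 440, 540, 570 nm.

    Shape (3, n_wavelengths); positive and linearly independent.  Synthetic
    placeholders for L/M/S-like channels.
    """
    peaks = np.array([570.0, 540.0, 440.0])
    widths = np.array([50.0, 45.0, 35.0])
    return np.exp(-0.5 * ((grid[None, :] - peaks[:, None]) / widths[:, None]) ** 2)


def blackbody_spectrum(temperature_k: float, grid: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Planck spectral radiance at the given temperature, normalized to unit mean.

    Daylight illuminants are well approximated by blackbody radiation over
    roughly 4000–10000 K; the normalization discards absolute intensity,
    which the constancy models treat separately.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    lam = grid * 1e-9
    spectral = (2 * _H * _C**2 / lam**5) / np.expm1(_H * _C / (lam * _KB * temperature_k))
    return spectral / spectral.mean()


def reflected_light(illuminant, albedo):
    """L_R = L_I · S, pointwise for spectra or scalars.

    Scalar albedo must lie in [0, 1]; spectral reflectance likewise per
    wavelength.  Illuminant must be non-negative.
    """
    L = np.asarray(illuminant, dtype=float)
    S = np.asarray(albedo, dtype=float)
    if np.any(L < 0):
        raise ValueError("illuminant intensity must be non-negative")
    if np.any(S < 0) or np.any(S > 1):
        raise ValueError("albedo/reflectance must lie in [0, 1]")
    out = L * S
    return float(out) if out.ndim == 0 else out


def lightness_ratio(albedo_a, albedo_b, illuminant) -> float:
    """Ratio of reflected light from two surfaces under a shared illuminant.

    Equals S_A / S_B exactly, independent of the illuminant intensity —
    the invariant of the illumination-scaling group.
    """
    la = np.sum(reflected_light(illuminant, albedo_a))
    lb = np.sum(reflected_light(illuminant, albedo_b))
    if lb == 0:
        raise ZeroDivisionError("reference surface reflects no light")
    return float(la / lb)


def cone_absorptions(illuminant_spectrum, reflectance_spectrum,
                     fundamentals: np.ndarray | None = None) -> np.ndarray:
    """Three cone absorption values: ∫ cone(λ) L(λ) S(λ) dλ (rectangle rule)."""
    if fundamentals is None:
        fundamentals = synthetic_cone_fundamentals()
    lr = reflected_light(illuminant_spectrum, reflectance_spectrum)
    return fundamentals @ np.asarray(lr, dtype=float)


def von_kries_adapt(absorptions, gains) -> np.ndarray:
    """Channel-wise rescaling of cone absorptions: the diagonal adaptation map."""
    a = np.atleast_2d(np.asarray(absorptions, dtype=float))
    g = np.asarray(gains, dtype=float)
    if g.shape != (3,):
        raise ValueError("need exactly 3 channel gains")
    if np.any(g <= 0):
        raise ValueError("gains must be positive")
    out = a * g[None, :]
    return out[0] if np.asarray(absorptions).ndim == 1 else out


def fit_von_kries_gains(absorptions_ill1, absorptions_ill2) -> tuple[np.ndarray, float]:
    """Least-squares diagonal gains mapping absorptions under illuminant 1 to
    those under illuminant 2, and the RMS relative residual of the fit.

    A ~0 residual certifies that a single von Kries gain triple explains
    the illuminant change for all patches — exact when reflectances lie in
    a 3-dimensional linear model under the two illuminants.
    """
    a1 = np.atleast_2d(np.asarray(absorptions_ill1, dtype=float))
    a2 = np.atleast_2d(np.asarray(absorptions_ill2, dtype=float))
    if a1.shape != a2.shape or a1.shape[1] != 3:
        raise ValueError("absorption arrays must be matching (n, 3)")
    denom = np.sum(a1 * a1, axis=0)
    if np.any(denom == 0):
        raise ValueError("degenerate fit: a cone channel absorbs nothing")
    gains = np.sum(a1 * a2, axis=0) / denom
    if np.any(gains <= 0):
        raise ValueError("degenerate fit produced non-positive gains")
    pred = a1 * gains[None, :]
    scale = np.linalg.norm(a2)
    residual = float(np.linalg.norm(pred - a2) / scale) if scale > 0 else 0.0
    return gains, residual


def reflectance_basis(n_basis: int = 3, grid: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Smooth synthetic reflectance basis functions (low-order cosines in
    wavelength), shape (n_basis, n_wavelengths)."""
    x = (grid - grid[0]) / (grid[-1] - grid[0])
    return np.array([np.cos(np.pi * k * x) for k in range(n_basis)])


def von_kries_exact_basis(ill1, ill2, fundamentals: np.ndarray | None = None,
                          gains=None) -> tuple[np.ndarray, np.ndarray]:
    """A 3-function reflectance basis for which von Kries holds *exactly*
    between two illuminants, together with the exact gain triple.

    Under a linear reflectance model the illuminant change acts linearly on
    cone absorptions; it is diagonal (independent channel scaling) exactly
    when every reflectance S satisfies, for each cone c with gain g_c,

        Σ_λ cone_c(λ) · (E2(λ) − g_c E1(λ)) · S(λ) = 0.

    These are three linear constraints on the 31-sample spectrum, so their
    null space is 28-dimensional; this function returns three smooth,
    linearly independent members of it (projections of a constant and two
    low-order cosines).  Reflectances built from this basis transform with
    the returned diagonal gains with zero residual; generic reflectances
    outside it do not.  Default gains are the per-channel illuminant
    absorption ratios.
    """
    E1 = np.asarray(ill1, dtype=float)
    E2 = np.asarray(ill2, dtype=float)
    if fundamentals is None:
        fundamentals = synthetic_cone_fundamentals()
    if gains is None:
        gains = (fundamentals @ E2) / (fundamentals @ E1)
    gains = np.asarray(gains, dtype=float)
    # constraint rows: cone_c ⊙ (E2 - g_c E1)
    C = fundamentals * (E2[None, :] - gains[:, None] * E1[None, :])
    # orthonormal basis of the null space of C
    _, s, Vt = np.linalg.svd(C)
    null = Vt[3:]
    x = np.linspace(0.0, 1.0, E1.shape[0])
    seeds = np.array([np.ones_like(x), np.cos(np.pi * x), np.cos(2 * np.pi * x)])
    basis = seeds @ null.T @ null  # project smooth seeds into the null space
    rank = np.linalg.matrix_rank(basis, tol=1e-10)
    if rank < 3:
        raise RuntimeError("constructed basis is degenerate for these illuminants")
    return basis, gains


def reflectances_in_linear_model(weights, basis: np.ndarray | None = None) -> np.ndarray:
    """Build reflectance spectra Σ w_k b_k(λ), clipped into [0, 1] only by
    validation (raises if the combination leaves the physical range)."""
    if basis is None:
        basis = reflectance_basis()
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    spectra = w @ basis
    if np.any(spectra < 0) or np.any(spectra > 1):
        raise ValueError("weights produce reflectance outside [0, 1]")
    return spectra
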