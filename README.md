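# mirrorshape

Recovering 3D shape from a single 2D perspective image is an ill-posed
inverse problem: perspective projection discards depth, has no inverse,
and therefore admits no invariants.  `mirrorshape` implements the
constraint that makes the problem well-posed for most natural objects —
**mirror symmetry** — together with the surrounding formal toolkit that
places shape perception alongside variational mechanics: a cost-functional
(energy/MAP) formulation, numerical least-action and Noether conservation
checks, transformation-group diagnostics, photometric constancy models,
and a model-observer shape-constancy experiment analyzed with signal
detection theory.

It is a library for computational vision researchers and for anyone
teaching or studying the symmetry → least-action → conservation chain in
the context of perception.

## The core construction

Put the image plane at `z = 0` with the projection center at
`F = (0, 0, z_F)`.  A mirror-symmetric pair (P_i, Q_i) is joined by a
chord perpendicular to the symmetry plane; all chords are parallel in 3D,
so their images converge at a vanishing point `v = (x_v, 0)` (after an
image rotation that the library applies and undoes automatically).  The
symmetry plane is

    -(x_v / z_F) x + z + d_c = 0,

its vanishing line is the vertical image line `x_h = -z_F² / x_v`, and the
image m_i of the 3D midpoint of each pair sits at the **harmonic mean** of
the two image radii measured from v:

    h_i = 2 r_φ r_ψ / (r_φ + r_ψ).

Depths then follow in closed form,

    z_Φi = z_F + 2 r_ψ (z_F + d_c) x_h / [(r_φ + r_ψ)(x_mi − x_h)],
    z_Ψi = z_F + 2 r_φ (z_F + d_c) x_h / [(r_φ + r_ψ)(x_mi − x_h)],

leaving a single free scalar d_c: one monocular view determines a
symmetric shape exactly, up to a similarity transform.  The same
interpretation is the minimizer of the cost functional

    E(X) = ‖A(X) − Y‖ + λ ‖P(X)‖,

where A is perspective projection, Y the observed image and P the
departure of X from perfect symmetry; under squared norms the minimizer is
the MAP estimate with λ equal to the noise/prior variance ratio.  The
orthographic case is the limit z_F → ∞.

## Worked example

```
$ python examples/recover_symmetric_shape.py
vanishing point x_v = 1.5651, vanishing line x_h = -2.5557
depth parameter d_c = 3.0000 (true value supplied)
max 3D vertex error: 1.33e-15
The error is at float precision: one 2D view plus the mirror-symmetry
constraint determines the 3D shape up to the single scalar d_c.
shape difference between d_c and 2 d_c recoveries: 2.07e-15 (pure scale family)
```

A random 16-vertex mirror-symmetric object is projected through a camera
with `z_F = 2` and recovered from that single image.  The vertex error at
float precision shows the closed form is exact on noiseless data; the last
line shows that changing d_c moves the recovery within a pure similarity
family — "shape", the invariant of rigid motion plus uniform scaling, is
fully determined.

The other scripts in `examples/` each demonstrate one capability:
`energy_map_recovery.py` (regularized recovery from noisy images),
`least_action_noether.py` (action stationarity and conservation drifts),
`group_axioms_and_invariance.py` (sampled group checks; the inverse-square
fall example), `photometric_constancy.py` (lightness ratios, von Kries
gains), `shape_constancy_experiment.py` (the full d′ table across six
stimulus classes).

A thin CLI mirrors the library: `mirrorshape simulate`, `recover`,
`groups check`, `noether-demo`, `photometric`, `experiment`, `moon-fall`
(see `mirrorshape --help`).

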