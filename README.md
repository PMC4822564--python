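# diffrefine

Diffraction-geometry (centroid) refinement for rotation-method
crystallography: predict Bragg-reflection centroids (X, Y, φ) from
generalized beam / goniometer / detector / crystal models, and refine those
models against observed centroids by robust, weighted nonlinear least
squares.

The package is aimed at people developing or studying data-reduction methods
for single-crystal rotation experiments: it provides the full refinement
stack — geometric prediction, model parameterisation, outlier rejection,
minimization and error propagation — as an importable library with a thin
command-line layer, plus a synthetic test-bed so every component can be
exercised without any experimental data.

## The model

A reflection with integer indices **h** is excited when its rotated
reciprocal-lattice vector touches the Ewald sphere,

    r_φ = R(ĝ, φ) U B h,        |s0 + r_φ| = |s0| ,

where **s0** is the incident wavevector (|s0| = 1/λ), ĝ the rotation axis,
**U** the crystal orientation and **B** = (a\*|b\*|c\*) the reciprocal-space
orthogonalization matrix.  The diffracted ray s1 = s0 + r_φ meets a detector
panel, described by the matrix d = (d̂₁|d̂₂|d₀), at millimetre coordinates
(X, Y) obtained from the homogeneous projection (u, v, w)ᵀ = d⁻¹ s1,
X = u/w, Y = v/w.  Refinement minimizes

    L = Σᵢ [ w_X r_X² + w_Y r_Y² + w_φ r_φ² ]ᵢ ,

the inverse-variance-weighted squared residuals between calculated and
observed centroids, over the parameters of:

* the beam (two rotations μ₁, μ₂ and the wavenumber ν = |s0|; μ₁ and ν are
  conventionally fixed),
* the crystal orientation (three missets φ₁, φ₂, φ₃ about the laboratory
  axes applied to the datum U₀),
* the crystal cell (the symmetry-free elements of the reciprocal metrical
  matrix G* = BᵀB, so lattice constraints hold exactly by construction),
* the detector (distance p₀ along the initial normal, in-plane shifts t₁,
  t₂, orientation τ₁, τ₂, τ₃), one rigid body per detector.

Gradients are analytic, via the implicit Ewald condition; reflections close
to the rotation axis, where ∂φ/∂p diverges with the Lorentz factor, are
removed by a triple-product filter (default cutoff 0.05).  Gross outliers
are rejected once, before final minimization, by Tukey fences or by
Mahalanobis distances from a FAST-MCD robust covariance (default: the 97.5%
χ²₃ quantile).  The default minimizer is Levenberg–Marquardt; Gauss–Newton
and L-BFGS are provided behind the same interface.  Crystal parameters can
vary smoothly with scan angle through a Gaussian smoother (36° default
interval, three-point averaging, adjacent weights at 13% of the peak), and
several experiments can be refined jointly when they share models — e.g.
multi-lattice data sharing one beam and detector — with sparse handling of
the block-structured Jacobian.  After convergence, inverting the normal
matrix JᵀWJ gives parameter covariances, which propagate to estimated
standard deviations of the real-space cell parameters.

## Worked example

```python
import numpy as np
from diffrefine import refine, predict_static
from diffrefine.synthetic import (
    SimulationConfig, PerturbationMagnitudes,
    make_experiment, simulate_observations, perturb,
)

cfg = SimulationConfig()            # tetragonal 57.7/150 A crystal, 30 deg scan
truth = make_experiment(cfg)
obs = simulate_observations(truth, cfg)          # noisy centroids, known variances
start = perturb(truth, PerturbationMagnitudes(
    detector_shift_mm=0.5, detector_tilt_deg=0.1,
    misset_deg=0.05, cell_strain=0.002), seed=42)

result, working, pmap = refine(start, obs, seed=1)
for h in result.history:
    print(h["step"], round(h["L"], 1), round(h["rmsd_x_mm"], 4),
          round(h["rmsd_y_mm"], 4), round(h["rmsd_phi_deg"], 5))
print("refined cell:", np.round(start.crystal.real_cell, 4))
```

prints (for these seeds)

```
0 21734.1 0.0485 0.0476 0.0191
1 21731.6 0.0485 0.0476 0.0191
2 21731.6 0.0485 0.0476 0.0191
refined cell: [ 57.6987  57.6987 149.9983  90.      90.      90.    ]
```

The first line is the state after the outlier-rejection prefit; the r.m.s.
deviations sit at the simulated noise floor (0.05 mm, 0.02°), and the
refined cell matches the 57.7 / 150.0 Å truth to a few parts in 10⁵ — the
0.5 mm detector shift, 0.1° tilts, 0.05° missets and 0.2% cell strain of the
starting model have been fitted out.

The same workflow is available from the shell:

```sh
diffrefine simulate --preset static --seed 3 --out-dir sim
diffrefine refine sim/experiment.json sim/reflections.csv --out-dir refined
diffrefine errors refined/refined_experiment.json refined/refined_reflections.csv
```

All files are plain JSON / CSV (degrees and 1-based image numbers in files;
radians and millimetres internally).

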