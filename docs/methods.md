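# Methods

This note records the model, the numerical choices and the limits of what
the test suite demonstrates.  It is written for someone who wants to trust —
or challenge — the package's results.

## Geometry and prediction

All geometry is expressed in arbitrary laboratory-frame vectors; nothing
depends on an idealized instrument orientation.  The default frame used by
the synthetic generator follows the imgCIF convention: rotation axis along
x̂, ẑ from the sample toward the source (beam direction (0, 0, −1)), ŷ
completing a right-handed set.  Frame independence is tested by applying a
random global rotation to every model vector and checking that predictions
are unchanged to 1e−8.

For a static crystal the diffraction condition |s0 + R(ĝ, φ) r₀| = |s0| is
reduced, via the Rodrigues expansion, to A cos φ + B sin φ = C, giving up to
two crossing angles per reciprocal-lattice point per turn; the sign of the
derivative of the sphere-distance function classifies each crossing as
entering or exiting.  Solutions are unwound by integer turns so a continuous
multi-turn scan (e.g. 720°) predicts each reflection once per turn.  A
tangential touch (discriminant below 1e−12) is reported as a single exiting
crossing.  Candidate indices are enumerated exhaustively inside the
resolution sphere |UBh| ≤ 1/d_min; at the problem sizes this package targets
(10³–10⁵ candidates) the exhaustive enumeration plus a per-image proximity
margin replaces shell-walking candidate generators with no measurable cost.

For a crystal whose orientation and cell vary with scan angle, prediction of
*unobserved* reflections walks the scan image by image: the reciprocal-space
path between consecutive image boundaries is approximated by the straight
chord Δr = r_{k+1} − r_k, a boundary sign change of the sphere distance
flags a crossing, and the fractional position β within the image solves
|s0 + r_k + βΔr|² = |s0|².  The chord error is O(Δφ²): with 0.1–0.5° images
it is orders of magnitude below centroid noise (verified against static
prediction with constant states: ≤ 0.01 image / 0.01 mm).  If both quadratic
roots fall inside one image (possible only without a boundary sign change)
both rows are kept and a warning is issued.

During *refinement*, each observed reflection already has an image number,
so the crystal state for that reflection is taken from the smoother at the
image boundary nearest the observed centroid and the crossing is re-solved
exactly with that fixed state, on the turn nearest the observation and with
the recorded entering flag.  States are cached per image; because the
smoother interval (36° default) is two orders of magnitude wider than an
image, quantizing the evaluation position to the nearest boundary changes
the state by a negligible amount while making the per-iteration cost linear
in the number of images, not reflections.

## Parameterisation

Parameters act along axes frozen from the initial model geometry (beam
rotation axes, detector frame), so refined states — not raw parameter values
— are the meaningful output and the algorithm is indifferent to the
laboratory-frame choice.  The cell is parameterised by the symmetry-free
elements of the reciprocal metrical matrix; the seven crystal systems are
implemented as explicit element ties (e.g. tetragonal g22 := g11,
off-diagonals zero; trigonal/hexagonal in the hexagonal setting with
g12 := g11/2).  This replaces full space-group machinery: the ties capture
exactly the refinement-relevant constraints (tied lengths, fixed angles).
A non-conventional (non-upper-triangular) input B is accommodated by
freezing its rotation from the conventional B at initialisation.

Derivatives of s0, U and the detector matrix with respect to their
parameters are analytic (verified against central differences at rtol 1e−6);
derivatives of B with respect to the metrical elements are deterministic
central differences of the composition with a fixed relative step of 1e−7
(the composition runs through a cell/metric round trip for which the
analytic form buys nothing at these problem sizes).  End-to-end, the
Jacobian of the full prediction pipeline matches finite differences at rtol
1e−4 for every parameter type, including scan-varying subparameters.

The Gaussian smoother divides the scan into max(round(range/interval), 1)
intervals (round-half-to-even — the allocation rule only requires spacing
"close to" the requested width) with one sample point per interior boundary
and one half-interval outside each end of the scan.  The Gaussian variance
is tied to the spacing so a neighbouring point's unnormalised weight is 13%
of the peak; values are normalised sums over the three nearest points.  A
720° scan at the default 36° interval therefore carries 22 subparameters per
crystal parameter, and the scan-varying tetragonal configuration refines
6 (detector) + 1 (beam) + 5 × 22 = 117 parameters.

The detector is one rigid body regardless of panel count: a group frame is
frozen from the initial panel geometry (mean normal, first panel's fast
axis, centroid of panel centres) and all panels move with it.  Deeper
hierarchies and per-panel refinement are out of scope.  The goniometer is
not parameterised.  μ₁ and the wavenumber ν are fixed by default (the first
to anchor the frame, the second because it is fully correlated with cell
volume); any parameter can be fixed or freed by configuration.

## Target, weighting and filters

Residuals are (X, Y, φ) per reflection, interleaved; weights are the
inverse observed centroid variances ("statistical", default) or user
constants.  φ and its variance are radians internally; files carry degrees.
Near-axis reflections are filtered on the volume of the parallelepiped of
the *normalised* rotation axis, beam vector and diffracted reciprocal-lattice
vector, with the default cutoff 0.05; normalising all three vectors makes
the cutoff dimensionless and scale-free (the unnormalised variant would
depend on wavelength and resolution).  Random subsampling (e.g. 50
reflections per degree) is available and seeded.

## Minimization and outlier rejection

Levenberg–Marquardt is the default: the damping multiplies the diagonal of
the normal matrix (scale-invariant across mm/rad/Å⁻² parameters), λ starts
at 1e−3 and is divided by 10 on acceptance, multiplied by 10 on rejection.
Termination: relative decrease of L below 1e−7, step norm below 1e−8, or 100
iterations.  Gauss–Newton solves the undamped normal equations (one step on
a linear problem, to machine precision).  L-BFGS consumes only (L, ∇L) with
a diagonal pre-scaling taken from the initial normal-matrix diagonal;
without the scaling the mixed parameter units defeat the line search.  All
three agree to 1e−6 relative in L on the synthetic recovery problem.  For
scan-varying and multi-experiment problems the Jacobian is assembled as
sparse triplets (smoother locality: three nonzero points per base parameter;
experiment blocks: zero columns for other experiments' parameters) and the
normal matrix is formed without storing structural zeros.

Outlier rejection runs once, between an initial minimization and the final
one.  The initial fit matters: the rejection rules model residuals as noise
plus outliers, and residuals computed from an unrefined starting model are
dominated by systematic geometry error, so rejecting on them trims
geometry-correlated tails and measurably biases the result (on the recovery
benchmark, ~0.27× the noise σ of bias versus ~0.04× when rejecting after a
prefit).  In a full processing pipeline the same effect is achieved by the
refinement that precedes outlier rejection during indexing.  Two rules are
provided: per-coordinate Tukey fences (cuboid acceptance region) and
Mahalanobis distances against a FAST-MCD robust location/covariance
(ellipsoidal region; default cutoff the 97.5% χ²₃ quantile).  The MCD
estimate comes from scikit-learn's MinCovDet, which implements the same
FAST-MCD algorithm with consistency and small-sample corrections; its
calibration is asserted behaviourally (2.5% ± 0.5% flag rate on clean normal
residuals, ≥ 95% detection of 10σ contamination, resistance to 40% gross
contamination).  The detector-plane-only (X, Y) rejection method is
recognised by name but deliberately not implemented.

## Error estimates

Parameter covariance is s²(JᵀWJ)⁻¹ with s² = L_min/(m − p).  The variance
factor is applied under statistical weighting too, so miscalibrated input
variances inflate the e.s.d.s consistently; the choice is validated by the
replicate calibration below.  Cell e.s.d.s follow by first-order propagation
through the map from free metrical parameters to real cell parameters, with
gradients by central differences (relative step 1e−8).  No symmetry is
enforced in the propagation: a tetragonal cell yields esd(α) = esd(β) =
esd(γ) = 0 and esd(a) = esd(b) *exactly* because the constrained directions
have identically zero gradient.  Correlation matrices between weighted
Jacobian columns are computed from sufficient statistics (works for sparse J)
and exported as labelled CSV.

## The synthetic test-bed, and what passing tests do not show

The generator emulates a synchrotron rotation experiment: tetragonal crystal
a = b = 57.7, c = 150.0 Å, a 423.6 × 434.6 mm single panel of 0.172 mm
pixels at 250 mm, λ = 1.0 Å, 0.1° images, with observed centroids = predicted
centroids + independent Gaussian noise of σ_X = σ_Y = 0.05 mm and
σ_φ = 0.02° whose true variances fill the variance columns.  Perturbations
are applied through the parameterisations, so they are representable by
refinement.  Statistical replicates are independent noise draws; a
multinomial count-splitting routine is provided to mirror pixel-level
replicate construction on synthetic count arrays (image-level simulation is
out of scope).

What this does *not* emulate: correlated centroid errors, mis-estimated
variances, parallax and other detector systematics, absorption, radiation
damage beyond smooth cell drift, partially overlapped or mis-indexed spots.
Passing the recovery and calibration tests therefore demonstrates the
correctness of the estimator under its own assumptions, not robustness to
real-data systematics.

Problem sizes used by the test suite are deliberate choices: recovery and
calibration run on a 30° or 10° wedge at d_min = 3.5–4 Å (≈ 2000–8000
reflections), which already puts parameter recovery well below 0.2× the
noise σ; the scan-varying benchmark uses a 360° scan of 0.5° images at
d_min = 3.5 Å (≈ 97 000 reflections, 117 parameters).

## Scan-varying recovery: the a/c asymmetry

The scan-varying benchmark applies the characteristic tetragonal pattern of
smooth cell evolution — a drift plus an oscillation whose period for a (90°)
is half that for c (180°) — with 0.02 Å amplitudes.  The a curve is
recovered with max error ≈ 0.003–0.004 Å, comfortably below half the
amplitude; part of that residual is the expected smoothing attenuation of a
90°-period signal sampled at 18° intervals.  The c curve is recovered to
only ≈ 0.01–0.02 Å max error, and this does not improve at the full
original scale of the experiment it models (a replicated 720° run with
~307 000 reflections gave 0.010–0.022 Å across noise seeds): the long
150 Å axis is strongly correlated with the detector distance, so its
pointwise uncertainty is several times that of a.  The same asymmetry is
visible in the source experiment, where the smooth c curve differs from a
block-wise reference by up to 0.02 Å while a agrees closely.  The test
suite therefore asserts half-amplitude recovery for a and a full-amplitude
sanity bound for c.

## Known limitations

* Rotation scans only; still shots (zero-width scans) are not predicted.
* Millimetre-space geometry throughout: pixel↔mm conversion is a pure scale
  by the pixel size; parallax, thickness and distortion corrections belong
  to detector-specific preprocessing.
* One rigid panel group per detector; no goniometer or wavelength
  refinement (a free-wavenumber flag exists for calibration-style use).
* No restrained (target-cell) refinement and no robust-loss (M-estimation)
  alternatives to outlier rejection.
* Smoothed-curve e.s.d.s (pointwise confidence bands for scan-varying
  parameters) are not computed.
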