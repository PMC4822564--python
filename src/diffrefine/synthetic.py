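"""Synthetic test-bed: ground-truth experiments, noisy observations, perturbations.

Everything the rest of the package needs for testing and calibration can be
generated here with no external data.  The default geometry emulates a
typical macromolecular rotation experiment at a synchrotron beamline: a
tetragonal crystal with a = b = 57.7, c = 150.0 angstroms, a large
single-panel pixel-array detector (0.172 mm pixels) at 250 mm, a 1.0
angstrom beam and 0.1 degree images.  Observations are predicted centroids
plus independent Gaussian noise with known variances, matching the
assumption behind the statistical weighting scheme.  All generators are
deterministic given (config, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .models import (
    B_from_cell,
    Beam,
    Crystal,
    Detector,
    Experiment,
    Goniometer,
    Panel,
    Scan,
)
from .parameterisation import (
    BeamParameterisation,
    CellParameterisation,
    CrystalOrientationParameterisation,
    DetectorParameterisation,
)
from .prediction import ReflectionTable, predict_static

__all__ = [
    "SimulationConfig",
    "PerturbationMagnitudes",
    "make_experiment",
    "simulate_observations",
    "perturb",
    "make_scan_varying_truth",
    "inject_outliers",
    "multinomial_split",
]


@dataclass
class SimulationConfig:
    """Ground-truth geometry, scan and noise model for the synthetic test-bed."""

    cell: tuple[float, float, float, float, float, float] = (57.7, 57.7, 150.0, 90.0, 90.0, 90.0)
    crystal_system: str = "tetragonal"
    detector_distance: float = 250.0  # mm
    image_size: tuple[int, int] = (2463, 2527)  # pixels, fast x slow
    pixel_size: tuple[float, float] = (0.172, 0.172)  # mm
    wavelength: float = 1.0  # angstroms
    n_images: int = 300
    osc_start: float = 0.0  # degrees
    osc_width: float = 0.1  # degrees per image
    sigma_x: float = 0.05  # mm
    sigma_y: float = 0.05  # mm
    sigma_phi: float = 0.02  # degrees
    dmin: float = 3.5  # angstroms
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detector_distance", "wavelength", "osc_width", "dmin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma_x", "sigma_y", "sigma_phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def make_experiment(config: SimulationConfig) -> Experiment:
    """Deterministic ground-truth experiment from a configuration.

    The beam travels along -z toward a detector normal to it, the rotation
    axis is +x (imgCIF-style frame) and the crystal orientation is a seeded
    random rotation.
    """
    beam = Beam(direction=np.array([0.0, 0.0, -1.0]), wavelength=config.wavelength)
    gonio = Goniometer(axis=np.array([1.0, 0.0, 0.0]))
    x_lim = config.image_size[0] * config.pixel_size[0]
    y_lim = config.image_size[1] * config.pixel_size[1]
    panel = Panel(
        d0=np.array([-0.5 * x_lim, -0.5 * y_lim, -config.detector_distance]),
        d1_hat=np.array([1.0, 0.0, 0.0]),
        d2_hat=np.array([0.0, 1.0, 0.0]),
        pixel_size=config.pixel_size,
        image_size=config.image_size,
    )
    rng = np.random.default_rng(config.seed)
    U = Rotation.random(random_state=rng).as_matrix()
    crystal = Crystal(U=U, B=B_from_cell(config.cell), crystal_system=config.crystal_system)
    scan = Scan(
        image_range=(1, config.n_images),
        osc_start=config.osc_start,
        osc_width=config.osc_width,
    )
    return Experiment(
        beam=beam, goniometer=gonio, detector=Detector([panel]), crystal=crystal, scan=scan
    )


def simulate_observations(
    experiment: Experiment,
    config: SimulationConfig,
    predictions: ReflectionTable | None = None,
    seed: int | None = None,
) -> ReflectionTable:
    """Noisy observed centroids from static prediction.

    Observations are the predicted centroids plus independent Gaussian noise
    of the configured standard deviations; the variance columns carry the
    true variances so statistical weights make each residual coordinate
    contribute unit variance to the target.
    """
    if predictions is None:
        predictions = predict_static(experiment, config.dmin)
    table = predictions.copy()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(table)
    sigma_phi_rad = np.deg2rad(config.sigma_phi)
    table["x_obs"] = table["x_calc"] + rng.normal(0.0, config.sigma_x, n)
    table["y_obs"] = table["y_calc"] + rng.normal(0.0, config.sigma_y, n)
    table["phi_obs"] = table["phi_calc"] + rng.normal(0.0, sigma_phi_rad, n)
    # zero noise still needs positive variances for statistical weighting
    table["var_x"] = max(config.sigma_x, 1e-6) ** 2
    table["var_y"] = max(config.sigma_y, 1e-6) ** 2
    table["var_phi"] = max(sigma_phi_rad, np.deg2rad(1e-6)) ** 2
    table["used"] = True
    return table


@dataclass
class PerturbationMagnitudes:
    """Scales (standard deviations of seeded draws) for model perturbations."""

    detector_shift_mm: float = 0.0
    detector_tilt_deg: float = 0.0
    beam_rotation_deg: float = 0.0
    misset_deg: float = 0.0
    cell_strain: float = 0.0  # fractional change of cell lengths


def perturb(experiment: Experiment, magnitudes: PerturbationMagnitudes, seed: int) -> Experiment:
    """Randomly perturbed copy of an experiment.

    Perturbations are applied through the model parameterisations, which
    guarantees they are representable by refinement: detector distance and
    in-plane shifts, detector tilts, a beam rotation within the beam/axis
    plane, crystal missets and a symmetric strain of the free metrical
    parameters.
    """
    m = magnitudes
    for name in (
        "detector_shift_mm",
        "detector_tilt_deg",
        "beam_rotation_deg",
        "misset_deg",
        "cell_strain",
    ):
        if getattr(m, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    exp = copy.deepcopy(experiment)
    rng = np.random.default_rng(seed)

    dp = DetectorParameterisation(exp.detector)
    vals = dp.get_params(only_free=False)
    vals[0:3] += rng.normal(0.0, m.detector_shift_mm, 3) if m.detector_shift_mm else 0.0
    vals[3:6] += (
        rng.normal(0.0, np.deg2rad(m.detector_tilt_deg), 3) if m.detector_tilt_deg else 0.0
    )
    dp.set_params(vals, only_free=False)
    dp.update_model()

    bp = BeamParameterisation(exp.beam, exp.goniometer, fixed=())
    bvals = bp.get_params(only_free=False)
    bvals[1] += rng.normal(0.0, np.deg2rad(m.beam_rotation_deg)) if m.beam_rotation_deg else 0.0
    bp.set_params(bvals, only_free=False)
    bp.update_model()

    op = CrystalOrientationParameterisation(exp.crystal)
    ovals = op.get_params(only_free=False)
    ovals += rng.normal(0.0, np.deg2rad(m.misset_deg), 3) if m.misset_deg else 0.0
    op.set_params(ovals, only_free=False)
    op.update_model()

    cp = CellParameterisation(exp.crystal)
    cvals = cp.get_params(only_free=False)
    # g scales as 1/length^2, so a relative length strain s is a 2s change in g
    cvals *= 1.0 + (rng.normal(0.0, 2.0 * m.cell_strain, len(cvals)) if m.cell_strain else 0.0)
    cp.set_params(cvals, only_free=False)
    cp.update_model()

    return exp


def make_scan_varying_truth(
    experiment: Experiment,
    cell_variation: dict[str, dict] | None = None,
    misset_variation: dict[str, dict] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-image (U_k, B_k) truth states with smooth drift and oscillation.

    ``cell_variation`` maps a cell length name ("a", "b", "c") to
    ``{"drift": angstrom per degree, "amplitude": angstrom, "period": degrees}``;
    ``misset_variation`` maps a misset name ("phi1", "phi2", "phi3") to the
    same keys in degrees.  Cell changes are projected onto the crystal
    system's constraints (a tetragonal cell varying "a" varies b identically),
    emulating gradual radiation-induced cell changes modulated by an
    orientation-coupled oscillation.
    """
    cell_variation = cell_variation or {}
    misset_variation = misset_variation or {}
    scan = experiment.scan
    crystal = experiment.crystal
    base_cell = np.array(crystal.real_cell)
    system = crystal.crystal_system
    U0 = crystal.U.copy()
    name_to_idx = {"a": 0, "b": 1, "c": 2}
    axes = (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    def wave(spec: dict, phi_deg: float) -> float:
        out = spec.get("drift", 0.0) * phi_deg
        amp, period = spec.get("amplitude", 0.0), spec.get("period", 0.0)
        if amp and period:
            out += amp * np.sin(2.0 * np.pi * phi_deg / period)
        return out

    states = []
    for kk in range(scan.n_images + 1):
        phi_deg = scan.osc_start + kk * scan.osc_width
        cell = base_cell.copy()
        for name, spec in cell_variation.items():
            cell[name_to_idx[name]] += wave(spec, phi_deg)
        # re-impose symmetry ties on the varied lengths
        if system in ("tetragonal", "trigonal", "hexagonal"):
            cell[1] = cell[0]
        elif system == "cubic":
            cell[1] = cell[2] = cell[0]
        B_k = B_from_cell(cell)
        U_k = U0
        if misset_variation:
            R = np.eye(3)
            for j, name in enumerate(("phi1", "phi2", "phi3")):
                if name in misset_variation:
                    ang = np.deg2rad(wave(misset_variation[name], phi_deg))
                    R = Rotation.from_rotvec(ang * axes[j]).as_matrix() @ R
            U_k = R @ U0
        states.append((U_k, B_k))
    return states


def inject_outliers(
    table: ReflectionTable, fraction: float, magnitude_sigma: float, seed: int
) -> tuple[ReflectionTable, np.ndarray]:
    """Displace a random subset of observations to act as gross outliers.

    Each selected row is moved by ``magnitude_sigma`` times its own centroid
    standard deviation in one randomly chosen coordinate (with random sign).
    Returns the modified table and the injected row indices for scoring.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    out = table.copy()
    n = len(out)
    rng = np.random.default_rng(seed)
    n_out = int(round(fraction * n))
    ids = np.sort(rng.choice(n, size=n_out, replace=False)) if n_out else np.array([], dtype=int)
    if n_out == 0:
        return out, ids
    coords = rng.integers(0, 3, n_out)
    signs = rng.choice([-1.0, 1.0], n_out)
    for col, var_col, c in (("x_obs", "var_x", 0), ("y_obs", "var_y", 1), ("phi_obs", "var_phi", 2)):
        sel = ids[coords == c]
        if len(sel):
            vals = out[col]
            vals[sel] += signs[coords == c] * magnitude_sigma * np.sqrt(out[var_col][sel])
            out[col] = vals
    return out, ids


def multinomial_split(counts: np.ndarray, n_replicates: int, seed: int) -> list[np.ndarray]:
    """Randomly redistribute integer counts into statistical replicates.

    Every count unit is assigned independently and uniformly to one of the
    replicates, so the replicates sum exactly to the input and each replicate
    element is Binomial(c, 1/n).  This mirrors reshuffling the photon counts
    of a summed data set into equivalent low-dose data sets that differ only
    by shot noise.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be integers")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    flat = counts.ravel()
    split = rng.multinomial(flat, np.full(n_replicates, 1.0 / n_replicates))
    return [split[:, j].reshape(counts.shape) for j in range(n_replicates)]
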