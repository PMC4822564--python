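"""Experimental models and core geometry algebra.

The models here describe a rotation-method diffraction experiment in fully
general vector terms: a monochromatic beam, a single rotation axis, one or
more flat detector panels and a crystal carried by its orientation matrix U
and reciprocal-space orthogonalization matrix B.  All algorithms elsewhere in
the package operate on these abstractions and are agnostic to the choice of
laboratory frame.

Conventions
-----------
* Lengths on the detector are millimetres; reciprocal space is in inverse
  angstroms; angles are radians internally and degrees in files.
* The default laboratory frame follows the imgCIF convention: the goniometer
  axis along ``(1, 0, 0)``, ``z`` pointing from the sample towards the source
  so that the default beam direction is ``(0, 0, -1)``, and ``y`` completing a
  right-handed set.  Nothing in the algorithms depends on this choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Beam",
    "Goniometer",
    "Panel",
    "Detector",
    "Crystal",
    "Scan",
    "Experiment",
    "detector_matrices",
    "project_ray",
    "B_from_cell",
    "cell_from_B",
    "Gstar_from_cell",
    "cell_from_Gstar",
    "load_experiment",
    "save_experiment",
]

CRYSTAL_SYSTEMS = (
    "triclinic",
    "monoclinic",
    "orthorhombic",
    "tetragonal",
    "trigonal",
    "hexagonal",
    "cubic",
)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


@dataclass
class Beam:
    """Monochromatic beam: unit direction from source toward sample, wavelength in angstroms."""

    direction: np.ndarray
    wavelength: float

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-8:
            raise ValueError("beam direction must be a unit vector")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def s0(self) -> np.ndarray:
        """Incident wavevector, length 1/wavelength (inverse angstroms)."""
        return self.direction / self.wavelength


@dataclass
class Goniometer:
    """Single rotation axis with a right-handed rotation sense."""

    axis: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-8:
            raise ValueError("goniometer axis must be a unit vector")


@dataclass
class Panel:
    """One flat detector panel.

    ``d0`` is the laboratory position (mm) of the corner that is the origin of
    the panel coordinate system; ``d1_hat`` and ``d2_hat`` are unit vectors
    along the fast and slow directions of the image array.
    """

    d0: np.ndarray
    d1_hat: np.ndarray
    d2_hat: np.ndarray
    pixel_size: tuple[float, float]
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        self.d0 = np.asarray(self.d0, dtype=float)
        self.d1_hat = np.asarray(self.d1_hat, dtype=float)
        self.d2_hat = np.asarray(self.d2_hat, dtype=float)
        for v, name in ((self.d1_hat, "fast"), (self.d2_hat, "slow")):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError(f"{name} axis must be a unit vector")
        if abs(float(np.dot(self.d1_hat, self.d2_hat))) > 1e-10:
            raise ValueError("fast and slow axes must be orthogonal")

    @property
    def x_lim(self) -> float:
        return self.image_size[0] * self.pixel_size[0]

    @property
    def y_lim(self) -> float:
        return self.image_size[1] * self.pixel_size[1]

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.d1_hat, self.d2_hat)

    @property
    def centre(self) -> np.ndarray:
        return self.d0 + 0.5 * self.x_lim * self.d1_hat + 0.5 * self.y_lim * self.d2_hat


@dataclass
class Detector:
    """Ordered collection of panels, moved as one rigid body during refinement."""

    panels: list[Panel]

    def __post_init__(self) -> None:
        if len(self.panels) < 1:
            raise ValueError("detector needs at least one panel")

    def __getitem__(self, i: int) -> Panel:
        return self.panels[i]

    def __len__(self) -> int:
        return len(self.panels)


@dataclass
class Crystal:
    """Crystal orientation U (rotation matrix) and reciprocal orthogonalization B.

    The columns of B are the reciprocal-cell vectors a*, b*, c* expressed in an
    orthogonal frame fixed to the crystal, so UB maps Miller indices to
    reciprocal-space vectors in the laboratory frame at rotation angle zero.
    """

    U: np.ndarray
    B: np.ndarray
    crystal_system: str = "triclinic"

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float).reshape(3, 3)
        self.B = np.asarray(self.B, dtype=float).reshape(3, 3)
        if self.crystal_system not in CRYSTAL_SYSTEMS:
            raise ValueError(f"unknown crystal system {self.crystal_system!r}")
        if not np.allclose(self.U.T @ self.U, np.eye(3), atol=1e-9):
            raise ValueError("U must be orthonormal")
        if abs(np.linalg.det(self.U) - 1.0) > 1e-9:
            raise ValueError("U must be a proper rotation (det = +1)")

    @property
    def UB(self) -> np.ndarray:
        return self.U @ self.B

    @property
    def real_cell(self) -> tuple[float, float, float, float, float, float]:
        return cell_from_B(self.B)[1]


@dataclass
class Scan:
    """Contiguous rotation scan: 1-based inclusive image range and oscillation.

    The continuous image coordinate k runs from 0 at the start of the first
    image to n_images at the end of the last; phi(k) = osc_start + k*osc_width.
    """

    image_range: tuple[int, int]
    osc_start: float  # degrees
    osc_width: float  # degrees per image

    def __post_init__(self) -> None:
        if self.osc_width <= 0:
            raise ValueError("oscillation width must be positive")
        if self.image_range[1] < self.image_range[0]:
            raise ValueError("empty image range")

    @property
    def n_images(self) -> int:
        return self.image_range[1] - self.image_range[0] + 1

    @property
    def phi_start_rad(self) -> float:
        return np.deg2rad(self.osc_start)

    @property
    def phi_end_rad(self) -> float:
        return np.deg2rad(self.osc_start + self.n_images * self.osc_width)

    @property
    def range_rad(self) -> float:
        return np.deg2rad(self.n_images * self.osc_width)

    def phi_from_image(self, k):
        """Rotation angle (rad) at continuous image coordinate k."""
        return np.deg2rad(self.osc_start + np.asarray(k, dtype=float) * self.osc_width)

    def image_from_phi(self, phi):
        """Continuous image coordinate at rotation angle phi (rad)."""
        return (np.rad2deg(np.asarray(phi, dtype=float)) - self.osc_start) / self.osc_width


@dataclass
class Experiment:
    """Exactly one beam, goniometer, detector, crystal and scan."""

    beam: Beam
    goniometer: Goniometer
    detector: Detector
    crystal: Crystal
    scan: Scan


# ---------------------------------------------------------------------------
# Detector algebra


def detector_matrices(panel: Panel) -> tuple[np.ndarray, np.ndarray]:
    """Return the detector matrix d = (d1_hat | d2_hat | d0) and D = d^-1.

    Raises
    ------
    ValueError
        If the panel plane passes through the laboratory origin, making d
        singular and the projection undefined.
    """
    d = np.column_stack([panel.d1_hat, panel.d2_hat, panel.d0])
    det = np.linalg.det(d)
    if abs(det) < 1e-12:
        raise ValueError("degenerate panel through origin")
    return d, np.linalg.inv(d)


def project_ray(s1: np.ndarray, panel: Panel) -> tuple[float, float, bool]:
    """Intersect the ray along s1 from the lab origin with a panel plane.

    Returns the in-plane millimetre coordinates (X, Y) and whether the point
    lies inside the panel limits.  Homogeneous coordinates (u, v, w) = D s1
    give X = u/w, Y = v/w.

    Raises
    ------
    ValueError
        If the ray does not meet the plane travelling forward (w <= 0).
    """
    _, D = detector_matrices(panel)
    u, v, w = D @ np.asarray(s1, dtype=float)
    if w <= 0:
        raise ValueError("no forward intersection with panel plane")
    X, Y = u / w, v / w
    inside = bool(0.0 <= X <= panel.x_lim and 0.0 <= Y <= panel.y_lim)
    return X, Y, inside


# ---------------------------------------------------------------------------
# Unit-cell algebra


def _check_cell(cell: Sequence[float]) -> tuple[float, ...]:
    a, b, c, alpha, beta, gamma = (float(x) for x in cell)
    if min(a, b, c) <= 0:
        raise ValueError("invalid cell: lengths must be positive")
    if not (0 < alpha < 180 and 0 < beta < 180 and 0 < gamma < 180):
        raise ValueError("invalid cell: angles must be in (0, 180) degrees")
    # triangle-like conditions for a valid parallelepiped
    if not (
        alpha + beta + gamma < 360
        and alpha + beta - gamma > 0
        and alpha - beta + gamma > 0
        and -alpha + beta + gamma > 0
    ):
        raise ValueError("invalid cell: angle triple violates parallelepiped conditions")
    return a, b, c, alpha, beta, gamma


def Gstar_from_cell(cell: Sequence[float]) -> np.ndarray:
    """Reciprocal metric tensor G* (3x3, inverse square angstroms) from a real cell."""
    B = B_from_cell(cell)
    return B.T @ B


def B_from_cell(cell: Sequence[float]) -> np.ndarray:
    """Busing & Levy reciprocal orthogonalization matrix from a real-space cell.

    The convention places a* along x, b* in the x-y plane with positive y
    component, right-handed.  ``cell`` is (a, b, c, alpha, beta, gamma) with
    lengths in angstroms and angles in degrees.
    """
    a, b, c, alpha, beta, gamma = _check_cell(cell)
    al, be, ga = np.deg2rad([alpha, beta, gamma])
    ca, cb, cg = np.cos([al, be, ga])
    sa, sb, sg = np.sin([al, be, ga])
    # real-space cell volume via the Gram determinant
    vfac = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if vfac <= 0:
        raise ValueError("invalid cell: non-positive metric determinant")
    V = a * b * c * np.sqrt(vfac)
    a_s = b * c * sa / V
    b_s = a * c * sb / V
    c_s = a * b * sg / V
    ca_s = (cb * cg - ca) / (sb * sg)
    cb_s = (ca * cg - cb) / (sa * sg)
    cg_s = (ca * cb - cg) / (sa * sb)
    sb_s = np.sqrt(max(1.0 - cb_s * cb_s, 0.0))
    sg_s = np.sqrt(max(1.0 - cg_s * cg_s, 0.0))
    return np.array(
        [
            [a_s, b_s * cg_s, c_s * cb_s],
            [0.0, b_s * sg_s, -c_s * sb_s * ca],
            [0.0, 0.0, 1.0 / c],
        ]
    )


def cell_from_B(B: np.ndarray) -> tuple[tuple, tuple]:
    """Recover (reciprocal cell, real cell) from an orthogonalization matrix."""
    B = np.asarray(B, dtype=float)
    return cell_from_Gstar_matrix(B.T @ B)


def cell_from_Gstar_matrix(Gstar: np.ndarray) -> tuple[tuple, tuple]:
    """Cells from a full 3x3 reciprocal metric tensor (see cell_from_Gstar)."""
    Gstar = np.asarray(Gstar, dtype=float)
    if not np.allclose(Gstar, Gstar.T, atol=1e-12):
        raise ValueError("metric tensor must be symmetric")
    if np.any(np.linalg.eigvalsh(Gstar) <= 0):
        raise ValueError("metric tensor must be positive definite")
    recip = _cell_from_metric(Gstar)
    real = _cell_from_metric(np.linalg.inv(Gstar))
    return recip, real


def _cell_from_metric(G: np.ndarray) -> tuple[float, ...]:
    lengths = np.sqrt(np.diag(G))
    cosang = np.array(
        [
            G[1, 2] / (lengths[1] * lengths[2]),
            G[0, 2] / (lengths[0] * lengths[2]),
            G[0, 1] / (lengths[0] * lengths[1]),
        ]
    )
    angles = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (*lengths, *angles)


def cell_from_Gstar(g: Sequence[float]) -> tuple[tuple, tuple]:
    """Cells from the six metrical elements (g11, g22, g33, g12, g13, g23) in inverse square angstroms.

    Returns (reciprocal cell, real cell), each as (a, b, c, alpha, beta,
    gamma) with angles in degrees; the real cell comes from inverting the
    reciprocal metric.
    """
    g11, g22, g33, g12, g13, g23 = (float(x) for x in g)
    G = np.array([[g11, g12, g13], [g12, g22, g23], [g13, g23, g33]])
    return cell_from_Gstar_matrix(G)


# ---------------------------------------------------------------------------
# Experiment JSON I/O


def experiment_to_dict(exp: Experiment) -> dict:
    return {
        "beam": {
            "direction": list(exp.beam.direction),
            "wavelength": exp.beam.wavelength,
        },
        "goniometer": {"axis": list(exp.goniometer.axis)},
        "detector": [
            {
                "origin": list(p.d0),
                "fast": list(p.d1_hat),
                "slow": list(p.d2_hat),
                "pixel_size": list(p.pixel_size),
                "image_size": list(p.image_size),
            }
            for p in exp.detector.panels
        ],
        "crystal": {
            "U": [float(x) for x in exp.crystal.U.ravel()],
            "B": [float(x) for x in exp.crystal.B.ravel()],
            "crystal_system": exp.crystal.crystal_system,
        },
        "scan": {
            "image_range": list(exp.scan.image_range),
            "osc_start_deg": exp.scan.osc_start,
            "osc_width_deg": exp.scan.osc_width,
        },
    }


def experiment_from_dict(d: dict) -> Experiment:
    beam = Beam(direction=np.array(d["beam"]["direction"]), wavelength=d["beam"]["wavelength"])
    gonio = Goniometer(axis=np.array(d["goniometer"]["axis"]))
    panels = [
        Panel(
            d0=np.array(p["origin"]),
            d1_hat=np.array(p["fast"]),
            d2_hat=np.array(p["slow"]),
            pixel_size=tuple(p["pixel_size"]),
            image_size=tuple(p["image_size"]),
        )
        for p in d["detector"]
    ]
    crystal = Crystal(
        U=np.array(d["crystal"]["U"]).reshape(3, 3),
        B=np.array(d["crystal"]["B"]).reshape(3, 3),
        crystal_system=d["crystal"]["crystal_system"],
    )
    scan = Scan(
        image_range=tuple(d["scan"]["image_range"]),
        osc_start=d["scan"]["osc_start_deg"],
        osc_width=d["scan"]["osc_width_deg"],
    )
    return Experiment(beam=beam, goniometer=gonio, detector=Detector(panels), crystal=crystal, scan=scan)


def _json_default(o):
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_experiment(exp: Experiment, path) -> None:
    with open(path, "w") as fh:
        json.dump(experiment_to_dict(exp), fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def load_experiment(path) -> Experiment:
    with open(path) as fh:
        return experiment_from_dict(json.load(fh))
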