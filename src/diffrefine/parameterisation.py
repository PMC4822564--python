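"""Model parameterisations: from parameter values to model states and derivatives.

A parameterisation attaches to one experimental model for the duration of a
refinement.  It designates a *state* (the s0 vector, the U or B matrix, or a
detector matrix per panel), composes that state from its current parameter
values and exposes the first derivatives of the state with respect to each
parameter.  Translation and rotation parameters act along or about axes
frozen from the *initial* geometry of the model, so the scheme is independent
of the arbitrary orientation of the laboratory frame; such frozen axes are
suffixed ``0`` here (the printed convention is a prime).

The default parameter set for one experiment totals 18: three beam (two
rotations mu1, mu2 and the wavenumber nu), three crystal orientation missets
(phi1..phi3 about the laboratory axes), up to six reciprocal metrical
elements for the unit cell, and six for the detector treated as one rigid
body (distance p0, in-plane shifts t1, t2, orientation tau1..tau3).  By
convention mu1 and nu are fixed in normal use.
"""

from __future__ import annotations

import numpy as np

from .models import (
    B_from_cell,
    Beam,
    Crystal,
    Detector,
    Goniometer,
    cell_from_Gstar_matrix,
)

__all__ = [
    "ModelParameterisation",
    "BeamParameterisation",
    "CrystalOrientationParameterisation",
    "CellParameterisation",
    "DetectorParameterisation",
    "GaussianSmoother",
    "ScanVaryingCrystalParameterisation",
    "smoother_num_points",
    "FREE_METRICAL_PARAMS",
]


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float)


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    K = _skew(np.asarray(axis, dtype=float))
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


class ModelParameterisation:
    """Base class: a named parameter vector with a fixed-mask.

    Subclasses implement ``compose`` to build the model state and its
    derivatives, and ``update_model`` to push the state into the attached
    model object.
    """

    param_names: list[str] = []

    def __init__(self, values: np.ndarray, fixed: list[str] | None = None):
        self._values = np.asarray(values, dtype=float).copy()
        self._fixed = np.zeros(len(self._values), dtype=bool)
        if fixed:
            self.fix(fixed)

    # -- parameter bookkeeping --------------------------------------------
    @property
    def num_total(self) -> int:
        return len(self._values)

    @property
    def num_free(self) -> int:
        return int((~self._fixed).sum())

    @property
    def free_names(self) -> list[str]:
        return [n for n, f in zip(self.param_names, self._fixed) if not f]

    def fix(self, names) -> None:
        for n in names:
            self._fixed[self.param_names.index(n)] = True

    def unfix(self, names) -> None:
        for n in names:
            self._fixed[self.param_names.index(n)] = False

    def get_params(self, only_free: bool = True) -> np.ndarray:
        return self._values[~self._fixed] if only_free else self._values.copy()

    def set_params(self, values, only_free: bool = True) -> None:
        values = np.asarray(values, dtype=float)
        if only_free:
            self._values[~self._fixed] = values
        else:
            self._values = values.copy()

    # -- state interface ---------------------------------------------------
    def get_state(self):
        raise NotImplementedError

    def get_ds_dp(self, only_free: bool = True) -> list:
        all_ds = self._all_derivatives()
        if only_free:
            return [d for d, f in zip(all_ds, self._fixed) if not f]
        return all_ds

    def _all_derivatives(self) -> list:
        raise NotImplementedError

    def update_model(self) -> None:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Beam


class BeamParameterisation(ModelParameterisation):
    """s0 = nu * R(e2_0, mu2) * R(e1_0, mu1) * s0_hat_0.

    The frozen axes e1_0 and e2_0 are perpendicular to the initial beam
    direction; e1_0 is built from the goniometer axis so that fixing mu1
    confines beam movements to the plane containing the initial beam and the
    rotation axis.  By default mu1 and nu (the wavenumber) are fixed.
    """

    param_names = ["mu1", "mu2", "nu"]

    def __init__(self, beam: Beam, goniometer: Goniometer, fixed: list[str] | None = ("mu1", "nu")):
        self.beam = beam
        s0 = beam.s0
        self._s0_hat0 = s0 / np.linalg.norm(s0)
        g = goniometer.axis
        e1 = np.cross(self._s0_hat0, g)
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(self._s0_hat0, np.array([0.0, 1.0, 0.0]))
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(self._s0_hat0, np.array([1.0, 0.0, 0.0]))
        self._e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(self._s0_hat0, self._e1)
        self._e2 = e2 / np.linalg.norm(e2)
        super().__init__(np.array([0.0, 0.0, np.linalg.norm(s0)]), list(fixed or []))

    def get_state(self) -> np.ndarray:
        mu1, mu2, nu = self._values
        return nu * (_rot(self._e2, mu2) @ _rot(self._e1, mu1) @ self._s0_hat0)

    def _all_derivatives(self) -> list[np.ndarray]:
        mu1, mu2, nu = self._values
        R1 = _rot(self._e1, mu1)
        R2 = _rot(self._e2, mu2)
        v1 = R1 @ self._s0_hat0
        v2 = R2 @ v1
        d_mu1 = nu * (R2 @ np.cross(self._e1, v1))
        d_mu2 = nu * np.cross(self._e2, v2)
        d_nu = v2
        return [d_mu1, d_mu2, d_nu]

    def update_model(self) -> None:
        s0 = self.get_state()
        nu = np.linalg.norm(s0)
        self.beam.direction = s0 / nu
        self.beam.wavelength = 1.0 / nu


# ---------------------------------------------------------------------------
# Crystal orientation


class CrystalOrientationParameterisation(ModelParameterisation):
    """Misset rotation applied to the datum orientation U0.

    U = R3(phi3) R2(phi2) R1(phi1) U0 with R1, R2, R3 about the laboratory
    x, y, z axes (Tait-Bryan convention, first listed applied first).  All
    angles are zero at initialisation, so gimbal lock is never approached for
    realistic refinement tasks.
    """

    param_names = ["phi1", "phi2", "phi3"]
    _axes = (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    def __init__(self, crystal: Crystal, fixed: list[str] | None = None):
        self.crystal = crystal
        self._U0 = crystal.U.copy()
        super().__init__(np.zeros(3), list(fixed or []))

    def get_state(self) -> np.ndarray:
        p1, p2, p3 = self._values
        return _rot(self._axes[2], p3) @ _rot(self._axes[1], p2) @ _rot(self._axes[0], p1) @ self._U0

    def _all_derivatives(self) -> list[np.ndarray]:
        p1, p2, p3 = self._values
        R1 = _rot(self._axes[0], p1)
        R2 = _rot(self._axes[1], p2)
        R3 = _rot(self._axes[2], p3)
        K1, K2, K3 = (_skew(a) for a in self._axes)
        dU1 = R3 @ R2 @ K1 @ R1 @ self._U0
        dU2 = R3 @ K2 @ R2 @ R1 @ self._U0
        dU3 = K3 @ R3 @ R2 @ R1 @ self._U0
        return [dU1, dU2, dU3]

    def update_model(self) -> None:
        self.crystal.U = self.get_state()


# ---------------------------------------------------------------------------
# Crystal unit cell via the reciprocal metrical matrix

# free elements of (g11, g22, g33, g12, g13, g23) per crystal system
FREE_METRICAL_PARAMS = {
    "triclinic": ("g11", "g22", "g33", "g12", "g13", "g23"),
    "monoclinic": ("g11", "g22", "g33", "g13"),
    "orthorhombic": ("g11", "g22", "g33"),
    "tetragonal": ("g11", "g33"),
    "trigonal": ("g11", "g33"),
    "hexagonal": ("g11", "g33"),
    "cubic": ("g11",),
}


def _expand_metricals(system: str, free: np.ndarray) -> np.ndarray:
    """Full (g11, g22, g33, g12, g13, g23) from the system's free elements."""
    if system == "triclinic":
        return np.asarray(free, dtype=float)
    if system == "monoclinic":
        g11, g22, g33, g13 = free
        return np.array([g11, g22, g33, 0.0, g13, 0.0])
    if system == "orthorhombic":
        g11, g22, g33 = free
        return np.array([g11, g22, g33, 0.0, 0.0, 0.0])
    if system == "tetragonal":
        g11, g33 = free
        return np.array([g11, g11, g33, 0.0, 0.0, 0.0])
    if system in ("trigonal", "hexagonal"):
        # hexagonal setting: gamma* = 60 degrees so g12 = g11 / 2
        g11, g33 = free
        return np.array([g11, g11, g33, 0.5 * g11, 0.0, 0.0])
    if system == "cubic":
        (g11,) = free
        return np.array([g11, g11, g11, 0.0, 0.0, 0.0])
    raise ValueError(f"unknown crystal system {system!r}")


class CellParameterisation(ModelParameterisation):
    """Unit cell through the symmetry-free elements of the reciprocal metrical matrix.

    The state is B.  Composition proceeds free elements -> full G* -> real
    cell -> conventional (upper-triangular) B, optionally re-oriented by a
    frozen rotation so that a non-conventional input B is reproduced exactly.
    State derivatives with respect to the metrical elements are evaluated by
    central differences of this composition with a fixed relative step, which
    is deterministic and exact to well beyond the accuracy needed by the
    normal equations.
    """

    def __init__(self, crystal: Crystal, fixed: list[str] | None = None):
        self.crystal = crystal
        system = crystal.crystal_system
        self.system = system
        self.param_names = list(FREE_METRICAL_PARAMS[system])
        Gstar = crystal.B.T @ crystal.B
        g_full = {
            "g11": Gstar[0, 0],
            "g22": Gstar[1, 1],
            "g33": Gstar[2, 2],
            "g12": Gstar[0, 1],
            "g13": Gstar[0, 2],
            "g23": Gstar[1, 2],
        }
        free = np.array([g_full[n] for n in self.param_names])
        # frozen re-orientation onto the conventional triangular B
        B_conv = self._conventional_B(free)
        R = crystal.B @ np.linalg.inv(B_conv)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError(
                f"crystal B is inconsistent with the {system} constraints"
            )
        self._R0 = R
        super().__init__(free, list(fixed or []))
        if not np.allclose(self.get_state(), crystal.B, atol=1e-9):
            raise ValueError(
                f"crystal B is not reproduced by the {system} metrical parameters"
            )

    def _conventional_B(self, free: np.ndarray) -> np.ndarray:
        g = _expand_metricals(self.system, free)
        try:
            _, real = cell_from_Gstar_matrix(
                np.array([[g[0], g[3], g[4]], [g[3], g[1], g[5]], [g[4], g[5], g[2]]])
            )
        except ValueError as exc:
            raise ValueError(
                f"metrical parameters {dict(zip(self.param_names, free))} "
                f"imply an invalid cell: {exc}"
            ) from exc
        return B_from_cell(real)

    def get_state(self) -> np.ndarray:
        return self._R0 @ self._conventional_B(self._values)

    def _all_derivatives(self) -> list[np.ndarray]:
        out = []
        for i in range(self.num_total):
            step = max(abs(self._values[i]), 1e-4) * 1e-7
            lo, hi = self._values.copy(), self._values.copy()
            lo[i] -= step
            hi[i] += step
            out.append(
                self._R0 @ (self._conventional_B(hi) - self._conventional_B(lo)) / (2.0 * step)
            )
        return out

    def real_cell(self) -> tuple[float, ...]:
        """Real-space cell (a, b, c, alpha, beta, gamma) from the current parameters."""
        return self.cell_from_params(self._values)

    def cell_from_params(self, free: np.ndarray) -> tuple[float, ...]:
        g = _expand_metricals(self.system, np.asarray(free, dtype=float))
        _, real = cell_from_Gstar_matrix(
            np.array([[g[0], g[3], g[4]], [g[3], g[1], g[5]], [g[4], g[5], g[2]]])
        )
        return real

    def update_model(self) -> None:
        self.crystal.B = self.get_state()


# ---------------------------------------------------------------------------
# Detector (one rigid group of panels)


class DetectorParameterisation(ModelParameterisation):
    """Six-parameter rigid-body parameterisation of a (multi-panel) detector.

    The state is the list of panel matrices d = (d1 | d2 | d0).  A frozen
    orthonormal group frame (g1_0, g2_0, gn_0) is built from the initial
    geometry with its reference point at the centre of the panel group.  The
    distance p0 acts along the initial group normal; shifts t1, t2 act along
    the initial in-plane axes; tau1 rotates about the initial normal through
    the laboratory origin, while tau2 and tau3 rotate about the initial
    in-plane axes taken through the point p0 * gn_0, a choice that decouples
    the rotational from the translational parameters.
    """

    param_names = ["p0", "t1", "t2", "tau1", "tau2", "tau3"]

    def __init__(self, detector: Detector, fixed: list[str] | None = None):
        self.detector = detector
        panels = detector.panels
        # frozen group frame from the initial panel-bounding geometry
        gn = np.sum([p.normal for p in panels], axis=0)
        gn = gn / np.linalg.norm(gn)
        g1 = panels[0].d1_hat - np.dot(panels[0].d1_hat, gn) * gn
        g1 = g1 / np.linalg.norm(g1)
        g2 = np.cross(gn, g1)
        self._E0 = np.column_stack([g1, g2, gn])
        q = np.mean([p.centre for p in panels], axis=0)
        p0 = float(np.dot(q, gn))
        t1 = float(np.dot(q, g1))
        t2 = float(np.dot(q, g2))
        # frozen per-panel geometry expressed in the group frame
        self._offsets = [self._E0.T @ (p.d0 - q) for p in panels]
        self._a1 = [self._E0.T @ p.d1_hat for p in panels]
        self._a2 = [self._E0.T @ p.d2_hat for p in panels]
        super().__init__(np.array([p0, t1, t2, 0.0, 0.0, 0.0]), list(fixed or []))

    def _frame(self):
        p0, t1, t2, tau1, tau2, tau3 = self._values
        g1, g2, gn = self._E0.T
        R1 = _rot(gn, tau1)
        R2 = _rot(g1, tau2)
        R3 = _rot(g2, tau3)
        Rtot = R3 @ R2 @ R1
        p1 = p0 * gn + t1 * g1 + t2 * g2
        centre = p0 * gn
        p4 = R3 @ R2 @ (R1 @ p1 - centre) + centre
        return Rtot, p4, (R1, R2, R3, p1, centre)

    def get_state(self) -> list[np.ndarray]:
        Rtot, p4, _ = self._frame()
        E = Rtot @ self._E0
        return [
            np.column_stack([E @ a1, E @ a2, p4 + E @ off])
            for a1, a2, off in zip(self._a1, self._a2, self._offsets)
        ]

    def _all_derivatives(self) -> list[list[np.ndarray]]:
        Rtot, p4, (R1, R2, R3, p1, centre) = self._frame()
        g1, g2, gn = self._E0.T
        K1, K2, Kn = _skew(g1), _skew(g2), _skew(gn)
        zero3 = np.zeros(3)

        # (dRtot, dp4) per parameter
        dp0 = (None, Rtot @ gn - R3 @ R2 @ gn + gn)
        dt1 = (None, Rtot @ g1)
        dt2 = (None, Rtot @ g2)
        dRt1 = R3 @ R2 @ Kn @ R1
        dtau1 = (dRt1, dRt1 @ p1)
        dRt2 = R3 @ K1 @ R2 @ R1
        dtau2 = (dRt2, R3 @ K1 @ R2 @ (R1 @ p1 - centre))
        dRt3 = K2 @ R3 @ R2 @ R1
        dtau3 = (dRt3, K2 @ (p4 - centre))

        out = []
        for dR, dp4 in (dp0, dt1, dt2, dtau1, dtau2, dtau3):
            dE = dR @ self._E0 if dR is not None else None
            per_panel = []
            for a1, a2, off in zip(self._a1, self._a2, self._offsets):
                if dE is None:
                    per_panel.append(np.column_stack([zero3, zero3, dp4]))
                else:
                    per_panel.append(
                        np.column_stack([dE @ a1, dE @ a2, dp4 + dE @ off])
                    )
            out.append(per_panel)
        return out

    def update_model(self) -> None:
        for panel, d in zip(self.detector.panels, self.get_state()):
            panel.d1_hat = d[:, 0]
            panel.d2_hat = d[:, 1]
            panel.d0 = d[:, 2]


# ---------------------------------------------------------------------------
# Gaussian smoother for scan-varying parameters


def smoother_num_points(scan_range_deg: float, interval_deg: float = 36.0) -> int:
    """Number of smoother sample points for a scan.

    The scan is divided into ``max(round(range / interval), 1)`` intervals
    (round-half-to-even) and the two extreme sample points lie half an
    interval outside the scan range, giving ``n_intervals + 2`` points.
    """
    if scan_range_deg <= 0:
        raise ValueError("scan range must be positive")
    n_intervals = max(round(scan_range_deg / interval_deg), 1)
    return n_intervals + 2


class GaussianSmoother:
    """Gaussian-weighted interpolation of subparameter values over a scan.

    Sample points are evenly spaced across the scan in the normalised
    coordinate z = (phi - phi_start) / spacing, at z = -0.5, 0.5, ...,
    n_intervals + 0.5 (the extremes lie outside the scan).  A value at any
    scan position is the normalised Gaussian-weighted sum of the three
    nearest subparameter values; the Gaussian variance is tied to the spacing
    so that one interval from a sample point the unnormalised weight has
    fallen to 13% of its peak.
    """

    #: unnormalised adjacent-point weight relative to the peak
    ADJACENT_FRACTION = 0.13
    NUM_AVERAGED = 3

    def __init__(self, phi_range: tuple[float, float], interval_width: float):
        """phi_range and interval_width in the same (angular) units, typically radians."""
        lo, hi = float(phi_range[0]), float(phi_range[1])
        if hi <= lo:
            raise ValueError("empty scan range")
        self.phi_range = (lo, hi)
        self.n_intervals = max(round((hi - lo) / interval_width), 1)
        self.n_points = self.n_intervals + 2
        self.spacing = (hi - lo) / self.n_intervals
        self.positions = np.arange(self.n_points) - 0.5  # in z units
        self.sigma_sq = -1.0 / np.log(self.ADJACENT_FRACTION)

    def _z(self, phi) -> np.ndarray:
        return (np.asarray(phi, dtype=float) - self.phi_range[0]) / self.spacing

    def weights(self, phi) -> tuple[np.ndarray, np.ndarray]:
        """Indices (n, 3) and normalised weights (n, 3) of the nearest points."""
        z = np.atleast_1d(self._z(phi))
        # tolerate half an interval beyond the scan (the extreme sample points)
        if np.any(z < self.positions[0]) or np.any(z > self.positions[-1]):
            raise ValueError("evaluation point outside the smoother's extended range")
        nearest = np.clip(np.round(z).astype(int), 0, self.n_points - 1)
        half = self.NUM_AVERAGED // 2
        centre = np.clip(nearest, half, self.n_points - 1 - half)
        idx = centre[:, None] + np.arange(-half, half + 1)[None, :]
        w = np.exp(-((z[:, None] - self.positions[idx]) ** 2) / self.sigma_sq)
        w /= w.sum(axis=1, keepdims=True)
        return idx, w

    def evaluate(self, phi, subparams: np.ndarray):
        """Smoothed value(s) at phi plus the sparse weights used."""
        subparams = np.asarray(subparams, dtype=float)
        if len(subparams) != self.n_points:
            raise ValueError(f"expected {self.n_points} subparameters, got {len(subparams)}")
        idx, w = self.weights(phi)
        values = np.sum(w * subparams[idx], axis=1)
        if np.isscalar(phi) or np.ndim(phi) == 0:
            return float(values[0]), (idx[0], w[0])
        return values, (idx, w)


# ---------------------------------------------------------------------------
# Scan-varying crystal


class ScanVaryingCrystalParameterisation:
    """Crystal orientation and cell as smooth functions of scan position.

    Each of the base crystal parameters (three missets plus the free metrical
    elements) carries ``n_points`` subparameters interpolated by one shared
    Gaussian smoother.  With all subparameters of a parameter equal, the
    composed state is constant across the scan.
    """

    def __init__(
        self,
        crystal: Crystal,
        phi_range: tuple[float, float],
        interval_width: float = np.deg2rad(36.0),
    ):
        self.crystal = crystal
        self.orientation = CrystalOrientationParameterisation(crystal)
        self.cell = CellParameterisation(crystal)
        self.smoother = GaussianSmoother(phi_range, interval_width)
        n_pts = self.smoother.n_points
        base = np.concatenate([self.orientation.get_params(only_free=False),
                               self.cell.get_params(only_free=False)])
        self.n_base = len(base)
        # subparameters: (n_base, n_points), initialised flat
        self._sub = np.tile(base[:, None], (1, n_pts))
        self.param_names = [
            f"{name}_s{i}"
            for name in (self.orientation.param_names + self.cell.param_names)
            for i in range(n_pts)
        ]

    @property
    def num_free(self) -> int:
        return self._sub.size

    @property
    def free_names(self) -> list[str]:
        return list(self.param_names)

    def get_params(self, only_free: bool = True) -> np.ndarray:
        return self._sub.ravel().copy()

    def set_params(self, values, only_free: bool = True) -> None:
        self._sub = np.asarray(values, dtype=float).reshape(self._sub.shape).copy()

    def base_params_at(self, phi) -> np.ndarray:
        """Interpolated base parameter values at scan position(s) phi (radians)."""
        idx, w = self.smoother.weights(phi)
        return np.einsum("nj,pnj->np", w, self._sub[:, idx])

    def compose_at(self, phi: float):
        """State and derivative factors at one scan position.

        Returns (U, B, base state derivatives, (subparameter indices, weights)):
        the derivative of the state with respect to subparameter i of base
        parameter j is ``weight_i * d(state)/d(base_j)``.
        """
        idx, w = self.smoother.weights(phi)
        idx, w = idx[0], w[0]
        base = np.sum(w * self._sub[:, idx], axis=1)
        self.orientation.set_params(base[:3], only_free=False)
        self.cell.set_params(base[3:], only_free=False)
        U = self.orientation.get_state()
        B = self.cell.get_state()
        dU = self.orientation.get_ds_dp(only_free=False)
        dB = self.cell.get_ds_dp(only_free=False)
        return U, B, dU, dB, (idx, w)

    def states_at_boundaries(self, scan) -> list[tuple[np.ndarray, np.ndarray]]:
        """(U_k, B_k) at every integer image boundary of a scan."""
        out = []
        for kk in range(scan.n_images + 1):
            phi = float(scan.phi_from_image(kk))
            U, B, _, _, _ = self.compose_at(phi)
            out.append((U.copy(), B.copy()))
        return out
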