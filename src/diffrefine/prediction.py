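"""Reflection centroid prediction for rotation scans.

A reflection's centroid is the triplet (X, Y, phi): the millimetre impact
position on a detector panel and the rotation angle at which the
reciprocal-lattice point crosses the Ewald sphere (a "central impact").  For
a static crystal the crossing angles are found analytically from the
Rodrigues expansion of the rotated reciprocal-lattice vector; for a
scan-varying crystal the reciprocal-space path is approximated by per-image
linear segments and the crossing located by solving a quadratic for the
fractional position within the image.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .models import Experiment, detector_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "ReflectionTable",
    "ewald_intersection_angles",
    "generate_hkls",
    "predict_static",
    "predict_scan_varying",
    "match_observations",
]

TWO_PI = 2.0 * np.pi

# internal (radian / mm) column names, in canonical order
_COLUMNS = [
    "h",
    "k",
    "l",
    "panel",
    "entering",
    "x_obs",
    "y_obs",
    "phi_obs",
    "var_x",
    "var_y",
    "var_phi",
    "x_calc",
    "y_calc",
    "phi_calc",
    "image_coord_calc",
    "used",
    "outlier",
    "near_axis",
    "exp_id",
]

_FLAG_BITS = {"used": 1, "outlier": 2, "near_axis": 4}


class ReflectionTable:
    """Thin wrapper around a pandas DataFrame of reflections.

    Internal units are mm for X/Y, radians for phi and rad^2 for the phi
    variance.  The CSV representation uses degrees and a fixed column order
    so files diff cleanly between runs.
    """

    def __init__(self, data: pd.DataFrame | dict | None = None):
        if data is None:
            data = {c: [] for c in _COLUMNS}
        df = pd.DataFrame(data)
        for c in _COLUMNS:
            if c not in df.columns:
                if c in ("used", "outlier", "near_axis", "entering"):
                    df[c] = False
                elif c in ("h", "k", "l", "panel", "exp_id"):
                    df[c] = 0
                else:
                    df[c] = np.nan
        self.df = df[_COLUMNS].reset_index(drop=True)
        for c in ("h", "k", "l", "panel", "exp_id"):
            self.df[c] = self.df[c].astype(int)
        for c in ("entering", "used", "outlier", "near_axis"):
            self.df[c] = self.df[c].astype(bool)

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.df[col].to_numpy()

    def __setitem__(self, col: str, values) -> None:
        self.df[col] = values

    def copy(self) -> "ReflectionTable":
        return ReflectionTable(self.df.copy())

    def select(self, mask) -> "ReflectionTable":
        return ReflectionTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    # -- CSV round trip ----------------------------------------------------
    _CSV_COLUMNS = [
        "h",
        "k",
        "l",
        "panel",
        "entering",
        "x_obs_mm",
        "y_obs_mm",
        "phi_obs_deg",
        "var_x_mm2",
        "var_y_mm2",
        "var_phi_deg2",
        "x_calc_mm",
        "y_calc_mm",
        "phi_calc_deg",
        "flags",
    ]

    def to_csv(self, path) -> None:
        out = pd.DataFrame(
            {
                "h": self.df.h,
                "k": self.df.k,
                "l": self.df.l,
                "panel": self.df.panel,
                "entering": self.df.entering.astype(int),
                "x_obs_mm": self.df.x_obs,
                "y_obs_mm": self.df.y_obs,
                "phi_obs_deg": np.rad2deg(self.df.phi_obs),
                "var_x_mm2": self.df.var_x,
                "var_y_mm2": self.df.var_y,
                "var_phi_deg2": self.df.var_phi * np.rad2deg(1.0) ** 2,
                "x_calc_mm": self.df.x_calc,
                "y_calc_mm": self.df.y_calc,
                "phi_calc_deg": np.rad2deg(self.df.phi_calc),
                "flags": (
                    self.df.used.astype(int) * _FLAG_BITS["used"]
                    + self.df.outlier.astype(int) * _FLAG_BITS["outlier"]
                    + self.df.near_axis.astype(int) * _FLAG_BITS["near_axis"]
                ),
            }
        )[self._CSV_COLUMNS]
        out.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ReflectionTable":
        raw = pd.read_csv(path)
        missing = [c for c in cls._CSV_COLUMNS if c not in raw.columns]
        if missing:
            raise ValueError(f"reflection CSV {path} missing columns: {missing}")
        flags = raw["flags"].fillna(0).astype(int)
        df = pd.DataFrame(
            {
                "h": raw["h"],
                "k": raw["k"],
                "l": raw["l"],
                "panel": raw["panel"],
                "entering": raw["entering"].astype(bool),
                "x_obs": raw["x_obs_mm"],
                "y_obs": raw["y_obs_mm"],
                "phi_obs": np.deg2rad(raw["phi_obs_deg"]),
                "var_x": raw["var_x_mm2"],
                "var_y": raw["var_y_mm2"],
                "var_phi": raw["var_phi_deg2"] * np.deg2rad(1.0) ** 2,
                "x_calc": raw["x_calc_mm"],
                "y_calc": raw["y_calc_mm"],
                "phi_calc": np.deg2rad(raw["phi_calc_deg"]),
                "used": (flags & _FLAG_BITS["used"]) > 0,
                "outlier": (flags & _FLAG_BITS["outlier"]) > 0,
                "near_axis": (flags & _FLAG_BITS["near_axis"]) > 0,
            }
        )
        return cls(df)


# ---------------------------------------------------------------------------
# Ewald-sphere intersection


def _abc_coefficients(r0, axis, s0):
    """Coefficients of A cos(phi) + B sin(phi) = C for the diffraction condition.

    Vectorized over leading axes of r0.
    """
    r0 = np.asarray(r0, dtype=float)
    axis = np.asarray(axis, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    r_par = np.tensordot(r0, axis, axes=([-1], [0]))  # component along axis
    A = np.tensordot(r0, s0, axes=([-1], [0])) - r_par * np.dot(axis, s0)
    B = np.tensordot(np.cross(axis, r0), s0, axes=([-1], [0]))
    C = -0.5 * np.sum(r0 * r0, axis=-1) - r_par * np.dot(axis, s0)
    return A, B, C


def ewald_intersection_angles(r0, axis, s0) -> list[tuple[float, bool]]:
    """Rotation angles at which r0, rotated about axis, meets the Ewald sphere.

    Uses the Rodrigues expansion of the rotated vector, reducing the
    diffraction condition r_phi . s0 = -|r0|^2 / 2 to
    A cos(phi) + B sin(phi) = C.  Returns up to two (phi, entering) pairs
    with phi in [0, 2*pi), sorted ascending; ``entering`` is True when the
    point passes from outside to inside the sphere.  A tangential touch
    (discriminant ~ 0) yields a single solution flagged as exiting.
    """
    r0 = np.asarray(r0, dtype=float)
    if np.linalg.norm(r0) == 0:
        raise ValueError("r0 must be nonzero")
    A, B, C = _abc_coefficients(r0, axis, s0)
    rho = np.hypot(A, B)
    scale = max(rho, abs(C), 1e-300)
    if rho == 0 or abs(C) > rho * (1.0 + 1e-12):
        return []
    base = np.arctan2(B, A)
    ratio = np.clip(C / rho, -1.0, 1.0)
    delta = np.arccos(ratio)
    if delta < 1e-12 or (np.pi - delta) < 1e-12:
        # tangential: single solution, conventionally flagged exiting
        phi = (base + delta) % TWO_PI
        return [(float(phi), False)]
    out = []
    for phi in ((base + delta) % TWO_PI, (base - delta) % TWO_PI):
        # f(phi) = |s0 + r_phi|^2 - |s0|^2; entering when decreasing
        fprime = -A * np.sin(phi) + B * np.cos(phi)
        out.append((float(phi), bool(fprime < 0)))
    out.sort(key=lambda t: t[0])
    return out


def generate_hkls(UB: np.ndarray, dmin: float, max_count: int = 2_000_000) -> np.ndarray:
    """All nonzero integer index vectors h with |UB h| <= 1/dmin.

    The list is symmetric under negation.  Raises if the search box implies
    more candidates than ``max_count``.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    UB = np.asarray(UB, dtype=float)
    limit = 1.0 / dmin
    # bounding box in index space: |h_i| <= limit * row norms of UB^-1
    inv = np.linalg.inv(UB)
    bounds = np.ceil(limit * np.linalg.norm(inv, axis=1)).astype(int)
    n_cand = np.prod(2 * bounds + 1)
    if n_cand > max_count:
        raise ValueError(
            f"dmin={dmin} implies {n_cand} candidate indices (cap {max_count})"
        )
    axes = [np.arange(-b, b + 1) for b in bounds]
    H = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    r = H @ UB.T
    lens = np.linalg.norm(r, axis=1)
    keep = (lens <= limit) & (lens > 0)
    return H[keep]


# ---------------------------------------------------------------------------
# Static prediction


def _project_many(s1: np.ndarray, panel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized panel projection: returns X, Y, valid (forward and on-panel)."""
    _, D = detector_matrices(panel)
    uvw = s1 @ D.T
    w = uvw[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        X = uvw[:, 0] / w
        Y = uvw[:, 1] / w
    valid = (w > 0) & (X >= 0) & (X <= panel.x_lim) & (Y >= 0) & (Y <= panel.y_lim)
    return X, Y, valid


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues form)."""
    axis = np.asarray(axis, dtype=float)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _assign_panels(experiment: Experiment, s1: np.ndarray):
    """Project rays onto the first panel that contains them.

    Returns (panel ids, X, Y, on_any_panel); off-panel rays get panel -1.
    """
    n = len(s1)
    panel_id = np.full(n, -1, dtype=int)
    X_out = np.full(n, np.nan)
    Y_out = np.full(n, np.nan)
    for ipanel, panel in enumerate(experiment.detector.panels):
        X, Y, valid = _project_many(s1, panel)
        take = valid & (panel_id < 0)
        panel_id[take] = ipanel
        X_out[take] = X[take]
        Y_out[take] = Y[take]
    return panel_id, X_out, Y_out, panel_id >= 0


def predict_static(experiment: Experiment, dmin: float) -> ReflectionTable:
    """Predict all reflection centroids in the scan for a static crystal model.

    Every Ewald solution is unwound by integer turns so multi-turn scans
    (e.g. a continuous 720 degree collection) predict each reflection once
    per turn.  Rows falling outside all panels are dropped.
    """
    axis = experiment.goniometer.axis
    scan = experiment.scan
    s0 = experiment.beam.s0
    UB = experiment.crystal.UB

    H = generate_hkls(UB, dmin)
    r0 = H @ UB.T
    A, B, C = _abc_coefficients(r0, axis, s0)
    rho = np.hypot(A, B)
    ok = (rho > 0) & (np.abs(C) <= rho)
    H, r0, A, B, C, rho = H[ok], r0[ok], A[ok], B[ok], C[ok], rho[ok]
    base = np.arctan2(B, A)
    delta = np.arccos(np.clip(C / rho, -1.0, 1.0))
    tangential = delta < 1e-12

    sol_idx, sol_phi, sol_entering = [], [], []
    for sign in (+1.0, -1.0):
        phi = (base + sign * delta) % TWO_PI
        fprime = -A * np.sin(phi) + B * np.cos(phi)
        entering = fprime < 0
        keep = np.ones(len(phi), dtype=bool) if sign > 0 else ~tangential
        sol_idx.append(np.nonzero(keep)[0])
        sol_phi.append(phi[keep])
        sol_entering.append(entering[keep])
    idx = np.concatenate(sol_idx)
    phi = np.concatenate(sol_phi)
    entering = np.concatenate(sol_entering)

    # unwind each solution into every 2*pi turn overlapping the scan
    phi0, phi1 = scan.phi_start_rad, scan.phi_end_rad
    m_lo = np.ceil((phi0 - phi) / TWO_PI - 1e-12).astype(int)
    m_hi = np.floor((phi1 - phi) / TWO_PI + 1e-12).astype(int)
    counts = np.maximum(m_hi - m_lo + 1, 0)
    rep = np.repeat(np.arange(len(phi)), counts)
    # per-repetition turn number m_lo[i] .. m_hi[i]
    offsets = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    turns = np.repeat(m_lo, counts) + offsets
    phi_all = phi[rep] + TWO_PI * turns
    in_range = (phi_all >= phi0 - 1e-12) & (phi_all <= phi1 + 1e-12)
    rep, phi_all = rep[in_range], phi_all[in_range]

    full_idx = idx[rep]
    s1 = s0[None, :] + _rodrigues_rows(r0[full_idx], axis, phi_all)
    panel_id, X, Y, on_panel = _assign_panels(experiment, s1)

    keep = on_panel
    table = ReflectionTable(
        pd.DataFrame(
            {
                "h": H[full_idx][keep, 0],
                "k": H[full_idx][keep, 1],
                "l": H[full_idx][keep, 2],
                "panel": panel_id[keep],
                "entering": entering[rep][keep],
                "x_calc": X[keep],
                "y_calc": Y[keep],
                "phi_calc": phi_all[keep],
                "image_coord_calc": scan.image_from_phi(phi_all[keep]),
            }
        )
    )
    table.df = table.df.sort_values(["h", "k", "l", "phi_calc"]).reset_index(drop=True)
    return table


def _rodrigues_rows(r0: np.ndarray, axis: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate each row of r0 about the unit axis by the matching angle in phi."""
    r0 = np.atleast_2d(r0)
    axis = np.asarray(axis, dtype=float)
    r_par = np.outer(r0 @ axis, axis)
    r_perp = r0 - r_par
    cross = np.cross(np.broadcast_to(axis, r0.shape), r0, axis=-1)
    return r_par + np.cos(phi)[:, None] * r_perp + np.sin(phi)[:, None] * cross


# ---------------------------------------------------------------------------
# Scan-varying prediction (per-image linear chords)


def predict_scan_varying(
    experiment: Experiment,
    states: Sequence[tuple[np.ndarray, np.ndarray]],
    dmin: float,
    margin: float = 0.1,
) -> ReflectionTable:
    """Predict centroids for per-image crystal states (U_k, B_k) at image boundaries.

    ``states`` holds n_images + 1 pairs, one per integer image boundary.  For
    each image the reciprocal-space path of each candidate point is
    approximated by the straight segment between its boundary positions
    r_k and r_{k+1}; a sphere crossing within the image is located by solving
    |s0 + r_k + beta (r_{k+1} - r_k)|^2 = |s0|^2 for beta in [0, 1].  Only
    candidates whose boundary distance from the sphere is within
    ``margin * |s0|`` are tested per image.
    """
    scan = experiment.scan
    n_img = scan.n_images
    if len(states) != n_img + 1:
        raise ValueError(f"need {n_img + 1} boundary states, got {len(states)}")
    axis = experiment.goniometer.axis
    s0 = experiment.beam.s0
    s0_len = np.linalg.norm(s0)

    # candidate enumeration off the first boundary state
    UB0 = np.asarray(states[0][0]) @ np.asarray(states[0][1])
    H = generate_hkls(UB0, dmin)

    def boundary(kk: int) -> tuple[np.ndarray, np.ndarray]:
        U_k, B_k = states[kk]
        A_k = _rot(axis, float(scan.phi_from_image(kk))) @ np.asarray(U_k) @ np.asarray(B_k)
        r = H @ A_k.T
        f = np.linalg.norm(s0[None, :] + r, axis=-1) - s0_len
        return r, f

    chunks = []
    r_prev, f_prev = boundary(0)
    for kk in range(n_img):
        r_next, f_next = boundary(kk + 1)
        f0, f1 = f_prev, f_next
        near = (np.abs(f0) < margin * s0_len) | (np.abs(f1) < margin * s0_len)
        cand = np.nonzero(near)[0]
        if len(cand):
            rk = r_prev[cand]
            dr = r_next[cand] - rk
            s = s0[None, :] + rk
            a = np.sum(dr * dr, axis=1)
            b = 2.0 * np.sum(s * dr, axis=1)
            c = np.sum(s * s, axis=1) - s0_len**2
            disc = b * b - 4.0 * a * c
            with np.errstate(invalid="ignore", divide="ignore"):
                sq = np.sqrt(np.maximum(disc, 0.0))
                betas = np.stack([(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)], axis=1)
            valid = (disc[:, None] >= 0) & (a[:, None] > 0) & (betas >= 0.0) & (betas <= 1.0)
            sign_change = np.sign(f0[cand]) != np.sign(f1[cand])
            both = valid.all(axis=1) & (np.abs(betas[:, 0] - betas[:, 1]) > 1e-12)
            # a genuine boundary sign change admits exactly one chord root
            valid[both & sign_change, 1] = False
            n_double = int(np.count_nonzero(both & ~sign_change))
            if n_double:
                warnings.warn(
                    f"{n_double} double Ewald crossing(s) within image {kk}; keeping both rows"
                )
            j, which = np.nonzero(valid)
            if len(j):
                beta = betas[j, which]
                s1 = s0[None, :] + rk[j] + beta[:, None] * dr[j]
                panel_id, X, Y, on_panel = _assign_panels(experiment, s1)
                keep = on_panel
                image_coord = kk + beta[keep]
                chunks.append(
                    pd.DataFrame(
                        {
                            "h": H[cand[j]][keep, 0],
                            "k": H[cand[j]][keep, 1],
                            "l": H[cand[j]][keep, 2],
                            "panel": panel_id[keep],
                            "entering": f0[cand[j]][keep] > 0,
                            "x_calc": X[keep],
                            "y_calc": Y[keep],
                            "phi_calc": scan.phi_from_image(image_coord),
                            "image_coord_calc": image_coord,
                        }
                    )
                )
        r_prev, f_prev = r_next, f_next
    if not chunks:
        return ReflectionTable()
    df = pd.concat(chunks, ignore_index=True)
    df = df.sort_values(["h", "k", "l", "phi_calc"]).reset_index(drop=True)
    return ReflectionTable(df)


# ---------------------------------------------------------------------------
# Matching observations to predictions


def match_observations(observed: ReflectionTable, predicted: ReflectionTable) -> ReflectionTable:
    """Attach predicted centroids to observed rows.

    Rows are matched on (h, k, l, entering); where a reflection is predicted
    on several turns of a multi-turn scan the prediction with phi closest to
    the observation is taken.  Unmatched observations are dropped with a
    logged count.
    """
    obs = observed.df.copy()
    pred = predicted.df[
        ["h", "k", "l", "panel", "entering", "x_calc", "y_calc", "phi_calc", "image_coord_calc"]
    ].copy()
    obs["_row"] = np.arange(len(obs))
    merged = obs.drop(columns=["x_calc", "y_calc", "phi_calc", "image_coord_calc", "panel"]).merge(
        pred, on=["h", "k", "l", "entering"], how="inner"
    )
    if len(merged) == 0:
        logger.warning("no observations matched predictions")
        return ReflectionTable(merged.drop(columns=["_row"]))
    merged["_dphi"] = np.abs(merged.phi_calc - merged.phi_obs)
    merged = merged.sort_values("_dphi").drop_duplicates("_row").sort_values("_row")
    n_dropped = len(obs) - len(merged)
    if n_dropped:
        logger.info("dropped %d unmatched observations", n_dropped)
    return ReflectionTable(merged.drop(columns=["_row", "_dphi"]).reset_index(drop=True))
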