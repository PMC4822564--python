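"""Least-squares target: residuals, weights, Jacobian and reflection filters.

The target is the weighted sum of squared residuals between calculated and
observed centroids, L = sum_i wX rX^2 + wY rY^2 + wphi rphi^2.  Residuals are
interleaved per reflection as (X, Y, phi) so the residual vector has length
3n.  Gradients of the predicted centroid follow from the implicit Ewald
condition f(phi, params) = |s0 + R(phi) U B h|^2 - |s0|^2 = 0: for any
parameter p, dphi/dp = -(df/dp) / (df/dphi), with df/dphi proportional to the
triple product of rotation axis, beam vector and reciprocal-lattice vector.
Reflections for which that triple product is small (near the rotation axis)
have unstable phi derivatives and are excluded by the near-axis filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse

from .prediction import ReflectionTable, _abc_coefficients, _rodrigues_rows

__all__ = [
    "TargetState",
    "compute_residuals_and_weights",
    "build_jacobian",
    "predict_for_refinement",
    "filter_near_axis",
    "subsample_reflections",
]

TWO_PI = 2.0 * np.pi


@dataclass
class TargetState:
    """Residuals, weights and (optionally) the Jacobian of one target evaluation."""

    residuals: np.ndarray  # (3n,) interleaved X, Y, phi
    weights: np.ndarray  # (3n,)
    L: float
    jacobian: np.ndarray | None = None  # (3n, p)

    @property
    def rmsd(self) -> tuple[float, float, float]:
        """Unweighted r.m.s. deviations (X mm, Y mm, phi rad)."""
        r = self.residuals.reshape(-1, 3)
        return tuple(np.sqrt(np.mean(r * r, axis=0)))

    @property
    def gradient(self) -> np.ndarray:
        """dL/dp = 2 sum w r dr/dp."""
        if self.jacobian is None:
            raise ValueError("jacobian not computed")
        g = self.jacobian.T @ (self.weights * self.residuals)
        return 2.0 * np.asarray(g).ravel()


def compute_residuals_and_weights(
    table: ReflectionTable,
    scheme: str = "statistical",
    constants: tuple[float, float, float] | None = None,
) -> TargetState:
    """Residual and weight vectors for the rows of a reflection table.

    ``scheme`` is ``"statistical"`` (weights are inverse observed centroid
    variances) or ``"constant"`` (user-supplied wX, wY, wphi).
    """
    rx = table["x_calc"] - table["x_obs"]
    ry = table["y_calc"] - table["y_obs"]
    rphi = table["phi_calc"] - table["phi_obs"]
    residuals = np.column_stack([rx, ry, rphi]).ravel()
    if scheme == "statistical":
        var = np.column_stack([table["var_x"], table["var_y"], table["var_phi"]])
        bad = ~(var > 0)
        if np.any(bad):
            row = int(np.nonzero(bad.any(axis=1))[0][0])
            raise ValueError(
                f"statistical weighting needs positive variances; row {row} has {var[row]}"
            )
        weights = (1.0 / var).ravel()
    elif scheme == "constant":
        if constants is None:
            constants = (1.0, 1.0, 1.0)
        weights = np.tile(np.asarray(constants, dtype=float), len(table))
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    L = float(np.sum(weights * residuals**2))
    return TargetState(residuals=residuals, weights=weights, L=L)


# ---------------------------------------------------------------------------
# Prediction for refinement (matched reflections, nearest-turn phi)


def _solve_phi_matched(r0, axis, s0, entering, phi_near):
    """Ewald crossing angles matching each row's entering flag, on the turn nearest phi_near.

    Returns (phi, valid); rows whose reciprocal-lattice point cannot reach the
    sphere are flagged invalid.
    """
    A, B, C = _abc_coefficients(r0, axis, s0)
    rho = np.hypot(A, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = C / rho
    valid = (rho > 0) & (np.abs(ratio) <= 1.0)
    ratio = np.clip(np.where(valid, ratio, 0.0), -1.0, 1.0)
    base = np.arctan2(B, A)
    delta = np.arccos(ratio)
    phi_plus = base + delta
    phi_minus = base - delta
    entering_plus = (-A * np.sin(phi_plus) + B * np.cos(phi_plus)) < 0
    phi = np.where(entering == entering_plus, phi_plus, phi_minus)
    phi = phi + TWO_PI * np.round((phi_near - phi) / TWO_PI)
    return phi, valid


def predict_for_refinement(experiment_param, table: ReflectionTable) -> dict:
    """Recompute calculated centroids for observed reflections and cache geometry.

    Each observed reflection keeps its identity (hkl, entering flag, recorded
    panel); the crossing angle is re-solved from the current model states on
    the turn nearest the observation and projected onto the recorded panel.
    For a scan-varying crystal the states are taken at the image boundary
    nearest the observed centroid, which is cached per image.  Updates the
    ``*_calc`` columns in place and returns the geometry cache used by
    ``build_jacobian``.
    """
    ep = experiment_param
    exp = ep.experiment
    axis = exp.goniometer.axis
    scan = exp.scan
    s0 = ep.beam.get_state()
    H = np.column_stack([table["h"], table["k"], table["l"]])
    n = len(table)

    if ep.scan_varying is not None:
        k_obs = scan.image_from_phi(table["phi_obs"])
        keys = np.clip(np.round(k_obs).astype(int), 0, scan.n_images)
        r0 = np.empty((n, 3))
        states = {}
        for key in np.unique(keys):
            states[key] = ep.scan_varying.compose_at(float(scan.phi_from_image(key)))
        for key, st in states.items():
            sel = keys == key
            r0[sel] = H[sel] @ (st[0] @ st[1]).T
        cache_states = (keys, states)
    else:
        U = ep.orientation.get_state()
        B = ep.cell.get_state()
        r0 = H @ (U @ B).T
        cache_states = None

    phi, valid = _solve_phi_matched(r0, axis, s0, table["entering"], table["phi_obs"])
    rphi = _rodrigues_rows(r0, axis, phi)
    s1 = s0[None, :] + rphi

    d_states = ep.detector.get_state()
    D = [np.linalg.inv(d) for d in d_states]
    panel_ids = table["panel"]
    uvw = np.empty((n, 3))
    for ip, Dm in enumerate(D):
        sel = panel_ids == ip
        if np.any(sel):
            uvw[sel] = s1[sel] @ Dm.T
    w = uvw[:, 2]
    valid &= w > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        X = uvw[:, 0] / w
        Y = uvw[:, 1] / w

    table["x_calc"] = np.where(valid, X, np.nan)
    table["y_calc"] = np.where(valid, Y, np.nan)
    table["phi_calc"] = np.where(valid, phi, np.nan)
    table["image_coord_calc"] = np.where(valid, scan.image_from_phi(phi), np.nan)

    return {
        "H": H,
        "r0": r0,
        "phi": phi,
        "rphi": rphi,
        "s1": s1,
        "uvw": uvw,
        "valid": valid,
        "s0": s0,
        "axis": axis,
        "D": D,
        "d": d_states,
        "panel_ids": panel_ids,
        "scan_varying": cache_states,
    }


# ---------------------------------------------------------------------------
# Jacobian


def _xy_phi_columns(cache, ds1, dphi, extra_duvw=None):
    """Columns (dX, dY, dphi) from per-row derivatives of s1 and phi."""
    n = len(ds1)
    duvw = np.empty((n, 3))
    for ip, Dm in enumerate(cache["D"]):
        sel = cache["panel_ids"] == ip
        if np.any(sel):
            duvw[sel] = ds1[sel] @ Dm.T
    if extra_duvw is not None:
        duvw = duvw + extra_duvw
    u, v, w = cache["uvw"].T
    du, dv, dw = duvw.T
    with np.errstate(divide="ignore", invalid="ignore"):
        dX = (du * w - u * dw) / (w * w)
        dY = (dv * w - v * dw) / (w * w)
    return dX, dY, dphi


def _crystal_column(cache, dr0):
    """Centroid derivative columns for a perturbation dr0 of the reciprocal-lattice vector."""
    r0, phi, rphi, s0, axis = (
        cache["r0"],
        cache["phi"],
        cache["rphi"],
        cache["s0"],
        cache["axis"],
    )
    den = 2.0 * np.cross(axis, rphi) @ s0
    Rdr0 = _rodrigues_rows(dr0, axis, phi)
    df = 2.0 * np.sum(r0 * dr0, axis=1) + 2.0 * (Rdr0 @ s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dphi = -df / den
    ds1 = np.cross(axis, rphi) * dphi[:, None] + Rdr0
    return _xy_phi_columns(cache, ds1, dphi)


class _JacobianWriter:
    """Accumulates Jacobian entries either densely or as sparse triplets.

    The sparse form suits scan-varying and multi-experiment problems, where
    most columns touch only a small subset of rows (smoother locality and
    experiment-block sparsity); the normal matrix is then assembled without
    storing the structural zeros.
    """

    def __init__(self, n_rows: int, n_cols: int, sparse: bool):
        self.sparse = sparse
        self.shape = (n_rows, n_cols)
        if sparse:
            self._rows: list[np.ndarray] = []
            self._cols: list[np.ndarray] = []
            self._vals: list[np.ndarray] = []
        else:
            self.J = np.zeros((n_rows, n_cols))

    def add(self, rows: np.ndarray, col: int, dX, dY, dphi) -> None:
        if self.sparse:
            for off, vals in ((0, dX), (1, dY), (2, dphi)):
                self._rows.append(rows * 3 + off)
                self._cols.append(np.full(len(rows), col, dtype=np.int64))
                self._vals.append(np.asarray(vals, dtype=float))
        else:
            self.J[rows * 3, col] += dX
            self.J[rows * 3 + 1, col] += dY
            self.J[rows * 3 + 2, col] += dphi

    def finalize(self):
        if not self.sparse:
            return self.J
        rows = np.concatenate(self._rows) if self._rows else np.array([], dtype=np.int64)
        cols = np.concatenate(self._cols) if self._cols else np.array([], dtype=np.int64)
        vals = np.concatenate(self._vals) if self._vals else np.array([])
        vals = np.nan_to_num(vals, nan=0.0)
        return scipy.sparse.coo_matrix((vals, (rows, cols)), shape=self.shape).tocsr()


def build_jacobian(
    parameter_map, table: ReflectionTable, caches: dict[int, dict], sparse: bool = False
):
    """Assemble the (3n, p) Jacobian of centroid residuals over all experiments.

    ``caches`` maps experiment index to the geometry cache returned by
    ``predict_for_refinement``.  Columns belonging to parameterisations not
    attached to a reflection's experiment stay exactly zero (block sparsity);
    with ``sparse=True`` those zeros are never stored.
    """
    n = len(table)
    writer = _JacobianWriter(3 * n, parameter_map.num_free, sparse)
    exp_ids = table["exp_id"]
    for iexp, ep in enumerate(parameter_map.experiment_params):
        rows = np.nonzero(exp_ids == iexp)[0]
        if len(rows) == 0:
            continue
        cache = caches[iexp]
        _fill_experiment_block(parameter_map, ep, cache, rows, writer)
    return writer.finalize()


def _fill_experiment_block(pmap, ep, cache, rows, writer):
    axis, s0, rphi, r0, phi = (
        cache["axis"],
        cache["s0"],
        cache["rphi"],
        cache["r0"],
        cache["phi"],
    )
    H = cache["H"]

    # beam parameters
    cols = pmap.columns_of(ep.beam)
    if cols is not None:
        den = 2.0 * np.cross(axis, rphi) @ s0
        for col, ds0 in zip(cols, ep.beam.get_ds_dp()):
            df = 2.0 * (rphi @ ds0)
            with np.errstate(divide="ignore", invalid="ignore"):
                dphi = -df / den
            ds1 = ds0[None, :] + np.cross(axis, rphi) * dphi[:, None]
            dX, dY, dphi_col = _xy_phi_columns(cache, ds1, dphi)
            writer.add(rows, col, dX, dY, dphi_col)

    # static crystal parameters
    if ep.scan_varying is None:
        U = ep.orientation.get_state()
        B = ep.cell.get_state()
        cols = pmap.columns_of(ep.orientation)
        if cols is not None:
            for col, dU in zip(cols, ep.orientation.get_ds_dp()):
                dr0 = H @ (dU @ B).T
                dX, dY, dphi = _crystal_column(cache, dr0)
                writer.add(rows, col, dX, dY, dphi)
        cols = pmap.columns_of(ep.cell)
        if cols is not None:
            for col, dB in zip(cols, ep.cell.get_ds_dp()):
                dr0 = H @ (U @ dB).T
                dX, dY, dphi = _crystal_column(cache, dr0)
                writer.add(rows, col, dX, dY, dphi)
    else:
        _fill_scan_varying(pmap, ep, cache, rows, writer)

    # detector parameters
    cols = pmap.columns_of(ep.detector)
    if cols is not None:
        s1 = cache["s1"]
        n = len(s1)
        for col, dd_panels in zip(cols, ep.detector.get_ds_dp()):
            duvw = np.zeros((n, 3))
            for ip, (Dm, dd) in enumerate(zip(cache["D"], dd_panels)):
                sel = cache["panel_ids"] == ip
                if np.any(sel):
                    dD = -Dm @ dd @ Dm
                    duvw[sel] = s1[sel] @ dD.T
            dX, dY, dphi = _xy_phi_columns(
                cache, np.zeros((n, 3)), np.zeros(n), extra_duvw=duvw
            )
            writer.add(rows, col, dX, dY, dphi)


def _fill_scan_varying(pmap, ep, cache, rows, writer):
    sv = ep.scan_varying
    cols = pmap.columns_of(sv)
    if cols is None:
        return
    keys, states = cache["scan_varying"]
    n_pts = sv.smoother.n_points
    col0 = cols[0]
    H = cache["H"]
    for key, st in states.items():
        sel = np.nonzero(keys == key)[0]
        if len(sel) == 0:
            continue
        U, B, dU_list, dB_list, (idx, wts) = st
        sub_cache = {
            "r0": cache["r0"][sel],
            "phi": cache["phi"][sel],
            "rphi": cache["rphi"][sel],
            "s1": cache["s1"][sel],
            "uvw": cache["uvw"][sel],
            "s0": cache["s0"],
            "axis": cache["axis"],
            "D": cache["D"],
            "panel_ids": cache["panel_ids"][sel],
        }
        base_derivs = [(j, dU_list[j] @ B) for j in range(3)] + [
            (3 + m, U @ dB_list[m]) for m in range(len(dB_list))
        ]
        for j, M in base_derivs:
            dr0 = H[sel] @ M.T
            dX, dY, dphi = _crystal_column(sub_cache, dr0)
            for i_pt, w_pt in zip(idx, wts):
                col = col0 + j * n_pts + int(i_pt)
                writer.add(rows[sel], col, w_pt * dX, w_pt * dY, w_pt * dphi)


# ---------------------------------------------------------------------------
# Filters


def filter_near_axis(table: ReflectionTable, experiments, cutoff: float = 0.05) -> ReflectionTable:
    """Flag reflections whose rotated reciprocal-lattice vector lies near the rotation axis.

    The criterion is the volume of the parallelepiped spanned by the
    normalised rotation axis, beam vector and reciprocal-lattice vector at
    the crossing angle; rows with volume below ``cutoff`` get the
    ``near_axis`` flag and are excluded from refinement.  All three vectors
    are normalised, making the volume dimensionless in [0, 1] and the default
    cutoff scale-free.
    """
    if not isinstance(experiments, (list, tuple)):
        experiments = [experiments]
    vol = np.empty(len(table))
    exp_ids = table["exp_id"] if "exp_id" in table.df.columns else np.zeros(len(table), dtype=int)
    for iexp, exp in enumerate(experiments):
        sel = np.nonzero(exp_ids == iexp)[0]
        if len(sel) == 0:
            continue
        H = np.column_stack([table["h"], table["k"], table["l"]])[sel]
        r0 = H @ exp.crystal.UB.T
        rphi = _rodrigues_rows(r0, exp.goniometer.axis, table["phi_calc"][sel])
        r_hat = rphi / np.linalg.norm(rphi, axis=1, keepdims=True)
        s0_hat = exp.beam.s0 / np.linalg.norm(exp.beam.s0)
        g_hat = exp.goniometer.axis
        vol[sel] = np.abs(np.cross(s0_hat, r_hat) @ g_hat)
    out = table.copy()
    out["near_axis"] = vol < cutoff
    out["used"] = out["used"] & ~out["near_axis"]
    return out


def subsample_reflections(
    table: ReflectionTable, per_degree: float, scan_range_deg: float, seed: int
) -> ReflectionTable:
    """Uniform random subset of about per_degree * scan_range rows (capped at the table size)."""
    if per_degree <= 0:
        raise ValueError("per_degree must be positive")
    target_n = int(round(per_degree * scan_range_deg))
    if target_n >= len(table):
        return table.copy()
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(table), size=target_n, replace=False))
    return table.select(np.isin(np.arange(len(table)), keep))
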