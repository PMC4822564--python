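"""Refinement orchestration: joint parameter vector, minimization, history.

One or more experiments are refined together against their observed
centroids.  Model sharing is expressed by attaching the *same*
parameterisation object to several experiments (e.g. one detector
parameterisation serving every experiment of a multi-lattice data set);
shared parameterisations contribute their parameters to the global vector
exactly once, and Jacobian columns for parameters not attached to a
reflection's experiment are identically zero.

Three minimizers are provided.  Gauss-Newton solves the normal equations
directly and converges fastest on well-conditioned problems; the default
Levenberg-Marquardt adds multiplicative damping of the normal-matrix
diagonal (scale-invariant across mm and radian parameters) with the damping
factor divided by 10 on an accepted step and multiplied by 10 on a rejected
one; L-BFGS uses only the target value and gradient and suits problems too
large for an explicit normal matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse

from .models import Experiment
from .parameterisation import (
    BeamParameterisation,
    CellParameterisation,
    CrystalOrientationParameterisation,
    DetectorParameterisation,
    ScanVaryingCrystalParameterisation,
)
from .prediction import ReflectionTable
from .target import (
    TargetState,
    build_jacobian,
    compute_residuals_and_weights,
    filter_near_axis,
    predict_for_refinement,
    subsample_reflections,
)
from . import outliers as outliers_mod

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentParameterisation",
    "ParameterMap",
    "RefinementResult",
    "minimize",
    "build_parameter_map",
    "refine",
]


@dataclass
class ExperimentParameterisation:
    """The set of model parameterisations attached to one experiment."""

    experiment: Experiment
    beam: BeamParameterisation
    orientation: CrystalOrientationParameterisation | None
    cell: CellParameterisation | None
    detector: DetectorParameterisation
    scan_varying: ScanVaryingCrystalParameterisation | None = None

    @classmethod
    def for_experiment(
        cls,
        experiment: Experiment,
        fix: dict[str, list[str]] | None = None,
        scan_varying: bool = False,
        interval_width_deg: float = 36.0,
    ) -> "ExperimentParameterisation":
        """Default parameterisation: beam (mu1, nu fixed), crystal, rigid detector."""
        fix = fix or {}
        beam = BeamParameterisation(
            experiment.beam, experiment.goniometer, fixed=fix.get("beam", ("mu1", "nu"))
        )
        detector = DetectorParameterisation(experiment.detector, fixed=fix.get("detector"))
        if scan_varying:
            scan = experiment.scan
            sv = ScanVaryingCrystalParameterisation(
                experiment.crystal,
                (scan.phi_start_rad, scan.phi_end_rad),
                interval_width=np.deg2rad(interval_width_deg),
            )
            return cls(experiment, beam, None, None, detector, sv)
        orientation = CrystalOrientationParameterisation(
            experiment.crystal, fixed=fix.get("orientation")
        )
        cell = CellParameterisation(experiment.crystal, fixed=fix.get("cell"))
        return cls(experiment, beam, orientation, cell, detector, None)

    def parameterisations(self) -> list:
        out = [self.beam]
        if self.scan_varying is not None:
            out.append(self.scan_varying)
        else:
            out.extend([self.orientation, self.cell])
        out.append(self.detector)
        return out

    def update_models(self) -> None:
        self.beam.update_model()
        self.detector.update_model()
        if self.scan_varying is None:
            self.orientation.update_model()
            self.cell.update_model()


class ParameterMap:
    """Global free-parameter vector across experiments with shared-model bookkeeping.

    Parameterisation objects appearing in more than one experiment (model
    sharing) are counted once, in first-seen order.
    """

    def __init__(self, experiment_params: list[ExperimentParameterisation]):
        self.experiment_params = list(experiment_params)
        for ep in self.experiment_params:
            if ep.experiment is None or ep.beam is None or ep.detector is None:
                raise ValueError("every experiment needs beam, crystal and detector models")
        self._unique = []
        self._columns: dict[int, range] = {}
        ofs = 0
        for ep in self.experiment_params:
            for p in ep.parameterisations():
                if id(p) in self._columns:
                    continue
                n = p.num_free
                self._columns[id(p)] = range(ofs, ofs + n)
                self._unique.append(p)
                ofs += n
        self.num_free = ofs
        if self.num_free == 0:
            raise ValueError("no free parameters")

    @property
    def names(self) -> list[str]:
        out = []
        for i, p in enumerate(self._unique):
            prefix = type(p).__name__.replace("Parameterisation", "")
            out.extend(f"{prefix}{i}.{n}" for n in p.free_names)
        return out

    def columns_of(self, parameterisation) -> range | None:
        return self._columns.get(id(parameterisation))

    def get_free_params(self) -> np.ndarray:
        return np.concatenate([p.get_params() for p in self._unique])

    def set_free_params(self, x: np.ndarray) -> None:
        for p in self._unique:
            cols = self._columns[id(p)]
            p.set_params(np.asarray(x)[cols.start : cols.stop])


def build_parameter_map(experiment_params) -> ParameterMap:
    """Assemble the joint parameter vector for one or more experiments."""
    return ParameterMap(experiment_params)


# ---------------------------------------------------------------------------
# Target evaluation over the joint problem


class JointTarget:
    """Evaluates residuals, weights and Jacobian for the current global parameters."""

    def __init__(
        self,
        parameter_map: ParameterMap,
        table: ReflectionTable,
        weighting: str = "statistical",
        constants: tuple[float, float, float] | None = None,
        sparse: bool | None = None,
    ):
        self.pmap = parameter_map
        self.table = table
        self.weighting = weighting
        self.constants = constants
        if sparse is None:
            # sparse pays off once smoother/multi-experiment columns dominate
            sparse = parameter_map.num_free > 40
        self.sparse = sparse

    def __call__(self, x: np.ndarray, jacobian: bool = True) -> TargetState:
        self.pmap.set_free_params(x)
        caches = {}
        exp_ids = self.table["exp_id"]
        for iexp, ep in enumerate(self.pmap.experiment_params):
            sub = self.table.select(exp_ids == iexp)
            caches[iexp] = predict_for_refinement(ep, sub)
            # write back the refreshed calc columns
            for col in ("x_calc", "y_calc", "phi_calc", "image_coord_calc"):
                vals = self.table[col]
                vals[exp_ids == iexp] = sub[col]
                self.table[col] = vals
        state = compute_residuals_and_weights(self.table, self.weighting, self.constants)
        bad = ~np.isfinite(state.residuals)
        if np.any(bad):
            # zero weight removes unreachable rows from L, gradient and normal matrix
            state.residuals = np.where(bad, 0.0, state.residuals)
            state.weights = np.where(bad, 0.0, state.weights)
            state.L = float(np.sum(state.weights * state.residuals**2))
        if jacobian:
            state.jacobian = build_jacobian(self.pmap, self.table, caches, sparse=self.sparse)
            if not scipy.sparse.issparse(state.jacobian) and np.any(bad):
                state.jacobian[bad] = 0.0
        return state


# ---------------------------------------------------------------------------
# Minimizers


@dataclass
class RefinementResult:
    """Outcome of a minimization: parameters, history and final target state."""

    x: np.ndarray
    state: TargetState
    history: list[dict] = field(default_factory=list)
    termination: str = ""
    n_iterations: int = 0

    @property
    def rmsd(self) -> tuple[float, float, float]:
        return self.state.rmsd


def _record(history, step, state, x):
    rx, ry, rphi = state.rmsd
    history.append(
        {
            "step": int(step),
            "L": float(state.L),
            "rmsd_x_mm": float(rx),
            "rmsd_y_mm": float(ry),
            "rmsd_phi_deg": float(np.rad2deg(rphi)),
            "params": [float(v) for v in x],
        }
    )


def minimize(
    target: JointTarget,
    x0: np.ndarray | None = None,
    method: str = "levenberg_marquardt",
    max_iterations: int = 100,
    rel_L_tol: float = 1e-7,
    step_tol: float = 1e-8,
    lm_lambda0: float = 1e-3,
) -> RefinementResult:
    """Minimize the centroid target from starting parameters x0.

    Termination: relative decrease of L below ``rel_L_tol``, step norm below
    ``step_tol`` or ``max_iterations`` reached.
    """
    if x0 is None:
        x0 = target.pmap.get_free_params()
    x = np.asarray(x0, dtype=float).copy()
    n_resid = 3 * len(target.table)
    if method in ("gauss_newton", "levenberg_marquardt") and n_resid <= len(x):
        raise ValueError("need more residuals than parameters for least squares")

    if method == "lbfgs":
        return _minimize_lbfgs(target, x, max_iterations, rel_L_tol)
    if method not in ("gauss_newton", "levenberg_marquardt"):
        raise ValueError(f"unknown minimization method {method!r}")

    lam = lm_lambda0 if method == "levenberg_marquardt" else 0.0
    state = target(x, jacobian=True)
    if not np.isfinite(state.L):
        raise ValueError("non-finite target at the starting point")
    history: list[dict] = []
    _record(history, 0, state, x)
    termination = "max_iterations"
    it = 0
    for it in range(1, max_iterations + 1):
        J = state.jacobian
        W = state.weights
        r = state.residuals
        if scipy.sparse.issparse(J):
            JTW = J.T @ scipy.sparse.diags(W)
            N = np.asarray((JTW @ J).todense())
            g = np.asarray(JTW @ r).ravel()
        else:
            JTW = J.T * W
            N = JTW @ J
            g = JTW @ r
        while True:
            if method == "levenberg_marquardt":
                N_damped = N + lam * np.diag(np.diag(N))
            else:
                N_damped = N
            try:
                step = np.linalg.solve(N_damped, -g)
            except np.linalg.LinAlgError as exc:
                if method == "gauss_newton":
                    raise ValueError(
                        "singular normal matrix in Gauss-Newton; try levenberg_marquardt"
                    ) from exc
                lam *= 10.0
                if lam > 1e12:
                    raise ValueError("Levenberg-Marquardt damping diverged") from exc
                continue
            x_new = x + step
            state_new = target(x_new, jacobian=True)
            if not np.isfinite(state_new.L):
                raise ValueError("non-finite target during refinement")
            if state_new.L <= state.L or method == "gauss_newton":
                accepted = True
            else:
                accepted = False
            if accepted:
                if method == "levenberg_marquardt":
                    lam = max(lam / 10.0, 1e-12)
                break
            lam *= 10.0
            if lam > 1e12:
                # cannot improve further
                state_new, x_new, step = state, x, np.zeros_like(x)
                break
        L_prev = state.L
        x, state = x_new, state_new
        _record(history, it, state, x)
        if np.linalg.norm(step) < step_tol:
            termination = "small_step"
            break
        if L_prev > 0 and abs(L_prev - state.L) / max(L_prev, 1e-300) < rel_L_tol:
            termination = "small_L_decrease"
            break
    target.pmap.set_free_params(x)
    for ep in target.pmap.experiment_params:
        ep.update_models()
    return RefinementResult(x=x, state=state, history=history, termination=termination, n_iterations=it)


def _minimize_lbfgs(target, x0, max_iterations, rel_L_tol):
    history: list[dict] = []

    # diagonal pre-scaling from the initial normal-matrix diagonal; without it
    # the mixed mm / rad / inverse-square-angstrom parameter scales defeat the
    # line search
    state0 = target(x0, jacobian=True)
    J = state0.jacobian
    W = state0.weights
    if scipy.sparse.issparse(J):
        diag = np.asarray(J.multiply(J).T @ W).ravel()
    else:
        diag = (J * J).T @ W
    scale = 1.0 / np.sqrt(np.where(diag > 0, diag, 1.0))

    def fun(y):
        state = target(x0 + scale * y, jacobian=True)
        return state.L, scale * state.gradient

    res = scipy.optimize.minimize(
        fun,
        np.zeros_like(x0),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iterations, "ftol": rel_L_tol, "gtol": 1e-12},
    )
    x = x0 + scale * res.x
    state = target(x, jacobian=True)
    _record(history, res.nit, state, x)
    target.pmap.set_free_params(x)
    for ep in target.pmap.experiment_params:
        ep.update_models()
    return RefinementResult(
        x=x, state=state, history=history, termination=str(res.message), n_iterations=int(res.nit)
    )


# ---------------------------------------------------------------------------
# High-level pipeline


def refine(
    experiments,
    observations: ReflectionTable,
    fix: dict[str, list[str]] | None = None,
    scan_varying: bool = False,
    interval_width_deg: float = 36.0,
    method: str = "levenberg_marquardt",
    outlier_algorithm: str = "mcd",
    outlier_level: float = 0.975,
    tukey_multiplier: float = 1.5,
    near_axis_cutoff: float = 0.05,
    sample_per_degree: float | None = None,
    weighting: str = "statistical",
    constants: tuple[float, float, float] | None = None,
    max_iterations: int = 100,
    seed: int = 0,
    experiment_params: list[ExperimentParameterisation] | None = None,
) -> tuple[RefinementResult, ReflectionTable, ParameterMap]:
    """Full refinement protocol for one or more experiments.

    Protocol: predict matched centroids, flag near-axis reflections, then —
    when outlier rejection is requested — run an initial minimization so the
    rejection operates on residuals free of systematic model error, reject
    once, and minimize again on the accepted subset.  Scan-varying
    refinement should be seeded with a converged scan-static model
    (``scan_varying=True`` builds the smoothed crystal parameterisation).
    Pass ``experiment_params`` to control sharing of parameterisations
    between experiments; otherwise each experiment gets its own.
    """
    if not isinstance(experiments, (list, tuple)):
        experiments = [experiments]
    if experiment_params is None:
        experiment_params = [
            ExperimentParameterisation.for_experiment(
                e, fix=fix, scan_varying=scan_varying, interval_width_deg=interval_width_deg
            )
            for e in experiments
        ]
    pmap = build_parameter_map(experiment_params)

    table = observations.copy()
    table["used"] = True
    # initial prediction for filtering
    exp_ids = table["exp_id"]
    for iexp, ep in enumerate(experiment_params):
        sub = table.select(exp_ids == iexp)
        predict_for_refinement(ep, sub)
        for col in ("x_calc", "y_calc", "phi_calc", "image_coord_calc"):
            vals = table[col]
            vals[exp_ids == iexp] = sub[col]
            table[col] = vals
    table["used"] = table["used"] & np.isfinite(table["phi_calc"])

    table = filter_near_axis(table, experiments, cutoff=near_axis_cutoff)

    if outlier_algorithm != "none":
        if outlier_algorithm not in ("tukey", "mcd"):
            raise ValueError(f"unknown outlier algorithm {outlier_algorithm!r}")
        # initial fit so rejection sees residuals free of systematic model error
        sel_idx = np.nonzero(table["used"])[0]
        prefit_table = table.select(table["used"])
        prefit_target = JointTarget(pmap, prefit_table, weighting, constants)
        minimize(prefit_target, method=method, max_iterations=max_iterations)
        resid = np.column_stack(
            [
                prefit_table["x_calc"] - prefit_table["x_obs"],
                prefit_table["y_calc"] - prefit_table["y_obs"],
                prefit_table["phi_calc"] - prefit_table["phi_obs"],
            ]
        )
        finite = np.all(np.isfinite(resid), axis=1)
        mask = np.zeros(len(resid), dtype=bool)
        if outlier_algorithm == "tukey":
            mask[finite] = outliers_mod.tukey_outliers(resid[finite], multiplier=tukey_multiplier)
        else:
            est = outliers_mod.fast_mcd(resid[finite], seed=seed)
            mask[finite] = outliers_mod.mahalanobis_outliers(
                resid[finite], level=outlier_level, estimate=est
            )
        outlier_col = table["outlier"]
        outlier_col[sel_idx[mask]] = True
        table["outlier"] = outlier_col
        table["used"] = table["used"] & ~table["outlier"]
        logger.info("flagged %d outliers of %d reflections", int(mask.sum()), len(mask))

    working = table.select(table["used"])
    if sample_per_degree is not None:
        range_deg = max(e.scan.n_images * e.scan.osc_width for e in experiments)
        working = subsample_reflections(working, sample_per_degree, range_deg, seed)

    target = JointTarget(pmap, working, weighting, constants)
    result = minimize(target, method=method, max_iterations=max_iterations)
    return result, working, pmap
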