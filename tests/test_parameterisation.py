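"""Parameter-to-state composition and analytic state derivatives."""

import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from diffrefine.models import B_from_cell, Beam, Crystal, Detector, Goniometer, Panel
from diffrefine.parameterisation import (
    FREE_METRICAL_PARAMS,
    BeamParameterisation,
    CellParameterisation,
    CrystalOrientationParameterisation,
    DetectorParameterisation,
    GaussianSmoother,
    ScanVaryingCrystalParameterisation,
    smoother_num_points,
)


def finite_difference_states(param, step_scale=1e-6):
    """Central-difference derivatives of a parameterisation's state."""
    values = param.get_params(only_free=False)
    out = []
    for i in range(len(values)):
        h = step_scale * max(abs(values[i]), 1.0)
        for sign in (+1, -1):
            v = values.copy()
            v[i] += sign * h
            param.set_params(v, only_free=False)
            if sign > 0:
                hi = _as_array(param.get_state())
            else:
                lo = _as_array(param.get_state())
        out.append((hi - lo) / (2 * h))
    param.set_params(values, only_free=False)
    return out


def _as_array(state):
    if isinstance(state, list):
        return np.stack(state)
    return np.asarray(state)


def _beam_and_gonio():
    return (
        Beam(direction=np.array([0.0, 0.0, -1.0]), wavelength=1.2),
        Goniometer(axis=np.array([1.0, 0.0, 0.0])),
    )


class TestBeamParameterisation:
    def test_initial_state_reproduced(self):
        beam, gonio = _beam_and_gonio()
        bp = BeamParameterisation(beam, gonio, fixed=())
        assert np.allclose(bp.get_state(), beam.s0, atol=1e-15)

    def test_quarter_turn_perpendicular(self):
        beam, gonio = _beam_and_gonio()
        bp = BeamParameterisation(beam, gonio, fixed=())
        vals = bp.get_params(only_free=False)
        vals[1] = np.pi / 2
        bp.set_params(vals, only_free=False)
        s0 = bp.get_state()
        assert abs(np.dot(s0, beam.direction)) < 1e-12
        assert np.linalg.norm(s0) == pytest.approx(vals[2])

    def test_default_fixed_parameters(self):
        beam, gonio = _beam_and_gonio()
        bp = BeamParameterisation(beam, gonio)
        assert bp.free_names == ["mu2"]
        assert bp.num_free == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_derivatives_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        beam, gonio = _beam_and_gonio()
        bp = BeamParameterisation(beam, gonio, fixed=())
        bp.set_params(
            [rng.normal(0, 0.01), rng.normal(0, 0.01), 1 / 1.2 * (1 + rng.normal(0, 0.001))],
            only_free=False,
        )
        fd = finite_difference_states(bp)
        for analytic, numeric in zip(bp.get_ds_dp(only_free=False), fd):
            assert np.allclose(analytic, numeric, rtol=1e-6, atol=1e-10)


class TestOrientationParameterisation:
    def _crystal(self, seed=0):
        U = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
        return Crystal(U=U, B=B_from_cell((10, 12, 14, 90, 90, 90)), crystal_system="orthorhombic")

    def test_zero_missets_give_datum(self):
        crystal = self._crystal()
        op = CrystalOrientationParameterisation(crystal)
        assert np.allclose(op.get_state(), crystal.U, atol=1e-15)

    def test_quarter_turn_about_z(self):
        crystal = Crystal(U=np.eye(3), B=np.eye(3) * 0.1, crystal_system="cubic")
        op = CrystalOrientationParameterisation(crystal)
        op.set_params([0.0, 0.0, np.pi / 2], only_free=False)
        U = op.get_state()
        assert np.allclose(U[:, 0], [0, 1, 0], atol=1e-12)
        assert np.allclose(U[:, 1], [-1, 0, 0], atol=1e-12)
        assert np.allclose(U[:, 2], [0, 0, 1], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_derivatives_and_rotation_property(self, seed):
        rng = np.random.default_rng(seed)
        op = CrystalOrientationParameterisation(self._crystal(seed))
        op.set_params(rng.normal(0, 0.02, 3), only_free=False)
        U = op.get_state()
        assert np.allclose(U.T @ U, np.eye(3), atol=1e-10)
        assert np.linalg.det(U) == pytest.approx(1.0, abs=1e-10)
        fd = finite_difference_states(op)
        for analytic, numeric in zip(op.get_ds_dp(only_free=False), fd):
            assert np.allclose(analytic, numeric, rtol=1e-6, atol=1e-9)


class TestCellParameterisation:
    @pytest.mark.parametrize(
        "system,cell,expected_free",
        [
            ("triclinic", (10, 11, 12, 85, 95, 100), 6),
            ("monoclinic", (10, 11, 12, 90, 95, 90), 4),
            ("orthorhombic", (10, 11, 12, 90, 90, 90), 3),
            ("tetragonal", (10, 10, 12, 90, 90, 90), 2),
            ("trigonal", (10, 10, 12, 90, 90, 120), 2),
            ("hexagonal", (10, 10, 12, 90, 90, 120), 2),
            ("cubic", (10, 10, 10, 90, 90, 90), 1),
        ],
    )
    def test_free_parameter_counts_and_round_trip(self, system, cell, expected_free):
        crystal = Crystal(U=np.eye(3), B=B_from_cell(cell), crystal_system=system)
        cp = CellParameterisation(crystal)
        assert cp.num_total == expected_free
        assert len(FREE_METRICAL_PARAMS[system]) == expected_free
        assert np.allclose(cp.get_state(), crystal.B, atol=1e-12)
        assert np.allclose(cp.real_cell(), cell, atol=1e-9)

    def test_cubic_compose(self):
        crystal = Crystal(U=np.eye(3), B=np.eye(3) * 0.1, crystal_system="cubic")
        cp = CellParameterisation(crystal)
        cp.set_params([0.01], only_free=False)
        assert np.allclose(cp.get_state(), np.eye(3) * 0.1, atol=1e-12)

    def test_tetragonal_tie(self):
        crystal = Crystal(
            U=np.eye(3), B=B_from_cell((10, 10, 12, 90, 90, 90)), crystal_system="tetragonal"
        )
        cp = CellParameterisation(crystal)
        g11, g33 = cp.get_params(only_free=False)
        cp.set_params([g11 * 1.01, g33], only_free=False)
        a, b, c, *_ = cp.real_cell()
        assert a == b
        assert c == pytest.approx(12.0)
        assert a == pytest.approx(10.0 / np.sqrt(1.01))

    def test_inconsistent_B_rejected(self):
        crystal = Crystal(
            U=np.eye(3), B=B_from_cell((10, 11, 12, 90, 90, 90)), crystal_system="orthorhombic"
        )
        crystal.crystal_system = "cubic"
        with pytest.raises(ValueError, match="cubic"):
            CellParameterisation(crystal)

    def test_non_spd_parameters_raise(self):
        crystal = Crystal(U=np.eye(3), B=np.eye(3) * 0.1, crystal_system="cubic")
        cp = CellParameterisation(crystal)
        cp.set_params([-0.01], only_free=False)
        with pytest.raises(ValueError, match="invalid cell"):
            cp.get_state()

    def test_rotated_datum_B_reproduced(self):
        # a B that is not upper-triangular must still round-trip exactly
        R = Rotation.from_rotvec([0.1, -0.2, 0.3]).as_matrix()
        B = R @ B_from_cell((10, 11, 12, 85, 95, 100))
        crystal = Crystal(U=np.eye(3), B=B, crystal_system="triclinic")
        cp = CellParameterisation(crystal)
        assert np.allclose(cp.get_state(), B, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_triclinic_derivatives(self, seed):
        rng = np.random.default_rng(seed)
        cell = (10 + rng.uniform(0, 2), 11.0, 12.0, 85.0, 95.0, 100.0)
        crystal = Crystal(U=np.eye(3), B=B_from_cell(cell), crystal_system="triclinic")
        cp = CellParameterisation(crystal)
        fd = finite_difference_states(cp, step_scale=1e-6)
        for analytic, numeric in zip(cp.get_ds_dp(only_free=False), fd):
            assert np.allclose(analytic, numeric, rtol=1e-5, atol=1e-6)


def _two_panel_detector():
    return Detector(
        [
            Panel(
                d0=np.array([-60.0, -30.0, -100.0]),
                d1_hat=np.array([1.0, 0.0, 0.0]),
                d2_hat=np.array([0.0, 1.0, 0.0]),
                pixel_size=(0.1, 0.1),
                image_size=(580, 600),
            ),
            Panel(
                d0=np.array([2.0, -30.0, -100.0]),
                d1_hat=np.array([1.0, 0.0, 0.0]),
                d2_hat=np.array([0.0, 1.0, 0.0]),
                pixel_size=(0.1, 0.1),
                image_size=(580, 600),
            ),
        ]
    )


class TestDetectorParameterisation:
    def test_initial_state_reproduced(self, flat_panel):
        det = Detector([copy.deepcopy(flat_panel)])
        dp = DetectorParameterisation(det)
        (d,) = dp.get_state()
        assert np.allclose(d[:, 0], flat_panel.d1_hat, atol=1e-12)
        assert np.allclose(d[:, 1], flat_panel.d2_hat, atol=1e-12)
        assert np.allclose(d[:, 2], flat_panel.d0, atol=1e-12)

    def test_pure_translation(self, flat_panel):
        det = Detector([copy.deepcopy(flat_panel)])
        dp = DetectorParameterisation(det)
        vals = dp.get_params(only_free=False)
        vals[1] += 5.0  # t1
        dp.set_params(vals, only_free=False)
        (d,) = dp.get_state()
        assert np.allclose(d[:, 0], flat_panel.d1_hat, atol=1e-12)
        assert np.allclose(d[:, 2], flat_panel.d0 + 5.0 * flat_panel.d1_hat, atol=1e-12)

    def test_multi_panel_rigidity(self):
        det = _two_panel_detector()
        gap = det[1].d0 - det[0].d0
        old_d1 = det[0].d1_hat.copy()
        dp = DetectorParameterisation(det)
        vals = dp.get_params(only_free=False)
        vals += np.array([1.0, 2.0, -3.0, 0.01, -0.02, 0.03])
        dp.set_params(vals, only_free=False)
        dp.update_model()
        # relative geometry between the two panels is preserved
        new_gap = det[1].d0 - det[0].d0
        assert np.linalg.norm(new_gap) == pytest.approx(np.linalg.norm(gap), abs=1e-10)
        assert np.dot(det[0].d1_hat, det[1].d1_hat) == pytest.approx(1.0, abs=1e-12)
        assert np.dot(new_gap, det[0].d1_hat) == pytest.approx(np.dot(gap, old_d1), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_derivatives_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        det = _two_panel_detector()
        dp = DetectorParameterisation(det)
        vals = dp.get_params(only_free=False)
        vals += np.concatenate([rng.normal(0, 0.5, 3), rng.normal(0, 0.01, 3)])
        dp.set_params(vals, only_free=False)
        fd = finite_difference_states(dp)
        for analytic, numeric in zip(dp.get_ds_dp(only_free=False), fd):
            assert np.allclose(np.stack(analytic), numeric, rtol=1e-6, atol=1e-8)

    def test_frozen_axes_give_frame_independence(self, flat_panel):
        # parameterising a rotated detector and composing the same parameter
        # update yields the rotation of the unrotated composition
        R = Rotation.random(random_state=np.random.default_rng(8)).as_matrix()
        det1 = Detector([copy.deepcopy(flat_panel)])
        panel2 = Panel(
            d0=R @ flat_panel.d0,
            d1_hat=R @ flat_panel.d1_hat,
            d2_hat=R @ flat_panel.d2_hat,
            pixel_size=flat_panel.pixel_size,
            image_size=flat_panel.image_size,
        )
        det2 = Detector([panel2])
        dp1 = DetectorParameterisation(det1)
        dp2 = DetectorParameterisation(det2)
        delta = np.array([0.5, 1.0, -2.0, 0.01, 0.02, -0.01])
        dp1.set_params(dp1.get_params(only_free=False) + delta, only_free=False)
        dp2.set_params(dp2.get_params(only_free=False) + delta, only_free=False)
        (d1,) = dp1.get_state()
        (d2,) = dp2.get_state()
        assert np.allclose(R @ d1, d2, atol=1e-9)


class TestGaussianSmoother:
    def test_num_points_rule(self):
        assert smoother_num_points(720, 36) == 22
        assert smoother_num_points(36, 36) == 3
        # round-half-to-even: 90/36 = 2.5 -> 2 intervals -> 4 points
        assert smoother_num_points(90, 36) == 4

    def test_flat_curve(self):
        sm = GaussianSmoother((0.0, np.deg2rad(360)), np.deg2rad(36))
        subparams = np.full(sm.n_points, 2.718)
        for phi in np.deg2rad([0.0, 17.3, 101.0, 359.9]):
            value, _ = sm.evaluate(phi, subparams)
            assert value == pytest.approx(2.718, abs=1e-12)

    def test_adjacent_weight_is_13_percent(self):
        sm = GaussianSmoother((0.0, np.deg2rad(360)), np.deg2rad(36))
        w_adjacent = np.exp(-1.0 / sm.sigma_sq)  # unnormalised weight one interval away
        assert w_adjacent == pytest.approx(0.13, abs=1e-12)

    def test_weights_normalised(self):
        sm = GaussianSmoother((0.0, np.deg2rad(100)), np.deg2rad(36))
        rng = np.random.default_rng(0)
        phis = rng.uniform(0, np.deg2rad(100), 50)
        idx, w = sm.weights(phis)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)
        assert idx.shape == w.shape == (50, 3)

    def test_outside_range_raises(self):
        sm = GaussianSmoother((0.0, np.deg2rad(90)), np.deg2rad(36))
        with pytest.raises(ValueError, match="outside"):
            sm.evaluate(np.deg2rad(120.0), np.zeros(sm.n_points))


class TestScanVaryingCrystal:
    def _crystal(self):
        return Crystal(
            U=np.eye(3), B=B_from_cell((57.7, 57.7, 150.0, 90, 90, 90)), crystal_system="tetragonal"
        )

    def test_flat_subparameters_give_constant_state(self):
        crystal = self._crystal()
        sv = ScanVaryingCrystalParameterisation(crystal, (0.0, np.deg2rad(360)))
        for phi in np.deg2rad([0.0, 33.0, 180.0, 359.0]):
            U, B, _, _, _ = sv.compose_at(phi)
            assert np.allclose(U, crystal.U, atol=1e-12)
            assert np.allclose(B, crystal.B, atol=1e-12)

    def test_subparameter_layout(self):
        sv = ScanVaryingCrystalParameterisation(
            self._crystal(), (0.0, np.deg2rad(720)), interval_width=np.deg2rad(36)
        )
        # 5 base parameters (3 missets + 2 tetragonal metricals) x 22 points
        assert sv.num_free == 110
        assert sv.smoother.n_points == 22
        assert sv.param_names[0] == "phi1_s0"
        assert sv.param_names[-1] == "g33_s21"

    def test_local_subparameter_has_local_effect(self):
        sv = ScanVaryingCrystalParameterisation(
            self._crystal(), (0.0, np.deg2rad(360)), interval_width=np.deg2rad(36)
        )
        params = sv.get_params()
        params = params.reshape(sv.n_base, -1)
        params[0, 5] += 0.01  # bump one phi1 subparameter mid-scan
        sv.set_params(params.ravel())
        near = sv.base_params_at(np.deg2rad([5 * 36.0 - 18.0]))[0]
        far = sv.base_params_at(np.deg2rad([300.0]))[0]
        assert abs(near[0]) > 1e-3
        assert abs(far[0]) < 1e-12
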