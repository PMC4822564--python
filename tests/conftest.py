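"""Shared fixtures: small synthetic experiments used across the test suite."""

import numpy as np
import pytest

from diffrefine.models import B_from_cell, Beam, Crystal, Detector, Experiment, Goniometer, Panel, Scan
from diffrefine.synthetic import SimulationConfig, make_experiment, simulate_observations


@pytest.fixture
def flat_panel() -> Panel:
    """100 x 100 mm beam-normal panel at 100 mm, origin at a corner."""
    return Panel(
        d0=np.array([-50.0, -50.0, -100.0]),
        d1_hat=np.array([1.0, 0.0, 0.0]),
        d2_hat=np.array([0.0, 1.0, 0.0]),
        pixel_size=(0.1, 0.1),
        image_size=(1000, 1000),
    )


@pytest.fixture
def cubic_experiment() -> Experiment:
    """Small cubic-crystal experiment with an identity orientation."""
    return Experiment(
        beam=Beam(direction=np.array([0.0, 0.0, -1.0]), wavelength=1.0),
        goniometer=Goniometer(axis=np.array([1.0, 0.0, 0.0])),
        detector=Detector(
            [
                Panel(
                    d0=np.array([-100.0, -100.0, -120.0]),
                    d1_hat=np.array([1.0, 0.0, 0.0]),
                    d2_hat=np.array([0.0, 1.0, 0.0]),
                    pixel_size=(0.1, 0.1),
                    image_size=(2000, 2000),
                )
            ]
        ),
        crystal=Crystal(U=np.eye(3), B=B_from_cell((10, 10, 10, 90, 90, 90)), crystal_system="cubic"),
        scan=Scan(image_range=(1, 200), osc_start=0.0, osc_width=0.1),
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    """Quick tetragonal simulation: 10 degree scan, ~1800 reflections."""
    return SimulationConfig(n_images=100, dmin=4.0, seed=0)


@pytest.fixture
def small_problem(small_config):
    """(truth experiment, noisy observations) for the quick configuration."""
    truth = make_experiment(small_config)
    obs = simulate_observations(truth, small_config)
    return truth, obs


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
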