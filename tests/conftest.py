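import numpy as np
import pytest

from imcluster import (
    ClusterGeometry,
    GaitParams,
    NoiseModel,
    reference_scenario,
    simulate_cluster_readings,
    synth_gait_trajectory,
)

ZERO_NOISE = dict(gyro_density=0.0, accel_density=0.0)


@pytest.fixture(scope="session")
def ideal_geometry():
    return ClusterGeometry()


@pytest.fixture(scope="session")
def walk_truth():
    """Ten-step walking ground truth in the simulated-walker regime."""
    return synth_gait_trajectory(GaitParams(duration=10 / 1.8, seed=5))


@pytest.fixture(scope="session")
def baseline_truth():
    """A 30 s unperturbed baseline recording (threshold extraction)."""
    return synth_gait_trajectory(GaitParams(duration=30.0, seed=1))


@pytest.fixture(scope="session")
def scenario_series(walk_truth):
    """Reference-scenario noisy measurements of the ten-step walk."""
    geometry, noise = reference_scenario(seed=11)
    return simulate_cluster_readings(geometry, walk_truth, noise)


def noiseless_readings(truth, geometry=None, seed=0):
    geom = geometry or ClusterGeometry()
    return simulate_cluster_readings(geom, truth, NoiseModel(seed=seed, **ZERO_NOISE))


@pytest.fixture(scope="session")
def static_truth_factory():
    from imcluster import KinematicTruth

    def make(n=2001, rate=200.0, gravity=9.81):
        t = np.arange(n) / rate
        a0 = np.tile([0.0, 0.0, gravity], (n, 1))
        return KinematicTruth(t, np.zeros((n, 3)), np.zeros((n, 3)), a0)

    return make
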