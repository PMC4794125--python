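import logging

import numpy as np
import pytest

from cfrwplan import cfrw
from cfrwplan.scene import (AngleLimits, NeedleGeometry, RigidTransform,
                            SuperQuadric, Target)
from cfrwplan.synthetic_scenes import make_sphere_oracle_scene

logging.getLogger("cfrwplan").setLevel(logging.ERROR)


def make_sphere_sq(radius, center, level=1000.0, label="sphere"):
    a = radius / np.sqrt(level)
    return SuperQuadric((a, a, a), (2, 2, 2), level,
                        RigidTransform(np.eye(3), np.asarray(center, float)),
                        label=label)


@pytest.fixture(scope="session")
def sphere_setup():
    """Sphere-obstacle scene with its closed-form tangent-cone oracle."""
    scene, oracle = make_sphere_oracle_scene(r=10.0, D=40.0, gamma=1.5)
    return scene, oracle


@pytest.fixture(scope="session")
def sphere_system(sphere_setup):
    scene, _oracle = sphere_setup
    return cfrw.CFRWSystem(scene.targets[0], scene.needle, scene.obstacles[0],
                           scene.angle_limits, 150.0, 1.5, 0.1)


@pytest.fixture(scope="session")
def sphere_boundary_state(sphere_system):
    """One polished boundary-criterion state on the z=150 circle."""
    return cfrw.find_boundary_point(sphere_system, np.array([120.0, 0.0]),
                                    np.array([-1.0, 0.0]))


@pytest.fixture(scope="session")
def sphere_curve(sphere_system, sphere_boundary_state):
    """The traced z=150 boundary circle (shared across tests)."""
    return cfrw.trace_boundary(sphere_system, sphere_boundary_state, step=0.5)


@pytest.fixture()
def default_needle():
    return NeedleGeometry.default()


@pytest.fixture()
def limits_full():
    return AngleLimits(0.0, 1.2, -np.pi, np.pi)


@pytest.fixture()
def origin_target():
    return Target(np.zeros(3))
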