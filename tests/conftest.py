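import numpy as np
import pytest

from twistloop.dynamics import SimulationState, make_state
from twistloop.forcefield import ForceFieldParams
from twistloop.geometry import (
    initial_frames,
    unit_tangents,
    unwrap_angles,
    wrapped_joint_angles,
)
from twistloop.model import build_fiber
from twistloop.units import UnitSystem


@pytest.fixture
def units():
    return UnitSystem()


@pytest.fixture
def params():
    return ForceFieldParams()


def perturbed_twisted_ring(n=12, seed=0, pos_noise=0.1, twist_noise=0.3, circular=True):
    """A thermally roughened fibre with random material twist: the standard
    non-trivial configuration for gradient and bookkeeping checks."""
    rng = np.random.default_rng(seed)
    f = build_fiber(n_beads=n, circular=circular)
    f.positions = f.positions + pos_noise * rng.standard_normal(f.positions.shape)
    f.frames = initial_frames(f.positions, circular)
    t = unit_tangents(f.positions, circular)
    ang = twist_noise * rng.standard_normal(len(t))
    c, s = np.cos(ang)[:, None], np.sin(ang)[:, None]
    m = f.frames
    tdotm = np.einsum("ij,ij->i", t, m)[:, None]
    f.frames = m * c + np.cross(t, m) * s + t * tdotm * (1 - c)
    f.joint_twist = unwrap_angles(
        wrapped_joint_angles(f.frames, t, circular), np.zeros(f.n_joints)
    )
    f.joint_twist0 = 0.2 * rng.standard_normal(f.n_joints)
    return f


@pytest.fixture
def twisted_ring_state():
    f = perturbed_twisted_ring()
    return make_state(f, seed=1)
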