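"""Shared fixtures and synthetic-trajectory helpers."""

import numpy as np
import pandas as pd
import pytest

from nanobrush import ForceField, Geometry, ParticleSystem, Trajectory
from nanobrush.geometry import CYLINDER, PLANAR


@pytest.fixture(scope="session")
def ff() -> ForceField:
    return ForceField(eps_b=1.0)


def make_system(positions, species=None, chains=None, frozen=None,
                velocities=None):
    """Assemble a ParticleSystem from raw arrays for targeted tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if species is None:
        species = np.zeros(n, dtype=np.int8)
    if chains is None:
        chains = np.zeros((0, 1), dtype=np.int32)
        anchors = np.zeros((0, 3))
    else:
        chains = np.asarray(chains, dtype=np.int32)
        anchors = positions[chains[:, 0]].copy()
    if frozen is None:
        frozen = np.zeros(n, dtype=bool)
    if velocities is None:
        velocities = np.zeros((n, 3))
    return ParticleSystem(positions, np.asarray(velocities, dtype=float),
                          np.asarray(species, dtype=np.int8), chains,
                          anchors, np.asarray(frozen, dtype=bool))


def make_traj(frames, geometry, species=None, chains=None, anchors=None):
    """Assemble a Trajectory from raw position frames for observables tests."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    n = frames.shape[1]
    if species is None:
        species = np.zeros(n, dtype=np.int8)
    if chains is None:
        chains = np.zeros((0, 1), dtype=np.int32)
    chains = np.asarray(chains, dtype=np.int32)
    if anchors is None:
        anchors = (frames[0][chains[:, 0]] if chains.size else np.zeros((0, 3)))
    return Trajectory(steps=np.arange(frames.shape[0], dtype=np.int64),
                      positions=frames, species=np.asarray(species, np.int8),
                      geometry=geometry, chains=chains,
                      graft_anchors=np.asarray(anchors, dtype=float),
                      thermo=pd.DataFrame())


@pytest.fixture
def planar_geom():
    return Geometry(kind=PLANAR, box=(16.0, 16.0, 60.0), sigma_g=0.0625)


@pytest.fixture
def cylinder_geom():
    return Geometry(kind=CYLINDER, box=(8.0, 40.0, 40.0), sigma_g=0.0625,
                    R=10.0)
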