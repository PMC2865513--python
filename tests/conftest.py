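"""Shared fixtures: toy tetramers and hand-built structures."""

from __future__ import annotations

import numpy as np
import pytest

from hbquat import TetramerModel, make_toy_tetramer
from hbquat.structure_io import SUBUNITS


@pytest.fixture(scope="session")
def toy():
    """Standard toy tetramer: 14 deg quaternary rotation, 0.1 nm tertiary."""
    return make_toy_tetramer(n_res_per_subunit=12, quat_angle_deg=14.0,
                             tert_amplitude=0.1, seed=3)


@pytest.fixture(scope="session")
def toy_quat_only():
    """Pure quaternary toy: endpoints differ only by the 14 deg rotation."""
    return make_toy_tetramer(n_res_per_subunit=12, quat_angle_deg=14.0,
                             tert_amplitude=0.0, seed=3)


def build_model(atoms, frame_time=0.0):
    """Build a TetramerModel from rows of
    (name, res_name, chain, res_seq, element, subunit, x, y, z [nm])."""
    cols = list(zip(*atoms))
    return TetramerModel.from_arrays(
        name=cols[0], residue_name=cols[1], chain_id=cols[2],
        residue_seq=cols[3], element=cols[4], subunit=cols[5],
        coords=np.array(cols[6:9], dtype=float).T, frame_time=frame_time)


def minimal_tetramer_rows():
    """Three C-alpha atoms per subunit: the smallest valid tetramer."""
    rows = []
    offsets = {"alpha1": (0, 0, 0), "beta1": (0, 3, 0),
               "alpha2": (3, 0, 0), "beta2": (3, 3, 0)}
    chains = {"alpha1": "A", "beta1": "B", "alpha2": "C", "beta2": "D"}
    for sub in SUBUNITS:
        ox, oy, oz = offsets[sub]
        for j in range(3):
            rows.append(("CA", "GLY", chains[sub], j + 1, "C", sub,
                         ox + 0.3 * j, oy + 0.1 * j * j, oz + 0.05 * j))
    return rows


@pytest.fixture()
def minimal_tetramer():
    return build_model(minimal_tetramer_rows())


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()
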