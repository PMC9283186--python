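"""Shared fixtures: generated meshes, flow bases and snapshot sets.

Heavy artifacts (structured/foamed fixtures, the 64-corner snapshot
set) are session-scoped so the acceptance tests and unit tests share
one offline phase.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from scaffoldrom._fem import P1Operators
from scaffoldrom.potential_flow import build_velocity_basis
from scaffoldrom.rom_pod import SnapshotSet, build_snapshots, corner_sampling
from scaffoldrom.scaffold_geometry import (
    BoxSpec,
    FoamedScaffoldSpec,
    StructuredScaffoldSpec,
    TetMesh,
    generate_foamed,
    generate_structured,
    tag_boundaries,
    voxel_to_tets,
)
from scaffoldrom.transport_fe import TransportSettings


@pytest.fixture(scope="session")
def box60() -> BoxSpec:
    return BoxSpec((60.0, 60.0, 60.0), 10.0)


@pytest.fixture(scope="session")
def box_mesh(box60) -> TetMesh:
    """Full 6x6x6-voxel box, corner tagging (no solid boundary)."""
    mask = np.ones(box60.shape, dtype=bool)
    mesh = voxel_to_tets(mask, box60)
    return tag_boundaries(mesh, box60, scheme="corner")


def make_duct(h: float, L: float = 200.0, width: float = 50.0):
    """Duct mesh for the 1-D transport oracle: inlet at x=0, Robin at
    x=L, natural zero-flux side walls."""
    box = BoxSpec((L, width, width), h)
    mask = np.ones(box.shape, dtype=bool)
    mesh = voxel_to_tets(mask, box)
    tag_boundaries(mesh, box, scheme="duct", axis=0)
    return box, mesh


@pytest.fixture(scope="session")
def duct_coarse():
    box, mesh = make_duct(25.0)
    ops = P1Operators(mesh)
    return box, mesh, ops, build_velocity_basis(mesh, ops)


@pytest.fixture(scope="session")
def structured_fixture():
    """Default printed-like scaffold: ~1.6k nodes, porosity ≈ 0.542."""
    box = BoxSpec((240.0, 240.0, 240.0), 20.0)
    mesh = generate_structured(
        box, StructuredScaffoldSpec(diameter=80.0, spacing=150.0)
    )
    ops = P1Operators(mesh)
    return box, mesh, ops, build_velocity_basis(mesh, ops)


@pytest.fixture(scope="session")
def foamed_fixture():
    box = BoxSpec((240.0, 240.0, 240.0), 20.0)
    mesh = generate_foamed(
        box,
        FoamedScaffoldSpec(median_radius=40.0, target_porosity=0.523, seed=1),
    )
    ops = P1Operators(mesh)
    return box, mesh, ops, build_velocity_basis(mesh, ops)


@pytest.fixture(scope="session")
def snaps64(structured_fixture) -> SnapshotSet:
    """64-corner training set on the structured fixture."""
    _, mesh, ops, flow = structured_fixture
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_snapshots(
            mesh, corner_sampling(), flow, TransportSettings(), ops=ops
        )


@pytest.fixture
def quiet_angles():
    """Silence out-of-range angle warnings for axis-aligned oracles."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
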