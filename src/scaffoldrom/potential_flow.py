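"""Directional potential-flow velocity basis and parametrized advection.

The advection field is a parametrized combination of three normalized
velocity fields obtained from potential flow along each box axis:

    v(v, γ, β) = v (sin γ cos β v_x + sin γ sin β v_y + cos γ v_z)

Each basis field solves Laplace's equation with unit potential drop
between the axis' min- and max-coordinate planes and natural (no-flux)
conditions on all remaining boundary, then is normalized so that its
volume-averaged speed is one.  With that convention the parameter v is
the mean interstitial speed in μm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from scaffoldrom import _fem
from scaffoldrom.scaffold_geometry import TetMesh

AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}
ANGLE_RANGE = (10.0, 80.0)


class FlowError(RuntimeError):
    pass


@dataclass
class VelocityBasis:
    """Three normalized nodal velocity fields and their provenance."""

    fields: tuple[np.ndarray, np.ndarray, np.ndarray]  # each (d, 3)
    normalization: tuple[float, float, float]
    mesh_fingerprint: str
    convention: str = "mean_speed"

    @property
    def vx(self) -> np.ndarray:
        return self.fields[0]

    @property
    def vy(self) -> np.ndarray:
        return self.fields[1]

    @property
    def vz(self) -> np.ndarray:
        return self.fields[2]


@dataclass
class AdvectionField:
    """Nodal advection velocity (μm/s) for one parameter combination."""

    values: np.ndarray  # (d, 3)
    v: float
    gamma: float
    beta: float


def _plane_nodes(mesh: TetMesh, axis: int, at_max: bool) -> np.ndarray:
    coords = mesh.nodes[:, axis]
    lengths = mesh.metadata.get("box_lengths")
    L = float(lengths[axis]) if lengths is not None else float(coords.max())
    tol = 1e-9 * max(1.0, L)
    target = L if at_max else 0.0
    return np.nonzero(np.abs(coords - target) < tol)[0]


def solve_potential(
    mesh: TetMesh,
    axis: int | str,
    ops: _fem.P1Operators | None = None,
) -> np.ndarray:
    """P1 Galerkin solution of Laplace's equation along ``axis``.

    Potential is 1 on the axis' minimum-coordinate plane, 0 on the
    maximum-coordinate plane, with zero normal flux elsewhere.
    """
    ax = AXES[axis]
    ops = ops or _fem.P1Operators(mesh)
    inlet = _plane_nodes(mesh, ax, at_max=False)
    outlet = _plane_nodes(mesh, ax, at_max=True)
    if inlet.size == 0 or outlet.size == 0:
        raise FlowError(
            f"axis {axis}: no nodes on the min/max planes; the fluid "
            "domain does not span the box along this axis"
        )
    K = ops.stiffness(np.ones(mesh.num_tets))
    f = np.zeros(mesh.num_nodes)
    dirichlet = np.concatenate([inlet, outlet])
    values = np.concatenate([np.ones(inlet.size), np.zeros(outlet.size)])
    Kbc, fbc = _fem.apply_dirichlet(K, f, dirichlet, values)
    phi = _fem.solve_sparse(Kbc, fbc)
    return phi


def potential_flux_balance(
    mesh: TetMesh, phi: np.ndarray, axis: int | str,
    ops: _fem.P1Operators | None = None,
) -> tuple[float, float]:
    """Discretely conservative (reaction-based) inlet and outlet fluxes.

    Sums the unconstrained stiffness residual over the Dirichlet node
    sets; Galerkin orthogonality makes inlet + outlet vanish to solver
    precision.
    """
    ax = AXES[axis]
    ops = ops or _fem.P1Operators(mesh)
    K = ops.stiffness(np.ones(mesh.num_tets))
    reaction = K @ phi
    inlet = _plane_nodes(mesh, ax, at_max=False)
    outlet = _plane_nodes(mesh, ax, at_max=True)
    return float(reaction[inlet].sum()), float(reaction[outlet].sum())


def velocity_from_potential(
    mesh: TetMesh, phi: np.ndarray, ops: _fem.P1Operators | None = None
) -> np.ndarray:
    """Nodal velocity −∇φ (volume-weighted average of element gradients)."""
    ops = ops or _fem.P1Operators(mesh)
    elem_v = -ops.element_gradient(phi)  # (m, 3)
    return ops.node_average(elem_v)


def mean_speed(mesh: TetMesh, field: np.ndarray, ops: _fem.P1Operators | None = None) -> float:
    """Volume-averaged speed (1/V_Ω) ∫ |v| dV with lumped nodal weights."""
    ops = ops or _fem.P1Operators(mesh)
    speed = np.linalg.norm(field, axis=1)
    return float((ops.lumped_volumes * speed).sum() / ops.lumped_volumes.sum())


def normalize_field(
    mesh: TetMesh, field: np.ndarray, ops: _fem.P1Operators | None = None
) -> tuple[np.ndarray, float]:
    """Scale a nodal field to unit volume-averaged speed."""
    c = mean_speed(mesh, field, ops)
    if c <= 0.0:
        raise FlowError("cannot normalize an identically zero field")
    return field / c, c


def build_velocity_basis(
    mesh: TetMesh, ops: _fem.P1Operators | None = None
) -> VelocityBasis:
    """Solve, differentiate and normalize the three directional fields."""
    ops = ops or _fem.P1Operators(mesh)
    fields = []
    constants = []
    for axis in ("x", "y", "z"):
        phi = solve_potential(mesh, axis, ops)
        vel = velocity_from_potential(mesh, phi, ops)
        vel, c = normalize_field(mesh, vel, ops)
        fields.append(vel)
        constants.append(c)
    return VelocityBasis(
        fields=tuple(fields),
        normalization=tuple(constants),
        mesh_fingerprint=mesh.fingerprint(),
    )


def combine_velocity(
    basis: VelocityBasis, v: float, gamma: float, beta: float
) -> AdvectionField:
    """Nodal advection field for speed ``v`` (μm/s) and angles in degrees."""
    if v < 0:
        raise FlowError("velocity module v must be non-negative")
    for name, angle in (("gamma", gamma), ("beta", beta)):
        if not ANGLE_RANGE[0] <= angle <= ANGLE_RANGE[1]:
            warnings.warn(
                f"{name}={angle} outside the configured range {ANGLE_RANGE}",
                stacklevel=2,
            )
    g = np.deg2rad(gamma)
    b = np.deg2rad(beta)
    coeffs = (np.sin(g) * np.cos(b), np.sin(g) * np.sin(b), np.cos(g))
    values = v * (
        coeffs[0] * basis.vx + coeffs[1] * basis.vy + coeffs[2] * basis.vz
    )
    return AdvectionField(values=values, v=v, gamma=gamma, beta=beta)


# -- persistence -------------------------------------------------------------


def save_velocity_basis(basis: VelocityBasis, path) -> None:
    with h5py.File(path, "w") as h5:
        for name, f in zip(("vx", "vy", "vz"), basis.fields):
            h5.create_dataset(name, data=f)
        h5.attrs["normalization"] = np.asarray(basis.normalization)
        h5.attrs["mesh_fingerprint"] = basis.mesh_fingerprint
        h5.attrs["convention"] = basis.convention


def load_velocity_basis(path) -> VelocityBasis:
    with h5py.File(path, "r") as h5:
        fields = tuple(h5[name][...] for name in ("vx", "vy", "vz"))
        return VelocityBasis(
            fields=fields,
            normalization=tuple(float(v) for v in h5.attrs["normalization"]),
            mesh_fingerprint=str(h5.attrs["mesh_fingerprint"]),
            convention=str(h5.attrs["convention"]),
        )
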