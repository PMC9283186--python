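"""Full-order steady advection-diffusion transport with Picard iteration.

The concentration c (normalized by the saturation value, so c ∈ [0, 1])
satisfies

    −∇·(ν ∇c) + v·∇c = 0      in Ω,
    c = 0                      on the inlet Γ_I,
    ∇c·n = 0                   on the outlet Γ_O,
    −ν ∂c/∂n = r (c − 1)       on the solid interface Γ_S,

with a concentration-dependent diffusivity ν = D_SE 10^(−α c) and the
Stokes–Einstein free-solution coefficient D_SE = k_B T / (6π η ρ).
For α > 0 the problem is nonlinear and solved by Picard iteration with
a relative-update stopping tolerance of 1e-8.

Internal unit system: μm, s; diffusivities are converted from m²/s to
μm²/s (×1e12).  The printed release-rate parameter r is mapped to an
effective Robin coefficient r_eff = r · r_scale in μm/s (r_scale is a
configuration knob, default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from scaffoldrom import _fem
from scaffoldrom.potential_flow import VelocityBasis, combine_velocity
from scaffoldrom.scaffold_geometry import TAG_INLET, TAG_SOLID, TetMesh

PARAMETER_NAMES = ("v", "gamma", "beta", "alpha", "eta", "r")

#: Parameter ranges (printed units: μm/s, degrees, –, Pa·s, release units).
TABLE_RANGES: dict[str, tuple[float, float]] = {
    "v": (1.0, 60.0),
    "gamma": (10.0, 80.0),
    "beta": (10.0, 80.0),
    "alpha": (0.0, 1.0),
    "eta": (5e-4, 1.5e-3),
    "r": (0.5, 2.0),
}


class TransportError(RuntimeError):
    pass


@dataclass(frozen=True)
class ParameterPoint:
    """One sample μ of the six-dimensional parametric space."""

    v: float
    gamma: float
    beta: float
    alpha: float
    eta: float
    r: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAMETER_NAMES])

    @classmethod
    def from_array(cls, arr) -> "ParameterPoint":
        return cls(**{k: float(v) for k, v in zip(PARAMETER_NAMES, arr)})

    def with_value(self, name: str, value: float) -> "ParameterPoint":
        if name not in PARAMETER_NAMES:
            raise TransportError(f"unknown parameter {name!r}")
        return replace(self, **{name: float(value)})


#: Mid-range point used as a default for sweeps and fixtures.
def midrange_point() -> ParameterPoint:
    return ParameterPoint.from_array(
        [0.5 * (lo + hi) for lo, hi in TABLE_RANGES.values()]
    )


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the Stokes-Einstein relation plus model scalings."""

    k_B: float = 1.38e-23  # J/K
    T: float = 310.15  # K  (37 °C)
    ion_radius: float = 114e-12  # m, Ca2+ ionic radius
    r_scale: float = 10.0  # μm/s per printed release-rate unit


@dataclass(frozen=True)
class TransportSettings:
    tol: float = 1e-8
    max_iterations: int = 50
    supg: bool = False


@dataclass
class AssembledSystem:
    K: object  # scipy CSR, Dirichlet rows reduced to identity
    f: np.ndarray
    dirichlet_nodes: np.ndarray


@dataclass
class ConcentrationField:
    values: np.ndarray
    mu: ParameterPoint
    iterations: int
    converged: bool
    residuals: list[float] = field(default_factory=list)

    @property
    def bounds_violation(self) -> float:
        """Largest excursion outside [0, 1] (maximum-principle check)."""
        return float(
            max(0.0, -self.values.min(), self.values.max() - 1.0)
        )


def stokes_einstein(
    eta: float, constants: PhysicalConstants = PhysicalConstants()
) -> tuple[float, float]:
    """Free-solution diffusivity, returned in (m²/s, μm²/s)."""
    if eta <= 0:
        raise TransportError("viscosity must be positive")
    D = constants.k_B * constants.T / (6.0 * np.pi * eta * constants.ion_radius)
    return D, D * 1e12


def diffusivity(
    c: np.ndarray,
    alpha: float,
    eta: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> np.ndarray:
    """Nodal diffusivity ν = D_SE 10^(−α c) in μm²/s."""
    c = np.asarray(c, dtype=np.float64)
    if not np.all(np.isfinite(c)):
        raise TransportError("non-finite concentration field")
    _, D_um = stokes_einstein(eta, constants)
    return D_um * np.power(10.0, -alpha * c)


def assemble(
    mesh: TetMesh,
    advection: np.ndarray,
    nu: np.ndarray,
    r_eff: float,
    ops: _fem.P1Operators | None = None,
    settings: TransportSettings = TransportSettings(),
    dirichlet_nodes: np.ndarray | None = None,
) -> AssembledSystem:
    """Assemble the P1 Galerkin system for given nodal ν and velocity.

    ``advection`` is the nodal velocity (d, 3) in μm/s, ``nu`` the nodal
    diffusivity in μm²/s and ``r_eff`` the effective Robin coefficient
    in μm/s applied on Γ_S.
    """
    ops = ops or _fem.P1Operators(mesh)
    advection = np.asarray(advection, dtype=np.float64)
    nu = np.asarray(nu, dtype=np.float64)
    if not (np.all(np.isfinite(advection)) and np.all(np.isfinite(nu))):
        raise TransportError("non-finite input field in assembly")

    nu_elem = ops.element_mean(nu)
    vel_elem = ops.element_mean(advection)
    K = ops.stiffness(nu_elem)
    K = K + ops.advection(vel_elem, supg_nu=nu_elem if settings.supg else None)
    f = np.zeros(mesh.num_nodes)
    if r_eff != 0.0:
        M, load = ops.robin_operators(mesh.faces_with_tag(TAG_SOLID))
        K = K + r_eff * M
        f = f + r_eff * load
    if dirichlet_nodes is None:
        dirichlet_nodes = mesh.nodes_with_tag(TAG_INLET)
    if dirichlet_nodes.size:
        K, f = _fem.apply_dirichlet(K, f, dirichlet_nodes, 0.0)
    return AssembledSystem(K=K.tocsr(), f=f, dirichlet_nodes=dirichlet_nodes)


def picard_solve(
    mesh: TetMesh,
    mu: ParameterPoint,
    basis: VelocityBasis,
    settings: TransportSettings = TransportSettings(),
    constants: PhysicalConstants = PhysicalConstants(),
    ops: _fem.P1Operators | None = None,
) -> ConcentrationField:
    """Solve the full-order nonlinear problem at parameter point ``mu``.

    Iterates K(μ, c_old) c_new = f(μ) from c = 0 until the relative
    Euclidean update norm drops below the tolerance.
    """
    ops = ops or _fem.P1Operators(mesh)
    if basis.mesh_fingerprint != mesh.fingerprint():
        raise TransportError("velocity basis does not match this mesh")
    advection = combine_velocity(basis, mu.v, mu.gamma, mu.beta).values
    r_eff = mu.r * constants.r_scale

    c_old = np.zeros(mesh.num_nodes)
    residuals: list[float] = []
    for it in range(1, settings.max_iterations + 1):
        nu = diffusivity(c_old, mu.alpha, mu.eta, constants)
        system = assemble(
            mesh, advection, nu, r_eff, ops=ops, settings=settings
        )
        c_new = _fem.solve_sparse(system.K, system.f)
        denom = np.linalg.norm(c_new)
        res = (
            np.linalg.norm(c_new - c_old) / denom if denom > 0 else 0.0
        )
        residuals.append(float(res))
        c_old = c_new
        if res < settings.tol:
            return ConcentrationField(
                values=c_new,
                mu=mu,
                iterations=it,
                converged=True,
                residuals=residuals,
            )
    raise TransportError(
        f"Picard iteration did not converge in {settings.max_iterations} "
        f"iterations (last relative update {residuals[-1]:.3e})"
    )
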