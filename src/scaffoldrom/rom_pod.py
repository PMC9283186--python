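"""Snapshot-based POD reduced-order solvers.

Offline: sample the parametric space, run the full-order solver per
point, center the snapshots and extract orthonormal modes by a thin
SVD with the cumulative-singular-value truncation criterion

    Σ_{i≤k} σ_i ≥ (1 − ε) Σ_i σ_i,   k minimal.

Online: Picard iterations where each full-order operator is assembled
and Galerkin-projected onto the k modes,

    [U*ᵀ K(μ) U*] z = U*ᵀ [f(μ) − K(μ) c̄],   c ≈ c̄ + U* z.

Variants: ``global`` (all snapshots), ``local`` (the n nearest training
points in range-normalized parameter distance, locally re-centered),
``quadratic`` (training matrix augmented with pairwise Hadamard
products of the centered snapshots), and ``local-quadratic`` (neighbor
reduction first, then quadratic augmentation).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np

from scaffoldrom import _fem
from scaffoldrom.potential_flow import VelocityBasis, combine_velocity
from scaffoldrom.scaffold_geometry import TetMesh
from scaffoldrom.transport_fe import (
    PARAMETER_NAMES,
    TABLE_RANGES,
    ParameterPoint,
    PhysicalConstants,
    TransportError,
    TransportSettings,
    assemble,
    diffusivity,
    picard_solve,
)

VARIANTS = ("global", "local", "quadratic", "local-quadratic")


class RomError(RuntimeError):
    pass


# -- sampling ----------------------------------------------------------------


def corner_sampling(
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[ParameterPoint]:
    """All 2^n combinations of the range endpoints (deduplicated)."""
    return grid_sampling(ranges, levels=2)


def sample_grid(
    ranges: Iterable[tuple[float, float]], levels: int
) -> np.ndarray:
    """Tensor grid of equidistant values (endpoints included) per range.

    Returns the deduplicated sample table, one row per point, rows in
    lexicographic order of the given range sequence.  Degenerate
    (zero-length) ranges collapse to a single level.
    """
    if levels < 2:
        raise RomError("levels must be >= 2")
    axes = [np.linspace(lo, hi, levels) for lo, hi in ranges]
    mesh = np.meshgrid(*axes, indexing="ij")
    table = np.column_stack([m.ravel() for m in mesh])
    _, keep = np.unique(table, axis=0, return_index=True)
    return table[np.sort(keep)]


def grid_sampling(
    ranges: dict[str, tuple[float, float]] | None = None, levels: int = 3
) -> list[ParameterPoint]:
    """Full tensor grid of ``levels`` equidistant values per parameter.

    Points are emitted in lexicographic parameter order
    (v, γ, β, α, η, r) and deduplicated.
    """
    ranges = dict(TABLE_RANGES if ranges is None else ranges)
    missing = [k for k in PARAMETER_NAMES if k not in ranges]
    if missing:
        raise RomError(f"missing parameter ranges: {missing}")
    table = sample_grid([ranges[k] for k in PARAMETER_NAMES], levels)
    return [ParameterPoint.from_array(row) for row in table]


# -- snapshots ---------------------------------------------------------------


@dataclass
class SnapshotSet:
    """Centered snapshot matrix with its parameter table."""

    X: np.ndarray  # (d, n_S), centered
    mean: np.ndarray  # (d,)
    mu: np.ndarray  # (n_S, 6)
    mesh_fingerprint: str
    failed: list[int] = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return self.X.shape[1]

    def raw(self, i: int) -> np.ndarray:
        return self.X[:, i] + self.mean

    def parameter_point(self, i: int) -> ParameterPoint:
        return ParameterPoint.from_array(self.mu[i])


def _mu_key(mu: ParameterPoint, fingerprint: str) -> str:
    h = hashlib.sha256()
    h.update(mu.as_array().tobytes())
    h.update(fingerprint.encode())
    return h.hexdigest()[:24]


def build_snapshots(
    mesh: TetMesh,
    points: Sequence[ParameterPoint],
    basis: VelocityBasis,
    settings: TransportSettings = TransportSettings(),
    constants: PhysicalConstants = PhysicalConstants(),
    ops: _fem.P1Operators | None = None,
    cache: str | None = None,
    progress: bool = False,
) -> SnapshotSet:
    """Run the full-order solver at every training point and center.

    Snapshots are cached (if ``cache`` names an HDF5 file) by a hash of
    the parameter point and mesh fingerprint, so interrupted offline
    phases resume.  Non-converged points are excluded with a warning;
    more than 10% failures aborts.
    """
    ops = ops or _fem.P1Operators(mesh)
    fingerprint = mesh.fingerprint()
    columns: list[np.ndarray] = []
    kept_mu: list[np.ndarray] = []
    failed: list[int] = []
    h5 = h5py.File(cache, "a") if cache else None
    try:
        for i, mu in enumerate(points):
            key = f"snapshots/{_mu_key(mu, fingerprint)}"
            if h5 is not None and key in h5:
                c = h5[key][...]
            else:
                try:
                    sol = picard_solve(
                        mesh, mu, basis, settings, constants, ops
                    )
                except (TransportError, _fem.FEMError) as exc:
                    warnings.warn(
                        f"snapshot {i} at {mu} failed: {exc}", stacklevel=2
                    )
                    failed.append(i)
                    continue
                c = sol.values
                if h5 is not None:
                    h5.create_dataset(key, data=c)
            columns.append(c)
            kept_mu.append(mu.as_array())
            if progress and (i + 1) % 25 == 0:
                print(f"  snapshots: {i + 1}/{len(points)}")
    finally:
        if h5 is not None:
            h5.close()
    if len(failed) > 0.1 * len(points):
        raise RomError(
            f"{len(failed)}/{len(points)} snapshots failed to converge"
        )
    if not columns:
        raise RomError("no snapshots were computed")
    raw = np.column_stack(columns)
    mean = raw.mean(axis=1)
    return SnapshotSet(
        X=raw - mean[:, None],
        mean=mean,
        mu=np.asarray(kept_mu),
        mesh_fingerprint=fingerprint,
        failed=failed,
    )


# -- reduction ---------------------------------------------------------------


@dataclass
class ReducedBasis:
    U: np.ndarray  # (d, k)
    singular_values: np.ndarray
    eps: float
    k: int
    center: np.ndarray  # (d,)
    provenance: str
    mesh_fingerprint: str


def truncation_rank(singular_values: np.ndarray, eps: float) -> int:
    """Smallest k with Σ_{i≤k} σ_i ≥ (1−ε) Σ σ_i (tiny σ zeroed)."""
    s = np.asarray(singular_values, dtype=np.float64).copy()
    if s.size == 0 or s[0] <= 0:
        raise RomError("no nonzero singular values")
    s[s < 1e-12 * s[0]] = 0.0
    cumulative = np.cumsum(s)
    total = cumulative[-1]
    k = int(np.searchsorted(cumulative, (1.0 - eps) * total, side="left")) + 1
    return min(k, int(np.count_nonzero(s)))


def pod_basis(
    X: np.ndarray,
    eps: float,
    center: np.ndarray | None = None,
    provenance: str = "global",
    mesh_fingerprint: str = "",
) -> ReducedBasis:
    """Thin SVD of a (centered) snapshot matrix with truncation."""
    X = np.asarray(X, dtype=np.float64)
    if X.size == 0 or not np.any(X):
        raise RomError("snapshot matrix is zero; nothing to reduce")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k = truncation_rank(s, eps)
    modes = U[:, :k].copy()
    # deterministic sign: largest-magnitude entry of each mode positive
    for j in range(k):
        i = int(np.argmax(np.abs(modes[:, j])))
        if modes[i, j] < 0:
            modes[:, j] = -modes[:, j]
    if center is None:
        center = np.zeros(X.shape[0])
    return ReducedBasis(
        U=modes,
        singular_values=s,
        eps=eps,
        k=k,
        center=np.asarray(center, dtype=np.float64),
        provenance=provenance,
        mesh_fingerprint=mesh_fingerprint,
    )


@dataclass
class NeighborSelection:
    mu: np.ndarray
    indices: np.ndarray
    distances: np.ndarray  # range-normalized, sorted ascending


def select_neighbors(
    mu: ParameterPoint,
    points: np.ndarray,
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> NeighborSelection:
    """The n nearest training points in range-normalized distance.

    d(μ, μⁱ)² = Σ_p ((μ_p − μⁱ_p)/|range_p|)²; ties broken by ascending
    snapshot index.
    """
    ranges = TABLE_RANGES if ranges is None else ranges
    points = np.asarray(points, dtype=np.float64)
    if not 1 <= n <= points.shape[0]:
        raise RomError(
            f"need 1 <= n <= {points.shape[0]} neighbours, got {n}"
        )
    lengths = np.array(
        [ranges[k][1] - ranges[k][0] for k in PARAMETER_NAMES]
    )
    lengths[lengths == 0.0] = 1.0  # degenerate (fixed) parameters
    query = mu.as_array()
    diff = (points - query) / lengths
    dist = np.sqrt((diff**2).sum(axis=1))
    order = np.lexsort((np.arange(points.shape[0]), dist))
    chosen = order[:n]
    return NeighborSelection(
        mu=query, indices=chosen, distances=dist[chosen]
    )


def local_center(
    snapshots: SnapshotSet, indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour snapshots re-centered by their local average.

    Operates on the raw snapshots (centered columns + global mean); the
    local mean is returned as the reconstruction offset.
    """
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size == 0:
        raise RomError("empty neighbour set")
    raw = snapshots.X[:, indices] + snapshots.mean[:, None]
    local_mean = raw.mean(axis=1)
    return raw - local_mean[:, None], local_mean


def quadratic_column_count(n_s: int) -> int:
    """Columns of the quadratic expansion: 2 n_S + n_S (n_S − 1) / 2."""
    return 2 * n_s + n_s * (n_s - 1) // 2


def quadratic_expand(
    Xc: np.ndarray, memory_cap_bytes: int = 4 * 1024**3
) -> np.ndarray:
    """Augment centered snapshots with pairwise Hadamard products.

    Column order: the n_S centered snapshots, then all unordered pairs
    including squares, (c̄¹⊙c̄¹, c̄¹⊙c̄², ..., c̄ⁿ⊙c̄ⁿ).  The result is
    not re-centered.
    """
    Xc = np.asarray(Xc, dtype=np.float64)
    d, n_s = Xc.shape
    cols = quadratic_column_count(n_s)
    predicted = d * cols * 8
    if predicted > memory_cap_bytes:
        raise RomError(
            f"quadratic expansion would allocate {predicted / 1e9:.2f} GB "
            f"({cols} columns); use a local variant or raise the memory cap"
        )
    out = np.empty((d, cols))
    out[:, :n_s] = Xc
    col = n_s
    for i in range(n_s):
        for j in range(i, n_s):
            out[:, col] = Xc[:, i] * Xc[:, j]
            col += 1
    return out


def build_variant_basis(
    snapshots: SnapshotSet,
    variant: str,
    eps: float,
    mu: ParameterPoint | None = None,
    n_neighbors: int | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
    memory_cap_bytes: int = 4 * 1024**3,
) -> ReducedBasis:
    """Assemble the training matrix for a POD variant and reduce it."""
    if variant not in VARIANTS:
        raise RomError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    fp = snapshots.mesh_fingerprint
    if variant == "global":
        return pod_basis(snapshots.X, eps, snapshots.mean, "global", fp)
    if variant == "quadratic":
        Xq = quadratic_expand(snapshots.X, memory_cap_bytes)
        return pod_basis(Xq, eps, snapshots.mean, "quadratic", fp)
    if mu is None or n_neighbors is None:
        raise RomError("local variants need a query point and n_neighbors")
    sel = select_neighbors(mu, snapshots.mu, n_neighbors, ranges)
    Xl, lmean = local_center(snapshots, sel.indices)
    if variant == "local":
        return pod_basis(Xl, eps, lmean, f"local({n_neighbors})", fp)
    Xlq = quadratic_expand(Xl, memory_cap_bytes)
    return pod_basis(Xlq, eps, lmean, f"local-quadratic({n_neighbors})", fp)


# -- online solve ------------------------------------------------------------


@dataclass
class ReducedSolution:
    z: np.ndarray
    values: np.ndarray  # reconstructed nodal field, center + U z
    mu: ParameterPoint
    iterations: int
    converged: bool
    residuals: list[float] = field(default_factory=list)


def reduced_solve(
    mesh: TetMesh,
    mu: ParameterPoint,
    basis: ReducedBasis,
    velocity_basis: VelocityBasis,
    settings: TransportSettings = TransportSettings(),
    constants: PhysicalConstants = PhysicalConstants(),
    ops: _fem.P1Operators | None = None,
) -> ReducedSolution:
    """Reduced-basis Picard solve (assemble full operator, project).

    Each iteration assembles K(μ, c_old) and f(μ) at full order,
    projects onto the k modes and solves the dense k×k system; the
    stopping rule matches the full-order solver (relative update of the
    reconstructed field below tolerance).
    """
    ops = ops or _fem.P1Operators(mesh)
    if basis.mesh_fingerprint and basis.mesh_fingerprint != mesh.fingerprint():
        raise RomError("reduced basis does not match this mesh")
    advection = combine_velocity(
        velocity_basis, mu.v, mu.gamma, mu.beta
    ).values
    r_eff = mu.r * constants.r_scale
    U = basis.U
    center = basis.center

    z = np.zeros(basis.k)
    c_old = center + U @ z
    residuals: list[float] = []
    for it in range(1, settings.max_iterations + 1):
        nu = diffusivity(c_old, mu.alpha, mu.eta, constants)
        system = assemble(
            mesh, advection, nu, r_eff, ops=ops, settings=settings
        )
        KU = system.K @ U
        Kr = U.T @ KU
        fr = U.T @ (system.f - system.K @ center)
        try:
            z = np.linalg.solve(Kr, fr)
        except np.linalg.LinAlgError as exc:
            raise RomError(f"reduced system singular: {exc}") from exc
        c_new = center + U @ z
        denom = np.linalg.norm(c_new)
        res = np.linalg.norm(c_new - c_old) / denom if denom > 0 else 0.0
        residuals.append(float(res))
        c_old = c_new
        if res < settings.tol:
            return ReducedSolution(
                z=z,
                values=c_new,
                mu=mu,
                iterations=it,
                converged=True,
                residuals=residuals,
            )
    raise RomError(
        "reduced Picard iteration did not converge "
        f"(residual trace: {['%.2e' % r for r in residuals]})"
    )


def relative_error(c_rom: np.ndarray, c_fe: np.ndarray) -> float:
    """E_r = ‖c_rom − c_fe‖₂ / ‖c_fe‖₂."""
    c_rom = np.asarray(c_rom, dtype=np.float64)
    c_fe = np.asarray(c_fe, dtype=np.float64)
    if c_rom.shape != c_fe.shape:
        raise RomError("fields have different lengths")
    ref = np.linalg.norm(c_fe)
    if ref == 0:
        raise RomError("reference field has zero norm")
    return float(np.linalg.norm(c_rom - c_fe) / ref)


# -- persistence -------------------------------------------------------------


def save_snapshots(snapshots: SnapshotSet, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("X", data=snapshots.X)
        h5.create_dataset("mean", data=snapshots.mean)
        ds = h5.create_dataset("mu", data=snapshots.mu)
        ds.attrs["columns"] = list(PARAMETER_NAMES)
        h5.create_dataset("mesh_fingerprint", data=snapshots.mesh_fingerprint)
        h5.create_dataset("failed", data=np.asarray(snapshots.failed, dtype=np.int64))


def load_snapshots(path) -> SnapshotSet:
    with h5py.File(path, "r") as h5:
        return SnapshotSet(
            X=h5["X"][...],
            mean=h5["mean"][...],
            mu=h5["mu"][...],
            mesh_fingerprint=h5["mesh_fingerprint"][()].decode(),
            failed=[int(i) for i in h5["failed"][...]],
        )


def save_basis(basis: ReducedBasis, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("U", data=basis.U)
        h5.create_dataset("singular_values", data=basis.singular_values)
        h5.create_dataset("center", data=basis.center)
        h5.attrs["eps"] = basis.eps
        h5.attrs["k"] = basis.k
        h5.attrs["provenance"] = basis.provenance
        h5.attrs["mesh_fingerprint"] = basis.mesh_fingerprint


def load_basis(path) -> ReducedBasis:
    with h5py.File(path, "r") as h5:
        return ReducedBasis(
            U=h5["U"][...],
            singular_values=h5["singular_values"][...],
            eps=float(h5.attrs["eps"]),
            k=int(h5.attrs["k"]),
            center=h5["center"][...],
            provenance=str(h5.attrs["provenance"]),
            mesh_fingerprint=str(h5.attrs["mesh_fingerprint"]),
        )
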