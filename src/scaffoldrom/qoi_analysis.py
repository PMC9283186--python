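"""High-concentration volume-ratio quantity of interest and sweeps.

QoI = V / V_Ω · 100, where V is the volume of interstitial fluid with
concentration above a threshold (default 0.9 of saturation).  V is
integrated exactly for the P1 interpolant: each tetrahedron is cut by
the linear level set and the sub-volume above the threshold computed
per vertex-sign case (corner tetrahedra by similarity scaling, the
two-two case by an exact prism decomposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from scaffoldrom import _fem
from scaffoldrom.potential_flow import VelocityBasis
from scaffoldrom.rom_pod import ReducedBasis, reduced_solve, relative_error
from scaffoldrom.scaffold_geometry import TetMesh
from scaffoldrom.transport_fe import (
    TABLE_RANGES,
    ParameterPoint,
    PhysicalConstants,
    TransportSettings,
    picard_solve,
)


class QoIError(ValueError):
    pass


@dataclass
class QoIResult:
    threshold: float
    volume_above: float  # μm³
    total_volume: float  # μm³
    percent: float  # V / V_Ω · 100


def _tet_volume(p0, p1, p2, p3) -> np.ndarray:
    return (
        np.abs(
            np.einsum(
                "ij,ij->i", p1 - p0, np.cross(p2 - p0, p3 - p0)
            )
        )
        / 6.0
    )


def tet_fraction_above(values: np.ndarray, threshold: float) -> np.ndarray:
    """Volume fraction of each tet where the linear interpolant > t.

    ``values``: (m, 4) vertex values.  Geometry-independent: the
    fraction depends only on the vertex values (affine invariance).
    """
    values = np.asarray(values, dtype=np.float64)
    above = values > threshold
    na = above.sum(axis=1)
    frac = np.zeros(values.shape[0])
    frac[na == 4] = 1.0

    def corner_product(mask: np.ndarray, invert: bool) -> None:
        # single vertex on one side: similar-tetrahedron scaling along
        # the three edges leaving that vertex
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            return
        vals = values[idx]
        side = above[idx] if not invert else ~above[idx]
        corner = np.argmax(side, axis=1)
        vc = vals[np.arange(idx.size), corner]
        prod = np.ones(idx.size)
        for j in range(4):
            other = j != corner
            num = np.where(invert, threshold - vc, vc - threshold)
            den = np.where(invert, vals[:, j] - vc, vc - vals[:, j])
            ratio = np.where(other, num / np.where(other, den, 1.0), 1.0)
            prod *= ratio
        frac[idx] = prod if not invert else 1.0 - prod

    corner_product(na == 1, invert=False)
    corner_product(na == 3, invert=True)
    frac[na == 2] = _two_two_fraction(values[na == 2], above[na == 2], threshold)
    return frac


def _two_two_fraction(
    vals: np.ndarray, above: np.ndarray, t: float
) -> np.ndarray:
    """Exact fraction for tets with two vertices above the level set.

    The region above is a prism with planar faces (two faces lie on
    original tet faces, one on the cut plane); its volume is computed
    on the reference tetrahedron via a 3-tet decomposition.
    """
    if vals.shape[0] == 0:
        return np.zeros(0)
    # reference tet corners; affine invariance lets us work there
    ref = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    m = vals.shape[0]
    order = np.argsort(~above, axis=1, kind="stable")  # above first
    a_idx = order[:, :2]
    b_idx = order[:, 2:]
    rows = np.arange(m)[:, None]
    va = vals[rows, a_idx]  # (m, 2)
    vb = vals[rows, b_idx]
    pa = ref[a_idx]  # (m, 2, 3)
    pb = ref[b_idx]
    # cut point on edge a_i -> b_j at parameter s from a_i
    p = np.empty((m, 2, 2, 3))
    for i in range(2):
        for j in range(2):
            s = (va[:, i] - t) / (va[:, i] - vb[:, j])
            p[:, i, j] = pa[:, i] + s[:, None] * (pb[:, j] - pa[:, i])
    A, Ap = pa[:, 0], pa[:, 1]
    B, Bp = p[:, 0, 0], p[:, 1, 0]
    C, Cp = p[:, 0, 1], p[:, 1, 1]
    vol = (
        _tet_volume(A, B, C, Ap)
        + _tet_volume(B, C, Ap, Bp)
        + _tet_volume(C, Ap, Bp, Cp)
    )
    return vol / (1.0 / 6.0)


def qoi_volume_ratio(
    mesh: TetMesh, c: np.ndarray, threshold: float = 0.9
) -> QoIResult:
    """Exact sub-volume percentage where the P1 field exceeds threshold."""
    if not 0.0 < threshold < 1.0:
        raise QoIError("threshold must lie in (0, 1)")
    c = np.asarray(c, dtype=np.float64)
    if c.shape[0] != mesh.num_nodes:
        raise QoIError("concentration field does not match mesh nodes")
    vols = mesh.tet_volumes()
    frac = tet_fraction_above(c[mesh.tets], threshold)
    V = float((frac * vols).sum())
    total = float(vols.sum())
    return QoIResult(
        threshold=threshold,
        volume_above=V,
        total_volume=total,
        percent=100.0 * V / total,
    )


def high_concentration_mask(
    mesh: TetMesh, c: np.ndarray, threshold: float = 0.9
) -> np.ndarray:
    """Per-element flag: mean nodal concentration above the threshold."""
    if not 0.0 < threshold < 1.0:
        raise QoIError("threshold must lie in (0, 1)")
    c = np.asarray(c, dtype=np.float64)
    return c[mesh.tets].mean(axis=1) > threshold


def export_mask_vtu(mesh: TetMesh, c: np.ndarray, path, threshold: float = 0.9) -> None:
    from scaffoldrom.mesh_io import write_point_data_vtu

    mask = high_concentration_mask(mesh, c, threshold)
    write_point_data_vtu(
        mesh,
        path,
        point_data={"concentration": c},
        cell_data={"high_concentration": mask.astype(np.int64)},
    )


# -- sweeps ------------------------------------------------------------------


@dataclass
class SweepRow:
    value: float
    solver: str  # "full" or a ROM variant name
    k: int  # 0 for full order
    qoi_percent: float
    e_r: float  # 0 for full order
    picard_iters: int
    error: str = ""


@dataclass
class SweepReport:
    parameter: str
    values: list[float]
    fixed: ParameterPoint
    threshold: float
    rows: list[SweepRow] = field(default_factory=list)

    def qoi_series(self, solver: str) -> list[float]:
        return [r.qoi_percent for r in self.rows if r.solver == solver and not r.error]

    def to_csv(self, path) -> None:
        lines = ["value,solver,k,QoI_percent,Er,picard_iters,error"]
        for r in self.rows:
            lines.append(
                f"{r.value:.10g},{r.solver},{r.k},{r.qoi_percent:.10g},"
                f"{r.e_r:.10g},{r.picard_iters},{r.error}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def plot(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        solvers = sorted({r.solver for r in self.rows})
        for solver in solvers:
            pts = [
                (r.value, r.qoi_percent)
                for r in self.rows
                if r.solver == solver and not r.error
            ]
            if pts:
                xs, ys = zip(*pts)
                ax.plot(xs, ys, marker="o", label=solver)
        ax.set_xlabel(self.parameter)
        ax.set_ylabel("QoI (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def sweep(
    mesh: TetMesh,
    velocity_basis: VelocityBasis,
    parameter: str,
    values,
    fixed: ParameterPoint,
    variants: dict[str, "BasisProvider"] | None = None,
    settings: TransportSettings = TransportSettings(),
    constants: PhysicalConstants = PhysicalConstants(),
    threshold: float = 0.9,
    ops: _fem.P1Operators | None = None,
) -> SweepReport:
    """Full-order (and optionally reduced) QoI along one parameter.

    ``variants`` maps a solver label to a callable μ → ReducedBasis
    (local variants rebuild their basis per query point).  Solver
    failures are recorded in the row and the sweep continues.
    """
    ops = ops or _fem.P1Operators(mesh)
    lo, hi = TABLE_RANGES.get(parameter, (-np.inf, np.inf))
    report = SweepReport(
        parameter=parameter,
        values=[float(v) for v in values],
        fixed=fixed,
        threshold=threshold,
    )
    for value in report.values:
        if not lo <= value <= hi:
            warnings.warn(
                f"{parameter}={value} outside range [{lo}, {hi}]",
                stacklevel=2,
            )
        mu = fixed.with_value(parameter, value)
        try:
            full = picard_solve(mesh, mu, velocity_basis, settings, constants, ops)
        except Exception as exc:  # propagate per-row, keep sweeping
            report.rows.append(
                SweepRow(value, "full", 0, np.nan, np.nan, 0, str(exc))
            )
            continue
        qoi_full = qoi_volume_ratio(mesh, full.values, threshold)
        report.rows.append(
            SweepRow(
                value, "full", 0, qoi_full.percent, 0.0, full.iterations
            )
        )
        for name, provider in (variants or {}).items():
            try:
                basis = provider(mu)
                rom = reduced_solve(
                    mesh, mu, basis, velocity_basis, settings, constants, ops
                )
                qoi_rom = qoi_volume_ratio(mesh, rom.values, threshold)
                report.rows.append(
                    SweepRow(
                        value,
                        name,
                        basis.k,
                        qoi_rom.percent,
                        relative_error(rom.values, full.values),
                        rom.iterations,
                    )
                )
            except Exception as exc:
                report.rows.append(
                    SweepRow(value, name, 0, np.nan, np.nan, 0, str(exc))
                )
    return report
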