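"""Shared P1 tetrahedral finite-element kernels.

Precomputes per-element shape-function gradients, volumes and scatter
indices once per mesh; assembly routines then reduce to einsums plus a
single COO construction.  Stiffness and boundary-mass terms use the
exact P1 formulas; the advection term uses one-point (centroid)
quadrature.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from scaffoldrom.scaffold_geometry import TetMesh


class FEMError(RuntimeError):
    pass


class P1Operators:
    """Geometry-dependent assembly data for a fixed mesh."""

    def __init__(self, mesh: TetMesh):
        self.mesh = mesh
        p = mesh.nodes[mesh.tets]  # (m, 4, 3)
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        vol6 = np.einsum("ij,ij->i", a, np.cross(b, c))
        if np.any(vol6 <= 0):
            raise FEMError("element with non-positive volume")
        self.volumes = vol6 / 6.0

        # gradients of barycentric shape functions: solve J^T grad = e_i
        J = np.stack([a, b, c], axis=2)  # (m, 3, 3), columns are edges
        Jinv = np.linalg.inv(J)  # (m, 3, 3)
        g = np.empty((mesh.num_tets, 4, 3))
        g[:, 1, :] = Jinv[:, 0, :]
        g[:, 2, :] = Jinv[:, 1, :]
        g[:, 3, :] = Jinv[:, 2, :]
        g[:, 0, :] = -(g[:, 1] + g[:, 2] + g[:, 3])
        self.grads = g  # (m, 4, 3)

        # exact ∫ ∇φ_i · ∇φ_j over each element, scaled by volume
        self.stiff_unit = (
            np.einsum("eik,ejk->eij", g, g) * self.volumes[:, None, None]
        )

        tets = mesh.tets
        self.rows = np.repeat(tets, 4, axis=1).reshape(-1)
        self.cols = np.tile(tets, (1, 4)).reshape(-1)
        self.n = mesh.num_nodes

        # lumped nodal volumes (for volume-weighted nodal averages)
        w = np.zeros(self.n)
        np.add.at(w, tets.ravel(), np.repeat(self.volumes / 4.0, 4))
        self.lumped_volumes = w

    # -- element data --------------------------------------------------------

    def element_mean(self, nodal: np.ndarray) -> np.ndarray:
        """Per-element average of a nodal field (scalar or vector)."""
        return np.asarray(nodal)[self.mesh.tets].mean(axis=1)

    def element_gradient(self, nodal_scalar: np.ndarray) -> np.ndarray:
        """Piecewise-constant gradient of a P1 scalar field, (m, 3)."""
        vals = np.asarray(nodal_scalar)[self.mesh.tets]  # (m, 4)
        return np.einsum("ei,eik->ek", vals, self.grads)

    def node_average(self, element_field: np.ndarray) -> np.ndarray:
        """Volume-weighted average of an element field onto nodes."""
        element_field = np.asarray(element_field)
        shape = (self.n,) + element_field.shape[1:]
        out = np.zeros(shape)
        w = self.volumes / 4.0
        for loc in range(4):
            idx = self.mesh.tets[:, loc]
            np.add.at(out, idx, element_field * w[:, None] if out.ndim == 2 else element_field * w)
        return out / (
            self.lumped_volumes[:, None] if out.ndim == 2 else self.lumped_volumes
        )

    # -- assembly ------------------------------------------------------------

    def stiffness(self, nu_elem: np.ndarray) -> sp.csr_matrix:
        """∫ ν ∇c·∇w with element-wise constant ν."""
        vals = nu_elem[:, None, None] * self.stiff_unit
        return self._scatter(vals)

    def advection(self, vel_elem: np.ndarray, supg_nu: np.ndarray | None = None) -> sp.csr_matrix:
        """∫ (v·∇c) w by centroid quadrature; optional SUPG stabilization.

        ``supg_nu`` (element diffusivity) switches on the streamline
        term τ_e (v·∇w)(v·∇c) with τ_e = (h_e/2|v|)(coth Pe − 1/Pe).
        """
        vdotg = np.einsum("ek,ejk->ej", vel_elem, self.grads)  # (m, 4)
        # row i: test function value is 1/4 at the centroid for every i
        vals = np.repeat(
            ((self.volumes[:, None] / 4.0) * vdotg)[:, None, :], 4, axis=1
        )
        if supg_nu is not None:
            speed = np.linalg.norm(vel_elem, axis=1)
            h_e = (6.0 * self.volumes) ** (1.0 / 3.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                pe = speed * h_e / (2.0 * supg_nu)
                coth = 1.0 / np.tanh(np.clip(pe, 1e-12, 700.0))
                tau = (h_e / (2.0 * np.maximum(speed, 1e-300))) * (
                    coth - 1.0 / np.clip(pe, 1e-12, None)
                )
            tau = np.where(speed > 0, np.nan_to_num(tau, nan=0.0), 0.0)
            vals = vals + (tau * self.volumes)[:, None, None] * np.einsum(
                "ei,ej->eij", vdotg, vdotg
            )
        return self._scatter(vals)

    def _scatter(self, element_values: np.ndarray) -> sp.csr_matrix:
        K = sp.coo_matrix(
            (np.ascontiguousarray(element_values).reshape(-1), (self.rows, self.cols)),
            shape=(self.n, self.n),
        )
        return K.tocsr()

    # -- boundary terms ------------------------------------------------------

    def robin_operators(self, faces: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
        """Boundary mass matrix ∫_Γ c w and load ∫_Γ w on given facets."""
        M = sp.csr_matrix((self.n, self.n))
        load = np.zeros(self.n)
        if faces.size == 0:
            return M, load
        areas = self.mesh.face_areas(faces)
        local = (np.full((3, 3), 1.0) + np.eye(3)) / 12.0  # exact P1 tri mass
        vals = areas[:, None, None] * local
        rows = np.repeat(faces, 3, axis=1).reshape(-1)
        cols = np.tile(faces, (1, 3)).reshape(-1)
        M = sp.coo_matrix(
            (vals.reshape(-1), (rows, cols)), shape=(self.n, self.n)
        ).tocsr()
        np.add.at(load, faces.ravel(), np.repeat(areas / 3.0, 3))
        return M, load


def apply_dirichlet(
    K: sp.csr_matrix,
    f: np.ndarray,
    nodes: np.ndarray,
    values: np.ndarray | float = 0.0,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Impose Dirichlet values by symmetric elimination.

    Lifts the constrained values into the right-hand side, zeroes the
    corresponding rows and columns and places 1 on the diagonal.
    """
    n = K.shape[0]
    if np.ndim(values) == 0:
        values = np.full(nodes.shape[0], float(values))
    g = np.zeros(n)
    g[nodes] = values
    f = f - K @ g
    keep = np.ones(n)
    keep[nodes] = 0.0
    D = sp.diags(keep)
    K = D @ K @ D + sp.diags(1.0 - keep)
    f = f * keep
    f[nodes] = values
    return K.tocsr(), f


def solve_sparse(K: sp.csr_matrix, f: np.ndarray) -> np.ndarray:
    try:
        lu = spla.splu(K.tocsc())
    except RuntimeError as exc:  # singular factorization
        raise FEMError(f"singular linear system: {exc}") from exc
    x = lu.solve(f)
    if not np.all(np.isfinite(x)):
        raise FEMError("linear solve produced non-finite values")
    return x
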