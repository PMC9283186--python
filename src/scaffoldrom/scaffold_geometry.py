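"""Synthetic scaffold fluid domains as tagged tetrahedral meshes.

The fluid (pore) space of a scaffold is represented on a regular voxel
grid and converted to a conforming linear-tetrahedra mesh by the
Freudenthal/Kuhn 6-tet cube split.  Two generators are provided:

* :func:`generate_structured` — box minus an orthogonal grid of
  rectilinear strands (3D-printed-like architecture);
* :func:`generate_foamed` — union of randomly placed overlapping
  spheres intersected with the box (foamed-like architecture).

Boundary facets are tagged ``INLET`` / ``OUTLET`` / ``SOLID``; the
default convention takes the three minimum-coordinate box planes as
inlets and the three maximum-coordinate planes as outlets, with every
remaining facet on the pore walls tagged as the solid interface.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

TAG_INLET = 1
TAG_OUTLET = 2
TAG_SOLID = 3

TAG_NAMES = {TAG_INLET: "INLET", TAG_OUTLET: "OUTLET", TAG_SOLID: "SOLID"}

_PLANE_TOL = 1e-9


class GeometryError(ValueError):
    """Raised when a geometry specification produces an invalid domain."""


@dataclass(frozen=True)
class BoxSpec:
    """Axis-aligned box domain with a uniform voxel resolution.

    Parameters
    ----------
    lengths:
        Edge lengths ``(Lx, Ly, Lz)`` in micrometres.
    h:
        Voxel edge length in micrometres.  Each box length must be an
        integer multiple of ``h``.
    """

    lengths: tuple[float, float, float]
    h: float

    def __post_init__(self) -> None:
        if len(self.lengths) != 3:
            raise GeometryError("lengths must have three components")
        if any(L <= 0 for L in self.lengths):
            raise GeometryError("box lengths must be positive")
        if self.h <= 0:
            raise GeometryError("voxel resolution h must be positive")
        for L in self.lengths:
            n = L / self.h
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise GeometryError(
                    f"length {L} is not an integer multiple of h={self.h}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Voxel counts ``(nx, ny, nz)``."""
        return tuple(int(round(L / self.h)) for L in self.lengths)

    @property
    def volume(self) -> float:
        Lx, Ly, Lz = self.lengths
        return Lx * Ly * Lz

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates (1-D arrays)."""
        return tuple(
            (np.arange(n) + 0.5) * self.h for n in self.shape
        )


@dataclass(frozen=True)
class StructuredScaffoldSpec:
    """Orthogonal grid of rectilinear strands (3D-printed-like).

    Strands are cylinders of ``diameter`` laid in layers of thickness
    equal to the diameter; layers alternate between the X and Y
    directions, spaced ``spacing`` apart within a layer.
    """

    diameter: float
    spacing: float
    offset: Literal["aligned", "staggered"] = "staggered"
    target_porosity: float = 0.541

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError("strand diameter must be positive")
        if self.diameter >= self.spacing:
            raise GeometryError(
                "strands overlap fully: diameter must be < spacing"
            )
        if not 0 < self.target_porosity < 1:
            raise GeometryError("target_porosity must be in (0, 1)")
        if self.offset not in ("aligned", "staggered"):
            raise GeometryError("offset must be 'aligned' or 'staggered'")


@dataclass(frozen=True)
class FoamedScaffoldSpec:
    """Overlapping-sphere pore network (foamed-like).

    Pore radii follow a lognormal distribution given by its median and
    log-scale ``shape``; spheres are inserted at uniformly random
    centres until the union reaches ``target_porosity``.
    """

    median_radius: float
    shape: float = 0.25
    target_porosity: float = 0.523
    seed: int = 0
    max_spheres: int = 20000

    def __post_init__(self) -> None:
        if self.median_radius <= 0:
            raise GeometryError("median pore radius must be positive")
        if not 0 < self.target_porosity < 1:
            raise GeometryError("target_porosity must be in (0, 1)")
        if self.shape < 0:
            raise GeometryError("lognormal shape must be non-negative")


@dataclass
class TetMesh:
    """Linear-tetrahedra mesh of the fluid domain with tagged boundary.

    Attributes
    ----------
    nodes:
        ``(d, 3)`` node coordinates in micrometres.
    tets:
        ``(m, 4)`` node indices, positively oriented.
    boundary_faces:
        ``(b, 3)`` node triples with outward orientation.
    boundary_tags:
        ``(b,)`` integer tags (``TAG_INLET``/``TAG_OUTLET``/``TAG_SOLID``;
        0 means untagged).
    metadata:
        Generator provenance (spec fields, seed, achieved porosity...).
    """

    nodes: np.ndarray
    tets: np.ndarray
    boundary_faces: np.ndarray
    boundary_tags: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.boundary_faces = np.ascontiguousarray(
            self.boundary_faces, dtype=np.int64
        )
        self.boundary_tags = np.ascontiguousarray(
            self.boundary_tags, dtype=np.int64
        )

    @property
    def num_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def num_tets(self) -> int:
        return self.tets.shape[0]

    def tet_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes (positive by orientation contract)."""
        p = self.nodes[self.tets]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    @property
    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def face_areas(self, faces: np.ndarray | None = None) -> np.ndarray:
        faces = self.boundary_faces if faces is None else faces
        p = self.nodes[faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def faces_with_tag(self, tag: int) -> np.ndarray:
        return self.boundary_faces[self.boundary_tags == tag]

    def nodes_with_tag(self, tag: int) -> np.ndarray:
        """Sorted unique node indices appearing on facets of ``tag``."""
        return np.unique(self.faces_with_tag(tag))

    def fingerprint(self) -> str:
        """Content hash of the discretization (nodes, tets, tags)."""
        hsh = hashlib.sha256()
        hsh.update(self.nodes.tobytes())
        hsh.update(self.tets.tobytes())
        hsh.update(self.boundary_faces.tobytes())
        hsh.update(self.boundary_tags.tobytes())
        return hsh.hexdigest()[:16]


# -- voxel meshing -----------------------------------------------------------

# Kuhn split of the unit cube: six tets around the (0,0,0)-(1,1,1)
# diagonal, one per axis permutation.  Translation-invariant, hence
# conforming across shared cube faces.
_KUHN_PERMS = list(itertools.permutations(range(3)))


def _kuhn_corner_indices() -> np.ndarray:
    """(6, 4) indices into the cube-corner array ordered (dx, dy, dz)."""
    tets = []
    for perm in _KUHN_PERMS:
        corner = np.zeros(3, dtype=np.int64)
        path = [corner.copy()]
        for ax in perm:
            corner[ax] = 1
            path.append(corner.copy())
        idx = [c[0] * 4 + c[1] * 2 + c[2] for c in path]
        tets.append(idx)
    return np.asarray(tets, dtype=np.int64)


_KUHN_TETS = _kuhn_corner_indices()


def check_face_connected(mask: np.ndarray) -> bool:
    """True if the fluid voxels form one 6-connected component."""
    structure = ndimage.generate_binary_structure(3, 1)
    _, num = ndimage.label(mask, structure=structure)
    return num == 1


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 6-connected component of a boolean voxel mask."""
    structure = ndimage.generate_binary_structure(3, 1)
    labels, num = ndimage.label(mask, structure=structure)
    if num == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(counts)) + 1
    return labels == keep


def voxel_to_tets(fluid_mask: np.ndarray, box: BoxSpec) -> TetMesh:
    """Convert a boolean voxel mask to a conforming tetrahedral mesh.

    Each fluid voxel is split into six tetrahedra with a globally
    consistent diagonal so that shared faces conform.  Boundary facets
    are extracted (untagged); apply :func:`tag_boundaries` afterwards.
    """
    fluid_mask = np.asarray(fluid_mask, dtype=bool)
    if fluid_mask.shape != box.shape:
        raise GeometryError(
            f"mask shape {fluid_mask.shape} does not match box voxels {box.shape}"
        )
    if not fluid_mask.any():
        raise GeometryError("fluid mask is empty")
    if not check_face_connected(fluid_mask):
        raise GeometryError(
            "fluid mask is not face-connected; reduce to one component first"
        )

    nx, ny, nz = box.shape
    h = box.h

    # mark lattice points touched by fluid voxels
    corner_used = np.zeros((nx + 1, ny + 1, nz + 1), dtype=bool)
    for dx, dy, dz in itertools.product((0, 1), repeat=3):
        corner_used[dx : nx + dx, dy : ny + dy, dz : nz + dz] |= fluid_mask
    node_id = np.full(corner_used.shape, -1, dtype=np.int64)
    node_id[corner_used] = np.arange(int(corner_used.sum()))

    gi, gj, gk = np.nonzero(corner_used)
    nodes = np.column_stack((gi * h, gj * h, gk * h)).astype(np.float64)

    vi, vj, vk = np.nonzero(fluid_mask)
    # cube corner ids per voxel, ordered (dx, dy, dz) binary
    corners = np.empty((vi.size, 8), dtype=np.int64)
    for c, (dx, dy, dz) in enumerate(itertools.product((0, 1), repeat=3)):
        corners[:, c] = node_id[vi + dx, vj + dy, vk + dz]
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)

    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        boundary_faces=np.empty((0, 3), dtype=np.int64),
        boundary_tags=np.empty(0, dtype=np.int64),
        metadata={
            "h": h,
            "box_lengths": list(box.lengths),
            "fluid_voxels": int(fluid_mask.sum()),
        },
    )
    _fix_orientation(mesh)
    faces = _extract_boundary(mesh)
    mesh.boundary_faces = faces
    mesh.boundary_tags = np.zeros(faces.shape[0], dtype=np.int64)
    _self_check(mesh, box)
    return mesh


def _fix_orientation(mesh: TetMesh) -> None:
    vols = mesh.tet_volumes()
    flip = vols < 0
    if flip.any():
        mesh.tets[flip, 2], mesh.tets[flip, 3] = (
            mesh.tets[flip, 3].copy(),
            mesh.tets[flip, 2].copy(),
        )
    if np.any(mesh.tet_volumes() <= 0):
        raise GeometryError("degenerate tetrahedron with non-positive volume")


# faces of a positively oriented tet (a,b,c,d) with outward normals
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])


def _extract_boundary(mesh: TetMesh) -> np.ndarray:
    faces = mesh.tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    boundary = counts[inverse] == 1
    if np.any(counts > 2):  # pragma: no cover - guarded by construction
        raise GeometryError("non-conforming face shared by >2 tetrahedra")
    return faces[boundary]


def _self_check(mesh: TetMesh, box: BoxSpec) -> None:
    nvox = mesh.metadata["fluid_voxels"]
    total = mesh.total_volume
    expected = nvox * box.h**3
    if abs(total - expected) > 1e-9 * expected:
        raise GeometryError("volume bookkeeping mismatch in voxel meshing")


def tag_boundaries(
    mesh: TetMesh,
    box: BoxSpec,
    scheme: Literal["corner", "axis", "duct"] = "corner",
    axis: int = 0,
) -> TetMesh:
    """Tag boundary facets in place and return the mesh.

    Schemes
    -------
    ``corner``
        Facets on the three minimum-coordinate box planes become
        ``INLET``, on the three maximum-coordinate planes ``OUTLET``,
        everything else ``SOLID``.
    ``axis``
        Only the chosen axis' min/max planes are inlet/outlet; all
        other facets are ``SOLID``.
    ``duct``
        Oracle configuration: axis-min plane is ``INLET``, axis-max
        plane is ``SOLID`` (ion-releasing wall), all side walls are
        ``OUTLET`` (natural zero-flux).
    """
    if mesh.boundary_faces.size == 0:
        raise GeometryError("mesh has no boundary facets to tag")
    coords = mesh.nodes[mesh.boundary_faces]  # (b, 3, 3)
    tol = _PLANE_TOL * max(box.lengths) + 1e-12
    on_min = np.all(coords < tol, axis=1)  # (b, 3) per axis
    on_max = np.empty_like(on_min)
    for ax, L in enumerate(box.lengths):
        on_max[:, ax] = np.all(np.abs(coords[:, :, ax] - L) < tol, axis=1)

    tags = np.full(mesh.boundary_faces.shape[0], TAG_SOLID, dtype=np.int64)
    if scheme == "corner":
        tags[on_max.any(axis=1)] = TAG_OUTLET
        tags[on_min.any(axis=1)] = TAG_INLET
    elif scheme == "axis":
        tags[on_max[:, axis]] = TAG_OUTLET
        tags[on_min[:, axis]] = TAG_INLET
    elif scheme == "duct":
        tags[:] = TAG_OUTLET  # side walls: natural zero flux
        tags[on_max[:, axis]] = TAG_SOLID
        tags[on_min[:, axis]] = TAG_INLET
    else:
        raise GeometryError(f"unknown tagging scheme {scheme!r}")
    mesh.boundary_tags = tags
    mesh.metadata["tagging_scheme"] = scheme
    return mesh


# -- generators --------------------------------------------------------------


def structured_fluid_mask(box: BoxSpec, spec: StructuredScaffoldSpec) -> np.ndarray:
    """Boolean fluid mask for the strand-grid scaffold (solid removed)."""
    xc, yc, zc = box.voxel_centers()
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    D, S = spec.diameter, spec.spacing
    layer = np.floor(Z / D).astype(np.int64)
    zc_layer = (layer + 0.5) * D
    dz = Z - zc_layer

    # distance from a voxel centre to the nearest strand axis of its layer
    def line_dist(u: np.ndarray, shift: np.ndarray) -> np.ndarray:
        t = np.mod(u - shift, S)
        return np.minimum(t, S - t)

    if spec.offset == "staggered":
        shift = (S / 2.0) * ((layer // 2) % 2) + S / 2.0
    else:
        shift = np.full_like(Z, S / 2.0)
    along_x = layer % 2 == 0
    du = np.where(along_x, line_dist(Y, shift), line_dist(X, shift))
    solid = du**2 + dz**2 <= (D / 2.0) ** 2
    return ~solid


def generate_structured(box: BoxSpec, spec: StructuredScaffoldSpec) -> TetMesh:
    """Mesh of the box minus an orthogonal grid of strands.

    Deterministic: no randomness is involved.  The achieved voxel
    porosity is recorded in ``mesh.metadata['porosity']``.
    """
    n_layers_fit = box.lengths[2] / spec.diameter
    if n_layers_fit < 1:
        raise GeometryError(
            "strand diameter exceeds box height; decrease 'diameter'"
        )
    fluid = structured_fluid_mask(box, spec)
    if not fluid.any():
        raise GeometryError("fluid domain is empty; decrease 'diameter'")
    if not check_face_connected(fluid):
        raise GeometryError(
            "fluid domain is disconnected; decrease 'diameter' or "
            "increase 'spacing'"
        )
    porosity = float(fluid.mean())
    mesh = voxel_to_tets(fluid, box)
    mesh = tag_boundaries(mesh, box, scheme="corner")
    mesh.metadata.update(
        generator="structured",
        porosity=porosity,
        target_porosity=spec.target_porosity,
        diameter=spec.diameter,
        spacing=spec.spacing,
        offset=spec.offset,
    )
    return mesh


def foamed_fluid_mask(
    box: BoxSpec, spec: FoamedScaffoldSpec
) -> tuple[np.ndarray, int]:
    """Union-of-spheres fluid mask; returns (mask, spheres placed)."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = box.shape
    xc, yc, zc = box.voxel_centers()
    fluid = np.zeros(box.shape, dtype=bool)
    placed = 0
    while placed < spec.max_spheres:
        if fluid.mean() >= spec.target_porosity:
            break
        center = rng.uniform(0.0, 1.0, size=3) * np.asarray(box.lengths)
        radius = spec.median_radius * np.exp(spec.shape * rng.standard_normal())
        placed += 1
        # carve on a bounding sub-grid only
        lo = np.maximum(((center - radius) / box.h).astype(int), 0)
        hi = np.minimum(
            np.ceil((center + radius) / box.h).astype(int), [nx, ny, nz]
        )
        if np.any(lo >= hi):
            continue
        sx = slice(lo[0], hi[0])
        sy = slice(lo[1], hi[1])
        sz = slice(lo[2], hi[2])
        dx = xc[sx] - center[0]
        dy = yc[sy] - center[1]
        dz = zc[sz] - center[2]
        inside = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
            <= radius**2
        )
        fluid[sx, sy, sz] |= inside
    return fluid, placed


def generate_foamed(box: BoxSpec, spec: FoamedScaffoldSpec) -> TetMesh:
    """Mesh of the largest connected pore network of a sphere foam.

    Same seed ⇒ bit-identical mesh.  Raises if the porosity target is
    unreachable within ``spec.max_spheres`` insertions.
    """
    fluid, placed = foamed_fluid_mask(box, spec)
    if fluid.mean() < spec.target_porosity:
        raise GeometryError(
            f"porosity target {spec.target_porosity} unreachable after "
            f"{placed} sphere insertions (achieved {fluid.mean():.4f}); "
            "increase 'median_radius' or 'max_spheres'"
        )
    component = largest_component(fluid)
    porosity = float(component.mean())
    mesh = voxel_to_tets(component, box)
    mesh = tag_boundaries(mesh, box, scheme="corner")
    mesh.metadata.update(
        generator="foamed",
        porosity=porosity,
        union_porosity=float(fluid.mean()),
        target_porosity=spec.target_porosity,
        median_radius=spec.median_radius,
        shape=spec.shape,
        seed=spec.seed,
        spheres=placed,
    )
    return mesh
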