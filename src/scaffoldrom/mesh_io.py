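"""Read/write tagged tetrahedral meshes (VTU, Gmsh MSH 4.1, XDMF+HDF5).

Conventions
-----------
* node indices are 0-based internally; MSH files (1-based) are shifted
  on read and write;
* boundary facet tags travel as the integer cell-data field
  ``boundary_tag`` with ``{1: INLET, 2: OUTLET, 3: SOLID}``; tets carry
  tag 0 in mixed-cell containers;
* the XDMF flavour stores heavy data in a sibling ``.h5`` file and the
  full generator metadata as a JSON attribute.

Only the subset of each format needed for tagged tet meshes is
supported; this module deliberately avoids a heavyweight mesh-I/O
dependency.
"""

from __future__ import annotations

import json
import os
import xml.etree.ElementTree as ET
from pathlib import Path

import h5py
import numpy as np

from scaffoldrom.scaffold_geometry import TAG_NAMES, TetMesh

_FORMATS = ("vtu", "msh", "xdmf")


class MeshIOError(ValueError):
    pass


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshIOError(f"unsupported mesh format {fmt!r}; use one of {_FORMATS}")
    return fmt


def write_mesh(mesh: TetMesh, path: str | os.PathLike, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "vtu":
        _write_vtu(mesh, path)
    elif fmt == "msh":
        _write_msh(mesh, path)
    else:
        _write_xdmf(mesh, path)


def read_mesh(path: str | os.PathLike, fmt: str | None = None) -> TetMesh:
    fmt = _infer_format(path, fmt)
    if fmt == "vtu":
        return _read_vtu(path)
    if fmt == "msh":
        return _read_msh(path)
    return _read_xdmf(path)


# -- VTU ---------------------------------------------------------------------


def _ascii(arr: np.ndarray, per_line: int) -> str:
    flat = np.asarray(arr).ravel()
    if flat.dtype.kind == "f":
        fmt = "%.17g"
    else:
        fmt = "%d"
    rows = [
        " ".join(fmt % v for v in flat[i : i + per_line])
        for i in range(0, flat.size, per_line)
    ]
    return "\n".join(rows)


def _write_vtu(mesh: TetMesh, path: str | os.PathLike) -> None:
    ntet = mesh.num_tets
    ntri = mesh.boundary_faces.shape[0]
    conn = np.concatenate(
        [mesh.tets.ravel(), mesh.boundary_faces.ravel()]
    ).astype(np.int64)
    offsets = np.concatenate(
        [4 * np.arange(1, ntet + 1), 4 * ntet + 3 * np.arange(1, ntri + 1)]
    )
    types = np.concatenate(
        [np.full(ntet, 10, dtype=np.uint8), np.full(ntri, 5, dtype=np.uint8)]
    )
    tags = np.concatenate(
        [np.zeros(ntet, dtype=np.int64), mesh.boundary_tags]
    )
    numeric_meta = {
        k: float(v)
        for k, v in mesh.metadata.items()
        if isinstance(v, (int, float)) and not isinstance(v, bool)
    }
    field_data = "\n".join(
        f'<DataArray type="Float64" Name="{k}" NumberOfTuples="1" '
        f'format="ascii">{v:.17g}</DataArray>'
        for k, v in sorted(numeric_meta.items())
    )
    body = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<FieldData>
{field_data}
</FieldData>
<Piece NumberOfPoints="{mesh.num_nodes}" NumberOfCells="{ntet + ntri}">
<Points>
<DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">
{_ascii(mesh.nodes, 3)}
</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{_ascii(conn, 12)}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{_ascii(offsets, 12)}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{_ascii(types, 24)}
</DataArray>
</Cells>
<CellData Scalars="boundary_tag">
<DataArray type="Int64" Name="boundary_tag" format="ascii">
{_ascii(tags, 24)}
</DataArray>
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    Path(path).write_text(body)


def write_point_data_vtu(
    mesh: TetMesh,
    path: str | os.PathLike,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a tet-only VTU carrying nodal and/or per-tet fields."""
    ntet = mesh.num_tets
    pieces = []
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr, dtype=np.float64)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        pieces.append(
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"{_ascii(arr, 3 if ncomp == 3 else 6)}\n</DataArray>"
        )
    point_block = "\n".join(pieces)
    cells = []
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr)
        typ = "Int64" if arr.dtype.kind in "iub" else "Float64"
        cells.append(
            f'<DataArray type="{typ}" Name="{name}" format="ascii">\n'
            f"{_ascii(arr.astype(np.int64) if typ == 'Int64' else arr, 12)}\n"
            "</DataArray>"
        )
    cell_block = "\n".join(cells)
    body = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{mesh.num_nodes}" NumberOfCells="{ntet}">
<Points>
<DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">
{_ascii(mesh.nodes, 3)}
</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{_ascii(mesh.tets.ravel(), 12)}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{_ascii(4 * np.arange(1, ntet + 1), 12)}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{_ascii(np.full(ntet, 10, dtype=np.uint8), 24)}
</DataArray>
</Cells>
<PointData>
{point_block}
</PointData>
<CellData>
{cell_block}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    Path(path).write_text(body)


def _parse_data_array(elem: ET.Element) -> np.ndarray:
    text = elem.text or ""
    dtype = np.float64 if elem.get("type", "").startswith("Float") else np.int64
    values = text.split()
    if not values:
        return np.empty(0, dtype=dtype)
    return np.array(values, dtype=np.float64).astype(dtype)


def _read_vtu(path: str | os.PathLike) -> TetMesh:
    tree = ET.parse(path)
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise MeshIOError("no <Piece> element in VTU file")
    arrays: dict[str, np.ndarray] = {}
    for da in piece.iter("DataArray"):
        name = da.get("Name")
        if name:
            arrays[name] = _parse_data_array(da)
    for required in ("Points", "connectivity", "offsets", "types"):
        if required not in arrays:
            raise MeshIOError(f"VTU file missing DataArray {required!r}")
    nodes = arrays["Points"].astype(np.float64).reshape(-1, 3)
    conn = arrays["connectivity"].astype(np.int64)
    offsets = arrays["offsets"].astype(np.int64)
    types = arrays["types"].astype(np.int64)
    starts = np.concatenate([[0], offsets[:-1]])
    tet_cells = types == 10
    tri_cells = types == 5
    if not tet_cells.any():
        raise MeshIOError("no tetrahedra in mesh file")
    tets = np.stack(
        [conn[s : s + 4] for s in starts[tet_cells]], axis=0
    )
    if tri_cells.any():
        faces = np.stack([conn[s : s + 3] for s in starts[tri_cells]], axis=0)
    else:
        faces = np.empty((0, 3), dtype=np.int64)
    if "boundary_tag" not in arrays:
        raise MeshIOError(
            "missing tag table: cell-data field 'boundary_tag' with "
            "{1: INLET, 2: OUTLET, 3: SOLID} is required"
        )
    all_tags = arrays["boundary_tag"].astype(np.int64)
    tags = all_tags[tri_cells]
    meta = {}
    for da in tree.getroot().iter("FieldData"):
        for arr in da.iter("DataArray"):
            if arr.get("Name"):
                meta[arr.get("Name")] = float((arr.text or "0").strip() or 0.0)
    return TetMesh(
        nodes=nodes,
        tets=tets,
        boundary_faces=faces,
        boundary_tags=tags,
        metadata=meta,
    )


# -- Gmsh MSH 4.1 ------------------------------------------------------------

_PHYS_VOLUME = 4  # physical tag for the fluid volume


def _write_msh(mesh: TetMesh, path: str | os.PathLike) -> None:
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", "4"]
    for tag, name in sorted(TAG_NAMES.items()):
        lines.append(f'2 {tag} "{name}"')
    lines.append(f'3 {_PHYS_VOLUME} "FLUID"')
    lines.append("$EndPhysicalNames")

    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    bbox = f"{lo[0]:.17g} {lo[1]:.17g} {lo[2]:.17g} {hi[0]:.17g} {hi[1]:.17g} {hi[2]:.17g}"
    present = sorted(set(int(t) for t in mesh.boundary_tags if t > 0))
    lines += ["$Entities", f"0 0 {len(present)} 1"]
    for tag in present:
        lines.append(f"{tag} {bbox} 1 {tag} 0")
    lines.append(f"1 {bbox} 1 {_PHYS_VOLUME} 0")
    lines.append("$EndEntities")

    n = mesh.num_nodes
    lines += ["$Nodes", f"1 {n} 1 {n}", f"3 1 0 {n}"]
    lines += [str(i + 1) for i in range(n)]
    lines += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in mesh.nodes]
    lines.append("$EndNodes")

    blocks = []
    nelem = 0
    for tag in present:
        faces = mesh.faces_with_tag(tag)
        block = [f"2 {tag} 2 {faces.shape[0]}"]
        for f in faces:
            nelem += 1
            block.append(f"{nelem} {f[0] + 1} {f[1] + 1} {f[2] + 1}")
        blocks.append("\n".join(block))
    tet_block = [f"3 1 4 {mesh.num_tets}"]
    for t in mesh.tets:
        nelem += 1
        tet_block.append(f"{nelem} {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}")
    blocks.append("\n".join(tet_block))
    lines += [
        "$Elements",
        f"{len(blocks)} {nelem} 1 {nelem}",
        "\n".join(blocks),
        "$EndElements",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _msh_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("$End"):
            current = None
        elif line.startswith("$"):
            current = line[1:]
            sections[current] = []
        elif current is not None and line:
            sections[current].append(line)
    return sections


def _read_msh(path: str | os.PathLike) -> TetMesh:
    sections = _msh_sections(Path(path).read_text())
    if "MeshFormat" not in sections or "Nodes" not in sections:
        raise MeshIOError("not a Gmsh MSH file")
    version = sections["MeshFormat"][0].split()[0]
    if not version.startswith("4"):
        raise MeshIOError(f"only MSH 4.x supported, got version {version}")

    # surface entity tag -> physical tag
    surf_phys: dict[int, int] = {}
    if "Entities" in sections:
        ent = sections["Entities"]
        npt, ncrv, nsurf, _nvol = (int(v) for v in ent[0].split()[:4])
        row = 1 + npt + ncrv
        for line in ent[row : row + nsurf]:
            vals = line.split()
            tag = int(vals[0])
            nphys = int(vals[7])
            surf_phys[tag] = int(vals[8]) if nphys > 0 else tag

    nodes_sec = sections["Nodes"]
    header = nodes_sec[0].split()
    nblocks = int(header[0])
    row = 1
    tag_to_index: dict[int, int] = {}
    coords: list[list[float]] = []
    for _ in range(nblocks):
        _, _, _, blk_n = (int(v) for v in nodes_sec[row].split())
        row += 1
        tags = [int(nodes_sec[row + i]) for i in range(blk_n)]
        row += blk_n
        for i in range(blk_n):
            tag_to_index[tags[i]] = len(coords)
            coords.append([float(v) for v in nodes_sec[row + i].split()[:3]])
        row += blk_n
    nodes = np.asarray(coords, dtype=np.float64)

    if "Elements" not in sections:
        raise MeshIOError("no tetrahedra in mesh file: missing $Elements")
    elems = sections["Elements"]
    nblocks = int(elems[0].split()[0])
    row = 1
    tets: list[list[int]] = []
    faces: list[list[int]] = []
    tags: list[int] = []
    for _ in range(nblocks):
        dim, etag, etype, blk_n = (int(v) for v in elems[row].split())
        row += 1
        for i in range(blk_n):
            vals = [int(v) for v in elems[row + i].split()[1:]]
            idx = [tag_to_index[v] for v in vals]
            if etype == 4:
                tets.append(idx)
            elif etype == 2:
                faces.append(idx)
                tags.append(surf_phys.get(etag, etag))
        row += blk_n
    if not tets:
        raise MeshIOError("no tetrahedra in mesh file")
    return TetMesh(
        nodes=nodes,
        tets=np.asarray(tets, dtype=np.int64),
        boundary_faces=np.asarray(faces, dtype=np.int64).reshape(-1, 3),
        boundary_tags=np.asarray(tags, dtype=np.int64),
        metadata={"source": str(path)},
    )


# -- XDMF + HDF5 -------------------------------------------------------------


def _write_xdmf(mesh: TetMesh, path: str | os.PathLike) -> None:
    path = Path(path)
    h5path = path.with_suffix(".h5")
    with h5py.File(h5path, "w") as h5:
        h5.create_dataset("nodes", data=mesh.nodes)
        h5.create_dataset("tets", data=mesh.tets)
        h5.create_dataset("boundary_faces", data=mesh.boundary_faces)
        h5.create_dataset("boundary_tag", data=mesh.boundary_tags)
        h5.attrs["metadata"] = json.dumps(mesh.metadata, sort_keys=True, default=str)
    xml = f"""<?xml version="1.0"?>
<Xdmf Version="3.0">
<Domain>
<Grid Name="fluid" GridType="Uniform">
<Topology TopologyType="Tetrahedron" NumberOfElements="{mesh.num_tets}">
<DataItem Dimensions="{mesh.num_tets} 4" NumberType="Int" Format="HDF">{h5path.name}:/tets</DataItem>
</Topology>
<Geometry GeometryType="XYZ">
<DataItem Dimensions="{mesh.num_nodes} 3" Format="HDF">{h5path.name}:/nodes</DataItem>
</Geometry>
</Grid>
<Grid Name="boundary" GridType="Uniform">
<Topology TopologyType="Triangle" NumberOfElements="{mesh.boundary_faces.shape[0]}">
<DataItem Dimensions="{mesh.boundary_faces.shape[0]} 3" NumberType="Int" Format="HDF">{h5path.name}:/boundary_faces</DataItem>
</Topology>
<Geometry GeometryType="XYZ">
<DataItem Dimensions="{mesh.num_nodes} 3" Format="HDF">{h5path.name}:/nodes</DataItem>
</Geometry>
<Attribute Name="boundary_tag" Center="Cell">
<DataItem Dimensions="{mesh.boundary_faces.shape[0]}" NumberType="Int" Format="HDF">{h5path.name}:/boundary_tag</DataItem>
</Attribute>
</Grid>
</Domain>
</Xdmf>
"""
    path.write_text(xml)


def _read_xdmf(path: str | os.PathLike) -> TetMesh:
    path = Path(path)
    h5path = path.with_suffix(".h5")
    if not h5path.exists():
        raise MeshIOError(f"heavy-data file {h5path} not found next to {path}")
    with h5py.File(h5path, "r") as h5:
        if "tets" not in h5:
            raise MeshIOError("no tetrahedra in mesh file")
        if "boundary_tag" not in h5:
            raise MeshIOError(
                "missing tag table: dataset 'boundary_tag' with "
                "{1: INLET, 2: OUTLET, 3: SOLID} is required"
            )
        meta = json.loads(h5.attrs.get("metadata", "{}"))
        return TetMesh(
            nodes=h5["nodes"][...],
            tets=h5["tets"][...],
            boundary_faces=h5["boundary_faces"][...],
            boundary_tags=h5["boundary_tag"][...],
            metadata=meta,
        )
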