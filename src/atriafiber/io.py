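"""Read and write tagged unstructured meshes and nodal/element fields.

Supported formats
-----------------
* GMSH MSH v2.2 ASCII with physical groups (read/write).  Boundary triangles
  carry 2D physical groups named after the boundary sets; tetrahedra carry a
  single 3D group.  Landmarks travel in a JSON sidecar.
* VTK XML unstructured grids (``.vtu``), ASCII or base64 binary (read/write).
  Tag names and landmarks are embedded in an XML comment so the file stays a
  plain VTU for standard tools.
* Legacy ASCII VTK unstructured grids (read only); tags require an integer
  cell array plus a name table.

Floats are written with ``repr``-precision so an ASCII round trip is exact.
"""

from __future__ import annotations

import base64
import json
import struct
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import AnatomyMesh, MeshError, TaggingError, locate_landmark

_VTK_TET = 10
_VTK_TRI = 5
_MSH_TRI = 2
_MSH_TET = 4


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def read_mesh(
    path,
    format: str | None = None,
    tag_map: dict[int, str] | None = None,
    landmarks=None,
    required_tags=None,
) -> AnatomyMesh:
    """Read a tagged mesh from MSH v2.2, VTU, or legacy VTK.

    Parameters
    ----------
    format:
        ``"msh"``, ``"vtu"`` or ``"vtk"``; inferred from the suffix if None.
    tag_map:
        Optional ``{physical id: name}`` table overriding / supplying names
        (required for legacy VTK and for MSH files without $PhysicalNames).
    landmarks:
        Either a path to a landmark JSON file or a dict; coordinates are
        snapped to the nearest node, integers are taken as node indices.
    required_tags:
        Tag names that must be present; a missing one raises
        :class:`TaggingError` naming it.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "msh":
        mesh = _read_msh(path, tag_map)
    elif fmt == "vtu":
        mesh = _read_vtu(path, tag_map)[0]
    elif fmt == "vtk":
        mesh = _read_vtk_legacy(path, tag_map)
    else:
        raise MeshError(f"unsupported mesh format {fmt!r}")
    if landmarks is not None:
        mesh.landmarks.update(resolve_landmarks(mesh, landmarks))
    if required_tags:
        for t in required_tags:
            if t not in mesh.tags:
                raise TaggingError(f"mesh is missing required boundary tag {t!r}")
    mesh.validate()
    return mesh


def write_mesh(mesh: AnatomyMesh, path, format: str | None = None,
               binary: bool = False) -> None:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "msh":
        _write_msh(mesh, path)
    elif fmt == "vtu":
        _write_vtu(mesh, path, scalars={}, vectors={}, binary=binary)
    else:
        raise MeshError(f"unsupported mesh format {fmt!r}")


def write_fields(mesh: AnatomyMesh, scalars: dict | None, vectors: dict | None,
                 path, cell_scalars: dict | None = None,
                 binary: bool = False) -> None:
    """Write a VTU with point-data scalars and per-element cell data.

    ``scalars`` are nodal (length ``n_nodes``); ``vectors`` and
    ``cell_scalars`` are per-element (length ``n_elements``).
    """
    scalars = dict(scalars or {})
    vectors = dict(vectors or {})
    cell_scalars = dict(cell_scalars or {})
    for name, v in scalars.items():
        if np.shape(v)[0] != mesh.n_nodes:
            raise ValueError(
                f"scalar field {name!r} has length {np.shape(v)[0]}, "
                f"expected {mesh.n_nodes} nodes"
            )
    for name, v in vectors.items():
        v = np.asarray(v)
        if v.shape != (mesh.n_elements, 3):
            raise ValueError(
                f"vector field {name!r} has shape {v.shape}, expected "
                f"({mesh.n_elements}, 3)"
            )
    for name, v in cell_scalars.items():
        if np.shape(v)[0] != mesh.n_elements:
            raise ValueError(
                f"cell field {name!r} has length {np.shape(v)[0]}, "
                f"expected {mesh.n_elements} elements"
            )
    _write_vtu(mesh, Path(path), scalars=scalars, vectors=vectors,
               cell_scalars=cell_scalars, binary=binary)


def read_fields(path, tag_map=None):
    """Read back a VTU written by :func:`write_fields`.

    Returns ``(mesh, scalars, vectors)``.
    """
    return _read_vtu(Path(path), tag_map)


def resolve_landmarks(mesh: AnatomyMesh, spec) -> dict[str, int]:
    """Resolve a landmark spec (path / dict of coords or indices) to nodes."""
    if isinstance(spec, (str, Path)):
        with open(spec) as f:
            spec = json.load(f)
    out: dict[str, int] = {}
    for name, val in spec.items():
        if np.isscalar(val):
            out[name] = int(val)
        else:
            idx, _dist = locate_landmark(mesh, val)
            out[name] = idx
    return out


def write_landmarks(mesh: AnatomyMesh, path) -> None:
    """Write landmark coordinates as JSON ``{"laa_tip": [x, y, z], ...}``."""
    data = {k: [float(c) for c in mesh.nodes[v]] for k, v in mesh.landmarks.items()}
    with open(path, "w") as f:
        json.dump(data, f, indent=1)


# ---------------------------------------------------------------------------
# MSH v2.2
# ---------------------------------------------------------------------------

def _write_msh(mesh: AnatomyMesh, path: Path) -> None:
    if mesh.mode != "volume":
        raise MeshError("MSH export supports volume meshes only")
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(mesh.tag_names) + 1)]
    for i, name in enumerate(mesh.tag_names):
        lines.append(f'2 {i + 1} "{name}"')
    lines.append(f'3 {len(mesh.tag_names) + 1} "myocardium"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(mesh.boundary_facets.shape[0] + mesh.n_elements))
    eid = 1
    for tri, tag in zip(mesh.boundary_facets, mesh.facet_tags):
        a, b, c = (tri + 1).tolist()
        lines.append(f"{eid} {_MSH_TRI} 2 {tag + 1} {tag + 1} {a} {b} {c}")
        eid += 1
    vol_id = len(mesh.tag_names) + 1
    for tet in mesh.elements:
        a, b, c, d = (tet + 1).tolist()
        lines.append(f"{eid} {_MSH_TET} 2 {vol_id} {vol_id} {a} {b} {c} {d}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path, tag_map=None) -> AnatomyMesh:
    text = path.read_text().split("\n")
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(text) and text[j].strip() != f"$End{name}":
                body.append(text[j])
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1
    if "MeshFormat" in sections:
        version = sections["MeshFormat"][0].split()[0]
        if not version.startswith("2."):
            raise MeshError(
                f"MSH version {version} not supported (ASCII v2.2 only)"
            )
    names: dict[int, str] = {}
    if "PhysicalNames" in sections:
        for line in sections["PhysicalNames"][1:]:
            parts = line.strip().split(" ", 2)
            if len(parts) == 3:
                dim, pid, name = int(parts[0]), int(parts[1]), parts[2].strip('"')
                if dim == 2:
                    names[pid] = name
    if tag_map:
        names.update(tag_map)
    node_lines = sections["Nodes"]
    n_nodes = int(node_lines[0])
    nodes = np.empty((n_nodes, 3))
    ids = np.empty(n_nodes, dtype=np.int64)
    for k, line in enumerate(node_lines[1:1 + n_nodes]):
        parts = line.split()
        ids[k] = int(parts[0])
        nodes[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
    remap = {int(g): k for k, g in enumerate(ids)}
    tets, tris, tri_phys = [], [], []
    for line in sections["Elements"][1:]:
        parts = line.split()
        if len(parts) < 2:
            continue
        etype = int(parts[1])
        ntags = int(parts[2])
        phys = int(parts[3]) if ntags >= 1 else 0
        conn = [remap[int(p)] for p in parts[3 + ntags:]]
        if etype == _MSH_TET:
            tets.append(conn)
        elif etype == _MSH_TRI:
            tris.append(conn)
            tri_phys.append(phys)
        else:
            raise MeshError(
                f"unsupported MSH element type {etype} (tet+tri meshes only)"
            )
    tag_ids = sorted({p for p in tri_phys})
    missing = [p for p in tag_ids if p not in names]
    if missing:
        raise TaggingError(
            f"no names for physical groups {missing}; supply a tag_map"
        )
    tag_names = [names[p] for p in tag_ids]
    lookup = {p: i for i, p in enumerate(tag_ids)}
    facet_tags = np.array([lookup[p] for p in tri_phys], dtype=np.int64)
    return AnatomyMesh(
        nodes=nodes,
        elements=np.asarray(tets, dtype=np.int64).reshape(-1, 4),
        boundary_facets=np.asarray(tris, dtype=np.int64).reshape(-1, 3),
        facet_tags=facet_tags,
        tag_names=tag_names,
    )


# ---------------------------------------------------------------------------
# VTU (XML unstructured grid)
# ---------------------------------------------------------------------------

def _fmt_array_ascii(a: np.ndarray) -> str:
    flat = np.asarray(a).ravel()
    if flat.dtype.kind == "f":
        return " ".join(repr(float(v)) for v in flat)
    return " ".join(str(int(v)) for v in flat)


def _fmt_array_binary(a: np.ndarray) -> str:
    a = np.ascontiguousarray(a)
    raw = a.tobytes()
    header = struct.pack("<Q", len(raw))
    return base64.b64encode(header + raw).decode("ascii")


def _data_array(name, a, n_comp, binary):
    a = np.asarray(a)
    vtype = {"f": "Float64", "i": "Int64"}[a.dtype.kind]
    if a.dtype.kind == "f":
        a = a.astype(np.float64)
    else:
        a = a.astype(np.int64)
    fmt = "binary" if binary else "ascii"
    attrs = f'type="{vtype}" Name="{name}" NumberOfComponents="{n_comp}" format="{fmt}"'
    body = _fmt_array_binary(a) if binary else _fmt_array_ascii(a)
    return f"<DataArray {attrs}>\n{body}\n</DataArray>"


def _write_vtu(mesh: AnatomyMesh, path: Path, scalars, vectors,
               cell_scalars=None, binary=False):
    cell_scalars = cell_scalars or {}
    n_tets = mesh.n_elements
    if mesh.mode == "volume":
        cells = [mesh.elements, mesh.boundary_facets]
        conn = np.concatenate([mesh.elements.ravel(), mesh.boundary_facets.ravel()])
        offsets = np.concatenate([
            4 * np.arange(1, n_tets + 1),
            4 * n_tets + 3 * np.arange(1, mesh.boundary_facets.shape[0] + 1),
        ])
        types = np.concatenate([
            np.full(n_tets, _VTK_TET), np.full(mesh.boundary_facets.shape[0], _VTK_TRI)
        ])
        cell_tag = np.concatenate([np.full(n_tets, -1, dtype=np.int64), mesh.facet_tags])
    else:
        conn = mesh.elements.ravel()
        offsets = 3 * np.arange(1, n_tets + 1)
        types = np.full(n_tets, _VTK_TRI)
        cell_tag = np.full(n_tets, -1, dtype=np.int64)
    n_cells = len(types)

    meta = {
        "tag_names": mesh.tag_names,
        "landmarks": {k: int(v) for k, v in mesh.landmarks.items()},
        "node_sets": {k: np.asarray(v).tolist() for k, v in mesh.node_sets.items()},
        "mode": mesh.mode,
        "layer": mesh.layer,
        "n_elements": int(mesh.n_elements),
    }
    pd = [_data_array(k, np.asarray(v, dtype=np.float64), 1, binary)
          for k, v in scalars.items()]
    cd = [_data_array("boundary_tag", cell_tag, 1, binary)]
    for k, v in vectors.items():
        full = np.zeros((n_cells, 3))
        full[: mesh.n_elements] = v
        cd.append(_data_array(k, full, 3, binary))
    for k, v in cell_scalars.items():
        v = np.asarray(v)
        fill = -1 if v.dtype.kind == "i" else np.nan
        full = np.full(n_cells, fill, dtype=v.dtype)
        full[: mesh.n_elements] = v
        cd.append(_data_array(k, full, 1, binary))

    parts = [
        '<?xml version="1.0"?>',
        f"<!--atriafiber:{json.dumps(meta, separators=(',', ':'))}-->",
        '<VTKFile type="UnstructuredGrid" version="1.0" '
        'byte_order="LittleEndian" header_type="UInt64">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{n_cells}">',
        "<Points>",
        _data_array("Points", mesh.nodes, 3, binary),
        "</Points>",
        "<Cells>",
        _data_array("connectivity", conn, 1, binary),
        _data_array("offsets", offsets, 1, binary),
        _data_array("types", types.astype(np.int64), 1, binary),
        "</Cells>",
        "<PointData>", *pd, "</PointData>",
        "<CellData>", *cd, "</CellData>",
        "</Piece>",
        "</UnstructuredGrid>",
        "</VTKFile>",
    ]
    path.write_text("\n".join(parts) + "\n")


def _parse_data_array(elem) -> np.ndarray:
    fmt = elem.get("format", "ascii")
    vtype = elem.get("type", "Float64")
    dtype = {"Float64": np.float64, "Float32": np.float32,
             "Int64": np.int64, "Int32": np.int32,
             "UInt8": np.uint8, "UInt64": np.uint64}[vtype]
    n_comp = int(elem.get("NumberOfComponents", "1"))
    if fmt == "ascii":
        text = elem.text or ""
        a = np.array(text.split(), dtype=dtype)
    elif fmt == "binary":
        raw = base64.b64decode((elem.text or "").strip())
        (nbytes,) = struct.unpack("<Q", raw[:8])
        a = np.frombuffer(raw[8:8 + nbytes], dtype=dtype)
    else:
        raise MeshError(f"unsupported VTU data format {fmt!r}")
    if n_comp > 1:
        a = a.reshape(-1, n_comp)
    return a


def _read_vtu(path: Path, tag_map=None):
    text = path.read_text()
    meta = {}
    marker = "<!--atriafiber:"
    if marker in text:
        start = text.index(marker) + len(marker)
        end = text.index("-->", start)
        meta = json.loads(text[start:end])
    # strip comments for the XML parser
    root = ET.fromstring(text[text.index("<VTKFile"):])
    piece = root.find(".//Piece")
    points = conn = offsets = types = None
    scalars: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    for da in piece.find("Points"):
        points = _parse_data_array(da).reshape(-1, 3)
    for da in piece.find("Cells"):
        name = da.get("Name")
        if name == "connectivity":
            conn = _parse_data_array(da).astype(np.int64)
        elif name == "offsets":
            offsets = _parse_data_array(da).astype(np.int64)
        elif name == "types":
            types = _parse_data_array(da).astype(np.int64)
    pd = piece.find("PointData")
    if pd is not None:
        for da in pd:
            scalars[da.get("Name")] = _parse_data_array(da).astype(np.float64)
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd:
            cell_data[da.get("Name")] = _parse_data_array(da)

    sizes = np.diff(np.concatenate([[0], offsets]))
    tet_mask = types == _VTK_TET
    tri_mask = types == _VTK_TRI
    if not np.all(tet_mask | tri_mask):
        raise MeshError("VTU contains cell types other than tetrahedra/triangles")
    starts = offsets - sizes
    tets = np.stack([conn[s:s + 4] for s in starts[tet_mask]]) if tet_mask.any() \
        else np.empty((0, 4), np.int64)
    tris = np.stack([conn[s:s + 3] for s in starts[tri_mask]]) if tri_mask.any() \
        else np.empty((0, 3), np.int64)

    mode = meta.get("mode", "volume" if tet_mask.any() else "surface")
    tag_names = list(meta.get("tag_names", []))
    if tag_map:
        for pid, name in sorted(tag_map.items()):
            if name not in tag_names:
                tag_names.append(name)
    if mode == "volume":
        bt = cell_data.get("boundary_tag")
        facet_tags = (np.asarray(bt).ravel()[tri_mask.nonzero()[0]]
                      if bt is not None else np.zeros(len(tris), np.int64))
        elements = tets
        facets = tris
    else:
        elements = tris
        facets = np.empty((0, 3), np.int64)
        facet_tags = np.empty(0, np.int64)
    mesh = AnatomyMesh(
        nodes=points,
        elements=elements,
        boundary_facets=facets,
        facet_tags=facet_tags.astype(np.int64),
        tag_names=tag_names,
        landmarks={k: int(v) for k, v in meta.get("landmarks", {}).items()},
        node_sets={k: np.asarray(v, dtype=np.int64)
                   for k, v in meta.get("node_sets", {}).items()},
        mode=mode,
        layer=meta.get("layer"),
    )
    vectors = {k: np.asarray(v, dtype=np.float64)[: mesh.n_elements]
               for k, v in cell_data.items() if np.ndim(v) == 2}
    return mesh, scalars, vectors


# ---------------------------------------------------------------------------
# legacy VTK (read only)
# ---------------------------------------------------------------------------

def _read_vtk_legacy(path: Path, tag_map=None) -> AnatomyMesh:
    lines = path.read_text().split("\n")
    i = 0
    points = None
    cells = []
    types = None
    cell_scalars = {}
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        kw = parts[0].upper()
        if kw == "POINTS":
            n = int(parts[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            points = np.array(vals).reshape(n, 3)
            continue
        if kw == "CELLS":
            n = int(parts[1])
            i += 1
            for _ in range(n):
                row = [int(v) for v in lines[i].split()]
                cells.append(row[1:1 + row[0]])
                i += 1
            continue
        if kw == "CELL_TYPES":
            n = int(parts[1])
            vals = []
            i += 1
            while len(vals) < n:
                vals.extend(int(v) for v in lines[i].split())
                i += 1
            types = np.array(vals)
            continue
        if kw == "SCALARS" and types is not None:
            name = parts[1]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < len(types):
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            cell_scalars[name] = np.array(vals)
            continue
        i += 1
    types = types if types is not None else np.empty(0, int)
    bad = ~np.isin(types, (_VTK_TET, _VTK_TRI))
    if bad.any():
        raise MeshError("legacy VTK contains cell types other than tet/tri")
    tets = np.array([c for c, t in zip(cells, types) if t == _VTK_TET],
                    dtype=np.int64).reshape(-1, 4)
    tris = np.array([c for c, t in zip(cells, types) if t == _VTK_TRI],
                    dtype=np.int64).reshape(-1, 3)
    tag_arr = None
    for arr in cell_scalars.values():
        tag_arr = arr
    tag_map = tag_map or {}
    tag_ids = (sorted({int(t) for c, t in zip(cells, tag_arr) if len(c) == 3})
               if tag_arr is not None else [])
    missing = [t for t in tag_ids if t not in tag_map]
    if tag_ids and missing:
        raise TaggingError(f"no names for legacy-VTK tag ids {missing}")
    tag_names = [tag_map[t] for t in tag_ids]
    if tag_arr is not None and len(tris):
        tri_tags_raw = tag_arr[types == _VTK_TRI].astype(int)
        lookup = {t: i for i, t in enumerate(tag_ids)}
        facet_tags = np.array([lookup[t] for t in tri_tags_raw], dtype=np.int64)
    else:
        facet_tags = np.zeros(len(tris), dtype=np.int64)
    return AnatomyMesh(
        nodes=points,
        elements=tets if len(tets) else tris,
        boundary_facets=tris if len(tets) else np.empty((0, 3), np.int64),
        facet_tags=facet_tags if len(tets) else np.empty(0, np.int64),
        tag_names=tag_names,
        mode="volume" if len(tets) else "surface",
        layer=None if len(tets) else "endo",
    )
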