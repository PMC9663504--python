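"""Readers and writers for the pipeline's file formats.

Meshes travel as VTU (ASCII XML unstructured grid, tetra cells, with
cell-data ``region`` and optional point-data ``displacement``) and
legacy ASCII VTK is accepted on input; surfaces as STL (binary and
ASCII, via trimesh); labeled volumes as NRRD (raw or ascii encodings)
or multi-page TIFF; doublets and profiles as CSV; scenarios as TOML.
Every writer has a matching reader and the round trip is exact up to
float formatting (17 significant digits are written).
"""

from __future__ import annotations

import json
import tomllib
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh as _trimesh

from .fem import DisplacementField, Material, RegionLoading
from .mesh import RegionPartition, TetMesh
from .orientation import DoubletSet
from .scenarios import Scenario
from .shape import DiameterProfile, LabeledVolume
from .synth import TriSurface

__all__ = [
    "write_vtu",
    "read_vtu",
    "read_legacy_vtk",
    "read_mesh",
    "write_stl",
    "read_stl",
    "write_nrrd",
    "read_nrrd",
    "write_volume_tiff",
    "read_volume_tiff",
    "write_scenario_toml",
    "read_scenario_toml",
    "write_doublets_csv",
    "read_doublets_csv",
    "write_profile_csv",
    "write_provenance",
]


class MeshParseError(ValueError):
    """Malformed mesh file; message carries file/line context."""


# ------------------------------------------------------------------ VTU


def _fmt_floats(a: np.ndarray) -> str:
    return "\n".join(" ".join(repr(float(x)) for x in row) for row in np.atleast_2d(a))


def write_vtu(path, mesh: TetMesh, point_data: dict = None, cell_data: dict = None):
    """Write a tet mesh as ASCII XML VTU.

    ``region`` is always written as cell data; extra per-vertex arrays
    (e.g. a displacement field or a deviation map) go in ``point_data``.
    """
    path = Path(path)
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region_of_tet)
    n_pts, n_cells = mesh.n_vertices, mesh.n_tets
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt_floats(mesh.vertices),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(map(str, t)) for t in mesh.tets),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(4 * (i + 1)) for i in range(n_cells)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("10" for _ in range(n_cells)),
        "</DataArray>",
        "</Cells>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            lines += [
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">',
                _fmt_floats(arr.reshape(n_pts, ncomp)),
                "</DataArray>",
            ]
        lines.append("</PointData>")
    lines.append("<CellData>")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            lines += [
                f'<DataArray type="Int64" Name="{name}" format="ascii">',
                " ".join(map(str, arr.tolist())),
                "</DataArray>",
            ]
        else:
            lines += [
                f'<DataArray type="Float64" Name="{name}" format="ascii">',
                _fmt_floats(arr.reshape(n_cells, -1)),
                "</DataArray>",
            ]
    lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>", ""]
    path.write_text("\n".join(lines))


def _parse_array(elem, dtype, path):
    try:
        return np.fromstring(elem.text.replace("\n", " "), sep=" ").astype(dtype)
    except (AttributeError, ValueError) as e:
        raise MeshParseError(f"{path}: cannot parse DataArray "
                             f"{elem.get('Name', '<points>')}: {e}") from e


def read_vtu(path):
    """Read an ASCII VTU tet mesh.

    Returns (TetMesh, point_data dict).  Only tetra (type 10) cells are
    accepted; other cell types raise :class:`MeshParseError`.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise MeshParseError(f"{path}: malformed XML at {e.position}: {e.msg}") from e
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshParseError(f"{path}: no <Piece> element")
    pts_el = piece.find("./Points/DataArray")
    if pts_el is None:
        raise MeshParseError(f"{path}: no Points DataArray")
    if pts_el.get("format", "ascii") != "ascii":
        raise MeshParseError(f"{path}: only ascii-format VTU is supported")
    vertices = _parse_array(pts_el, float, path).reshape(-1, 3)
    arrays = {el.get("Name"): el for el in piece.findall("./Cells/DataArray")}
    for req in ("connectivity", "offsets", "types"):
        if req not in arrays:
            raise MeshParseError(f"{path}: missing Cells array {req!r}")
    types = _parse_array(arrays["types"], int, path)
    if not np.all(types == 10):
        raise MeshParseError(f"{path}: non-tetra cell types present: "
                             f"{sorted(set(types.tolist()) - {10})}")
    conn = _parse_array(arrays["connectivity"], np.int64, path)
    offsets = _parse_array(arrays["offsets"], np.int64, path)
    if len(conn) != 4 * len(offsets) or np.any(np.diff(offsets) != 4):
        raise MeshParseError(f"{path}: connectivity/offsets inconsistent")
    tets = conn.reshape(-1, 4)
    region = None
    for el in piece.findall("./CellData/DataArray"):
        if el.get("Name") == "region":
            region = _parse_array(el, np.int64, path)
    point_data = {}
    for el in piece.findall("./PointData/DataArray"):
        ncomp = int(el.get("NumberOfComponents", 1))
        arr = _parse_array(el, float, path)
        point_data[el.get("Name")] = arr.reshape(len(vertices), ncomp) if ncomp > 1 else arr
    mesh = TetMesh(vertices=vertices, tets=tets,
                   surface_tris=_surface_of(vertices, tets),
                   region_of_tet=region)
    return mesh, point_data


def _surface_of(vertices, tets):
    from .mesh import extract_surface

    return extract_surface(np.asarray(vertices), np.asarray(tets, dtype=np.int64))


def read_legacy_vtk(path):
    """Read a legacy ASCII VTK unstructured grid of tetrahedra."""
    path = Path(path)
    lines = path.read_text().splitlines()
    it = iter(enumerate(lines, 1))

    def seek(prefix):
        for ln, line in it:
            if line.strip().upper().startswith(prefix):
                return ln, line.split()
        raise MeshParseError(f"{path}: keyword {prefix!r} not found")

    _, ds = seek("DATASET")
    if ds[1].upper() != "UNSTRUCTURED_GRID":
        raise MeshParseError(f"{path}: expected UNSTRUCTURED_GRID, got {ds[1]}")
    ln, pts = seek("POINTS")
    n = int(pts[1])
    vals = []
    while len(vals) < 3 * n:
        ln, line = next(it)
        vals += [float(x) for x in line.split()]
    vertices = np.array(vals).reshape(n, 3)
    ln, cells = seek("CELLS")
    m = int(cells[1])
    vals = []
    while len(vals) < int(cells[2]):
        ln, line = next(it)
        vals += [int(x) for x in line.split()]
    vals = np.array(vals)
    tets, i = [], 0
    for _ in range(m):
        k = vals[i]
        if k != 4:
            raise MeshParseError(f"{path}: non-tetra cell with {k} points")
        tets.append(vals[i + 1 : i + 5])
        i += k + 1
    tets = np.array(tets, dtype=np.int64)
    return TetMesh(vertices=vertices, tets=tets,
                   surface_tris=_surface_of(vertices, tets)), {}


def read_mesh(path):
    """Dispatch on extension: .vtu -> XML VTU, .vtk -> legacy ASCII."""
    path = Path(path)
    if path.suffix.lower() == ".vtu":
        return read_vtu(path)
    if path.suffix.lower() == ".vtk":
        return read_legacy_vtk(path)
    raise MeshParseError(f"{path}: unsupported mesh extension {path.suffix!r}")


# ------------------------------------------------------------------ STL


def write_stl(path, surface: TriSurface, ascii_format: bool = False):
    """Write a triangulated surface as STL (binary by default).

    Degenerate (zero-area) triangles are counted and warned about but
    still written.
    """
    v, t = surface.vertices, surface.tris
    areas = 0.5 * np.linalg.norm(
        np.cross(v[t][:, 1] - v[t][:, 0], v[t][:, 2] - v[t][:, 0]), axis=1
    )
    n_deg = int(np.count_nonzero(areas == 0))
    if n_deg:
        warnings.warn(f"{n_deg} degenerate zero-area triangles in surface",
                      stacklevel=2)
    tm = _trimesh.Trimesh(vertices=v, faces=t, process=False)
    tm.export(str(path), file_type="stl_ascii" if ascii_format else "stl")


def read_stl(path) -> TriSurface:
    """Read STL (either dialect); coincident soup vertices are merged so
    shared edges are recovered (STL itself stores only a triangle soup)."""
    tm = _trimesh.load(str(path), file_type="stl", process=False)
    tm.merge_vertices()
    return TriSurface(vertices=np.asarray(tm.vertices, float),
                      tris=np.asarray(tm.faces, np.int64))


# ----------------------------------------------------------------- NRRD


_NRRD_TYPES = {"int8": np.int8, "uint8": np.uint8, "int16": np.int16,
               "uint16": np.uint16, "int32": np.int32}


def write_nrrd(path, volume: LabeledVolume, encoding: str = "raw"):
    """Write a labeled volume as NRRD (detached nothing; single file).

    ``encoding`` is ``raw`` (little-endian) or ``ascii``.
    """
    if encoding not in ("raw", "ascii"):
        raise ValueError("encoding must be 'raw' or 'ascii'")
    data = volume.data
    dtype_name = {v: k for k, v in _NRRD_TYPES.items()}.get(data.dtype.type)
    if dtype_name is None:
        data = data.astype(np.int16)
        dtype_name = "int16"
    header = [
        "NRRD0004",
        "# labeled volume written by bulkybone",
        f"type: {dtype_name}",
        "dimension: 3",
        f"sizes: {data.shape[2]} {data.shape[1]} {data.shape[0]}",
        f"spacings: {volume.voxel_mm!r} {volume.voxel_mm!r} {volume.voxel_mm!r}",
        f"encoding: {encoding}",
    ]
    if encoding == "raw":
        header.append("endian: little")
    head = "\n".join(header) + "\n\n"
    with open(path, "wb") as fh:
        fh.write(head.encode())
        if encoding == "raw":
            fh.write(np.ascontiguousarray(data).astype(data.dtype.newbyteorder("<")).tobytes())
        else:
            fh.write(" ".join(map(str, data.reshape(-1).tolist())).encode())


def read_nrrd(path) -> LabeledVolume:
    """Read a single-file NRRD labeled volume (raw or ascii encoding)."""
    raw = Path(path).read_bytes()
    try:
        head_end = raw.index(b"\n\n")
    except ValueError as e:
        raise MeshParseError(f"{path}: NRRD header terminator not found") from e
    head = raw[:head_end].decode()
    body = raw[head_end + 2:]
    lines = head.splitlines()
    if not lines[0].startswith("NRRD"):
        raise MeshParseError(f"{path}: not an NRRD file")
    fields = {}
    for line in lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        k, v = line.split(":", 1)
        fields[k.strip()] = v.strip()
    dtype = _NRRD_TYPES.get(fields.get("type"))
    if dtype is None:
        raise MeshParseError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    sizes = [int(x) for x in fields["sizes"].split()]
    shape = tuple(reversed(sizes))  # NRRD sizes are fastest-axis first
    spacing = float(fields.get("spacings", "1 1 1").split()[0])
    enc = fields.get("encoding", "raw")
    if enc == "raw":
        data = np.frombuffer(body, dtype=np.dtype(dtype).newbyteorder("<"),
                             count=int(np.prod(shape))).reshape(shape)
    elif enc in ("ascii", "text", "txt"):
        data = np.fromstring(body.decode(), dtype=float, sep=" ").astype(dtype).reshape(shape)
    else:
        raise MeshParseError(f"{path}: unsupported NRRD encoding {enc!r}")
    return LabeledVolume(data=np.ascontiguousarray(data).astype(dtype), voxel_mm=spacing)


def write_volume_tiff(path, volume: LabeledVolume):
    """Multi-page TIFF; voxel size stored in the ImageDescription tag."""
    tifffile.imwrite(path, volume.data.astype(np.uint8),
                     photometric="minisblack",
                     description=json.dumps({"voxel_mm": volume.voxel_mm}))


def read_volume_tiff(path) -> LabeledVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        voxel = float(json.loads(desc).get("voxel_mm", 1.0))
    except (json.JSONDecodeError, AttributeError):
        voxel = 1.0
    return LabeledVolume(data=data.astype(np.int16), voxel_mm=voxel)


# ----------------------------------------------------------------- TOML


def _toml_value(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot emit TOML value of type {type(v)}")


def _emit_toml(tables: dict) -> str:
    out = []
    for name, table in tables.items():
        out.append(f"[{name}]")
        for k, v in table.items():
            out.append(f"{k} = {_toml_value(v)}")
        out.append("")
    return "\n".join(out)


def write_scenario_toml(path, scenario: Scenario):
    """Persist a scenario with explicit per-region moduli (round-trip
    exact)."""
    n = scenario.partition.n_regions
    tables = {
        "scenario": {"name": scenario.name,
                     "normalization": scenario.normalization},
        "material": {"young_modulus": scenario.material.young_modulus,
                     "poisson_ratio": scenario.material.poisson_ratio},
        "regions": {"boundaries": list(scenario.partition.boundaries)},
        "loads": {
            "axial": [scenario.loads.axial[k] for k in range(1, n + 1)],
            "radial": [scenario.loads.radial[k] for k in range(1, n + 1)],
        },
    }
    Path(path).write_text(_emit_toml(tables))


def read_scenario_toml(path) -> Scenario:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    part = RegionPartition(tuple(doc["regions"]["boundaries"]))
    ax = {i + 1: float(v) for i, v in enumerate(doc["loads"]["axial"])}
    ra = {i + 1: float(v) for i, v in enumerate(doc["loads"]["radial"])}
    return Scenario(
        name=doc["scenario"]["name"],
        partition=part,
        loads=RegionLoading(axial=ax, radial=ra),
        material=Material(doc["material"]["young_modulus"],
                          doc["material"]["poisson_ratio"]),
        normalization=doc["scenario"].get("normalization", 0.2),
    )


# ------------------------------------------------------------------ CSV


def write_doublets_csv(path, doublets: DoubletSet, seed=None):
    """CSV with header id,ax,ay,az,bx,by,bz,group; the generator seed is
    echoed in a comment line for provenance."""
    df = doublets.to_dataframe()
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_doublets_csv(path, axis=(0.0, 0.0, 1.0)) -> DoubletSet:
    df = pd.read_csv(path, comment="#")
    return DoubletSet.from_dataframe(df, axis=axis)


def write_profile_csv(path, profile: DiameterProfile):
    pd.DataFrame({
        "z_mm": profile.bin_centers,
        "effective_radius_mm": profile.effective_radius,
        "max_radius_mm": profile.max_radius,
        "count": profile.counts,
    }).to_csv(path, index=False)


def write_provenance(path, config_hash: str, seed, extra: dict = None):
    """JSON sidecar: config hash, seed, tool version."""
    from . import __version__

    doc = {"config_hash": config_hash, "seed": seed, "version": __version__}
    doc.update(extra or {})
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
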