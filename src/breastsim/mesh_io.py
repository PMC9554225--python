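"""Volume/surface mesh I/O, boundary-node tagging and ROI cropping.

Coordinates are stored in millimetres (the convention of surface scanners
and CT exports).  The patient frame used throughout the package is

    x : patient left -> right
    y : caudal -> cranial
    z : posterior -> anterior  (supine gravity points along -z)

Volume meshes are linear tetrahedra; tet orientation is normalised on read
so every signed rest volume is positive.  Rigid (chest-wall-coupled) node
sets travel in a sidecar JSON file next to the mesh file.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TetMesh",
    "SurfaceScan",
    "RoiSpec",
    "read_tet_mesh",
    "write_tet_mesh",
    "write_deformed_mesh",
    "read_surface",
    "write_surface",
    "crop_to_roi",
    "tag_rigid_nodes",
    "tet_volumes",
    "boundary_faces",
]

MM_PER_M = 1000.0


class MeshIOError(RuntimeError):
    """Raised for unreadable, empty or structurally invalid mesh files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TetMesh:
    """Rest-configuration tetrahedral discretisation of the breast domain.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres, patient frame.
    tets : (m, 4) int array of vertex indices, positively oriented.
    rigid_nodes : sorted int array of nodes coupled to the chest wall.
    """

    vertices: np.ndarray
    tets: np.ndarray
    rigid_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.intp)
        self.rigid_nodes = np.unique(np.asarray(self.rigid_nodes, dtype=np.intp))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshIOError("vertices must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshIOError("tets must be (m, 4)")
        n = len(self.vertices)
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= n):
            raise MeshIOError("tet indices out of range")
        if self.rigid_nodes.size and (
            self.rigid_nodes.min() < 0 or self.rigid_nodes.max() >= n
        ):
            raise MeshIOError("rigid node indices out of range")
        if self.tets.size:
            self.tets = _fix_orientation(self.vertices, self.tets)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def free_nodes(self) -> np.ndarray:
        """Complement of ``rigid_nodes`` (sorted)."""
        mask = np.ones(self.n_vertices, dtype=bool)
        mask[self.rigid_nodes] = False
        return np.flatnonzero(mask)

    def volumes(self) -> np.ndarray:
        """Signed tet volumes in mm^3 (positive after orientation fixing)."""
        return tet_volumes(self.vertices, self.tets)

    def with_rigid(self, rigid_nodes: np.ndarray) -> "TetMesh":
        return replace(self, rigid_nodes=np.asarray(rigid_nodes, dtype=np.intp))


@dataclass
class SurfaceScan:
    """A 3D surface scan: point cloud with optional triangles and normals."""

    points: np.ndarray
    triangles: np.ndarray | None = None
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.triangles is not None:
            self.triangles = np.ascontiguousarray(self.triangles, dtype=np.intp)
            if self.triangles.size == 0:
                self.triangles = None
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
            lens = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(lens - 1.0) > 1e-6):
                raise MeshIOError("normals must have unit length")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RoiSpec:
    """Spherical region of interest: a centre point and a radius, in mm."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of linear tets, same length unit cubed as *vertices*."""
    v = vertices[tets]
    d = v[:, 1:] - v[:, :1]
    return np.linalg.det(d) / 6.0


def _fix_orientation(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two indices of negatively oriented tets; reject degenerate ones."""
    tets = tets.copy()
    vol = tet_volumes(vertices, tets)
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    vol = np.abs(vol)
    scale = np.max(np.abs(vertices)) if len(vertices) else 1.0
    bad = np.flatnonzero(vol <= 1e-12 * max(scale, 1.0) ** 3)
    if bad.size:
        raise MeshIOError(f"degenerate (zero-volume) tetrahedron at index {bad[0]}")
    return tets


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a positively oriented tet mesh.

    Each face of each tet is taken with the vertex order that makes its
    normal point away from the opposite vertex; faces shared by two tets
    cancel and only the surface remains.
    """
    # local faces with outward orientation for a positively oriented tet
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, local].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


# ---------------------------------------------------------------------------
# Volume-mesh readers / writers (ASCII VTU, legacy VTK, Gmsh MSH v2.2)
# ---------------------------------------------------------------------------

_VTK_TET = 10


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".nodesets.json")


def _load_sidecar(path: Path) -> np.ndarray:
    sc = _sidecar_path(path)
    if sc.exists():
        data = json.loads(sc.read_text())
        return np.asarray(data.get("rigid_nodes", []), dtype=np.intp)
    return np.empty(0, dtype=np.intp)


def _parse_vtu(path: Path) -> tuple[np.ndarray, np.ndarray]:
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshIOError(f"{path}: no UnstructuredGrid piece")
    pts_da = piece.find("./Points/DataArray")
    points = np.array(pts_da.text.split(), dtype=float).reshape(-1, 3)
    arrays = {
        da.get("Name"): np.array(da.text.split(), dtype=float)
        for da in piece.findall("./Cells/DataArray")
    }
    conn = arrays["connectivity"].astype(np.intp)
    offs = arrays["offsets"].astype(np.intp)
    types = arrays["types"].astype(int)
    tets = []
    start = 0
    for off, ct in zip(offs, types):
        if ct == _VTK_TET:
            tets.append(conn[start:off])
        start = off
    if not tets:
        raise MeshIOError(f"{path}: no tetrahedral cells")
    return points, np.asarray(tets, dtype=np.intp)


def _parse_legacy_vtk(path: Path) -> tuple[np.ndarray, np.ndarray]:
    tokens = path.read_text().split()
    it = iter(range(len(tokens)))
    upper = [t.upper() for t in tokens]
    if "POINTS" not in upper or "CELLS" not in upper:
        raise MeshIOError(f"{path}: not a legacy VTK unstructured grid")
    i = upper.index("POINTS")
    npts = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * npts], dtype=float).reshape(-1, 3)
    i = upper.index("CELLS")
    ncells = int(tokens[i + 1])
    pos = i + 3
    cells = []
    for _ in range(ncells):
        k = int(tokens[pos])
        cells.append([int(t) for t in tokens[pos + 1 : pos + 1 + k]])
        pos += k + 1
    i = upper.index("CELL_TYPES")
    types = [int(t) for t in tokens[i + 2 : i + 2 + ncells]]
    tets = [c for c, t in zip(cells, types) if t == _VTK_TET and len(c) == 4]
    if not tets:
        raise MeshIOError(f"{path}: no tetrahedral cells")
    return pts, np.asarray(tets, dtype=np.intp)


def _parse_msh(path: Path) -> tuple[np.ndarray, np.ndarray]:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("$MeshFormat"):
        raise MeshIOError(f"{path}: not a Gmsh MSH file")
    version = lines[1].split()[0]
    if not version.startswith("2"):
        raise MeshIOError(f"{path}: only MSH v2.x ASCII is supported, got {version}")
    idx = {ln.strip(): i for i, ln in enumerate(lines)}
    ni = idx["$Nodes"]
    nn = int(lines[ni + 1])
    ids, coords = [], []
    for ln in lines[ni + 2 : ni + 2 + nn]:
        parts = ln.split()
        ids.append(int(parts[0]))
        coords.append([float(p) for p in parts[1:4]])
    remap = {nid: k for k, nid in enumerate(ids)}
    ei = idx["$Elements"]
    ne = int(lines[ei + 1])
    tets = []
    for ln in lines[ei + 2 : ei + 2 + ne]:
        parts = [int(p) for p in ln.split()]
        etype, ntags = parts[1], parts[2]
        if etype == 4:  # 4-node tetrahedron
            tets.append([remap[v] for v in parts[3 + ntags :]])
    if not tets:
        raise MeshIOError(f"{path}: no tetrahedral elements")
    return np.asarray(coords, dtype=float), np.asarray(tets, dtype=np.intp)


def read_tet_mesh(path: str | Path, format: str | None = None) -> TetMesh:
    """Read a tetrahedral mesh (VTU, legacy VTK, or Gmsh MSH v2 ASCII).

    Tet orientation is normalised so all signed volumes are positive; a
    degenerate element is rejected with its index.  A sidecar
    ``<name>.nodesets.json`` file, when present, supplies ``rigid_nodes``.
    """
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"mesh file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "vtu":
        pts, tets = _parse_vtu(path)
    elif fmt == "vtk":
        pts, tets = _parse_legacy_vtk(path)
    elif fmt == "msh":
        pts, tets = _parse_msh(path)
    else:
        raise MeshIOError(f"unsupported volume mesh format: {fmt}")
    tets = _fix_orientation(pts, tets)
    return TetMesh(pts, tets, _load_sidecar(path))


def _format_floats(a: np.ndarray) -> str:
    return "\n".join(" ".join(f"{x:.17g}" for x in row) for row in np.atleast_2d(a))


def write_tet_mesh(mesh: TetMesh, path: str | Path, format: str | None = None) -> None:
    """Write a tet mesh as ASCII VTU, legacy VTK or MSH v2.2, plus sidecar."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "vtu":
        _write_vtu(path, mesh.vertices, mesh.tets, {})
    elif fmt == "vtk":
        n, m = mesh.n_vertices, mesh.n_tets
        out = [
            "# vtk DataFile Version 3.0",
            "breastsim mesh",
            "ASCII",
            "DATASET UNSTRUCTURED_GRID",
            f"POINTS {n} double",
            _format_floats(mesh.vertices),
            f"CELLS {m} {5 * m}",
            "\n".join("4 " + " ".join(map(str, t)) for t in mesh.tets),
            f"CELL_TYPES {m}",
            "\n".join(["10"] * m),
        ]
        path.write_text("\n".join(out) + "\n")
    elif fmt == "msh":
        out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
               str(mesh.n_vertices)]
        out += [
            f"{i + 1} {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
            for i, v in enumerate(mesh.vertices)
        ]
        out += ["$EndNodes", "$Elements", str(mesh.n_tets)]
        out += [
            f"{i + 1} 4 0 " + " ".join(str(v + 1) for v in t)
            for i, t in enumerate(mesh.tets)
        ]
        out += ["$EndElements"]
        path.write_text("\n".join(out) + "\n")
    else:
        raise MeshIOError(f"unsupported volume mesh format: {fmt}")
    _sidecar_path(path).write_text(
        json.dumps({"rigid_nodes": [int(i) for i in mesh.rigid_nodes]})
    )


def _write_vtu(
    path: Path,
    points: np.ndarray,
    tets: np.ndarray,
    point_data: dict[str, np.ndarray],
) -> None:
    m = len(tets)
    pd = []
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        comps = 1 if arr.ndim == 1 else arr.shape[1]
        pd.append(
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{comps}" format="ascii">\n'
            + _format_floats(arr.reshape(len(points), -1))
            + "\n</DataArray>"
        )
    body = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{len(points)}" NumberOfCells="{m}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">
{_format_floats(points)}
</DataArray>
</Points>
<PointData>
{chr(10).join(pd)}
</PointData>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{chr(10).join(" ".join(map(str, t)) for t in tets)}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{" ".join(str(4 * (i + 1)) for i in range(m))}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{" ".join(["10"] * m)}
</DataArray>
</Cells>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    path.write_text(body)


def write_deformed_mesh(mesh: TetMesh, state, path: str | Path) -> None:
    """Write a VTU of the deformed mesh with a ``displacement_mm`` field.

    ``state`` is a :class:`~breastsim.fem.DeformationState` (positions in
    metres); output coordinates are millimetres.
    """
    pos_mm = np.asarray(state.positions, dtype=float) * MM_PER_M
    if pos_mm.shape != mesh.vertices.shape:
        raise MeshIOError("state has wrong number of positions for this mesh")
    disp = np.linalg.norm(pos_mm - mesh.vertices, axis=1)
    _write_vtu(Path(path), pos_mm, mesh.tets, {"displacement_mm": disp})


# ---------------------------------------------------------------------------
# Surface readers / writers (trimesh-backed)
# ---------------------------------------------------------------------------


def read_surface(path: str | Path, format: str | None = None) -> SurfaceScan:
    """Read an STL/PLY/OBJ surface (triangulated mesh or bare point cloud)."""
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"surface file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply", "obj"):
        raise MeshIOError(f"unsupported surface format: {fmt}")
    loaded = trimesh.load(str(path), file_type=fmt, process=False)
    if isinstance(loaded, trimesh.points.PointCloud):
        pts = np.asarray(loaded.vertices, dtype=float)
        tris = None
    elif isinstance(loaded, trimesh.Trimesh):
        pts = np.asarray(loaded.vertices, dtype=float)
        tris = np.asarray(loaded.faces, dtype=np.intp)
        if tris.size == 0:
            tris = None
    else:
        raise MeshIOError(f"{path}: unsupported surface contents")
    if len(pts) == 0:
        raise MeshIOError(f"{path}: empty surface")
    return SurfaceScan(points=pts, triangles=tris)


def write_surface(scan: SurfaceScan, path: str | Path, format: str | None = None) -> None:
    """Write a surface scan as STL (triangles required) or PLY/OBJ."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if scan.triangles is None:
        if fmt == "stl":
            raise MeshIOError("STL requires triangles")
        trimesh.points.PointCloud(scan.points).export(str(path), file_type=fmt)
    else:
        trimesh.Trimesh(
            vertices=scan.points, faces=scan.triangles, process=False
        ).export(str(path), file_type=fmt)


# ---------------------------------------------------------------------------
# ROI cropping and rigid-node tagging
# ---------------------------------------------------------------------------


def crop_to_roi(mesh: TetMesh, roi: RoiSpec) -> TetMesh:
    """Keep tets whose centroid lies within the ROI sphere; reindex vertices.

    Rigid tags are carried over to the surviving vertices.  Centroid-based
    selection makes the crop a partition: every tet belongs to exactly one
    side of the sphere.
    """
    centroids = mesh.vertices[mesh.tets].mean(axis=1)
    keep = np.linalg.norm(centroids - np.asarray(roi.center), axis=1) <= roi.radius
    if not keep.any():
        raise MeshIOError("ROI does not contain any tet centroid")
    tets = mesh.tets[keep]
    used = np.unique(tets)
    remap = np.full(mesh.n_vertices, -1, dtype=np.intp)
    remap[used] = np.arange(len(used))
    rigid = remap[np.intersect1d(mesh.rigid_nodes, used)]
    return TetMesh(mesh.vertices[used], remap[tets], rigid)


def tag_rigid_nodes(
    mesh: TetMesh, chest_surface: SurfaceScan, tol: float
) -> TetMesh:
    """Tag nodes within ``tol`` mm of the chest-wall surface as rigid.

    Distance is point-to-triangle when the surface is triangulated, else
    point-to-nearest-scan-point.  Monotone in ``tol`` by construction.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    from .registration import _surface_distance  # deferred: avoids cycle

    dist = _surface_distance(mesh.vertices, chest_surface)
    rigid = np.flatnonzero(dist <= tol + 1e-12)
    if rigid.size == 0:
        raise MeshIOError("no node lies within tol of the chest surface")
    return mesh.with_rigid(rigid)
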