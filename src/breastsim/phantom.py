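"""Synthetic breast phantom: meshes, tumors, and noisy multi-orientation
surface "scans".

The phantom is a hemisphere (the breast, radius 60 mm by default) resting
on a flat plate (the chest wall); plate nodes are pre-tagged rigid, so
the phantom exposes the same free/rigid structure as a patient mesh.  A
study case bundles the supine (scan-configuration) surface, a sitting
surface obtained by rotating gravity 90 degrees about the patient x-axis,
and an intraoperative surface at a given bed inclination, all with
configurable Gaussian scanner noise (default sigma 0.5 mm, typical of
consumer structured-light scanners) - the scan triplet the estimation and
validation pipelines expect.  Everything is reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay

from .fem import DeformationState, GravitySpec, STANDARD_GRAVITY, material_from_young_poisson
from .mesh_io import (
    SurfaceScan,
    TetMesh,
    _fix_orientation,
    boundary_faces,
    tet_volumes,
)
from .solver import SolverSettings, bed_angles_to_gravity, simulate_configuration

__all__ = ["PhantomSpec", "StudyCase", "make_phantom", "make_scan", "make_study_case"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, resolution and noise parameters of the phantom."""

    breast_radius: float = 60.0       # mm
    plate_half_width: float = 80.0    # mm
    plate_thickness: float = 10.0     # mm
    target_tet_count: int = 2000
    tumor_offset: tuple[float, float, float] = (0.0, 0.0, -15.0)  # from apex, mm
    noise_sigma: float = 0.5          # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.breast_radius <= 0:
            raise ValueError("breast_radius must be positive")
        if self.target_tet_count < 50:
            raise ValueError("target_tet_count must be >= 50")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def tumor_position(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.breast_radius]) + np.asarray(
            self.tumor_offset, dtype=float
        )


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------


def _sample_points(spec: PhantomSpec, h: float, rng: np.random.Generator) -> np.ndarray:
    R, hw, th = spec.breast_radius, spec.plate_half_width, spec.plate_thickness
    xs = np.linspace(-hw, hw, max(int(round(2 * hw / h)), 2) + 1)
    z_plate = np.linspace(-th, 0.0, max(int(round(th / h)), 1) + 1)
    z_dome = np.arange(h, R, h)

    pts = []
    # plate block (grid incl. all boundary planes)
    gx, gy, gz = np.meshgrid(xs, xs, z_plate, indexing="ij")
    pts.append(np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))
    # dome interior: grid points strictly inside the hemisphere, jittered
    if len(z_dome):
        gx, gy, gz = np.meshgrid(xs, xs, z_dome, indexing="ij")
        g = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        inside = np.linalg.norm(g, axis=1) < R - 0.45 * h
        g = g[inside]
        g += rng.uniform(-0.2 * h, 0.2 * h, g.shape)
        pts.append(g)
    # hemispherical shell: Fibonacci lattice on z > 0
    n_shell = max(int(round(2 * np.pi * R**2 / h**2)), 8)
    i = np.arange(n_shell)
    zf = (i + 0.5) / n_shell  # in (0, 1): upper hemisphere
    phi = np.pi * (1 + 5**0.5) * i
    r_xy = R * np.sqrt(1 - zf**2)
    pts.append(np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), R * zf]))
    # equator ring at z = 0 (junction between dome and plate)
    n_ring = max(int(round(2 * np.pi * R / h)), 8)
    ang = 2 * np.pi * np.arange(n_ring) / n_ring
    pts.append(np.column_stack([R * np.cos(ang), R * np.sin(ang), np.zeros(n_ring)]))
    return np.unique(np.vstack(pts), axis=0)


def _inside_shape(spec: PhantomSpec, p: np.ndarray) -> np.ndarray:
    R, hw, th = spec.breast_radius, spec.plate_half_width, spec.plate_thickness
    in_plate = (
        (np.abs(p[:, 0]) <= hw + 1e-9)
        & (np.abs(p[:, 1]) <= hw + 1e-9)
        & (p[:, 2] <= 1e-9)
        & (p[:, 2] >= -th - 1e-9)
    )
    in_dome = (p[:, 2] > 1e-9) & (np.linalg.norm(p, axis=1) <= R + 1e-9)
    return in_plate | in_dome


def _build_mesh(spec: PhantomSpec, h: float, rng: np.random.Generator) -> TetMesh:
    pts = _sample_points(spec, h, rng)
    tri = Delaunay(pts)
    tets = tri.simplices
    centroids = pts[tets].mean(axis=1)
    keep = _inside_shape(spec, centroids)
    vol = np.abs(tet_volumes(pts, tets))
    keep &= vol > 1e-6 * h**3  # discard slivers on the curved boundary
    tets = tets[keep]
    used = np.unique(tets)
    remap = np.full(len(pts), -1, dtype=np.intp)
    remap[used] = np.arange(len(used))
    verts = pts[used]
    tets = _fix_orientation(verts, remap[tets])
    rigid = np.flatnonzero(verts[:, 2] <= 1e-6)
    return TetMesh(verts, tets, rigid)


def _chest_surface(spec: PhantomSpec, h: float) -> SurfaceScan:
    """Triangulated z = 0 plate-top plane (the chest wall surface)."""
    hw = spec.plate_half_width
    n = max(int(round(2 * hw / h)), 2) + 1
    xs = np.linspace(-hw, hw, n)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = i * n + j, i * n + j + 1, (i + 1) * n + j, (i + 1) * n + j + 1
            tris += [[a, b, d], [a, d, c]]
    return SurfaceScan(points=pts, triangles=np.asarray(tris, dtype=np.intp))


def make_phantom(spec: PhantomSpec) -> tuple[TetMesh, np.ndarray, SurfaceScan]:
    """Generate the phantom mesh, tumor position and chest-wall surface.

    The grid spacing is calibrated so the tet count lands within +-30% of
    ``spec.target_tet_count``.  Generation is deterministic for a fixed
    spec (including its seed).
    """
    tumor = spec.tumor_position
    if np.linalg.norm(tumor) >= spec.breast_radius or tumor[2] <= 0:
        raise ValueError("tumor lies outside the breast hemisphere")
    volume = (2 * spec.plate_half_width) ** 2 * spec.plate_thickness + (
        2.0 / 3.0
    ) * np.pi * spec.breast_radius**3
    h = (6.0 * volume / spec.target_tet_count) ** (1.0 / 3.0)
    mesh = None
    for _ in range(4):
        rng = np.random.default_rng(spec.seed)
        mesh = _build_mesh(spec, h, rng)
        ratio = mesh.n_tets / spec.target_tet_count
        if 0.75 <= ratio <= 1.25:
            break
        h *= ratio ** (1.0 / 3.0)
    return mesh, tumor, _chest_surface(spec, h)


# ---------------------------------------------------------------------------
# Scan synthesis
# ---------------------------------------------------------------------------


def make_scan(
    mesh: TetMesh,
    state: DeformationState,
    noise_sigma: float = 0.5,
    dropout: float = 0.0,
    seed=0,
) -> SurfaceScan:
    """Noisy surface "scan" of the deformed mesh.

    Takes the outward-oriented boundary surface of the tet mesh at the
    given state, perturbs each vertex with isotropic Gaussian noise
    (sigma in mm) and drops a random fraction of points (triangles
    touching a dropped point are removed).
    """
    if not (0.0 <= dropout < 1.0):
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    faces = boundary_faces(mesh.tets)
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.intp)
    remap[used] = np.arange(len(used))
    pts = state.positions_mm[used]
    tris = remap[faces]
    if noise_sigma > 0:
        pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
    if dropout > 0:
        keep = rng.random(len(pts)) >= dropout
        remap2 = np.full(len(pts), -1, dtype=np.intp)
        remap2[keep] = np.arange(int(keep.sum()))
        tris = remap2[tris]
        tris = tris[(tris >= 0).all(axis=1)]
        pts = pts[keep]
    return SurfaceScan(points=pts, triangles=tris if len(tris) else None)


# ---------------------------------------------------------------------------
# Study cases
# ---------------------------------------------------------------------------


def sitting_gravity() -> GravitySpec:
    """Sitting posture: gravity rotated 90 deg about the patient x-axis,
    pointing caudally (-y)."""
    return GravitySpec(g_target=np.array([0.0, -STANDARD_GRAVITY, 0.0]))


@dataclass
class StudyCase:
    """Synthetic analogue of one patient's data: mesh + scan triplet +
    tumor + ground truth."""

    mesh: TetMesh
    tumor: np.ndarray
    scan_supine: SurfaceScan
    scan_sitting: SurfaceScan
    scan_intraop: SurfaceScan
    E_true: float
    ap_deg: float
    lat_deg: float
    spec: PhantomSpec
    seed: int
    states: dict = field(default_factory=dict, repr=False)

    def manifest(self) -> dict:
        return {
            "E_true_pa": self.E_true,
            "ap_deg": self.ap_deg,
            "lat_deg": self.lat_deg,
            "seed": self.seed,
            "tumor_mm": [float(v) for v in self.tumor],
            "n_vertices": self.mesh.n_vertices,
            "n_tets": self.mesh.n_tets,
            "noise_sigma_mm": self.spec.noise_sigma,
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def make_study_case(
    spec: PhantomSpec,
    E_true: float = 800.0,
    ap_deg: float = 7.0,
    lat_deg: float = 5.0,
    seed: int | None = None,
    settings: SolverSettings | None = None,
) -> StudyCase:
    """Generate a full synthetic study case.

    The supine scan images the rest (scan-configuration) surface; the
    sitting scan images the equilibrium under the 90-degree gravity
    rotation; the intraoperative scan images the equilibrium at the given
    bed inclination.  All three carry the spec's scanner noise.
    """
    if not (50.0 <= E_true <= 10_000.0):
        raise ValueError("E_true outside the supported [0.05, 10] kPa range")
    seed = spec.seed if seed is None else seed
    mesh, tumor, _ = make_phantom(spec)
    mat = material_from_young_poisson(E_true)
    rest = DeformationState.rest(mesh)
    sit_state, rep_sit = simulate_configuration(mesh, mat, sitting_gravity(), settings)
    if not rep_sit.converged:
        raise RuntimeError(f"sitting solve failed at E_true = {E_true} Pa")
    intra_state, rep_int = simulate_configuration(
        mesh, mat, bed_angles_to_gravity(ap_deg, lat_deg), settings
    )
    if not rep_int.converged:
        raise RuntimeError(f"intraoperative solve failed at E_true = {E_true} Pa")
    ss = np.random.SeedSequence(seed)
    s_sup, s_sit, s_int = ss.spawn(3)
    sigma = spec.noise_sigma
    return StudyCase(
        mesh=mesh,
        tumor=tumor,
        scan_supine=make_scan(mesh, rest, sigma, seed=s_sup),
        scan_sitting=make_scan(mesh, sit_state, sigma, seed=s_sit),
        scan_intraop=make_scan(mesh, intra_state, sigma, seed=s_int),
        E_true=E_true,
        ap_deg=ap_deg,
        lat_deg=lat_deg,
        spec=spec,
        seed=seed,
        states={"rest": rest, "sitting": sit_state, "intraop": intra_state},
    )
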