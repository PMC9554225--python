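"""Scan transfer, rigid registration, error metrics, and E estimation.

The elastic deformation computed on the volume mesh is transferred to a
surface scan by embedding each scan point barycentrically in its host
tetrahedron (the transfer operator T).  The transformed scan is rigidly
registered to the target scan with point-to-point ICP (closed-form
orthogonal fitting per iteration), and the residual drives a bounded
one-dimensional search for the patient-specific Young modulus:

    E* = argmin_E  | register( T(S_supine, x(E)) ) - S_target |^2

with the simulated configuration x(E) solved per candidate E.  Rigid
(not non-rigid) registration is essential here: a non-rigid step would
absorb the very deformation being fitted.

All surface quantities are in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .fem import DeformationState, GravitySpec, Material, material_from_young_poisson
from .mesh_io import MM_PER_M, SurfaceScan, TetMesh
from .solver import SolverSettings, simulate_configuration

__all__ = [
    "SurfaceEmbedding",
    "RigidTransform",
    "ErrorReport",
    "embed_surface",
    "embed_points",
    "transform_scan",
    "rigid_register",
    "signed_distance",
    "tumor_roi",
    "estimate_young",
    "E_INIT_PA",
]

log = logging.getLogger("breastsim.registration")

# literature-average breast soft-tissue stiffness used to initialise the
# estimation: C1 = 0.105 kPa at nu = 0.45  =>  E = 0.609 kPa
E_INIT_PA = 609.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceEmbedding:
    """Barycentric coordinates of scan points inside host tets (operator T)."""

    host_tet: np.ndarray     # (p,) tet index per scan point
    barycentric: np.ndarray  # (p, 4), rows sum to 1
    triangles: np.ndarray | None = None  # carried over from the source scan


@dataclass
class RigidTransform:
    """Proper rigid map p -> R p + t (t in mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if np.abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(p) = R_s (R_o p + t_o) + t_s."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class ErrorReport:
    """Per-point signed distances (mm) with summary statistics."""

    per_point_signed_distance: np.ndarray
    mean_abs: float
    max_abs: float
    rms: float
    roi_mask: np.ndarray

    @classmethod
    def from_distances(
        cls, sd: np.ndarray, roi_mask: np.ndarray | None = None
    ) -> "ErrorReport":
        sd = np.asarray(sd, dtype=float)
        if roi_mask is None:
            roi_mask = np.ones(len(sd), dtype=bool)
        a = np.abs(sd)
        return cls(sd, float(a.mean()), float(a.max()), float(np.sqrt((sd**2).mean())), roi_mask)

    def restricted(self, mask: np.ndarray) -> "ErrorReport":
        """Summary over a point subset (e.g. the tumor-proximal ROI)."""
        return ErrorReport.from_distances(
            self.per_point_signed_distance[mask], np.ones(int(mask.sum()), bool)
        )

    def to_csv(self, path) -> None:
        lines = ["point,signed_distance_mm,in_roi"]
        lines += [
            f"{i},{d:.6f},{int(m)}"
            for i, (d, m) in enumerate(
                zip(self.per_point_signed_distance, self.roi_mask)
            )
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def summary(self) -> dict:
        roi = self.restricted(self.roi_mask) if self.roi_mask.any() else self
        return {
            "mean_abs_mm": self.mean_abs,
            "max_abs_mm": self.max_abs,
            "rms_mm": self.rms,
            "roi_mean_abs_mm": roi.mean_abs,
            "roi_max_abs_mm": roi.max_abs,
            "roi_rms_mm": roi.rms,
        }


# ---------------------------------------------------------------------------
# Barycentric embedding (operator T)
# ---------------------------------------------------------------------------


def _barycentric(points: np.ndarray, tet_verts: np.ndarray) -> np.ndarray:
    """Barycentric coords of points[i] w.r.t. tet_verts[i] (p,4,3) -> (p,4)."""
    T = np.swapaxes(tet_verts[:, 1:] - tet_verts[:, :1], 1, 2)
    rhs = points - tet_verts[:, 0]
    lam = np.linalg.solve(T, rhs[..., None])[..., 0]
    return np.concatenate([1.0 - lam.sum(axis=1, keepdims=True), lam], axis=1)


def embed_points(
    points_mm: np.ndarray, mesh: TetMesh, snap_distance: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Host tet and barycentric coordinates for each query point.

    Points inside a tet get exact coordinates; outside points snap to the
    best nearby tet with coordinates clamped to the simplex.  A point whose
    snapped image lies farther than ``snap_distance`` mm is rejected.
    """
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    centroids = mesh.vertices[mesh.tets].mean(axis=1)
    tree = cKDTree(centroids)
    k = min(48, mesh.n_tets)
    _, cand = tree.query(points_mm, k=k)
    cand = np.atleast_2d(cand)
    p = len(points_mm)
    host = np.full(p, -1, dtype=np.intp)
    bary = np.zeros((p, 4))
    best_err = np.full(p, np.inf)
    for j in range(cand.shape[1]):
        tid = cand[:, j]
        tv = mesh.vertices[mesh.tets[tid]]
        lam = _barycentric(points_mm, tv)
        inside = lam.min(axis=1) >= -1e-9
        newly = inside & (best_err > 0)
        host[newly] = tid[newly]
        bary[newly] = lam[newly]
        best_err[newly] = 0.0
        # snapped candidate for outside points: clamp + renormalise
        lam_c = np.clip(lam, 0.0, None)
        lam_c /= lam_c.sum(axis=1, keepdims=True)
        rec = np.einsum("pa,pax->px", lam_c, tv)
        err = np.linalg.norm(rec - points_mm, axis=1)
        better = (~inside) & (err < best_err)
        host[better] = tid[better]
        bary[better] = lam_c[better]
        best_err[better] = err[better]
    if np.any(best_err > snap_distance):
        i = int(np.argmax(best_err))
        raise ValueError(
            f"scan point {i} lies {best_err[i]:.2f} mm from the mesh "
            f"(snap distance {snap_distance} mm)"
        )
    return host, bary


def embed_surface(
    scan: SurfaceScan, mesh: TetMesh, snap_distance: float = 5.0
) -> SurfaceEmbedding:
    """Embed every scan point in the rest-configuration mesh."""
    host, bary = embed_points(scan.points, mesh, snap_distance)
    return SurfaceEmbedding(host, bary, scan.triangles)


def transform_scan(
    embedding: SurfaceEmbedding, mesh: TetMesh, deformed: DeformationState
) -> SurfaceScan:
    """Map embedded scan points through the volumetric deformation (mm)."""
    pos_mm = deformed.positions * MM_PER_M
    if len(pos_mm) != mesh.n_vertices:
        raise ValueError("deformed state does not match the mesh")
    tv = pos_mm[mesh.tets[embedding.host_tet]]
    pts = np.einsum("pa,pax->px", embedding.barycentric, tv)
    return SurfaceScan(points=pts, triangles=embedding.triangles)


# ---------------------------------------------------------------------------
# Rigid registration (ICP with Kabsch fitting)
# ---------------------------------------------------------------------------


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping src onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cd - R @ cs)


def rigid_register(
    source: SurfaceScan,
    target: SurfaceScan,
    max_iters: int = 50,
    rms_change_tol: float = 1e-6,
) -> tuple[RigidTransform, float]:
    """Point-to-point ICP of source onto target.

    Returns the cumulative rigid transform and the final RMS of
    nearest-neighbour distances (mm).  RMS is non-increasing across
    iterations; orthonormality is restored in closed form each step.
    """
    if source.n_points < 3 or target.n_points < 3:
        raise ValueError("registration needs at least 3 points on each side")
    tree = cKDTree(target.points)
    cur = source.points.copy()
    total = RigidTransform()
    prev_rms = np.inf
    rms = np.inf
    for _ in range(max_iters):
        d, idx = tree.query(cur)
        rms = float(np.sqrt((d**2).mean()))
        if prev_rms - rms < rms_change_tol:
            break
        prev_rms = rms
        step = _kabsch(cur, target.points[idx])
        cur = step.apply(cur)
        total = step.compose(total)
    d, _ = tree.query(cur)
    rms = float(np.sqrt((d**2).mean()))
    return total, rms


# ---------------------------------------------------------------------------
# Signed distance to a triangulated reference surface
# ---------------------------------------------------------------------------


def _closest_on_triangles(p: np.ndarray, a, b, c):
    """Closest points of p[i] on triangle (a,b,c)[i] plus barycentric coords.

    Vectorised version of the standard region-based point/triangle test.
    """
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    u = np.zeros(len(p))
    v = np.zeros(len(p))
    w = np.zeros(len(p))
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, uu, vv, ww):
        m = mask & ~done
        u[m], v[m], w[m] = (
            np.broadcast_to(uu, u.shape)[m] if np.ndim(uu) else uu,
            np.broadcast_to(vv, v.shape)[m] if np.ndim(vv) else vv,
            np.broadcast_to(ww, w.shape)[m] if np.ndim(ww) else ww,
        )
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), 1.0, 0.0, 0.0)                       # vertex a
    settle((d3 >= 0) & (d4 <= d3), 0.0, 1.0, 0.0)                      # vertex b
    settle((d6 >= 0) & (d5 <= d6), 0.0, 0.0, 1.0)                      # vertex c
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), 1.0 - t_ab, t_ab, 0.0)   # edge ab
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), 1.0 - t_ac, 0.0, t_ac)   # edge ac
        den = (d4 - d3) + (d5 - d6)
        t_bc = np.where(den != 0, (d4 - d3) / den, 0.0)
        settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), 0.0, 1.0 - t_bc, t_bc)
        denom = va + vb + vc
        vv = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        ww = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    settle(np.ones(len(p), dtype=bool), 1.0 - vv - ww, vv, ww)         # interior
    closest = u[:, None] * a + v[:, None] * b + w[:, None] * c
    return closest, np.stack([u, v, w], axis=1)


class _TriangleField:
    """Nearest-feature queries with angle-weighted pseudo-normals."""

    def __init__(self, scan: SurfaceScan):
        if scan.triangles is None:
            raise ValueError("reference surface must carry triangles")
        self.V = scan.points
        self.T = scan.triangles
        a, b, c = (self.V[self.T[:, i]] for i in range(3))
        fn = np.cross(b - a, c - a)
        norms = np.linalg.norm(fn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self.face_normals = fn / norms
        # angle-weighted vertex pseudo-normals
        vn = np.zeros_like(self.V)
        for i in range(3):
            e1 = self.V[self.T[:, (i + 1) % 3]] - self.V[self.T[:, i]]
            e2 = self.V[self.T[:, (i + 2) % 3]] - self.V[self.T[:, i]]
            cosang = np.einsum("ij,ij->i", e1, e2) / (
                np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(vn, self.T[:, i], ang[:, None] * self.face_normals)
        ln = np.linalg.norm(vn, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        self.vertex_normals = vn / ln
        # edge pseudo-normals: sum of the (<=2) adjacent face normals
        edges = np.sort(
            self.T[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1
        )
        self.edge_keys, inv = np.unique(edges, axis=0, return_inverse=True)
        en = np.zeros((len(self.edge_keys), 3))
        np.add.at(en, inv, np.repeat(self.face_normals, 3, axis=0))
        ln = np.linalg.norm(en, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        self.edge_normals = en / ln
        self._edge_index = {tuple(e): i for i, e in enumerate(self.edge_keys)}
        self.centroid_tree = cKDTree((a + b + c) / 3.0)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(closest points, signed distances) for query points (mm)."""
        points = np.atleast_2d(points)
        k = min(24, len(self.T))
        _, cand = self.centroid_tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        best_d = np.full(len(points), np.inf)
        best_cp = np.zeros_like(points)
        best_tri = np.zeros(len(points), dtype=np.intp)
        best_bary = np.zeros((len(points), 3))
        for j in range(cand.shape[1]):
            tid = cand[:, j]
            tri = self.T[tid]
            cp, bary = _closest_on_triangles(
                points, self.V[tri[:, 0]], self.V[tri[:, 1]], self.V[tri[:, 2]]
            )
            d = np.linalg.norm(points - cp, axis=1)
            better = d < best_d
            best_d[better] = d[better]
            best_cp[better] = cp[better]
            best_tri[better] = tid[better]
            best_bary[better] = bary[better]
        signs = self._signs(points, best_cp, best_tri, best_bary)
        return best_cp, signs * best_d

    def _signs(self, points, cp, tri_idx, bary) -> np.ndarray:
        eps = 1e-9
        normals = np.empty_like(points)
        tri = self.T[tri_idx]
        on_vertex = (bary > 1.0 - eps).any(axis=1)
        on_edge = (~on_vertex) & (bary < eps).any(axis=1)
        interior = ~(on_vertex | on_edge)
        normals[interior] = self.face_normals[tri_idx[interior]]
        if on_vertex.any():
            vi = tri[on_vertex, np.argmax(bary[on_vertex], axis=1)]
            normals[on_vertex] = self.vertex_normals[vi]
        for i in np.flatnonzero(on_edge):
            zero = int(np.argmin(bary[i]))
            pair = tuple(sorted((tri[i, (zero + 1) % 3], tri[i, (zero + 2) % 3])))
            normals[i] = self.edge_normals[self._edge_index[pair]]
        dots = np.einsum("ij,ij->i", points - cp, normals)
        return np.where(dots >= 0, 1.0, -1.0)


def signed_distance(points: SurfaceScan, reference: SurfaceScan) -> ErrorReport:
    """Signed distance of each point to a triangulated reference surface.

    Positive outside (along the angle-weighted pseudo-normal of the
    nearest feature), negative inside.  Inverting the reference's
    triangle orientation flips every sign.
    """
    field_ = _TriangleField(reference)
    _, sd = field_.query(points.points)
    return ErrorReport.from_distances(sd)


def _surface_distance(points_mm: np.ndarray, surface: SurfaceScan) -> np.ndarray:
    """Unsigned distance from points to a scan (triangles if available)."""
    if surface.triangles is not None:
        field_ = _TriangleField(surface)
        _, sd = field_.query(points_mm)
        return np.abs(sd)
    tree = cKDTree(surface.points)
    d, _ = tree.query(points_mm)
    return d


# ---------------------------------------------------------------------------
# Tumor-proximal ROI
# ---------------------------------------------------------------------------


def tumor_roi(
    tumor_mm: np.ndarray, surface: SurfaceScan, radius: float = 20.0
) -> np.ndarray:
    """Mask of surface points within ``radius`` of the skin point nearest
    the tumor (default 20 mm, a 2-cm tumor-proximal patch)."""
    if radius <= 0:
        raise ValueError("ROI radius must be positive")
    if surface.n_points == 0:
        raise ValueError("empty surface")
    pts = surface.points
    anchor = pts[np.argmin(np.linalg.norm(pts - np.asarray(tumor_mm), axis=1))]
    mask = np.linalg.norm(pts - anchor, axis=1) <= radius
    if not mask.any():  # radius -> 0 limit: keep the anchor itself
        mask = np.linalg.norm(pts - anchor, axis=1) <= 1e-12
    return mask


# ---------------------------------------------------------------------------
# Young-modulus estimation
# ---------------------------------------------------------------------------


def estimate_young(
    mesh: TetMesh,
    scan_ref: SurfaceScan,
    scan_target: SurfaceScan,
    grav_target: GravitySpec,
    bounds_pa: tuple[float, float] = (50.0, 10_000.0),
    settings: SolverSettings | None = None,
    nu: float = 0.45,
    density: float = 1000.0,
    log_tol: float = 1e-3,
) -> tuple[float, list[tuple[float, float]]]:
    """Estimate the homogeneous Young modulus from a scan pair.

    For each candidate E the pipeline solves the simulated configuration,
    pushes the reference scan through the deformation, rigidly registers
    it to the target scan, and scores the mean squared nearest-neighbour
    distance.  The search is a bounded scalar minimisation over log10(E)
    (absolute tolerance ``log_tol``), reflecting the order-of-magnitude
    spread of breast stiffness in vivo.  Returns (E*, trace of
    (E, objective) evaluations).
    """
    lo, hi = bounds_pa
    if not (0 < lo < hi):
        raise ValueError("invalid bounds")
    settings = settings or SolverSettings()
    embedding = embed_surface(scan_ref, mesh)
    from .fem import build_precomp

    precomp = build_precomp(mesh)
    target_tree = cKDTree(scan_target.points)
    trace: list[tuple[float, float]] = []

    def objective(log_e: float) -> float:
        E = 10.0**log_e
        mat = material_from_young_poisson(E, nu, density)
        state, report = simulate_configuration(
            mesh, mat, grav_target, settings, precomp=precomp
        )
        if not report.converged:
            log.warning("solve did not converge at E = %.1f Pa; rejecting", E)
            trace.append((E, np.inf))
            return 1e12
        moved = transform_scan(embedding, mesh, state)
        transform, _ = rigid_register(moved, scan_target)
        d, _ = target_tree.query(transform.apply(moved.points))
        obj = float((d**2).mean())
        trace.append((E, obj))
        log.debug("E = %.1f Pa -> objective %.4f mm^2", E, obj)
        return obj

    res = minimize_scalar(
        objective,
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": log_tol},
    )
    e_star = float(10.0**res.x)
    if min(abs(res.x - np.log10(lo)), abs(np.log10(hi) - res.x)) < 2 * log_tol:
        log.warning("estimated E = %.1f Pa sits at a search bound", e_star)
    return e_star, trace
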