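"""Real-time navigation: applicator-driven boundary conditions and
tumor tracking.

During intraoperative radiotherapy the rigid applicator is optically
tracked; its pose drives the simulation as a moving Dirichlet boundary
condition.  Mesh nodes captured inside the applicator cylinder at
engagement move rigidly with it (bilateral pinning - a deliberate
simplification of tool-tissue contact), the chest-wall nodes stay fixed,
and each pose update triggers a warm-started quasi-static solve.  The
tumor is a barycentrically embedded material point whose position is
interpolated from the deformed mesh.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .fem import DeformationState, ElementPrecomp, Material, build_precomp
from .mesh_io import MM_PER_M, TetMesh
from .registration import RigidTransform, embed_points
from .solver import SolveReport, SolverError, SolverSettings, solve_equilibrium

__all__ = [
    "Applicator",
    "TumorMarker",
    "engage_applicator",
    "step_navigation",
    "track_tumor",
    "embed_tumor",
    "displacement_report",
    "read_pose_stream",
]

log = logging.getLogger("breastsim.navigation")


@dataclass
class Applicator:
    """Rigid cylindrical IORT applicator.

    The applicator frame has its axis along local +z with the base at the
    origin; ``pose`` maps applicator-frame coordinates to patient-frame
    millimetres.  ``engaged_nodes`` and their applicator-frame
    ``local_coords`` are filled by :func:`engage_applicator`.
    """

    radius: float
    length: float
    pose: RigidTransform
    engaged_nodes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.intp)
    )
    local_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @property
    def engaged(self) -> bool:
        return self.engaged_nodes.size > 0


@dataclass
class TumorMarker:
    """Tumor material point: host tet + barycentric coordinates."""

    host_tet: int
    barycentric: np.ndarray


class EngagementError(RuntimeError):
    pass


def engage_applicator(
    mesh: TetMesh,
    state: DeformationState,
    applicator: Applicator,
    capture_tol: float = 0.5,
) -> Applicator:
    """Capture mesh nodes inside the applicator cylinder.

    Nodes of the *current* state inside the cylinder (inflated by
    ``capture_tol`` mm), excluding chest-wall rigid nodes, become the
    engaged set; their applicator-frame coordinates are stored so later
    poses can reposition them rigidly.
    """
    pos_mm = state.positions * MM_PER_M
    local = applicator.pose.inverse().apply(pos_mm)
    r = np.linalg.norm(local[:, :2], axis=1)
    inside = (
        (r <= applicator.radius + capture_tol)
        & (local[:, 2] >= -capture_tol)
        & (local[:, 2] <= applicator.length + capture_tol)
    )
    inside[mesh.rigid_nodes] = False
    nodes = np.flatnonzero(inside)
    if nodes.size == 0:
        raise EngagementError("applicator does not capture any free node")
    log.info("applicator engaged %d nodes", nodes.size)
    return replace(
        applicator, engaged_nodes=nodes, local_coords=local[nodes].copy()
    )


def _interp_pose(p0: RigidTransform, p1: RigidTransform, t: float) -> RigidTransform:
    from scipy.spatial.transform import Rotation, Slerp

    slerp = Slerp([0.0, 1.0], Rotation.from_matrix([p0.rotation, p1.rotation]))
    return RigidTransform(
        slerp(t).as_matrix(), (1 - t) * p0.translation + t * p1.translation
    )


def step_navigation(
    mesh: TetMesh,
    mat: Material,
    applicator: Applicator,
    new_pose: RigidTransform,
    settings: SolverSettings | None = None,
    state: DeformationState | None = None,
    g_eff: np.ndarray | None = None,
    precomp: ElementPrecomp | None = None,
    _depth: int = 0,
) -> tuple[Applicator, DeformationState, SolveReport]:
    """Advance the simulation to a new applicator pose.

    Engaged nodes are placed at ``new_pose`` applied to their stored
    applicator-frame coordinates; chest-wall nodes stay at their scan
    positions; the solve warm-starts from the previous state.  A pose
    change large enough to invert an element at the boundary is split
    into sub-steps automatically.  On non-convergence the previous state
    is returned unchanged (rolled back) together with the failure report.
    """
    if not applicator.engaged:
        raise EngagementError("applicator is not engaged")
    settings = settings or SolverSettings()
    if precomp is None:
        precomp = build_precomp(mesh)
    if state is None:
        state = DeformationState.rest(mesh)
    g_eff = np.zeros(3) if g_eff is None else np.asarray(g_eff, dtype=float)
    bc_nodes = np.concatenate([mesh.rigid_nodes, applicator.engaged_nodes])
    engaged_mm = new_pose.apply(applicator.local_coords)
    bc_positions = np.vstack(
        [precomp.rest_positions[mesh.rigid_nodes], engaged_mm / MM_PER_M]
    )
    init = state.copy() if settings.warm_start else None
    if init is not None:  # keep the warm start feasible under the new BCs
        init.positions[bc_nodes] = bc_positions
    t0 = time.perf_counter()
    try:
        new_state, report = solve_equilibrium(
            mesh,
            mat,
            g_eff,
            bc_positions=bc_positions,
            settings=settings,
            init=init,
            bc_nodes=bc_nodes,
            precomp=precomp,
        )
    except SolverError as exc:
        if _depth < 6:
            log.debug("subdividing pose step (%s)", exc)
            mid = _interp_pose(applicator.pose, new_pose, 0.5)
            app1, st1, rep1 = step_navigation(
                mesh, mat, applicator, mid, settings, state, g_eff, precomp,
                _depth + 1,
            )
            if rep1.converged:
                app2, st2, rep2 = step_navigation(
                    mesh, mat, app1, new_pose, settings, st1, g_eff, precomp,
                    _depth + 1,
                )
                if rep2.converged:
                    rep2.iterations += rep1.iterations
                    return app2, st2, rep2
        log.warning("navigation step failed (%s); state rolled back", exc)
        return applicator, state, SolveReport(0, np.inf, [], False)
    dt = time.perf_counter() - t0
    log.info(
        "navigation step: %d newton iters, %.1f ms wall",
        report.iterations,
        1e3 * dt,
    )
    if not report.converged:
        return applicator, state, report
    return replace(applicator, pose=new_pose), new_state, report


def embed_tumor(tumor_mm: np.ndarray, mesh: TetMesh) -> TumorMarker:
    """Embed the tumor point (patient mm) as a material marker."""
    host, bary = embed_points(np.asarray(tumor_mm, dtype=float)[None, :], mesh)
    return TumorMarker(int(host[0]), bary[0])


def track_tumor(
    marker: TumorMarker, mesh: TetMesh, state: DeformationState
) -> np.ndarray:
    """Current tumor position (mm) by barycentric interpolation."""
    tv = state.positions[mesh.tets[marker.host_tet]] * MM_PER_M
    return marker.barycentric @ tv


def displacement_report(
    initial: DeformationState, final: DeformationState
) -> np.ndarray:
    """Per-vertex Euclidean distances between two states, mm."""
    if initial.positions.shape != final.positions.shape:
        raise ValueError("states are defined on different meshes")
    return np.linalg.norm(final.positions - initial.positions, axis=1) * MM_PER_M


def read_pose_stream(path: str | Path) -> list[RigidTransform]:
    """Read an applicator pose stream CSV.

    Columns: ``t,x_mm,y_mm,z_mm,qw,qx,qy,qz`` (unit quaternion, scalar
    first).  Returns the poses in stream order.
    """
    poses = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            q = np.array(
                [float(row["qw"]), float(row["qx"]), float(row["qy"]), float(row["qz"])]
            )
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
                ]
            )
            t = np.array([float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])])
            poses.append(RigidTransform(R, t))
    return poses
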