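"""Quasi-static equilibrium solver and gravity-protocol helpers.

Equilibrium is the minimiser of the total potential (elastic + gravity)
over the free nodal positions, with the chest-wall (and, during
navigation, applicator-engaged) nodes held as Dirichlet boundary
conditions.  The minimisation uses Newton's method with a Jacobi-
preconditioned conjugate-gradient linear solver, per-element PSD
projection of the Hessian, and Armijo backtracking on the energy.

The scan geometry (supine) is treated as the stress-free reference;
simulating a torso orientation applies the *difference* between the
target gravity and the supine reference gravity.  This reproduces the
"negative gravity, then rotated gravity" protocol in a single solve,
since the gravity potential is linear in g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .fem import (
    STANDARD_GRAVITY,
    DeformationState,
    ElementPrecomp,
    GravitySpec,
    Material,
    assemble_gradient,
    assemble_hessian,
    assemble_total_energy,
    build_precomp,
)
from .mesh_io import TetMesh

__all__ = [
    "SolverSettings",
    "SolveReport",
    "SolverError",
    "solve_equilibrium",
    "bed_angles_to_gravity",
    "simulate_configuration",
]

log = logging.getLogger("breastsim.solver")


class SolverError(RuntimeError):
    pass


@dataclass
class SolverSettings:
    """Newton / line-search / CG tolerances.

    ``grad_tol`` is a force norm in Newtons; when None it defaults to
    1e-6 * rho * 9.81 * V_total, i.e. one part in a million of the total
    gravity load on the mesh, which makes convergence scale-free.
    """

    grad_tol: float | None = None
    max_newton_iters: int = 100
    cg_rel_tol: float = 1e-8
    backtrack_factor: float = 0.5
    max_halvings: int = 20
    armijo_c: float = 1e-4
    warm_start: bool = True
    n_ramp_steps: int = 5  # load-continuation fallback on hard solves

    def __post_init__(self) -> None:
        if self.grad_tol is not None and self.grad_tol <= 0:
            raise ValueError("grad_tol must be positive")
        if self.max_newton_iters < 1:
            raise ValueError("max_newton_iters must be >= 1")
        if not (0.0 < self.backtrack_factor < 1.0):
            raise ValueError("backtracking factor must lie in (0, 1)")

    def resolved_grad_tol(self, mat: Material, total_volume: float) -> float:
        if self.grad_tol is not None:
            return self.grad_tol
        return 1e-6 * mat.density * STANDARD_GRAVITY * total_volume


@dataclass
class SolveReport:
    iterations: int
    final_gradient_norm: float
    energy_trace: list[float] = field(default_factory=list)
    converged: bool = False


# ---------------------------------------------------------------------------
# Core Newton solve with Dirichlet elimination
# ---------------------------------------------------------------------------


def _newton(
    precomp: ElementPrecomp,
    mat: Material,
    g_eff: np.ndarray,
    x: np.ndarray,
    free_dofs: np.ndarray,
    grad_tol: float,
    settings: SolverSettings,
) -> tuple[np.ndarray, SolveReport]:
    state = DeformationState(x)
    energy = assemble_total_energy(precomp, state, mat, g_eff)
    if not np.isfinite(energy):
        raise SolverError("infeasible initial state (inverted element)")
    trace = [energy]
    n_iter = 0
    gnorm = np.inf
    for n_iter in range(1, settings.max_newton_iters + 1):
        grad = assemble_gradient(precomp, state, mat, g_eff).ravel()[free_dofs]
        gnorm = np.linalg.norm(grad)
        if gnorm <= grad_tol:
            return x, SolveReport(n_iter - 1, gnorm, trace, True)
        H = assemble_hessian(precomp, state, mat, project_psd=True)
        Hff = H[free_dofs][:, free_dofs].tocsr()
        diag = Hff.diagonal()
        diag = np.where(diag > 0, diag, 1.0)
        M = spla.LinearOperator(Hff.shape, matvec=lambda v: v / diag)
        d, info = spla.cg(
            Hff,
            -grad,
            rtol=settings.cg_rel_tol,
            maxiter=10 * len(grad),
            M=M,
        )
        if info != 0 or not np.all(np.isfinite(d)) or d @ grad >= 0:
            d = -grad / max(np.max(diag), 1.0)  # safeguarded descent step
        # Armijo backtracking on the energy
        slope = float(d @ grad)
        alpha = 1.0
        accepted = False
        for _ in range(settings.max_halvings + 1):
            x_new = x.copy()
            x_new.ravel()[free_dofs] += alpha * d
            e_new = assemble_total_energy(
                precomp, DeformationState(x_new), mat, g_eff
            )
            if e_new <= energy + settings.armijo_c * alpha * slope:
                accepted = True
                break
            alpha *= settings.backtrack_factor
        if not accepted:
            log.debug("line search stalled at iter %d (|g|=%.3e)", n_iter, gnorm)
            return x, SolveReport(n_iter, gnorm, trace, gnorm <= grad_tol)
        x = x_new
        state = DeformationState(x)
        energy = e_new
        trace.append(energy)
        log.debug("newton iter %d: energy %.6e, |g| %.3e", n_iter, energy, gnorm)
    grad = assemble_gradient(precomp, state, mat, g_eff).ravel()[free_dofs]
    gnorm = np.linalg.norm(grad)
    return x, SolveReport(settings.max_newton_iters, gnorm, trace, gnorm <= grad_tol)


def solve_equilibrium(
    mesh: TetMesh,
    mat: Material,
    g_eff: np.ndarray,
    bc_positions: np.ndarray | None = None,
    settings: SolverSettings | None = None,
    init: DeformationState | None = None,
    bc_nodes: np.ndarray | None = None,
    precomp: ElementPrecomp | None = None,
) -> tuple[DeformationState, SolveReport]:
    """Minimise the total potential over free nodes under Dirichlet BCs.

    Parameters
    ----------
    g_eff : effective gravity vector (m/s^2) applied to the reference mesh.
    bc_positions : (k, 3) metres — prescribed positions of ``bc_nodes``
        (default: the mesh's rigid nodes at their rest/scan positions).
    bc_nodes : node indices held fixed; defaults to ``mesh.rigid_nodes``.
    init : warm-start state (default: rest configuration).

    The boundary nodes are eliminated from the unknowns, so they satisfy
    their prescribed positions exactly.  If the direct Newton solve fails
    to converge, the load is ramped in ``settings.n_ramp_steps`` equal
    increments (quasi-static continuation).
    """
    settings = settings or SolverSettings()
    if precomp is None:
        precomp = build_precomp(mesh)
    bc_nodes = mesh.rigid_nodes if bc_nodes is None else np.asarray(bc_nodes, dtype=np.intp)
    if bc_nodes.size == 0:
        raise SolverError("mesh has no boundary (rigid) nodes")
    if bc_nodes.size >= mesh.n_vertices:
        raise SolverError("mesh has no free nodes")
    x = (init.positions if init is not None else precomp.rest_positions).copy()
    if bc_positions is not None:
        bc_positions = np.asarray(bc_positions, dtype=float)
        if bc_positions.shape != (len(bc_nodes), 3):
            raise SolverError("bc_positions must be (len(bc_nodes), 3)")
        x[bc_nodes] = bc_positions
    free_mask = np.ones(mesh.n_vertices, dtype=bool)
    free_mask[bc_nodes] = False
    free_dofs = np.flatnonzero(np.repeat(free_mask, 3))
    g_eff = np.asarray(g_eff, dtype=float)
    grad_tol = settings.resolved_grad_tol(mat, precomp.total_volume)

    x_out, report = _newton(precomp, mat, g_eff, x, free_dofs, grad_tol, settings)
    if not report.converged and settings.n_ramp_steps > 1:
        log.debug("direct solve failed; ramping load in %d steps", settings.n_ramp_steps)
        x_out = x.copy()
        trace: list[float] = []
        iters = 0
        for frac in np.linspace(1.0 / settings.n_ramp_steps, 1.0, settings.n_ramp_steps):
            x_out, rep = _newton(
                precomp, mat, frac * g_eff, x_out, free_dofs, grad_tol, settings
            )
            trace.extend(rep.energy_trace)
            iters += rep.iterations
        report = SolveReport(iters, rep.final_gradient_norm, trace, rep.converged)
    return DeformationState(x_out), report


# ---------------------------------------------------------------------------
# Gravity protocol
# ---------------------------------------------------------------------------


def bed_angles_to_gravity(ap_deg: float, lat_deg: float) -> GravitySpec:
    """Gravity vector for a surgical-bed inclination (AP, LAT) in degrees.

    AP tilts about the patient x-axis (left-right), LAT about the y-axis
    (caudal-cranial); rotations are applied AP first, then LAT, to the
    supine gravity (0, 0, -9.81).  Both rotations preserve |g| = 9.81.
    """
    for name, a in (("ap", ap_deg), ("lat", lat_deg)):
        if not (-90.0 < a < 90.0):
            raise ValueError(f"{name} angle must lie in (-90, 90) degrees")
    a = np.deg2rad(ap_deg)
    l = np.deg2rad(lat_deg)
    rx = np.array(
        [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
    )
    ry = np.array(
        [[np.cos(l), 0, np.sin(l)], [0, 1, 0], [-np.sin(l), 0, np.cos(l)]]
    )
    g0 = np.array([0.0, 0.0, -STANDARD_GRAVITY])
    return GravitySpec(g_reference=g0, g_target=ry @ rx @ g0,
                       ap_deg=ap_deg, lat_deg=lat_deg)


def simulate_configuration(
    mesh: TetMesh,
    mat: Material,
    grav: GravitySpec,
    settings: SolverSettings | None = None,
    init: DeformationState | None = None,
    precomp: ElementPrecomp | None = None,
) -> tuple[DeformationState, SolveReport]:
    """Deform the scan-configuration mesh to the gravity of ``grav``.

    Solves equilibrium with effective gravity g_target - g_reference and
    the chest-wall nodes pinned at their scan positions.  When target and
    reference gravity coincide the effective load vanishes and the scan
    geometry itself is the solution.
    """
    return solve_equilibrium(
        mesh,
        mat,
        grav.g_effective,
        bc_positions=None,
        settings=settings,
        init=init,
        precomp=precomp,
    )
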