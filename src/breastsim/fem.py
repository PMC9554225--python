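"""Neo-Hookean constitutive model and linear-tet FEM assembly.

The breast soft tissue is modelled as a homogeneous, compressible
Neo-Hookean solid with energy density

    Psi(F) = mu/2 (tr(F^T F) - 3) - mu ln(det F) + lambda/2 (ln det F)^2

on linear tetrahedra with a single quadrature point (constant deformation
gradient F per element).  The gravity potential

    V_grav = -integral_Omega rho g . x dOmega

is lumped equally onto the four nodes of each tet, which is exact for the
linear displacement field of a P1 element.  All quantities in this module
are SI (metres, Pascal, Joule, Newton); conversion from the millimetre
mesh frame happens at the module boundary.

States with det F <= 0 in any element have infinite energy, so the
solver's line search rejects element inversion (the log term of Psi acts
as a barrier).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mesh_io import MM_PER_M, TetMesh

__all__ = [
    "Material",
    "ElementPrecomp",
    "DeformationState",
    "GravitySpec",
    "STANDARD_GRAVITY",
    "material_from_young_poisson",
    "build_precomp",
    "deformation_gradients",
    "deformation_gradient",
    "neohookean_energy_density",
    "neohookean_piola",
    "assemble_total_energy",
    "assemble_gradient",
    "assemble_hessian",
]

STANDARD_GRAVITY = 9.81  # m/s^2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Material:
    """Homogeneous material: Young modulus E (Pa), Poisson ratio nu,
    density rho (kg/m^3), and derived Lame constants mu, lam and c1 = mu/2
    (the stiffness parameter reported in the breast-modelling literature)."""

    young_modulus: float
    poisson_ratio: float
    density: float
    mu: float
    lam: float
    c1: float


def material_from_young_poisson(
    E: float, nu: float = 0.45, rho: float = 1000.0
) -> Material:
    """Build a :class:`Material` from (E, nu, rho).

    mu = E / (2 (1 + nu)),  lam = E nu / ((1 + nu)(1 - 2 nu)),  c1 = mu / 2.

    nu defaults to 0.45 (nearly incompressible soft tissue) and rho to
    1000 kg/m^3, the density of water.
    """
    if E <= 0:
        raise ValueError("Young modulus must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    if rho <= 0:
        raise ValueError("density must be positive")
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return Material(E, nu, rho, mu, lam, mu / 2.0)


@dataclass
class ElementPrecomp:
    """Per-element rest-shape data: inverse edge matrix Dm^-1 and rest
    volume (m^3), plus cached assembly index maps."""

    dm_inv: np.ndarray          # (m, 3, 3)
    rest_volume: np.ndarray     # (m,)
    rest_positions: np.ndarray  # (n, 3) metres
    tets: np.ndarray            # (m, 4)
    lumped_volume: np.ndarray   # (n,) nodal volume shares, m^3
    _hess_rows: np.ndarray = field(default=None, repr=False)
    _hess_cols: np.ndarray = field(default=None, repr=False)

    @property
    def total_volume(self) -> float:
        return float(self.rest_volume.sum())


def build_precomp(mesh: TetMesh) -> ElementPrecomp:
    """Precompute rest-shape inverses and volumes (converting mm -> m)."""
    x0 = mesh.vertices / MM_PER_M
    v = x0[mesh.tets]
    dm = np.swapaxes(v[:, 1:] - v[:, :1], 1, 2)  # columns are edge vectors
    vol = np.linalg.det(dm) / 6.0
    if np.any(vol <= 0):
        raise ValueError("mesh contains non-positively-oriented tets")
    lumped = np.zeros(mesh.n_vertices)
    np.add.at(lumped, mesh.tets.ravel(), np.repeat(vol / 4.0, 4))
    # global dof indices of the 12x12 element hessian blocks
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(len(mesh.tets), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    return ElementPrecomp(
        np.linalg.inv(dm), vol, x0, mesh.tets.copy(), lumped, rows, cols
    )


@dataclass
class DeformationState:
    """Current nodal positions x in metres (one row per mesh vertex)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @classmethod
    def rest(cls, mesh: TetMesh) -> "DeformationState":
        return cls(mesh.vertices / MM_PER_M)

    @property
    def positions_mm(self) -> np.ndarray:
        return self.positions * MM_PER_M

    def copy(self) -> "DeformationState":
        return DeformationState(self.positions.copy())


@dataclass
class GravitySpec:
    """Reference (scan) and target gravity vectors, m/s^2.

    The scan is acquired supine with gravity ``g_reference`` (default
    (0, 0, -9.81) in the patient frame); ``g_target`` is the gravity of
    the configuration to simulate.  The solver applies the *difference*,
    treating the gravity-loaded scan geometry as stress-free.
    """

    g_reference: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -STANDARD_GRAVITY])
    )
    g_target: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -STANDARD_GRAVITY])
    )
    ap_deg: float = 0.0
    lat_deg: float = 0.0

    def __post_init__(self) -> None:
        self.g_reference = np.asarray(self.g_reference, dtype=float)
        self.g_target = np.asarray(self.g_target, dtype=float)

    @property
    def g_effective(self) -> np.ndarray:
        """Gravity actually applied to the scan-initialised mesh."""
        return self.g_target - self.g_reference


# ---------------------------------------------------------------------------
# Kinematics and constitutive law
# ---------------------------------------------------------------------------


def deformation_gradients(
    precomp: ElementPrecomp, state: DeformationState
) -> np.ndarray:
    """All per-element deformation gradients F = Ds Dm^-1, shape (m, 3, 3)."""
    v = state.positions[precomp.tets]
    ds = np.swapaxes(v[:, 1:] - v[:, :1], 1, 2)
    return ds @ precomp.dm_inv


def deformation_gradient(
    element: int, state: DeformationState, precomp: ElementPrecomp
) -> np.ndarray:
    """Deformation gradient of one element (F = I at rest)."""
    v = state.positions[precomp.tets[element]]
    ds = (v[1:] - v[:1]).T
    return ds @ precomp.dm_inv[element]


def neohookean_energy_density(F: np.ndarray, mat: Material) -> float:
    """Psi(F) in Pa; +inf when det F <= 0 (inverted element)."""
    J = np.linalg.det(F)
    if J <= 0:
        return np.inf
    logJ = np.log(J)
    return (
        0.5 * mat.mu * (np.trace(F.T @ F) - 3.0)
        - mat.mu * logJ
        + 0.5 * mat.lam * logJ**2
    )


def neohookean_piola(F: np.ndarray, mat: Material) -> np.ndarray:
    """First Piola-Kirchhoff stress P = mu (F - F^-T) + lam ln(J) F^-T."""
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("det F must be positive")
    Finv_T = np.linalg.inv(F).T
    return mat.mu * (F - Finv_T) + mat.lam * np.log(J) * Finv_T


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _psi_batch(F: np.ndarray, mat: Material) -> np.ndarray:
    J = np.linalg.det(F)
    if np.any(J <= 0):
        return None
    logJ = np.log(J)
    tr = np.einsum("eij,eij->e", F, F)
    return 0.5 * mat.mu * (tr - 3.0) - mat.mu * logJ + 0.5 * mat.lam * logJ**2


def assemble_total_energy(
    precomp: ElementPrecomp,
    state: DeformationState,
    mat: Material,
    g_eff: np.ndarray,
) -> float:
    """Total potential (J): sum_e V_e Psi(F_e) + V_grav(g_eff).

    Returns +inf for infeasible (element-inverting) states.
    """
    F = deformation_gradients(precomp, state)
    psi = _psi_batch(F, mat)
    if psi is None:
        return np.inf
    elastic = float(precomp.rest_volume @ psi)
    grav = -mat.density * float(
        precomp.lumped_volume @ (state.positions @ np.asarray(g_eff))
    )
    return elastic + grav


def assemble_gradient(
    precomp: ElementPrecomp,
    state: DeformationState,
    mat: Material,
    g_eff: np.ndarray,
) -> np.ndarray:
    """Gradient of the total potential w.r.t. nodal positions, (n, 3), N.

    The negative of this is the nodal force residual; the gravity force on
    node i is rho * g_eff * (sum of V_e/4 over incident elements).
    """
    F = deformation_gradients(precomp, state)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("infeasible state: inverted element")
    Finv_T = np.linalg.inv(np.swapaxes(F, 1, 2))
    logJ = np.log(J)
    P = mat.mu * (F - Finv_T) + mat.lam * logJ[:, None, None] * Finv_T
    # dPsi/dx: element force matrix G = V_e * P * Dm^-T, columns = nodes 1..3
    G = precomp.rest_volume[:, None, None] * (
        P @ np.swapaxes(precomp.dm_inv, 1, 2)
    )
    grad = np.zeros_like(state.positions)
    np.add.at(grad, precomp.tets[:, 1:].ravel(),
              np.swapaxes(G, 1, 2).reshape(-1, 3))
    np.add.at(grad, precomp.tets[:, 0], -G.sum(axis=2))
    grad -= mat.density * precomp.lumped_volume[:, None] * np.asarray(g_eff)
    return grad


def _element_hessians(
    precomp: ElementPrecomp,
    state: DeformationState,
    mat: Material,
    project_psd: bool,
) -> np.ndarray:
    """Dense 12x12 elastic Hessian blocks, optionally eigenvalue-clamped."""
    F = deformation_gradients(precomp, state)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("infeasible state: inverted element")
    G = np.linalg.inv(np.swapaxes(F, 1, 2))  # F^-T, (m,3,3)
    logJ = np.log(J)
    dm_inv = precomp.dm_inv
    # w: (m, 4, 3) nodal shape-gradient weights; row a gives dF_ij/dx_{a,i}
    w = np.empty((len(J), 4, 3))
    w[:, 1:, :] = dm_inv
    w[:, 0, :] = -dm_inv.sum(axis=1)
    S = np.einsum("eaj,ebj->eab", w, w)                 # (m,4,4)
    M = np.einsum("eaj,ekj->eak", w, G)                 # (m,4,3)
    mu, lam = mat.mu, mat.lam
    coef = mu - lam * logJ
    eye3 = np.eye(3)
    H = (
        mu * np.einsum("eab,kl->eakbl", S, eye3)
        + coef[:, None, None, None, None] * np.einsum("eal,ebk->eakbl", M, M)
        + lam * np.einsum("eak,ebl->eakbl", M, M)
    ).reshape(-1, 12, 12)
    H *= precomp.rest_volume[:, None, None]
    if project_psd:
        evals, evecs = np.linalg.eigh(H)
        floor = 1e-12 * mu
        evals = np.where(evals < 0.0, floor, evals)
        H = np.einsum("eik,ek,ejk->eij", evecs, evals, evecs)
    return H


def assemble_hessian(
    precomp: ElementPrecomp,
    state: DeformationState,
    mat: Material,
    project_psd: bool = False,
) -> sp.csr_matrix:
    """Sparse symmetric (3n, 3n) Hessian of the total potential.

    Gravity is linear in x so only the elastic part contributes.  With
    ``project_psd`` each element block has its negative eigenvalues clamped
    to 1e-12*mu, guaranteeing a positive semi-definite global operator.
    """
    He = _element_hessians(precomp, state, mat, project_psd)
    n = 3 * len(state.positions)
    Hg = sp.coo_matrix(
        (He.ravel(), (precomp._hess_rows, precomp._hess_cols)), shape=(n, n)
    ).tocsr()
    return Hg
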