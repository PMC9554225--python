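"""Constitutive model, kinematics, and assembly correctness.

Expected values are either hand-evaluated from the closed-form energy or
checked against central finite differences of the assembled quantities.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breastsim import (
    DeformationState,
    assemble_gradient,
    assemble_hessian,
    assemble_total_energy,
    build_precomp,
    deformation_gradient,
    material_from_young_poisson,
    neohookean_energy_density,
    neohookean_piola,
)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_feasible_F(rng, scale=0.3):
    F = np.eye(3) + scale * rng.normal(size=(3, 3))
    if np.linalg.det(F) <= 0.05:
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
    return F


class TestMaterial:
    def test_literature_average_stiffness(self):
        # E = 0.609 kPa at nu = 0.45 corresponds to mu = 210 Pa, C1 = 0.105 kPa
        mat = material_from_young_poisson(609.0, 0.45)
        assert mat.mu == pytest.approx(210.0, rel=1e-12)
        assert mat.c1 == pytest.approx(105.0, rel=1e-12)
        # lam = E nu / ((1+nu)(1-2nu)) = 609*0.45 / (1.45*0.10) = 1890
        assert mat.lam == pytest.approx(1890.0, rel=1e-12)

    def test_zero_poisson_limit(self):
        mat = material_from_young_poisson(100.0, 0.0)
        assert mat.lam == 0.0
        assert mat.mu == pytest.approx(50.0)

    @pytest.mark.parametrize("E,nu", [(0.0, 0.3), (-5.0, 0.3), (100.0, 0.5), (100.0, 0.6)])
    def test_invalid_parameters(self, E, nu):
        with pytest.raises(ValueError):
            material_from_young_poisson(E, nu)

    @given(
        E=st.floats(1.0, 1e6),
        nu=st.floats(0.0, 0.499),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_lame_consistency(self, E, nu):
        mat = material_from_young_poisson(E, nu)
        assert mat.mu == pytest.approx(E / (2 * (1 + nu)), rel=1e-12)
        assert mat.lam == pytest.approx(E * nu / ((1 + nu) * (1 - 2 * nu)), rel=1e-12)
        assert mat.c1 == pytest.approx(mat.mu / 2, rel=1e-12)


class TestDeformationGradient:
    def test_rest_state_is_identity(self, blob_mesh):
        pre = build_precomp(blob_mesh)
        rest = DeformationState.rest(blob_mesh)
        for e in range(blob_mesh.n_tets):
            assert np.allclose(deformation_gradient(e, rest, pre), np.eye(3), atol=1e-12)

    def test_uniform_scaling(self, blob_mesh):
        pre = build_precomp(blob_mesh)
        rest = DeformationState.rest(blob_mesh)
        scaled = DeformationState(2.0 * (rest.positions - 0.01) + 0.01)
        F = deformation_gradient(0, scaled, pre)
        assert np.allclose(F, 2.0 * np.eye(3), atol=1e-12)

    def test_random_affine_map_recovered(self, blob_mesh):
        rng = np.random.default_rng(5)
        A = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        pre = build_precomp(blob_mesh)
        rest = DeformationState.rest(blob_mesh)
        mapped = DeformationState(rest.positions @ A.T + rng.normal(size=3) * 1e-3)
        for e in range(blob_mesh.n_tets):
            assert np.allclose(deformation_gradient(e, mapped, pre), A, atol=1e-12)


class TestNeoHookean:
    def test_identity_and_rotations_have_zero_energy(self, soft_tissue):
        assert neohookean_energy_density(np.eye(3), soft_tissue) == 0.0
        rng = np.random.default_rng(2)
        for _ in range(20):
            R = random_rotation(rng)
            assert abs(neohookean_energy_density(R, soft_tissue)) < 1e-10
            assert np.allclose(neohookean_piola(R, soft_tissue), 0.0, atol=1e-9)

    def test_hand_evaluated_stretch(self):
        # mu = 1, lam = 0, F = diag(2,1,1):  0.5*(6-3) - ln 2
        from breastsim.fem import Material

        mat = Material(1.0, 0.0, 1000.0, 1.0, 0.0, 0.5)
        val = neohookean_energy_density(np.diag([2.0, 1.0, 1.0]), mat)
        assert val == pytest.approx(1.5 - np.log(2.0), rel=1e-12)

    def test_energy_nonnegative_on_feasible_states(self, soft_tissue):
        rng = np.random.default_rng(3)
        for _ in range(100):
            F = random_feasible_F(rng)
            assert neohookean_energy_density(F, soft_tissue) >= -1e-12

    def test_frame_invariance(self, soft_tissue):
        rng = np.random.default_rng(4)
        for _ in range(30):
            F = random_feasible_F(rng)
            R = random_rotation(rng)
            assert neohookean_energy_density(R @ F, soft_tissue) == pytest.approx(
                neohookean_energy_density(F, soft_tissue), abs=1e-10, rel=1e-10
            )

    def test_inverted_state_is_infeasible(self, soft_tissue):
        F = np.diag([-1.0, 1.0, 1.0])
        assert neohookean_energy_density(F, soft_tissue) == np.inf
        with pytest.raises(ValueError):
            neohookean_piola(F, soft_tissue)

    def test_piola_matches_finite_differences(self, soft_tissue):
        rng = np.random.default_rng(6)
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        P = neohookean_piola(F, soft_tissue)
        h = 1e-6
        fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                fd[i, j] = (
                    neohookean_energy_density(Fp, soft_tissue)
                    - neohookean_energy_density(Fm, soft_tissue)
                ) / (2 * h)
        assert np.allclose(P, fd, rtol=1e-5, atol=1e-8 * np.abs(fd).max())


class TestAssembly:
    def test_rest_energy_zero_without_gravity(self, blob_mesh, soft_tissue):
        pre = build_precomp(blob_mesh)
        rest = DeformationState.rest(blob_mesh)
        assert assemble_total_energy(pre, rest, soft_tissue, np.zeros(3)) == pytest.approx(0.0, abs=1e-15)
        assert np.allclose(
            assemble_gradient(pre, rest, soft_tissue, np.zeros(3)), 0.0, atol=1e-12
        )

    def test_single_tet_gravity_energy(self, unit_tet_mesh, soft_tissue):
        # V_grav = +rho * V * g * mean height for g = (0,0,-g)
        pre = build_precomp(unit_tet_mesh)
        rest = DeformationState.rest(unit_tet_mesh)
        g = np.array([0.0, 0.0, -9.81])
        e = assemble_total_energy(pre, rest, soft_tissue, g)
        V = 1.0 / 6.0  # m^3
        zbar = 0.25  # m, mean nodal height of this tet
        assert e == pytest.approx(soft_tissue.density * V * 9.81 * zbar, rel=1e-12)

    def test_translation_invariance_of_elastic_energy(self, blob_mesh, soft_tissue, perturbed_state):
        pre = build_precomp(blob_mesh)
        e0 = assemble_total_energy(pre, perturbed_state, soft_tissue, np.zeros(3))
        shifted = DeformationState(perturbed_state.positions + np.array([0.3, -0.1, 0.2]))
        e1 = assemble_total_energy(pre, shifted, soft_tissue, np.zeros(3))
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_gradient_matches_finite_differences(self, blob_mesh, soft_tissue, perturbed_state):
        pre = build_precomp(blob_mesh)
        g = np.array([0.0, 0.0, -9.81])
        grad = assemble_gradient(pre, perturbed_state, soft_tissue, g)
        x = perturbed_state.positions
        h = 1e-7
        fd = np.zeros_like(grad)
        for i in range(len(x)):
            for k in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, k] += h
                xm[i, k] -= h
                fd[i, k] = (
                    assemble_total_energy(pre, DeformationState(xp), soft_tissue, g)
                    - assemble_total_energy(pre, DeformationState(xm), soft_tissue, g)
                ) / (2 * h)
        assert np.linalg.norm(fd - grad) / np.linalg.norm(fd) < 1e-5

    def test_total_gravity_force_conserves_volume(self, blob_mesh, soft_tissue, perturbed_state):
        pre = build_precomp(blob_mesh)
        g = np.array([0.1, -0.4, -9.81])
        with_g = assemble_gradient(pre, perturbed_state, soft_tissue, g)
        without = assemble_gradient(pre, perturbed_state, soft_tissue, np.zeros(3))
        total_force = -(with_g - without).sum(axis=0)
        assert np.allclose(
            total_force, soft_tissue.density * g * pre.total_volume, rtol=1e-12
        )

    def test_hessian_symmetry_and_fd(self, blob_mesh, soft_tissue, perturbed_state):
        pre = build_precomp(blob_mesh)
        g = np.array([0.0, 0.0, -9.81])
        H = assemble_hessian(pre, perturbed_state, soft_tissue).toarray()
        assert np.abs(H - H.T).max() < 1e-12 * max(np.abs(H).max(), 1.0)
        x = perturbed_state.positions
        h = 1e-7
        fd = np.zeros_like(H)
        for i in range(len(x)):
            for k in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, k] += h
                xm[i, k] -= h
                gp = assemble_gradient(pre, DeformationState(xp), soft_tissue, g)
                gm = assemble_gradient(pre, DeformationState(xm), soft_tissue, g)
                fd[3 * i + k] = ((gp - gm) / (2 * h)).ravel()
        assert np.abs(fd - H).max() / np.abs(fd).max() < 1e-4

    def test_psd_projection(self, blob_mesh, soft_tissue):
        # squash the blob to create an indefinite raw Hessian
        pre = build_precomp(blob_mesh)
        rest = DeformationState.rest(blob_mesh)
        squashed = DeformationState(rest.positions * np.array([1.0, 1.0, 0.35]))
        Hp = assemble_hessian(pre, squashed, soft_tissue, project_psd=True).toarray()
        free = np.setdiff1d(np.arange(blob_mesh.n_vertices), blob_mesh.rigid_nodes)
        idx = (3 * free[:, None] + np.arange(3)).ravel()
        evals = np.linalg.eigvalsh(Hp[np.ix_(idx, idx)])
        assert evals.min() >= -1e-10 * np.abs(evals).max()

    def test_inverted_state_rejected(self, blob_mesh, soft_tissue):
        rest = DeformationState.rest(blob_mesh)
        pre = build_precomp(blob_mesh)
        inverted = DeformationState(rest.positions * np.array([1.0, 1.0, -1.0]))
        assert assemble_total_energy(pre, inverted, soft_tissue, np.zeros(3)) == np.inf
        with pytest.raises(ValueError):
            assemble_gradient(pre, inverted, soft_tissue, np.zeros(3))
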