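"""Growth-decomposed neo-Hookean mechanics and the quasi-static solve."""

import numpy as np
import pytest

from conftest import make_block, make_column
from ossiforge.config import SolverConfig
from ossiforge.grid import BackgroundGrid
from ossiforge.mechanics import (first_pk_stress, lame_from_moduli,
                                 solve_equilibrium, strain_energy_density,
                                 update_points)


def test_lame_conversion():
    lam, mu = lame_from_moduli(1.0, 0.4)
    assert lam == pytest.approx(1.0 * 0.4 / (1.4 * 0.2))
    assert mu == pytest.approx(1.0 / 2.8)


class TestStrainEnergy:
    LAME = lame_from_moduli(np.array(1.0), np.array(0.4))

    def test_zero_at_rest(self):
        assert strain_energy_density(np.eye(3), np.eye(3), self.LAME) == 0.0
        # elastically relaxed grown state: F = Fg, any Fg
        Fg = np.diag([1.3, 1.1, 2.0])
        assert strain_energy_density(Fg, Fg, self.LAME) == pytest.approx(0.0)

    def test_uniaxial_stretch_value(self):
        # Fe = diag(2,1,1): I1 = 6, I3 = 4; value frozen from the closed form
        psi = strain_energy_density(np.diag([2.0, 1.0, 1.0]), np.eye(3),
                                    self.LAME)
        assert psi == pytest.approx(0.6313424454558778, rel=1e-12)

    def test_linear_in_growth_jacobian(self):
        F_e = np.diag([2.0, 1.0, 1.0])
        psi1 = strain_energy_density(F_e, np.eye(3), self.LAME)
        # same elastic state with Fg = 2I (Jg = 8): F = Fe·Fg
        psi8 = strain_energy_density(F_e @ (2 * np.eye(3)), 2 * np.eye(3),
                                     self.LAME)
        assert psi8 == pytest.approx(8 * psi1, rel=1e-12)

    def test_singular_growth_raises(self):
        with pytest.raises(ValueError):
            strain_energy_density(np.eye(3), np.diag([1.0, 1.0, 0.0]),
                                  self.LAME)

    def test_stress_vanishes_at_rest(self):
        lam = np.array([1.42857]); mu = np.array([0.35714])
        Fg = np.diag([1.2, 1.2, 1.2])
        P = first_pk_stress(Fg[None], Fg[None], lam, mu)
        np.testing.assert_allclose(P, 0.0, atol=1e-12)

    def test_stress_is_energy_gradient(self):
        rng = np.random.default_rng(0)
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        Fg = np.eye(3) * 1.1
        lam = np.array([1.4]); mu = np.array([0.36])
        P = first_pk_stress(F[None], Fg[None], lam, mu)[0]
        num = np.zeros((3, 3))
        eps = 1e-6
        for i in range(3):
            for j in range(3):
                dF = np.zeros((3, 3)); dF[i, j] = eps
                num[i, j] = (strain_energy_density(F + dF, Fg, (lam, mu))
                             - strain_energy_density(F - dF, Fg, (lam, mu))
                             )[0] / (2 * eps)
        np.testing.assert_allclose(P, num, rtol=1e-5, atol=1e-8)


class TestEquilibrium:
    def test_rest_state_gives_zero_displacement(self, block):
        grid = BackgroundGrid.covering(block.x, 50.0)
        res = solve_equilibrium(block, grid, SolverConfig())
        assert res.converged
        np.testing.assert_allclose(grid.u, 0.0, atol=1e-12)

    def test_uniform_growth_relaxes_stress_free(self):
        block = make_block(4, 10.0)
        block.Fg = np.broadcast_to(1.1 * np.eye(3), (block.n, 3, 3)).copy()
        grid = BackgroundGrid.covering(block.x, 50.0)
        solve_equilibrium(block, grid, SolverConfig())
        update_points(block, grid)
        Fe = block.F @ np.linalg.inv(block.Fg)
        Ce = np.swapaxes(Fe, -1, -2) @ Fe
        assert np.abs(Ce - np.eye(3)).max() < 0.01

    def test_column_tip_displacement_matches_compatibility(self):
        # uniform axial growth θ against the z=0 slip plane: tip moves by
        # (θ-1)·L where L is the tip's initial height
        col = make_column(6, 10.0)
        theta = 1.2
        Fg = np.eye(3); Fg[2, 2] = theta
        col.Fg = np.broadcast_to(Fg, (col.n, 3, 3)).copy()
        grid = BackgroundGrid.covering(col.x, 25.0)
        solve_equilibrium(col, grid, SolverConfig())
        u_tip = grid.interpolate_displacement(col.x[-1:])[0, 2]
        assert u_tip == pytest.approx((theta - 1) * col.x[-1, 2], rel=0.01)


class TestUpdatePoints:
    def test_zero_displacement_is_identity(self, block):
        grid = BackgroundGrid.covering(block.x, 50.0)
        x0, F0, V0 = block.x.copy(), block.F.copy(), block.V.copy()
        update_points(block, grid)
        np.testing.assert_array_equal(block.x, x0)
        np.testing.assert_array_equal(block.F, F0)
        np.testing.assert_array_equal(block.V, V0)

    def test_rigid_translation_preserves_F_and_V(self, block):
        grid = BackgroundGrid.covering(block.x, 50.0)
        grid.u[:] = [5.0, -3.0, 2.0]
        x0, F0, V0 = block.x.copy(), block.F.copy(), block.V.copy()
        update_points(block, grid)
        np.testing.assert_allclose(block.x, x0 + [5.0, -3.0, 2.0],
                                   atol=1e-10)
        np.testing.assert_allclose(block.F, F0, atol=1e-12)
        np.testing.assert_allclose(block.V, V0, rtol=1e-12)

    def test_uniform_dilation_scales_volume(self, block):
        grid = BackgroundGrid.covering(block.x, 50.0)
        grid.u = 0.1 * grid.node_coords     # ∇u = 0.1 I
        V0 = block.V.copy()
        update_points(block, grid)
        np.testing.assert_allclose(block.V, V0 * 1.1 ** 3, rtol=1e-9)

    def test_total_volume_unchanged_by_interpolation_alone(self, block):
        # growth-free equilibrium + update must conserve ΣV exactly
        grid = BackgroundGrid.covering(block.x, 50.0)
        solve_equilibrium(block, grid, SolverConfig())
        V0 = block.V.sum()
        update_points(block, grid)
        assert block.V.sum() == pytest.approx(V0, rel=1e-12)
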