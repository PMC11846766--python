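"""Production schedules and reaction–diffusion transport."""

import numpy as np
import pytest

from ossiforge.config import SECONDS_PER_DAY, SignalingParams
from ossiforge.signaling import (ChemicalField, ihh_production,
                                 pthrp_production_periarticular,
                                 pthrp_production_resting)

PARAMS = SignalingParams()


class TestIhhProduction:
    def test_hat_schedule_pointwise(self):
        # rises to the max over prehypertrophy, back to zero by mid-hypertrophy
        assert ihh_production(0.0, PARAMS) == 0.0
        assert ihh_production(0.5, PARAMS) == pytest.approx(1.0, rel=1e-12)
        assert ihh_production(0.75, PARAMS) == pytest.approx(0.5, rel=1e-12)
        assert ihh_production(1.0, PARAMS) == pytest.approx(0.0, abs=1e-12)
        assert ihh_production(3.0, PARAMS) == 0.0

    def test_vectorized(self):
        t = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(ihh_production(t, PARAMS),
                                   [0.0, 0.5, 1.0, 0.5, 0.0], atol=1e-12)


class TestPTHrPProduction:
    def test_periarticular_linear_in_total(self):
        assert pthrp_production_periarticular(0.0, PARAMS) == 0.0
        assert pthrp_production_periarticular(1.5e6, PARAMS) == \
            pytest.approx(1.0, rel=1e-12)
        assert pthrp_production_periarticular(7.5e5, PARAMS) == \
            pytest.approx(0.5, rel=1e-12)

    def test_resting_ramp(self):
        assert pthrp_production_resting(1.5e6, 0.0, PARAMS) == 0.0
        assert pthrp_production_resting(1.5e6, 0.25, PARAMS) == \
            pytest.approx(0.5, rel=1e-12)

    def test_resting_saturates_at_periarticular_level(self):
        for t in (0.5, 0.6, 10.0):
            assert pthrp_production_resting(9.9e5, t, PARAMS) == \
                pytest.approx(pthrp_production_periarticular(9.9e5, PARAMS),
                              rel=1e-12)

    def test_continuity_at_maturation(self):
        eps = 1e-9
        below = pthrp_production_resting(1.2e6, PARAMS.T_mat_days - eps,
                                         PARAMS)
        above = pthrp_production_resting(1.2e6, PARAMS.T_mat_days + eps,
                                         PARAMS)
        assert below == pytest.approx(above, abs=1e-6)

    def test_before_onset_raises(self):
        with pytest.raises(ValueError):
            pthrp_production_resting(1.0e6, -0.1, PARAMS)


def _field_1d(n=40, h=50.0, D=86400.0, k=432.0, **kw):
    return ChemicalField((0,), (n,), h, D, k, symmetry_axes=(True,), **kw)


class TestTotals:
    def test_zero_field(self):
        f = _field_1d()
        assert f.total("ihh") == 0.0

    def test_uniform_concentration(self):
        f = _field_1d(cross_section_um2=100.0)
        f.C_ihh[:] = 3.0
        assert f.total("ihh") == pytest.approx(3.0 * 40 * 50.0 * 100.0)
        assert f.total("ihh", multiplicity=8) == \
            pytest.approx(8 * 3.0 * 40 * 50.0 * 100.0)

    def test_checkerboard(self):
        f = _field_1d()
        f.C_ihh[::2] = 4.0
        assert f.total("ihh") == pytest.approx(4.0 * 20 * f.node_volume)


class TestReactionDiffusion:
    def test_steady_state_is_production_over_degradation(self):
        # uniform source, homogeneous interior: C* = P/k = 200 exactly
        # (fixed point of the implicit update, independent of D)
        k_day = 0.005 * SECONDS_PER_DAY
        f = ChemicalField((0,), (30,), 50.0, 86400.0, k_day)
        src = np.full(30, 1.0)               # pM/μm³·s
        f.C_ihh[:] = 200.0                   # start at the analytic C*
        interior = np.arange(0, 20)          # away from the far Dirichlet end
        f.step(0.02, src_ihh=src)
        np.testing.assert_allclose(f.C_ihh[interior], 200.0, rtol=1e-10)

    def test_exponential_decay_rate(self):
        # sources off: total decays at rate k (D=0 isolates the reaction)
        k_day = 0.005 * SECONDS_PER_DAY
        f = ChemicalField((0,), (20,), 50.0, 0.0, k_day)
        f.C_ihh[:] = 1.0
        dt = 200.0 / SECONDS_PER_DAY / 100   # 100 substeps over 200 s
        for _ in range(100):
            f.step(dt)
        assert f.C_ihh[5] == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_screening_length(self):
        # steady point source: e-fold distance matches sqrt(D/k) ≈ 14.14 μm
        h = 2.0
        f = ChemicalField((0,), (200,), h, 86400.0, 432.0,
                          symmetry_axes=(True,))
        src = np.zeros(200); src[0] = 1.0
        for _ in range(300):
            f.step(0.01, src_ihh=src)
        z = np.arange(200) * h
        sel = (z > 10) & (z < 60) & (f.C_ihh > 0)
        slope = np.polyfit(z[sel], np.log(f.C_ihh[sel]), 1)[0]
        ell = -1.0 / slope
        assert ell == pytest.approx(np.sqrt(1.0 / 0.005), rel=0.05)

    def test_diffusion_matches_gaussian_kernel(self):
        # pure diffusion of a narrow pulse ≈ Gaussian with σ² = 2Dt
        h, n = 5.0, 240
        f = ChemicalField((-n // 2,), (n,), h, 86400.0, 0.0,
                          symmetry_axes=(False,))
        z = f.node_coords[:, 0]
        sigma0 = 12.0
        f.C_ihh = np.exp(-z ** 2 / (2 * sigma0 ** 2))
        t = 0.002   # days; σ grows to sqrt(σ0² + 2Dt) ≈ 22.6 μm
        nstep = 400
        for _ in range(nstep):
            f.step(t / nstep, scheme="explicit")
        sig2 = sigma0 ** 2 + 2 * 86400.0 * t
        expect = sigma0 / np.sqrt(sig2) * np.exp(-z ** 2 / (2 * sig2))
        err = np.linalg.norm(f.C_ihh - expect) / np.linalg.norm(expect)
        assert err < 0.01

    def test_mass_conserved_without_reaction(self):
        h, n = 10.0, 120
        f = ChemicalField((-n // 2,), (n,), h, 86400.0, 0.0,
                          symmetry_axes=(False,))
        z = f.node_coords[:, 0]
        f.C_ihh = np.exp(-z ** 2 / (2 * 30.0 ** 2))
        m0 = f.total("ihh")
        for _ in range(20):
            f.step(0.0005)
        assert f.total("ihh") == pytest.approx(m0, rel=1e-10)

    def test_non_negativity_preserved(self):
        f = _field_1d()
        f.C_ihh[::3] = 5.0
        for _ in range(50):
            f.step(0.02)
            assert np.all(f.C_ihh >= 0.0)

    def test_explicit_stability_bound_enforced(self):
        f = _field_1d()
        with pytest.raises(ValueError):
            f.step(1.0, scheme="explicit")

    def test_explicit_implicit_agree_at_steady_state(self):
        k_day = 432.0
        fe = ChemicalField((0,), (25,), 50.0, 86400.0, k_day)
        fi = ChemicalField((0,), (25,), 50.0, 86400.0, k_day)
        src = np.zeros(25); src[3:6] = 0.7
        dt = 50.0 / 86400.0
        for _ in range(2000):
            fe.step(dt, src_ihh=src, scheme="explicit")
        for _ in range(2000):
            fi.step(dt, src_ihh=src, scheme="implicit")
        np.testing.assert_allclose(fe.C_ihh, fi.C_ihh, rtol=1e-6, atol=1e-9)


class TestExchange:
    def test_point_at_node_center_gets_full_mass(self):
        f = _field_1d(cross_section_um2=100.0)
        src = f.deposit(np.array([[100.0]]), np.array([500.0]))
        assert src.sum() * f.node_volume == pytest.approx(500.0)
        assert src[2] == pytest.approx(0.75 * 500.0 / f.node_volume)

    def test_zero_production_zero_sources(self):
        f = _field_1d()
        src = f.deposit(np.array([[100.0], [230.0]]), np.zeros(2))
        np.testing.assert_array_equal(src, 0.0)

    def test_symmetric_producers_mirror_symmetric_sources(self):
        f = ChemicalField((-10,), (21,), 50.0, 86400.0, 432.0,
                          symmetry_axes=(False,))
        src = f.deposit(np.array([[-130.0], [130.0]]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(src, src[::-1], atol=1e-15)
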