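"""Threshold differentiation, terminal fates and property transitions."""

import numpy as np
import pytest

from ossiforge.config import (FateThresholds, PropertySchedule,
                              SignalingParams)
from ossiforge.fate import (EmptyRestingZoneWarning, define_resting_zone,
                            initiate_poc, initiate_soc,
                            transition_properties, update_fate)
from ossiforge.points import CellType, ParticleState

TH = FateThresholds()
SIG = SignalingParams()
SCHED = PropertySchedule()


def _cells(n, kind, z=None):
    x = np.zeros((n, 3))
    x[:, 2] = np.arange(n) * 10.0 if z is None else z
    p = ParticleState(x, 1000.0)
    p.cell_type[:] = kind
    return p


def _step(p, rng=None, dt=0.02):
    update_fate(p, dt, TH, SIG, SCHED,
                rng or np.random.default_rng(0))


class TestThresholds:
    def test_quiescent_to_proliferative(self):
        p = _cells(2, CellType.QUIESCENT)
        p.C_ihh[:] = [1.5, 0.9]
        _step(p)
        assert p.cell_type[0] == CellType.PROLIFERATIVE
        assert p.cell_type[1] == CellType.QUIESCENT

    def test_pthrp_gate_blocks_prehypertrophy(self):
        p = _cells(2, CellType.PROLIFERATIVE)
        p.C_ihh[:] = 31.0
        p.C_pthrp[:] = [0.6, 0.4]
        _step(p)
        assert p.cell_type[0] == CellType.PROLIFERATIVE
        assert p.cell_type[1] == CellType.PREHYPERTROPHIC
        assert p.t_H[1] == 0.0

    def test_strict_comparisons_at_threshold(self):
        p = _cells(3, CellType.QUIESCENT)
        p.C_ihh[:] = [1.0, 1.0 + 1e-9, 1.0 - 1e-9]
        _step(p)
        assert p.cell_type[0] == CellType.QUIESCENT      # strictly greater
        assert p.cell_type[1] == CellType.PROLIFERATIVE
        assert p.cell_type[2] == CellType.QUIESCENT

    def test_timed_hypertrophy(self):
        p = _cells(1, CellType.PREHYPERTROPHIC)
        p.t_H[:] = SIG.T_prehyp_days - 0.01
        _step(p)  # t_H advances past T_prehyp
        assert p.cell_type[0] == CellType.HYPERTROPHIC

    def test_perichondrium_to_bone_collar(self):
        p = _cells(2, CellType.PERICHONDRIUM)
        p.C_ihh[:] = [10.5, 9.5]
        _step(p)
        assert p.cell_type[0] == CellType.BONE_COLLAR
        assert p.cell_type[1] == CellType.PERICHONDRIUM

    def test_closed_gate_freezes_differentiation(self):
        # the gate requires C_PTHrP strictly below the threshold, so a zero
        # threshold can never be satisfied: no proliferative cell matures
        thresholds = FateThresholds(C_pthrp_prehyp=0.0)
        p = _cells(5, CellType.PROLIFERATIVE)
        p.C_ihh[:] = 1e6
        p.C_pthrp[:] = 0.0
        for _ in range(20):
            update_fate(p, 0.02, thresholds, SIG, SCHED,
                        np.random.default_rng(0))
        assert np.all(p.cell_type == CellType.PROLIFERATIVE)


class TestTerminalFate:
    def test_fifty_fifty_split(self):
        p = _cells(10_000, CellType.HYPERTROPHIC)
        p.t_H[:] = SIG.T_prehyp_days + SIG.T_hyp_days + 0.01
        _step(p, np.random.default_rng(7))
        frac = np.mean(p.cell_type == CellType.MATRIX)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_absorbing_states(self):
        p = _cells(100, CellType.MATRIX)
        p.C_ihh[:] = 1e6
        p.C_pthrp[:] = 0.0
        for _ in range(50):
            _step(p)
        assert np.all(p.cell_type == CellType.MATRIX)


class TestPropertyTransition:
    def test_endpoints_exact(self):
        E, nu = transition_properties(1.0, 0.4, 1000.0, 0.3, 0.0, 1.0)
        assert (E, nu) == (pytest.approx(1.0), pytest.approx(0.4))
        E, nu = transition_properties(1.0, 0.4, 1000.0, 0.3, 1.0, 1.0)
        assert (E, nu) == (pytest.approx(1000.0), pytest.approx(0.3))
        E, nu = transition_properties(1.0, 0.4, 1000.0, 0.3, 5.0, 1.0)
        assert E == pytest.approx(1000.0)    # clamped beyond schedule end

    def test_log_linear_midpoint(self):
        E, nu = transition_properties(1.0, 0.4, 1000.0, 0.3, 0.5, 1.0)
        assert E == pytest.approx(10 ** 1.5, rel=1e-12)   # ≈ 31.62 kPa
        assert nu == pytest.approx(0.35)

    def test_negative_elapsed_raises(self):
        with pytest.raises(ValueError):
            transition_properties(1.0, 0.4, 1000.0, 0.3, -0.1, 1.0)

    def test_matrix_cells_stiffen_in_simulation_sweep(self):
        p = _cells(10, CellType.HYPERTROPHIC)
        p.t_H[:] = SIG.T_prehyp_days + SIG.T_hyp_days + 0.01
        rng = np.random.default_rng(3)
        for _ in range(60):   # 1.2 days: past T_calcif
            _step(p, rng)
        calcified = np.isin(p.cell_type,
                            [CellType.MATRIX, CellType.APOPTOTIC])
        assert np.all(calcified)
        np.testing.assert_allclose(p.E, 1000.0, rtol=1e-9)
        np.testing.assert_allclose(p.nu, 0.3, rtol=1e-9)


class TestOssificationCenters:
    def test_poc_slab_selection_and_idempotence(self):
        p = _cells(20, CellType.QUIESCENT)   # z = 0, 10, ..., 190
        ids = initiate_poc(p, z_center=0.0, thickness=60.0)
        assert set(ids) <= set(range(4))
        before = p.cell_type.copy()
        initiate_poc(p, z_center=0.0, thickness=60.0)
        np.testing.assert_array_equal(p.cell_type, before)

    def test_empty_slab_raises(self):
        p = _cells(5, CellType.QUIESCENT)
        with pytest.raises(ValueError):
            initiate_poc(p, z_center=1e4, thickness=10.0)

    def test_soc_seed(self):
        p = _cells(30, CellType.QUIESCENT)
        ids = initiate_soc(p, center=[0.0, 0.0, 150.0], radius=25.0)
        assert np.all(p.cell_type[ids] == CellType.PREHYPERTROPHIC)
        with pytest.raises(ValueError):
            initiate_soc(p, center=[0.0, 0.0, 150.0], radius=0.0)

    def test_resting_zone_band(self):
        # proliferative band z ∈ [100, 150], SOC seed z ∈ [300, 350]
        p = _cells(40, CellType.QUIESCENT)   # z = 0..390
        z = p.x[:, 2]
        p.cell_type[(z >= 100) & (z <= 150)] = CellType.PROLIFERATIVE
        p.cell_type[(z >= 300) & (z <= 350)] = CellType.PREHYPERTROPHIC
        ids = define_resting_zone(p, 150.0, 300.0)
        assert np.all(p.cell_type[ids] == CellType.RESTING_PTHRP)
        np.testing.assert_array_equal(
            np.sort(p.x[ids, 2]), np.arange(160.0, 300.0, 10.0))

    def test_resting_zone_tags_only_quiescent(self):
        p = _cells(10, CellType.PROLIFERATIVE)
        with pytest.warns(EmptyRestingZoneWarning):
            ids = define_resting_zone(p, 0.0, 100.0)
        assert ids.size == 0
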