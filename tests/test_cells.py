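"""Cell cycle, growth stretches, G0 statistics and division."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_block
from ossiforge.cells import (advance_cycles, apply_growth_tensor,
                             division_direction, sample_g0_duration,
                             split_points)
from ossiforge.config import CycleConfig, SimulationConfig
from ossiforge.points import CellType, GrowthMode, ParticleState
from ossiforge.signaling import ChemicalField


class TestGrowthTensor:
    def test_theta_one_is_identity(self):
        Fg0 = np.diag([1.2, 1.0, 1.5])
        for mode, ns in ((GrowthMode.ISOTROPIC, None),
                         (GrowthMode.UNIDIRECTIONAL, [0.0, 0.0, 1.0])):
            np.testing.assert_allclose(
                apply_growth_tensor(Fg0, 1.0, mode, ns), Fg0)

    def test_isotropic_volume_doubling(self):
        theta = 2.0 ** (1.0 / 3.0)
        Fg = apply_growth_tensor(np.eye(3), theta, GrowthMode.ISOTROPIC)
        assert np.linalg.det(Fg) == pytest.approx(2.0)

    def test_unidirectional_rank_one(self):
        Fg = apply_growth_tensor(np.eye(3), 2.0, GrowthMode.UNIDIRECTIONAL,
                                 [0.0, 0.0, 1.0])
        np.testing.assert_allclose(Fg, np.diag([1.0, 1.0, 2.0]))

    def test_unidirectional_requires_axis(self):
        with pytest.raises(ValueError):
            apply_growth_tensor(np.eye(3), 2.0, GrowthMode.UNIDIRECTIONAL)


class TestG0Sampling:
    def test_closed_form(self):
        assert sample_g0_duration(5.0, 0.0) == 0.0
        assert sample_g0_duration(5.0, 0.5) == pytest.approx(np.log(2) / 5)

    def test_invalid_draw(self):
        with pytest.raises(ValueError):
            sample_g0_duration(5.0, 1.0)

    def test_monte_carlo_mean(self, rng):
        draws = sample_g0_duration(5.0, rng.random(100_000))
        assert draws.mean() == pytest.approx(0.2, rel=0.01)

    def test_exponential_distribution_ks(self, rng):
        draws = sample_g0_duration(5.0, rng.random(10_000))
        res = stats.kstest(draws, "expon", args=(0, 1.0 / 5.0))
        assert res.pvalue > 0.01


def _prolif_pool(n, cycling=True):
    p = ParticleState(np.random.default_rng(0).random((n, 3)) * 100, 1000.0)
    p.cell_type[:] = CellType.PROLIFERATIVE
    p.cycling[:] = cycling
    p.n_s[:] = [0.0, 0.0, 1.0]
    p.has_ns[:] = True
    p.growth_mode[:] = GrowthMode.UNIDIRECTIONAL
    return p


class TestCycle:
    CFG = CycleConfig()

    def test_g0_timer_only_decrements(self, rng):
        p = _prolif_pool(1, cycling=False)
        p.T_G0_left[:] = 0.5
        ids = advance_cycles(p, 0.02, self.CFG, rng)
        assert ids.size == 0
        assert p.T_G0_left[0] == pytest.approx(0.48)
        assert not p.cycling[0]

    def test_division_emitted_at_midcycle(self, rng):
        p = _prolif_pool(1)
        p.t_cycle[:] = 0.49
        ids = advance_cycles(p, 0.02, self.CFG, rng)
        assert list(ids) == [0]
        # crossing is emitted exactly once
        ids = advance_cycles(p, 0.02, self.CFG, rng)
        assert ids.size == 0

    def test_prehypertrophic_in_g0_never_divides(self, rng):
        p = _prolif_pool(1, cycling=False)
        p.cell_type[:] = CellType.PREHYPERTROPHIC
        p.cycle_locked[:] = True
        for _ in range(100):
            assert advance_cycles(p, 0.02, self.CFG, rng).size == 0
        assert not p.cycling[0]

    def test_prehypertrophic_with_inflight_cycle_divides_once(self, rng):
        p = _prolif_pool(1)
        p.cell_type[:] = CellType.PREHYPERTROPHIC  # differentiated in S phase
        p.t_cycle[:] = 0.4
        divisions = 0
        for _ in range(200):
            ids = advance_cycles(p, 0.02, self.CFG, rng)
            if ids.size:
                divisions += 1
                split_points(p, ids, p.n_s[ids], 0.0, self.CFG)
        assert divisions == 1
        assert p.cycle_locked[0]

    def test_population_doubling_time(self, rng):
        # colony of always-cycling proliferative cells doubles every
        # T_cycle + E[T_G0] = 1.2 days
        p = _prolif_pool(400)
        dt, counts, days = 0.02, [], []
        day = 0.0
        while day < 4.8:
            ids = advance_cycles(p, dt, self.CFG, rng)
            if ids.size:
                split_points(p, ids, p.n_s[ids], day, self.CFG)
            day += dt
            days.append(day)
            counts.append(p.n)
        days, counts = np.array(days), np.array(counts)
        t1, t2 = 1.2, 4.8
        n1 = counts[np.searchsorted(days, t1)]
        n2 = counts[-1]
        rate = np.log2(n2 / n1) / (t2 - t1)
        assert rate == pytest.approx(1.0 / 1.2, rel=0.05)


class TestDivisionDirection:
    def _field(self):
        f = ChemicalField((0, 0, 0), (6, 6, 6), 50.0, 86400.0, 432.0)
        return f

    def test_linear_field_gives_axis(self):
        f = self._field()
        f.C_ihh = 2.0 + 0.03 * f.node_coords[:, 2]
        n = division_direction(f, [[60.0, 60.0, 60.0]])
        np.testing.assert_allclose(n[0], [0.0, 0.0, 1.0], atol=1e-9)

    def test_radial_field_points_outward(self):
        f = self._field()
        c = f.node_coords - 125.0
        f.C_ihh = 1e-3 * np.sum(c ** 2, axis=1)   # f(r), f' > 0
        x = np.array([[160.0, 150.0, 170.0]])
        n = division_direction(f, x)
        expect = (x[0] - 125.0) / np.linalg.norm(x[0] - 125.0)
        np.testing.assert_allclose(n[0], expect, atol=1e-6)

    def test_uniform_field_tiebreak_unit(self, rng):
        f = self._field()
        f.C_ihh[:] = 7.0
        n = division_direction(f, [[100.0, 100.0, 100.0]], rng=rng)
        assert np.linalg.norm(n[0]) == pytest.approx(1.0)


class TestSplit:
    def test_volume_halving_and_conservation(self):
        p = _prolif_pool(3)
        V0 = p.V.sum()
        events = split_points(p, [0, 2], np.tile([0.0, 0.0, 1.0], (2, 1)),
                              1.0, CycleConfig())
        assert len(events) == 2
        assert p.n == 5
        assert p.V.sum() == pytest.approx(V0, rel=1e-14)
        assert p.V[0] == pytest.approx(500.0)
        assert p.V[3] == pytest.approx(500.0)   # child of parent 0

    def test_children_positions_symmetric(self):
        p = ParticleState(np.zeros((1, 3)), 1000.0)
        p.cell_type[:] = CellType.PROLIFERATIVE
        split_points(p, [0], [[1.0, 0.0, 0.0]], 0.0, CycleConfig())
        offset = 0.5 * 500.0 ** (1.0 / 3.0)
        np.testing.assert_allclose(p.x[0], [-offset, 0, 0], atol=1e-12)
        np.testing.assert_allclose(p.x[1], [offset, 0, 0], atol=1e-12)

    def test_unset_axis_raises(self):
        p = _prolif_pool(1)
        with pytest.raises(ValueError):
            split_points(p, [0], [[0.0, 0.0, 0.0]], 0.0, CycleConfig())
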