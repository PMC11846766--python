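"""Full capsule simulation: mechanics + signaling + fate per increment.

Main-loop order per Δt = 0.02-day increment (fixed contract):

1. commit growth tensors (θ schedules) for every growing point;
2. quasi-static equilibrium solve on a freshly built background grid;
3. point update (positions, F, volumes; boundary markers advected);
4. chemistry sub-steps (Ihh/PTHrP reaction–diffusion with current sources);
5. per-point field sampling and fate update (differentiation, 50/50
   terminal split, property ramps);
6. cell-cycle advance and division.

Scheduled events: primary ossification at Day 0 (diaphyseal slab set
prehypertrophic), secondary ossification at the configured day (the
future-SOC cluster flagged at Day 0 is activated and the resting zone is
tagged between the proliferative-zone top and the SOC seed).

The ``coarse`` preset (20 μm point spacing) preserves the full physics at
~1/8 the point count for desk-scale experimentation; headline quantitative
claims belong to the full 10 μm resolution.
"""

from __future__ import annotations

import copy
import warnings

import numpy as np

from . import fate as fate_mod
from .cells import advance_cycles, division_direction, split_points
from .cells import update_growth_tensors
from .config import SimulationConfig
from .geometry import (assign_initial_types, build_capsule, soc_center)
from .grid import BackgroundGrid
from .mechanics import solve_equilibrium, update_points
from .metrics import (OutcomeRecord, detect_fusion, detect_penetration,
                      mean_resting_production, zone_metrics)
from .points import CellType, GrowthMode, ParticleState
from .signaling import (ChemicalField, ihh_production,
                        pthrp_production_periarticular,
                        pthrp_production_resting)

__all__ = ["Simulation", "run_simulation"]

_PRESETS = {"full": 10.0, "coarse": 20.0}


class Simulation:
    """Capsule endochondral-ossification simulation (one octant)."""

    def __init__(self, config: SimulationConfig | None = None,
                 preset: str = "coarse"):
        self.cfg = copy.deepcopy(config) if config else SimulationConfig()
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; use full|coarse")
        self.cfg.capsule.spacing_um = _PRESETS[preset]
        # keep per-point volume = spacing³ so points tile the tissue
        self.cfg.capsule.point_volume_um3 = _PRESETS[preset] ** 3
        self.rng = np.random.default_rng(self.cfg.seed)
        self.points, self.boundary = build_capsule(self.cfg.capsule)
        assign_initial_types(self.points, self.cfg.capsule,
                             self.cfg.events.soc_seed_radius_um)
        self.poc_ids = fate_mod.initiate_poc(
            self.points, z_center=0.0,
            thickness=self.cfg.events.poc_slab_thickness_um)
        self.day = 0.0
        self.t_soc = None
        self.soc_ids = np.array([], dtype=int)
        self.resting_ids = np.array([], dtype=int)
        self.metrics = []
        self.census = []
        self.pthrp_series = []
        self.division_log = []
        self.fusion_day = None
        self.penetration_day = None
        self.field = None
        self._rebuild_field()

    # ------------------------------------------------------------------
    def _rebuild_field(self):
        h = self.cfg.grid.h_um
        pad = self.cfg.chem.padding_cells
        hi = np.ceil(self.points.x.max(axis=0) / h).astype(int) + 1 + pad
        old = self.field
        if old is not None and all(int(n) <= s for n, s in
                                   zip(hi, old.shape)):
            return
        field = ChemicalField((0, 0, 0), tuple(int(n) for n in hi), h,
                              self.cfg.chem.D, self.cfg.chem.k,
                              symmetry_axes=(True, True, True))
        if old is not None:
            sl = tuple(slice(0, s) for s in old.shape)
            for name in ("C_ihh", "C_pthrp"):
                new = np.zeros(field.shape)
                new[sl] = getattr(old, name).reshape(old.shape)
                setattr(field, name, new.ravel())
        self.field = field

    def _tissue_mask(self):
        occ = self.field.deposit(self.points.x, self.points.V)
        return occ > 1e-12

    def ihh_total(self) -> float:
        mult = 8 if self.cfg.signaling.ihh_total_scope == "whole_tissue" else 1
        return self.field.total("ihh", mask=self._tissue_mask(),
                                multiplicity=mult)

    # ------------------------------------------------------------------
    def _mechanics(self):
        grid = BackgroundGrid.covering(self.points.x, self.cfg.grid.h_um,
                                       self.cfg.grid.padding_cells)
        solve_equilibrium(self.points, grid, self.cfg.solver)
        # advect boundary markers passively before moving the points
        self.boundary.x = self.boundary.x + grid.interpolate_displacement(
            self.boundary.x)
        update_points(self.points, grid)
        self.grid = grid

    def _chemistry(self, dt):
        p = self.points
        sig = self.cfg.signaling
        prod_ihh = np.zeros(p.n)
        mask = p.types(CellType.PREHYPERTROPHIC, CellType.HYPERTROPHIC)
        prod_ihh[mask] = ihh_production(p.t_H[mask], sig)
        prod_pthrp = np.zeros(p.n)
        total = self.ihh_total()
        peri = p.types(CellType.PERIARTICULAR_PTHRP)
        prod_pthrp[peri] = pthrp_production_periarticular(total, sig)
        if (self.t_soc is not None and self.resting_ids.size
                and self.cfg.events.resting_pthrp_enabled):
            resting = self.resting_ids[
                p.cell_type[self.resting_ids] == CellType.RESTING_PTHRP]
            prod_pthrp[resting] = pthrp_production_resting(total, self.t_soc,
                                                           sig)
        self._last_prod_pthrp = prod_pthrp
        src_i = self.field.deposit(p.x, prod_ihh * p.V)
        src_p = self.field.deposit(p.x, prod_pthrp * p.V)
        sub = dt / self.cfg.chem.substeps
        for _ in range(self.cfg.chem.substeps):
            self.field.step(sub, src_i, src_p, scheme=self.cfg.chem.scheme)
        p.C_ihh = self.field.sample(p.x, "ihh")
        p.C_pthrp = self.field.sample(p.x, "pthrp")

    def _cycle_division(self, dt):
        p = self.points
        ids = advance_cycles(p, dt, self.cfg.cycle, self.rng)
        fresh = (p.cycling
                 & (p.growth_mode == GrowthMode.UNIDIRECTIONAL)
                 & ~p.has_ns)
        if np.any(fresh):
            fi = np.flatnonzero(fresh)
            p.n_s[fi] = division_direction(self.field, p.x[fi],
                                           prev_ns=None, rng=self.rng)
            p.has_ns[fi] = True
        if ids.size:
            n_s = division_direction(self.field, p.x[ids],
                                     prev_ns=p.n_s[ids], rng=self.rng)
            self.division_log.extend(
                split_points(p, ids, n_s, self.day, self.cfg.cycle))

    def _maybe_initiate_soc(self):
        ev = self.cfg.events
        if self.t_soc is not None or self.day < ev.soc_day - 1e-9:
            return
        p = self.points
        seed = np.flatnonzero(p.future_soc)
        if seed.size == 0:
            warnings.warn("no future-SOC cluster flagged; SOC skipped")
            self.t_soc = 0.0
            return
        p.cell_type[seed] = CellType.PREHYPERTROPHIC
        p.t_H[seed] = 0.0
        p.growth_mode[seed] = GrowthMode.NONE
        p.cycle_locked[seed] = True
        self.soc_ids = seed
        self.t_soc = 0.0
        prolif = p.types(CellType.PROLIFERATIVE)
        z_low = p.x[prolif, 2].max() if np.any(prolif) else 0.0
        radial = (np.hypot(p.x[prolif, 0], p.x[prolif, 1]).max()
                  if np.any(prolif) else None)
        z_high = p.x[seed, 2].min()
        if ev.resting_pthrp_enabled:
            self.resting_ids = fate_mod.define_resting_zone(
                p, z_low, z_high, radial_extent=radial)

    # ------------------------------------------------------------------
    def step(self):
        cfg = self.cfg
        dt = cfg.dt_days
        self._maybe_initiate_soc()
        update_growth_tensors(self.points, cfg.cycle, cfg.signaling)
        self._mechanics()
        self._rebuild_field()
        self._chemistry(dt)
        fate_mod.update_fate(self.points, dt, cfg.thresholds, cfg.signaling,
                             cfg.properties, self.rng)
        self._cycle_division(dt)
        self.day += dt
        if self.t_soc is not None:
            self.t_soc += dt
        self._record()

    def _record(self):
        self.metrics.append(zone_metrics(self.points, self.day))
        types, counts = np.unique(self.points.cell_type, return_counts=True)
        self.census.append((self.day,
                            {int(t): int(c) for t, c in zip(types, counts)}))
        if self.t_soc is not None:
            self.pthrp_series.append(
                (self.day,
                 mean_resting_production(self._last_prod_pthrp,
                                         self.resting_ids)))
            if self.fusion_day is None and self.soc_ids.size and detect_fusion(
                    self.points, self.poc_ids, self.soc_ids,
                    self.cfg.grid.h_um):
                self.fusion_day = self.day
            if (self.penetration_day is None and self.resting_ids.size
                    and detect_penetration(self.points, self.resting_ids)):
                self.penetration_day = self.day

    def run(self, until_day: float | None = None) -> "Simulation":
        until = until_day if until_day is not None else self.cfg.events.end_day
        while self.day < until - 1e-9:
            self.step()
        return self

    def outcome(self) -> OutcomeRecord:
        penetrated = (detect_penetration(self.points, self.resting_ids)
                      if self.resting_ids.size else
                      self.penetration_day is not None)
        return OutcomeRecord(
            T_mat=self.cfg.signaling.T_mat_days,
            fused=self.fusion_day is not None,
            fusion_day=self.fusion_day,
            resting_zone_penetrated=penetrated,
            penetration_day=self.penetration_day,
            pthrp_series=self.pthrp_series)


def run_simulation(config: SimulationConfig | None = None,
                   preset: str = "coarse",
                   until_day: float | None = None) -> Simulation:
    """Build and run a capsule simulation; returns the finished driver."""
    sim = Simulation(config, preset=preset)
    sim.run(until_day)
    return sim
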