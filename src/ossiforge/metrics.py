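"""Zone measurements and outcome detection.

Zone extents are axial (z) spans of each cell type; the headline quantity is
the combined proliferative + hypertrophic length of the growth plate.
Growth-plate fusion is formalized as grid connectivity of the calcified
occupancy (matrix ∪ apoptotic voxels) between material descended from the
primary and secondary ossification seeds; penetration of the resting zone is
any differentiating chondrocyte inside the materially tracked axial band
that was tagged as resting at SOC onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .points import (ACTIVE_CHONDROCYTE_TYPES, CALCIFIED_TYPES, CellType,
                     ParticleState)

__all__ = ["ZoneMetrics", "OutcomeRecord", "zone_metrics", "detect_fusion",
           "detect_penetration", "mean_resting_production"]


@dataclass
class ZoneMetrics:
    """Axial zone extents (μm) at one time point."""
    day: float
    proliferative: float
    prehypertrophic: float
    hypertrophic: float
    subarticular_um: float = float("nan")

    @property
    def combined(self) -> float:
        """Combined proliferative + hypertrophic length."""
        return self.proliferative + self.hypertrophic


@dataclass
class OutcomeRecord:
    """Outcome of one secondary-ossification run."""
    T_mat: float
    fused: bool
    fusion_day: float | None
    resting_zone_penetrated: bool
    penetration_day: float | None
    pthrp_series: list = field(default_factory=list, repr=False)

    @property
    def slope_per_day(self) -> float:
        """Maturation-ramp slope 1/T_mat."""
        return 1.0 / self.T_mat


def _span(z: np.ndarray) -> float:
    return float(z.max() - z.min()) if z.size >= 2 else 0.0


def zone_metrics(points: ParticleState, day: float) -> ZoneMetrics:
    """Axial spans of the proliferative / prehypertrophic / hypertrophic zones.

    The subarticular thickness is the distance from the tissue apex down to
    the highest differentiated (non-quiescent chondrocyte) point.
    """
    z = points.x[:, 2]
    spans = {}
    for name, kind in (("proliferative", CellType.PROLIFERATIVE),
                       ("prehypertrophic", CellType.PREHYPERTROPHIC),
                       ("hypertrophic", CellType.HYPERTROPHIC)):
        spans[name] = _span(z[points.types(kind)])
    diff = points.types(CellType.PROLIFERATIVE, CellType.PREHYPERTROPHIC,
                        CellType.HYPERTROPHIC, *CALCIFIED_TYPES)
    sub = float(z.max() - z[diff].max()) if np.any(diff) else float("nan")
    return ZoneMetrics(day=day, subarticular_um=sub, **spans)


def _voxelize(points: ParticleState, mask: np.ndarray, h: float):
    """Voxel indices (per axis with nonzero extent) of masked points."""
    x = points.x[mask]
    idx = np.floor(x / h).astype(int)
    lo = np.floor(points.x.min(axis=0) / h).astype(int)
    hi = np.floor(points.x.max(axis=0) / h).astype(int)
    return idx - lo, hi - lo + 1


def detect_fusion(points: ParticleState, poc_ids, soc_ids,
                  h: float = 50.0) -> bool:
    """True when POC- and SOC-seeded calcified material is grid-connected.

    Calcified (matrix/apoptotic) points are binned to voxels of size ``h``;
    fusion holds when a voxel holding a calcified POC-seed point and one
    holding a calcified SOC-seed point share a connected component of the
    calcified occupancy — equivalently, no band of non-calcified chondrocytes
    separates the two ossification centers.
    """
    poc_ids = np.asarray(poc_ids, dtype=int)
    soc_ids = np.asarray(soc_ids, dtype=int)
    if poc_ids.size == 0 or soc_ids.size == 0:
        return False
    calc = points.types(*CALCIFIED_TYPES)
    if not (np.any(calc[poc_ids]) and np.any(calc[soc_ids])):
        return False
    idx, shape = _voxelize(points, calc, h)
    occ = np.zeros(shape, dtype=bool)
    occ[tuple(idx.T)] = True
    labels, _ = ndimage.label(occ)
    lo = np.floor(points.x.min(axis=0) / h).astype(int)

    def seed_labels(ids):
        ids = ids[calc[ids]]
        vox = np.floor(points.x[ids] / h).astype(int) - lo
        return set(labels[tuple(vox.T)]) - {0}

    return bool(seed_labels(poc_ids) & seed_labels(soc_ids))


def detect_penetration(points: ParticleState, resting_ids) -> bool:
    """True when differentiating chondrocytes occupy the resting band.

    The band is the current axial interval spanned by the material points
    tagged resting at SOC onset (tracked by id, i.e. materially).  Any
    prehypertrophic or hypertrophic point inside the band counts, as does
    any foreign proliferative point; a resting-tagged cell that is merely
    proliferating in place does not — the resting zone is the growth plate's
    stem pool and its own turnover is renewal, not invasion.  Warns and
    returns False when the tag set is empty.
    """
    resting_ids = np.asarray(resting_ids, dtype=int)
    if resting_ids.size == 0:
        warnings.warn("empty resting zone: penetration undefined, "
                      "reporting False")
        return False
    # the band is the axial interval of the *surviving* resting material;
    # tagged cells already absorbed into an ossification front are no longer
    # part of the cartilage band (a fully consumed band is penetration)
    alive = resting_ids[
        points.cell_type[resting_ids] == CellType.RESTING_PTHRP]
    if alive.size == 0:
        return True
    z = points.x[:, 2]
    z_lo, z_hi = z[alive].min(), z[alive].max()
    in_band = (z >= z_lo) & (z <= z_hi)
    hyp = points.types(CellType.PREHYPERTROPHIC, CellType.HYPERTROPHIC)
    prolif = points.types(CellType.PROLIFERATIVE)
    foreign = np.ones(points.n, dtype=bool)
    foreign[resting_ids] = False
    return bool(np.any(in_band & (hyp | (prolif & foreign))))


def mean_resting_production(production_per_point, resting_ids) -> float:
    """Mean PTHrP production over resting-zone producers (pM/μm³·s)."""
    resting_ids = np.asarray(resting_ids, dtype=int)
    if resting_ids.size == 0:
        return 0.0
    return float(np.mean(np.asarray(production_per_point)[resting_ids]))
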