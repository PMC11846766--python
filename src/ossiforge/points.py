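"""Material-point state container.

A material point represents one chondrocyte together with its share of
extracellular matrix.  State is held struct-of-arrays so that the mechanics,
signaling and fate kernels can operate on whole populations with vectorized
numpy.  Points are only ever appended (division) — never deleted — so integer
ids are stable for the lifetime of a simulation.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = ["CellType", "GrowthMode", "ParticleState", "CALCIFIED_TYPES",
           "CHONDROCYTE_TYPES", "ACTIVE_CHONDROCYTE_TYPES"]


class CellType(enum.IntEnum):
    """Cell-type taxonomy of the growth plate and ossification centers."""

    QUIESCENT = 0
    PROLIFERATIVE = 1
    PREHYPERTROPHIC = 2
    HYPERTROPHIC = 3
    APOPTOTIC = 4          # absorbing
    MATRIX = 5             # absorbing (calcified matrix)
    PERICHONDRIUM = 6
    BONE_COLLAR = 7
    RESTING_PTHRP = 8      # quiescent + PTHrP producer (resting zone)
    PERIARTICULAR_PTHRP = 9  # perichondrial + PTHrP producer


#: calcified / primary-spongiosa types (used by fusion detection)
CALCIFIED_TYPES = (CellType.APOPTOTIC, CellType.MATRIX)

#: every chondrocyte type (excludes perichondrium-derived types)
CHONDROCYTE_TYPES = (CellType.QUIESCENT, CellType.PROLIFERATIVE,
                     CellType.PREHYPERTROPHIC, CellType.HYPERTROPHIC,
                     CellType.RESTING_PTHRP)

#: differentiating chondrocytes whose presence in the resting zone counts as
#: penetration
ACTIVE_CHONDROCYTE_TYPES = (CellType.PROLIFERATIVE,
                            CellType.PREHYPERTROPHIC,
                            CellType.HYPERTROPHIC)


class GrowthMode(enum.IntEnum):
    NONE = 0
    UNIDIRECTIONAL = 1   # columnar proliferation
    ISOTROPIC = 2        # hypertrophic enlargement


_I3 = np.eye(3)


class ParticleState:
    """Struct-of-arrays container for a population of material points.

    Parameters
    ----------
    x : (n, 3) float array
        Positions in μm.
    volume : (n,) float array
        Current point volumes in μm³.
    cell_type : (n,) int array, optional
        Initial cell types (default quiescent).
    """

    #: per-point 1-D float fields
    _SCALARS = ("V", "E", "nu", "t_H", "t_transition", "E_start", "nu_start",
                "E_target", "nu_target", "t_cycle", "T_G0_left", "theta",
                "C_ihh", "C_pthrp")
    #: per-point 1-D small-int fields
    _INTS = ("cell_type", "growth_mode")
    #: per-point boolean fields
    _BOOLS = ("cycling", "divided_this_cycle", "has_ns", "in_transition",
              "cycle_locked", "future_soc")

    def __init__(self, x, volume, cell_type=None):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        self.x = x.copy()
        self.F = np.broadcast_to(_I3, (n, 3, 3)).copy()
        self.Fg = np.broadcast_to(_I3, (n, 3, 3)).copy()
        self.Fg0 = np.broadcast_to(_I3, (n, 3, 3)).copy()
        self.V = np.asarray(volume, dtype=float).copy()
        if self.V.ndim == 0:
            self.V = np.full(n, float(volume))
        self.E = np.full(n, 1.0)        # kPa, chondrocyte default
        self.nu = np.full(n, 0.4)
        self.E_start = self.E.copy()
        self.nu_start = self.nu.copy()
        self.E_target = self.E.copy()
        self.nu_target = self.nu.copy()
        self.t_H = np.zeros(n)
        self.t_transition = np.zeros(n)
        self.t_cycle = np.zeros(n)
        self.T_G0_left = np.zeros(n)
        self.theta = np.ones(n)
        self.C_ihh = np.zeros(n)
        self.C_pthrp = np.zeros(n)
        self.cell_type = (np.full(n, int(CellType.QUIESCENT), dtype=np.int16)
                          if cell_type is None
                          else np.asarray(cell_type, dtype=np.int16).copy())
        self.growth_mode = np.full(n, int(GrowthMode.NONE), dtype=np.int16)
        self.cycling = np.zeros(n, dtype=bool)
        self.divided_this_cycle = np.zeros(n, dtype=bool)
        self.has_ns = np.zeros(n, dtype=bool)
        self.in_transition = np.zeros(n, dtype=bool)
        # a prehypertrophic cell finishing its in-flight cycle never re-enters
        self.cycle_locked = np.zeros(n, dtype=bool)
        self.future_soc = np.zeros(n, dtype=bool)
        self.n_s = np.zeros((n, 3))

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.x.shape[0]

    def __len__(self) -> int:
        return self.n

    @property
    def det_F(self):
        return np.linalg.det(self.F)

    @property
    def V_ref(self):
        """Reference (undeformed, ungrown) volume V / det(F)."""
        return self.V / self.det_F

    def types(self, *kinds) -> np.ndarray:
        """Boolean mask of points whose cell_type is in ``kinds``."""
        codes = np.array([int(k) for k in kinds])
        return np.isin(self.cell_type, codes)

    # ------------------------------------------------------------------
    def validate(self):
        """Check container invariants; raise ValueError on violation."""
        if np.any(self.V <= 0):
            raise ValueError("non-positive point volume")
        if np.any(np.linalg.det(self.F) <= 0):
            raise ValueError("non-positive det(F): inverted point")
        if np.any(np.linalg.det(self.Fg) <= 0):
            raise ValueError("non-positive det(F^g)")
        if np.any(self.E <= 0):
            raise ValueError("non-positive Young's modulus")
        if np.any((self.nu < 0) | (self.nu >= 0.5)):
            raise ValueError("Poisson ratio outside [0, 0.5)")
        norms = np.linalg.norm(self.n_s[self.has_ns], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("non-unit division axis")

    # ------------------------------------------------------------------
    def append(self, other: "ParticleState") -> np.ndarray:
        """Append all points of ``other``; return the new ids."""
        n0 = self.n
        self.x = np.vstack([self.x, other.x])
        self.F = np.concatenate([self.F, other.F])
        self.Fg = np.concatenate([self.Fg, other.Fg])
        self.Fg0 = np.concatenate([self.Fg0, other.Fg0])
        self.n_s = np.vstack([self.n_s, other.n_s])
        for name in self._SCALARS + self._INTS + self._BOOLS:
            setattr(self, name,
                    np.concatenate([getattr(self, name), getattr(other, name)]))
        return np.arange(n0, self.n)

    def copy(self) -> "ParticleState":
        new = ParticleState.__new__(ParticleState)
        for name in ("x", "F", "Fg", "Fg0", "n_s"):
            setattr(new, name, getattr(self, name).copy())
        for name in self._SCALARS + self._INTS + self._BOOLS:
            setattr(new, name, getattr(self, name).copy())
        return new
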