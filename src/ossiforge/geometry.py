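"""Initial geometry of the one-eighth distal-metatarsal capsule.

The template is a cylinder (radius 300 μm, height 300 μm) capped by an
ellipsoidal dome with x/y semi-axes 330 μm and z semi-axis 250 μm whose apex
rises 340 μm above the cylinder top — i.e. the ellipsoid center sits 90 μm
above the cylinder top, and its equator slightly overhangs the cylinder wall
(r ≈ 307.9 μm).  Mirror symmetry on x = 0, y = 0, z = 0 reduces the model to
one octant.

Membership convention (frozen; chosen because it reproduces the published
discretization counts exactly): material points on a cell-centered lattice at
half-spacing offsets (5, 15, 25, … μm for 10 μm spacing), a point belongs to
the solid if it lies in the closed cylinder (z ≤ H, r ≤ R) or the closed
ellipsoid with z > H, with no radial clamp of the dome.  The default spec
yields 42,861 material points.

Boundary points are placed on the analytic outer surface (cylinder wall,
dome, and the overhang annulus on the dome's underside) on latitude rings,
with per-ring counts apportioned from a frozen surface density by
largest-remainder rounding; the default density reproduces the published
5,491 boundary points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CapsuleSpec
from .points import CellType, ParticleState

__all__ = ["BoundaryPointSet", "build_capsule", "assign_initial_types",
           "apply_symmetry", "soc_center", "DEFAULT_BOUNDARY_DENSITY"]

#: frozen boundary-point surface density (points/μm²); calibrated once so the
#: default octant surface (area ≈ 3.367e5 μm²) carries the published count
DEFAULT_BOUNDARY_DENSITY = 0.016307084013354105


@dataclass
class BoundaryPointSet:
    """Passive surface markers: positions on the analytic surface + normals.

    They carry no mass; they are advected with the displacement field and
    used for visualization and surface metrics only.
    """
    x: np.ndarray        # (m, 3) μm
    normals: np.ndarray  # (m, 3) unit outward

    @property
    def n(self) -> int:
        return self.x.shape[0]


def _dome_params(spec: CapsuleSpec):
    """(a, c, z_center, z_apex, phi_max) of the dome ellipsoid."""
    a, c = spec.dome_xy_semiaxis_um, spec.dome_z_semiaxis_um
    H = spec.cylinder_height_um
    zc = H + spec.dome_rise_um - c
    z_apex = H + spec.dome_rise_um
    phi_max = np.arccos(np.clip((H - zc) / c, -1.0, 1.0))
    return a, c, zc, z_apex, phi_max


def _inside(spec: CapsuleSpec, x):
    """Solid-membership predicate for (P, 3) positions (octant assumed)."""
    a, c, zc, _, _ = _dome_params(spec)
    R, H = spec.cylinder_radius_um, spec.cylinder_height_um
    x = np.atleast_2d(x)
    r2 = x[:, 0] ** 2 + x[:, 1] ** 2
    z = x[:, 2]
    cyl = (z <= H) & (r2 <= R * R)
    dome = (z > H) & (r2 / a ** 2 + (z - zc) ** 2 / c ** 2 <= 1.0)
    return cyl | dome


def build_capsule(spec: CapsuleSpec | None = None):
    """Discretize the octant capsule; return (ParticleState, BoundaryPointSet).

    Material points sit on the cell-centered lattice described in the module
    docstring, each with the configured initial volume.  Raises if the dome
    parameters are inconsistent (apex below the cylinder top).
    """
    spec = spec or CapsuleSpec()
    if spec.dome_rise_um <= 0 or spec.dome_z_semiaxis_um <= 0:
        raise ValueError("dome must rise above the cylinder top; the dome is "
                         "interpreted as an ellipsoid whose apex sits "
                         "dome_rise above the cylinder top")
    s = spec.spacing_um
    _, _, _, z_apex, _ = _dome_params(spec)
    n_xy = int(np.ceil(max(spec.cylinder_radius_um,
                           spec.dome_xy_semiaxis_um) / s)) + 1
    n_z = int(np.ceil(z_apex / s)) + 1
    ax_xy = (np.arange(n_xy) + 0.5) * s
    ax_z = (np.arange(n_z) + 0.5) * s
    X, Y, Z = np.meshgrid(ax_xy, ax_xy, ax_z, indexing="ij")
    lattice = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = lattice[_inside(spec, lattice)]
    points = ParticleState(pts, spec.point_volume_um3)
    boundary = _sample_boundary(spec)
    return points, boundary


# ----------------------------------------------------------------------
def _surface_rings(spec: CapsuleSpec, s0: float):
    """Latitude rings of the octant outer surface.

    Returns a list of (radius, z, area, kind) where ``area`` is the ring's
    share of the quarter-surface and kind ∈ {cyl, dome, annulus}.
    """
    R, H = spec.cylinder_radius_um, spec.cylinder_height_um
    a, c, zc, _, phi_max = _dome_params(spec)
    rings = []
    # cylinder wall
    n_rows = max(1, round(H / s0))
    dz = H / n_rows
    for j in range(n_rows):
        rings.append((R, (j + 0.5) * dz, dz * 0.5 * np.pi * R, "cyl"))
    # dome meridian, equal arc-length rings from apex to the z=H latitude
    n_fine = 4000
    phis = np.linspace(0.0, phi_max, n_fine + 1)
    seg = np.sqrt((a * np.cos(phis[:-1])) ** 2
                  + (c * np.sin(phis[:-1])) ** 2) * (phi_max / n_fine)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = cum[-1]
    n_rings = max(1, round(L / s0))
    ds = L / n_rings
    for j in range(n_rings):
        phi = np.interp((j + 0.5) * ds, cum, phis)
        r = a * np.sin(phi)
        rings.append((r, zc + c * np.cos(phi), ds * 0.5 * np.pi * r, "dome"))
    # dome-underside annulus between the cylinder wall and the overhang
    r_out = a * np.sqrt(max(0.0, 1.0 - (H - zc) ** 2 / c ** 2))
    if r_out > R + 1e-9:
        n_r = max(1, round((r_out - R) / s0))
        dr = (r_out - R) / n_r
        for j in range(n_r):
            r = R + (j + 0.5) * dr
            rings.append((r, H, dr * 0.5 * np.pi * r, "annulus"))
    return rings


def _apportion(quotas: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` over ``quotas``."""
    shares = quotas / quotas.sum() * total
    counts = np.floor(shares).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(shares - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _sample_boundary(spec: CapsuleSpec) -> BoundaryPointSet:
    density = (spec.boundary_density_per_um2
               if spec.boundary_density_per_um2 is not None
               else DEFAULT_BOUNDARY_DENSITY)
    s0 = 1.0 / np.sqrt(density)
    rings = _surface_rings(spec, s0)
    areas = np.array([r[2] for r in rings])
    n_total = int(round(density * areas.sum()))
    counts = _apportion(areas, n_total)
    a, c, zc, _, _ = _dome_params(spec)
    xs, ns = [], []
    for (r, z, _, kind), m in zip(rings, counts):
        if m == 0:
            continue
        t = (np.arange(m) + 0.5) * (0.5 * np.pi) / m
        x = np.column_stack([r * np.cos(t), r * np.sin(t), np.full(m, z)])
        if kind == "cyl":
            nrm = np.column_stack([np.cos(t), np.sin(t), np.zeros(m)])
        elif kind == "dome":
            nrm = np.column_stack([x[:, 0] / a ** 2, x[:, 1] / a ** 2,
                                   np.full(m, (z - zc) / c ** 2)])
            nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        else:  # annulus underside faces −z
            nrm = np.tile([0.0, 0.0, -1.0], (m, 1))
        xs.append(x)
        ns.append(nrm)
    return BoundaryPointSet(np.vstack(xs), np.vstack(ns))


# ----------------------------------------------------------------------
def soc_center(spec: CapsuleSpec) -> np.ndarray:
    """Axis point at the epiphysis (dome) volume centroid — the SOC seed."""
    a, c, zc, z_apex, _ = _dome_params(spec)
    H = spec.cylinder_height_um
    z = np.linspace(H, z_apex, 2001)
    A = np.clip(1.0 - (z - zc) ** 2 / c ** 2, 0.0, None)  # ∝ cross-section
    zbar = np.trapezoid(z * A, z) / np.trapezoid(A, z)
    return np.array([0.0, 0.0, zbar])


def assign_initial_types(points: ParticleState, spec: CapsuleSpec,
                         soc_seed_radius: float = 40.0) -> None:
    """Tag the initial perichondrium, periarticular producers and SOC seed.

    Surface shells one lattice spacing thick: the dome cap becomes
    PTHrP-producing periarticular tissue, the lateral cylinder wall
    perichondrium (periarticular takes precedence); everything else stays
    quiescent.  Points within ``soc_seed_radius`` of the epiphysis centroid
    are flagged as the future secondary ossification center.
    """
    a, c, zc, _, _ = _dome_params(spec)
    R, H, s = (spec.cylinder_radius_um, spec.cylinder_height_um,
               spec.spacing_um)
    x = points.x
    r = np.hypot(x[:, 0], x[:, 1])
    z = x[:, 2]

    wall = (z <= H) & (R - r <= s)
    # along-ray distance to the ellipsoid surface for dome points
    rel = x - np.array([0.0, 0.0, zc])
    rho = np.sqrt((x[:, 0] / a) ** 2 + (x[:, 1] / a) ** 2
                  + ((z - zc) / c) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ray_dist = np.linalg.norm(rel, axis=1) * (1.0 / np.maximum(rho, 1e-12)
                                                  - 1.0)
    cap = (z > H) & (ray_dist <= s)

    points.cell_type[wall] = CellType.PERICHONDRIUM
    points.cell_type[cap] = CellType.PERIARTICULAR_PTHRP  # precedence
    seed = np.linalg.norm(x - soc_center(spec), axis=1) <= soc_seed_radius
    points.future_soc |= seed


def apply_symmetry(grid, field) -> None:
    """Cross-check mechanical slip and chemical mirror tags are consistent.

    The octant model requires slip (zero normal displacement) and zero-flux
    behavior on all three world planes; raises if either container was built
    without them.
    """
    if not all(grid.slip_planes):
        raise ValueError("background grid lacks slip tags on a symmetry plane")
    if not all(field.symmetry_axes):
        raise ValueError("chemical field lacks mirror tags on a symmetry axis")
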