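"""Euler rotations and 3-D grid discretization for FFT docking.

The receptor (protein) is mapped onto a shape grid whose occupied cells
carry either a surface weight (reward for contact) or a core penalty
(punishment for penetration), and onto an electrostatic-potential grid
computed with Coulomb's law under a distance-dependent dielectric.  The
ligand (RNA) is mapped onto a binary occupancy grid and a trilinear
charge grid.  The cross-correlation of receptor and ligand grids over
all translations is then the docking score surface for one orientation.

Default geometric parameters follow the FTDOCK lineage and are all
configurable: van-der-Waals radii per element, 1.5 Angstrom surface
thickness, surface weight +1, core penalty -15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.fft import next_fast_len
from scipy.spatial.transform import Rotation

from .structure_io import Structure

__all__ = [
    "GridSpec",
    "ShapeGrid",
    "ChargeGrid",
    "EulerAngles",
    "VDW_RADII",
    "rotate_euler",
    "discretize_shape",
    "discretize_charge",
    "dielectric",
    "auto_grid_spec",
]

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}
DEFAULT_VDW = 1.7

SURFACE_THICKNESS = 1.5   # Angstrom
SURFACE_WEIGHT = 1.0
CORE_PENALTY = -15.0
ELEC_CUTOFF = 12.0        # Angstrom, receptor potential truncation
SOFT_CORE = 2.0           # Angstrom, lower clamp on r in Coulomb sum


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic z-y-z Euler angles in degrees."""
    alpha: float
    beta: float
    gamma: float

    def as_rotation(self) -> Rotation:
        return Rotation.from_euler("ZYZ", [self.alpha, self.beta, self.gamma], degrees=True)


@dataclass(frozen=True)
class GridSpec:
    step: float
    n: int
    origin: np.ndarray

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def cell_centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.step * np.arange(self.n)

    def __eq__(self, other):
        return (isinstance(other, GridSpec) and self.step == other.step
                and self.n == other.n and np.allclose(self.origin, other.origin))


@dataclass
class ShapeGrid:
    values: np.ndarray
    role: str            # receptor | ligand
    spec: GridSpec


@dataclass
class ChargeGrid:
    values: np.ndarray   # receptor: potential phi; ligand: cell charges
    role: str
    spec: GridSpec


def rotate_euler(s: Structure, e: EulerAngles) -> Structure:
    """Rotate all coordinates about the structure's centroid (z-y-z
    intrinsic convention, degrees). The centroid is preserved."""
    xyz = s.coords()
    if xyz.shape[0] == 0:
        raise ValueError("cannot rotate an empty structure")
    centroid = xyz.mean(axis=0)
    rotated = e.as_rotation().apply(xyz - centroid) + centroid
    out = s.copy()
    out.set_coords(rotated)
    return out


def _structure_extent(s: Structure, vdw: dict[str, float]) -> float:
    """Diameter of the structure including vdW radii."""
    xyz = s.coords()
    lo = xyz.min(axis=0)
    hi = xyz.max(axis=0)
    rmax = max((vdw.get(a.element.upper(), DEFAULT_VDW) for a in s.atoms()), default=DEFAULT_VDW)
    return float(np.max(hi - lo)) + 2 * rmax


def auto_grid_spec(receptor: Structure, ligand: Structure, step: float,
                   vdw: dict[str, float] | None = None, margin: float = 2.0) -> GridSpec:
    """Smallest FFT-friendly grid covering both molecules with enough
    clearance that circular wraparound cannot create false contacts.
    The grid is centered on the receptor centroid."""
    vdw = vdw or VDW_RADII
    need = _structure_extent(receptor, vdw) + _structure_extent(ligand, vdw) + 2 * margin
    n = next_fast_len(int(np.ceil(need / step)) + 2, real=True)
    center = receptor.coords().mean(axis=0)
    origin = center - step * (n - 1) / 2.0
    return GridSpec(step=step, n=n, origin=origin)


def _occupancy(s: Structure, spec: GridSpec, vdw: dict[str, float]) -> np.ndarray:
    """Boolean grid: cell center within any atom's vdW radius."""
    occ = np.zeros((spec.n,) * 3, dtype=bool)
    step = spec.step
    for a in s.atoms():
        r = vdw.get(a.element.upper(), DEFAULT_VDW)
        rc = int(np.floor(r / step)) + 1
        cidx = (a.coord - spec.origin) / step
        lo = np.floor(cidx).astype(int) - rc
        hi = np.floor(cidx).astype(int) + rc + 1
        if np.any(lo < 0) or np.any(hi > spec.n):
            raise ValueError(
                "molecule exceeds grid extent; increase grid size n "
                f"(atom at {a.coord}, grid n={spec.n} step={step})")
        ix = np.arange(lo[0], hi[0])
        iy = np.arange(lo[1], hi[1])
        iz = np.arange(lo[2], hi[2])
        dx = (ix - cidx[0]) * step
        dy = (iy - cidx[1]) * step
        dz = (iz - cidx[2]) * step
        d2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return occ


def discretize_shape(s: Structure, spec: GridSpec, role: str,
                     surface_thickness: float = SURFACE_THICKNESS,
                     surface_weight: float = SURFACE_WEIGHT,
                     core_penalty: float = CORE_PENALTY,
                     vdw: dict[str, float] | None = None) -> ShapeGrid:
    """Discretize a molecule for the geometric-complementarity score.

    Ligand grids are binary occupancy.  Receptor occupied cells within
    `surface_thickness` of an empty cell carry `surface_weight`; deeper
    (core) cells carry `core_penalty`.
    """
    if role not in ("receptor", "ligand"):
        raise ValueError(f"role must be receptor or ligand, got {role!r}")
    vdw = vdw or VDW_RADII
    occ = _occupancy(s, spec, vdw)
    if role == "ligand":
        return ShapeGrid(values=occ.astype(float), role=role, spec=spec)
    values = np.zeros_like(occ, dtype=float)
    if occ.any():
        # Distance (in Angstrom) from each occupied cell to the nearest empty cell.
        dist = ndimage.distance_transform_edt(occ, sampling=spec.step)
        surface = occ & (dist <= surface_thickness)
        core = occ & ~surface
        values[surface] = surface_weight
        values[core] = core_penalty
    return ShapeGrid(values=values, role=role, spec=spec)


def dielectric(r):
    """Distance-dependent dielectric, continuous piecewise-linear:
    eps = 4 for r <= 6 A; 38r - 224 for 6 < r < 8; 80 for r >= 8."""
    r = np.asarray(r, dtype=float)
    eps = np.where(r <= 6.0, 4.0, np.where(r >= 8.0, 80.0, 38.0 * r - 224.0))
    return eps if eps.ndim else float(eps)


def discretize_charge(s: Structure, spec: GridSpec, role: str,
                      cutoff: float = ELEC_CUTOFF,
                      soft_core: float = SOFT_CORE) -> ChargeGrid:
    """Electrostatics grids.

    Ligand: each atomic charge is spread over the 8 surrounding cell
    centers with trilinear weights (total charge preserved to 1e-6).
    Receptor: each cell center c receives the potential
    phi(c) = sum_j q_j / (eps(r_cj) * r_cj) over receptor atoms within
    `cutoff`, with r clamped below at `soft_core` Angstrom.
    """
    if role not in ("receptor", "ligand"):
        raise ValueError(f"role must be receptor or ligand, got {role!r}")
    charges = np.array([a.charge for a in s.atoms()])
    values = np.zeros((spec.n,) * 3, dtype=float)
    if np.all(charges == 0.0):
        warnings.warn("all atomic charges are zero; electrostatic grid is zero")
        return ChargeGrid(values=values, role=role, spec=spec)
    xyz = s.coords()
    step = spec.step
    if role == "ligand":
        f = (xyz - spec.origin) / step
        i0 = np.floor(f).astype(int)
        frac = f - i0
        if np.any(i0 < 0) or np.any(i0 + 1 >= spec.n):
            raise ValueError("molecule exceeds grid extent; increase grid size n")
        for (ix, iy, iz), (fx, fy, fz), q in zip(i0, frac, charges):
            for dx in (0, 1):
                wx = fx if dx else 1.0 - fx
                for dy in (0, 1):
                    wy = fy if dy else 1.0 - fy
                    for dz in (0, 1):
                        wz = fz if dz else 1.0 - fz
                        values[ix + dx, iy + dy, iz + dz] += q * wx * wy * wz
        return ChargeGrid(values=values, role=role, spec=spec)

    rc = int(np.ceil(cutoff / step))
    for p, q in zip(xyz, charges):
        if q == 0.0:
            continue
        cidx = (p - spec.origin) / step
        lo = np.maximum(np.floor(cidx).astype(int) - rc, 0)
        hi = np.minimum(np.floor(cidx).astype(int) + rc + 1, spec.n)
        ix = np.arange(lo[0], hi[0])
        iy = np.arange(lo[1], hi[1])
        iz = np.arange(lo[2], hi[2])
        dx = (ix - cidx[0]) * step
        dy = (iy - cidx[1]) * step
        dz = (iz - cidx[2]) * step
        r = np.sqrt(dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
        mask = r <= cutoff
        rr = np.clip(r, soft_core, None)
        contrib = q / (dielectric(rr) * rr)
        values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += np.where(mask, contrib, 0.0)
    return ChargeGrid(values=values, role=role, spec=spec)
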