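"""FFT rigid-body docking engine.

For each orientation on a uniform Euler-angle lattice the (rotated,
re-gridded) ligand is scanned over every grid translation at once via
circular FFT cross-correlation.  The per-translation score is

    total[t] = GC[t] + w_elec * ELEC[t]

where GC correlates the ligand occupancy against the receptor
surface/core grid and ELEC is the negated Coulomb interaction energy
(sum of ligand cell charge times receptor potential), so that larger
total is always better: surface contact and favourable electrostatics
raise the score, core penetration lowers it.  The best
`keep_per_rotation` translations of every orientation are retained
(default 3), ties broken by lexicographic translation order.

Results are read and written in the 11-column whitespace-separated
G_DATA record format: tag, rotation index, 0, score, 0, translation
x y z (grid units), Euler angles alpha beta gamma (degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from . import grids
from .grids import ChargeGrid, EulerAngles, GridSpec, ShapeGrid, auto_grid_spec
from .structure_io import Structure, assign_charges, read_pdb, select_chains

__all__ = [
    "PoseRecord",
    "DockParams",
    "correlate",
    "score_rotation",
    "rotation_lattice",
    "dock",
    "dock_structures",
    "write_gdata",
    "read_gdata",
    "signed_translation",
    "ligand_anchor_shift",
    "grid_center",
]


@dataclass(frozen=True)
class PoseRecord:
    rotation_index: int
    score: float
    translation: tuple[int, int, int]
    rotation: EulerAngles


@dataclass
class DockParams:
    receptor_path: str
    receptor_chains: str
    ligand_path: str
    ligand_chains: str
    outfile: str = "dock.out"
    grid_step: float = 1.0
    out_pdb: int = 0
    rotation_step: float = 15.0
    elec_weight: float = 1.0
    keep_per_rotation: int = 3
    surface_thickness: float = grids.SURFACE_THICKNESS
    surface_weight: float = grids.SURFACE_WEIGHT
    core_penalty: float = grids.CORE_PENALTY

    def __post_init__(self):
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.out_pdb < 0:
            raise ValueError("out_pdb must be >= 0")
        if self.keep_per_rotation < 1:
            raise ValueError("keep_per_rotation must be >= 1")


def correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular cross-correlation out[t] = sum_x a[x] * b[x+t] via FFT."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    fa = sp_fft.rfftn(a)
    fb = sp_fft.rfftn(b)
    return sp_fft.irfftn(np.conj(fa) * fb, s=a.shape)


def grid_center(spec: GridSpec) -> np.ndarray:
    return spec.origin + spec.step * (spec.n - 1) / 2.0


def signed_translation(t, n: int) -> np.ndarray:
    """Map translation components from [0, n) to the centered
    representative in [-n/2, n/2)."""
    t = np.asarray(t, dtype=int)
    return ((t + n // 2) % n) - n // 2


def _top_k(total: np.ndarray, k: int) -> list[tuple[float, tuple[int, int, int]]]:
    """k best translations; equal scores rank by lexicographic (x,y,z)."""
    flat = total.reshape(-1)
    # stable sort keeps C-order (lexicographic) flat index order among ties
    idx = np.argsort(-flat, kind="stable")[:k]
    n = total.shape[0]
    out = []
    for i in idx:
        t = (int(i // (n * n)), int((i // n) % n), int(i % n))
        out.append((float(flat[i]), t))
    return out


def score_rotation(recv_shape: ShapeGrid, recv_elec: ChargeGrid | None,
                   lig_shape: ShapeGrid, lig_elec: ChargeGrid | None,
                   elec_weight: float, k: int,
                   rotation_index: int = 0,
                   rotation: EulerAngles = EulerAngles(0.0, 0.0, 0.0),
                   ) -> list[PoseRecord]:
    """Score one ligand orientation over all translations, keep the k best."""
    if recv_shape.spec != lig_shape.spec:
        raise ValueError("receptor and ligand grids use different GridSpecs")
    total = correlate(lig_shape.values, recv_shape.values)
    if elec_weight != 0.0 and recv_elec is not None and lig_elec is not None:
        if recv_elec.spec != recv_shape.spec or lig_elec.spec != recv_shape.spec:
            raise ValueError("electrostatic grids use a different GridSpec")
        # negated interaction energy: attraction scores positive
        total -= elec_weight * correlate(lig_elec.values, recv_elec.values)
    return [PoseRecord(rotation_index=rotation_index, score=s, translation=t,
                       rotation=rotation)
            for s, t in _top_k(total, k)]


def rotation_lattice(step_deg: float) -> list[EulerAngles]:
    """Uniform Euler lattice: alpha, gamma in [0, 360) and beta in
    [0, 180], all at `step_deg` spacing."""
    if step_deg <= 0:
        raise ValueError("rotation step must be positive")
    alphas = np.arange(0.0, 360.0, step_deg)
    betas = np.arange(0.0, 180.0 + 1e-9, step_deg)
    betas = betas[betas <= 180.0]
    gammas = np.arange(0.0, 360.0, step_deg)
    return [EulerAngles(float(a), float(b), float(g))
            for a in alphas for b in betas for g in gammas]


def ligand_anchor_shift(ligand: Structure, spec: GridSpec) -> np.ndarray:
    """Integer cell shift bringing the ligand centroid nearest the grid
    center.  Shifting by whole cells keeps the input placement exactly
    representable: a bound-input ligand is reproduced by the identity
    rotation plus an integer translation, with no sub-cell residual."""
    centroid = ligand.coords().mean(axis=0)
    return np.round((grid_center(spec) - centroid) / spec.step).astype(int)


def _center_ligand(ligand: Structure, spec: GridSpec) -> Structure:
    out = ligand.copy()
    out.set_coords(out.coords() + ligand_anchor_shift(ligand, spec) * spec.step)
    return out


def dock_structures(receptor: Structure, ligand: Structure, p: DockParams,
                    spec: GridSpec | None = None,
                    ) -> tuple[list[PoseRecord], GridSpec]:
    """Full rotation/translation scan of a prepared (charged) pair.

    The ligand is anchored near the grid center by an integer cell
    shift before the rotation sweep, so a pose's translation is
    relative to the receptor-centered grid and the input placement is
    exactly representable.  Returns records sorted best-first and the
    GridSpec used.
    """
    if spec is None:
        spec = auto_grid_spec(receptor, ligand, p.grid_step)
    use_elec = p.elec_weight != 0.0
    recv_shape = grids.discretize_shape(
        receptor, spec, "receptor", p.surface_thickness, p.surface_weight,
        p.core_penalty)
    recv_elec = grids.discretize_charge(receptor, spec, "receptor") if use_elec else None
    lig0 = _center_ligand(ligand, spec)

    records: list[PoseRecord] = []
    for ridx, euler in enumerate(rotation_lattice(p.rotation_step)):
        lig_rot = grids.rotate_euler(lig0, euler)
        lig_shape = grids.discretize_shape(lig_rot, spec, "ligand")
        lig_elec = grids.discretize_charge(lig_rot, spec, "ligand") if use_elec else None
        records.extend(score_rotation(
            recv_shape, recv_elec, lig_shape, lig_elec, p.elec_weight,
            p.keep_per_rotation, rotation_index=ridx, rotation=euler))
    records.sort(key=lambda r: (-r.score, r.rotation_index, r.translation))
    return records, spec


def dock(p: DockParams) -> tuple[list[PoseRecord], GridSpec]:
    """Read the receptor/ligand PDB files, assign charges, run the scan,
    and write the G_DATA outfile."""
    receptor = select_chains(read_pdb(p.receptor_path), p.receptor_chains)
    ligand = select_chains(read_pdb(p.ligand_path), p.ligand_chains)
    receptor, _ = assign_charges(receptor)
    ligand, _ = assign_charges(ligand)
    records, spec = dock_structures(receptor, ligand, p)
    write_gdata(records, p.outfile)
    return records, spec


def write_gdata(records: list[PoseRecord], path: str, negate_output: bool = False) -> None:
    sign = -1.0 if negate_output else 1.0
    with open(path, "w") as fh:
        for r in records:
            tx, ty, tz = r.translation
            e = r.rotation
            fh.write(f"G_DATA {r.rotation_index} 0 {sign * r.score:.2f} 0 "
                     f"{tx} {ty} {tz} {e.alpha:.1f} {e.beta:.1f} {e.gamma:.1f}\n")


def read_gdata(path: str) -> list[PoseRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 11 or fields[0] != "G_DATA":
                raise ValueError(f"{path}:{lineno}: malformed G_DATA line "
                                 f"({len(fields)} fields): {line.rstrip()!r}")
            try:
                records.append(PoseRecord(
                    rotation_index=int(fields[1]),
                    score=float(fields[3]),
                    translation=(int(fields[5]), int(fields[6]), int(fields[7])),
                    rotation=EulerAngles(float(fields[8]), float(fields[9]),
                                         float(fields[10])),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable G_DATA fields: "
                                 f"{line.rstrip()!r}") from exc
    return records
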