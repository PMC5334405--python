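"""Rebuild full-atom complexes from docked pose records.

A pose record stores an orientation (Euler triple) and a translation in
grid units; applying it reproduces exactly the placement the FFT scan
scored: the ligand is rotated about its centroid, anchored to the grid
by the same integer cell shift the scan used, and then moved by the
centered (signed) translation times the grid step.
"""

from __future__ import annotations

import string
import warnings

import numpy as np

from .fft_scan import PoseRecord, ligand_anchor_shift, signed_translation
from .grids import GridSpec, rotate_euler
from .structure_io import PURINES, Structure, normalize_nt, write_pdb

__all__ = ["apply_pose", "build_complexes", "combine", "stacking_bonus"]

# ring atoms used for aromatic/base centroid distances
_AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def apply_pose(ligand: Structure, rec: PoseRecord, spec: GridSpec) -> Structure:
    """Place the ligand according to a docked pose record."""
    t = np.asarray(rec.translation)
    if np.any(t < 0) or np.any(t >= spec.n):
        raise ValueError(f"translation {rec.translation} outside grid of size {spec.n}")
    posed = rotate_euler(ligand, rec.rotation)
    shift = ligand_anchor_shift(ligand, spec) + signed_translation(t, spec.n)
    posed.set_coords(posed.coords() + shift * spec.step)
    return posed


def combine(receptor: Structure, posed_ligand: Structure) -> Structure:
    """Merge receptor and ligand chains into one complex.  Ligand chain
    IDs colliding with receptor IDs are remapped to unused characters."""
    used = {c.chain_id for c in receptor.chains}
    pool = iter(ch for ch in string.ascii_uppercase + string.digits + string.ascii_lowercase
                if ch not in used and all(ch != c.chain_id for c in posed_ligand.chains))
    lig = posed_ligand.copy()
    for c in lig.chains:
        if c.chain_id in used:
            new_id = next(pool)
            warnings.warn(f"ligand chain {c.chain_id} collides with receptor; "
                          f"renamed to {new_id}")
            c.chain_id = new_id
        used.add(c.chain_id)
    return Structure(chains=receptor.copy().chains + lig.chains,
                     source=receptor.source)


def build_complexes(receptor: Structure, ligand: Structure,
                    records: list[PoseRecord], spec: GridSpec,
                    n_out: int, prefix: str = "complex") -> list[str]:
    """Write the first n_out poses as {prefix}1.pdb ... {prefix}{n_out}.pdb
    in record (score) order.  Receptor coordinates are never moved."""
    if n_out > len(records):
        raise ValueError(f"n_out={n_out} exceeds {len(records)} available records")
    paths = []
    for i, rec in enumerate(records[:n_out], start=1):
        cplx = combine(receptor, apply_pose(ligand, rec, spec))
        path = f"{prefix}{i}.pdb"
        write_pdb(cplx, path)
        paths.append(path)
    return paths


def _ring_centroids(structure: Structure, chain_ids: str, kind: str) -> list[np.ndarray]:
    cents = []
    for cid in chain_ids:
        chain = structure.chain(cid)
        if chain is None:
            raise KeyError(f"chain {cid} not found")
        for res in chain.residues:
            if kind == "aromatic":
                ring = _AROMATIC_RINGS.get(res.res_name)
            else:
                nt = normalize_nt(res.res_name)
                if nt is None:
                    continue
                ring = _PURINE_RING if nt in PURINES else _PYRIMIDINE_RING
            if ring is None:
                continue
            pts = [res.atom(n).coord for n in ring if res.atom(n) is not None]
            if len(pts) >= 3:
                cents.append(np.mean(pts, axis=0))
    return cents


def stacking_bonus(cplx: Structure, protein_chains: str, rna_chains: str,
                   dmax: float = 5.5, bonus: float = 1.0) -> float:
    """Optional rescoring term rewarding aromatic side-chain / base
    stacking: `bonus` per (aromatic ring, base ring) centroid pair
    within `dmax` Angstrom.  Aromatic residues: PHE TYR TRP HIS."""
    aro = _ring_centroids(cplx, protein_chains, "aromatic")
    base = _ring_centroids(cplx, rna_chains, "base")
    if not aro or not base:
        return 0.0
    a = np.array(aro)
    b = np.array(base)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return bonus * int(np.sum(d <= dmax))
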