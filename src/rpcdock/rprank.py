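"""RMSD-clustered knowledge-based potential for ranking docked poses.

The statistical unit is the residue-base pair: one amino-acid residue
and one nucleotide whose minimum heavy-atom distance is at most 10
Angstrom, represented by a fixed reduced-atom set so that RMSD between
two pairs of the same (residue type, base type) class is well defined:

  residue    N, CA, C, O, CB   (CA stands in for CB in glycine)
  nucleotide P (O5' if absent), C4', C1', N9 (purine) / N1 (pyrimidine)

Training clusters the pairs of each type class by greedy leader
clustering at a 6 Angstrom RMSD threshold; each cluster's leader
becomes a "standard pair" carrying the inverse-Boltzmann-style energy

  E_c = -ln(n_c / n_bar)

with n_c the cluster population and n_bar the mean cluster size within
the class, so frequently observed geometries are rewarded.  A decoy
pair inherits the energy of its nearest standard pair of identical type
when their RMSD is below 6 Angstrom, otherwise 0; the decoy's score is
the sum over its pairs.  Lower is better.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .analysis import kabsch_superpose
from .structure_io import (PURINES, Residue, Structure, normalize_nt,
                           read_pdb, select_chains)

__all__ = [
    "ResidueBasePair",
    "PairLibrary",
    "extract_pairs",
    "pair_rmsd",
    "train_potential",
    "score_complex",
    "score_list",
    "PAIR_CUTOFF",
    "MATCH_THRESHOLD",
]

PAIR_CUTOFF = 10.0       # Angstrom, inclusive extraction boundary
MATCH_THRESHOLD = 6.0    # Angstrom, strict (<) match and cluster threshold

_RES_ATOMS = ("N", "CA", "C", "O", "CB")


@dataclass
class ResidueBasePair:
    res_type: str
    base_type: str
    coords: np.ndarray          # (9, 3), centroid-centered local frame
    source: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (9, 3) or not np.all(np.isfinite(self.coords)):
            raise ValueError("pair coords must be a finite 9x3 array")

    @property
    def type_key(self) -> tuple[str, str]:
        return (self.res_type, self.base_type)


@dataclass
class PairLibrary:
    standard_pairs: list[tuple[ResidueBasePair, float, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def by_type(self) -> dict:
        out: dict = {}
        for sp, e, cid in self.standard_pairs:
            out.setdefault(sp.type_key, []).append((sp, e, cid))
        return out

    def save(self, path: str) -> None:
        doc = {
            "format": "rpcdock-pair-library",
            "version": 1,
            "meta": self.meta,
            "pairs": [
                {"res_type": sp.res_type, "base_type": sp.base_type,
                 "energy": e, "cluster_id": cid,
                 "coords": [[round(v, 6) for v in row] for row in sp.coords]}
                for sp, e, cid in self.standard_pairs
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "PairLibrary":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "rpcdock-pair-library":
            raise ValueError(f"{path}: not a pair-library file")
        lib = cls(meta=doc.get("meta", {}))
        for p in doc["pairs"]:
            lib.standard_pairs.append((
                ResidueBasePair(p["res_type"], p["base_type"],
                                np.array(p["coords"])),
                float(p["energy"]), int(p["cluster_id"]),
            ))
        return lib


def _reduced_residue(res: Residue) -> np.ndarray | None:
    pts = []
    for name in _RES_ATOMS:
        a = res.atom(name)
        if a is None and name == "CB":
            a = res.atom("CA")   # glycine
        if a is None:
            return None
        pts.append(a.coord)
    return np.array(pts)


def _reduced_nucleotide(res: Residue) -> np.ndarray | None:
    nt = normalize_nt(res.res_name)
    if nt is None:
        return None
    p = res.atom("P") or res.atom("O5'")
    ref = res.atom("N9") if nt in PURINES else res.atom("N1")
    c4 = res.atom("C4'")
    c1 = res.atom("C1'")
    if p is None or ref is None or c4 is None or c1 is None:
        return None
    return np.array([p.coord, c4.coord, c1.coord, ref.coord])


def _heavy(res: Residue) -> np.ndarray:
    return np.array([a.coord for a in res.atoms if a.element.upper() not in ("H", "D")])


def extract_pairs(cplx: Structure, protein_chains: str, rna_chains: str,
                  cutoff: float = PAIR_CUTOFF) -> list[ResidueBasePair]:
    """All (residue, nucleotide) pairs whose minimum heavy-atom distance
    is <= cutoff (boundary inclusive), in chain/residue order, with
    reduced-atom coordinates centered on the pair centroid."""
    prot_res = []
    for cid in protein_chains:
        chain = cplx.chain(cid)
        if chain is None:
            raise KeyError(f"chain {cid} not found")
        prot_res.extend((cid, r) for r in chain.residues if r.is_amino_acid)
    rna_res = []
    for cid in rna_chains:
        chain = cplx.chain(cid)
        if chain is None:
            raise KeyError(f"chain {cid} not found")
        rna_res.extend((cid, r) for r in chain.residues if r.is_nucleotide)
    if not prot_res or not rna_res:
        return []

    rna_xyz = np.concatenate([_heavy(r) for _, r in rna_res])
    rna_owner = np.concatenate([[i] * len(_heavy(r)) for i, (_, r) in enumerate(rna_res)])
    tree = cKDTree(rna_xyz)
    pairs = []
    for pcid, pres in prot_res:
        red_p = _reduced_residue(pres)
        if red_p is None:
            continue
        hits = tree.query_ball_point(_heavy(pres), cutoff)
        owners = sorted({int(rna_owner[j]) for lst in hits for j in lst})
        for i in owners:
            rcid, rres = rna_res[i]
            red_n = _reduced_nucleotide(rres)
            if red_n is None:
                continue
            coords = np.vstack([red_p, red_n])
            coords = coords - coords.mean(axis=0)
            pairs.append(ResidueBasePair(
                res_type=pres.res_name,
                base_type=normalize_nt(rres.res_name),
                coords=coords,
                source=f"{cplx.source}:{pcid}{pres.res_id}-{rcid}{rres.res_id}",
            ))
    return pairs


def pair_rmsd(a: ResidueBasePair, b: ResidueBasePair) -> float | None:
    """RMSD after optimal rigid superposition of the shared reduced-atom
    sets; None (incomparable) when the type classes differ."""
    if a.type_key != b.type_key:
        return None
    _, _, rmsd = kabsch_superpose(a.coords, b.coords)
    return rmsd


def train_potential(native_complexes, cluster_threshold: float = MATCH_THRESHOLD,
                    cutoff: float = PAIR_CUTOFF) -> PairLibrary:
    """Build a PairLibrary from native complexes.

    `native_complexes` is an iterable of (Structure, protein_chains,
    rna_chains).  Pairs are pooled per type class and clustered by
    deterministic greedy leader clustering (first pair seeds the first
    cluster; each pair joins the first leader within `cluster_threshold`
    RMSD, else seeds a new cluster).
    """
    by_type: dict[tuple[str, str], list[ResidueBasePair]] = {}
    total = 0
    for cplx, pchains, rchains in native_complexes:
        for pr in extract_pairs(cplx, pchains, rchains, cutoff):
            by_type.setdefault(pr.type_key, []).append(pr)
            total += 1
    if total == 0:
        raise ValueError("no residue-base pairs in the training set")

    lib = PairLibrary(meta={
        "cutoff": cutoff,
        "cluster_threshold": cluster_threshold,
        "n_training_pairs": total,
        "cluster_sizes": {},
    })
    cluster_id = 0
    for type_key in sorted(by_type):
        members = by_type[type_key]
        leaders: list[ResidueBasePair] = []
        counts: list[int] = []
        for pr in members:
            placed = False
            for li, leader in enumerate(leaders):
                r = pair_rmsd(pr, leader)
                if r is not None and r < cluster_threshold:
                    counts[li] += 1
                    placed = True
                    break
            if not placed:
                leaders.append(pr)
                counts.append(1)
        n_bar = sum(counts) / len(counts)
        for leader, n_c in zip(leaders, counts):
            energy = -math.log(n_c / n_bar)
            lib.standard_pairs.append((leader, energy, cluster_id))
            cluster_id += 1
        lib.meta["cluster_sizes"]["/".join(type_key)] = counts
    return lib


def score_complex(cplx: Structure, protein_chains: str, rna_chains: str,
                  lib: PairLibrary, match_threshold: float = MATCH_THRESHOLD,
                  ) -> float:
    """Sum of standard-pair energies inherited by the decoy's pairs.

    Each extracted pair takes the energy of the nearest standard pair
    of identical type if that RMSD is strictly below `match_threshold`,
    else 0.
    """
    cutoff = float(lib.meta.get("cutoff", PAIR_CUTOFF))
    standards = lib.by_type()
    energy = 0.0
    for pr in extract_pairs(cplx, protein_chains, rna_chains, cutoff):
        best = None
        best_e = 0.0
        for sp, e, _ in standards.get(pr.type_key, ()):
            r = pair_rmsd(pr, sp)
            if r is not None and (best is None or r < best):
                best, best_e = r, e
        if best is not None and best < match_threshold:
            energy += best_e
    return energy


def score_list(list_path: str, lib: PairLibrary, out_path: str) -> list[tuple[str, float]]:
    """Score every complex in a list file of lines
    'name protein_chains rna_chains'; write 'name energy' lines in list
    order."""
    entries = []
    with open(list_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{list_path}:{lineno}: expected "
                                 f"'name protein_chains rna_chains', got {line.rstrip()!r}")
            entries.append(fields)
    results = []
    for name, pchains, rchains in entries:
        cplx = read_pdb(name)
        cplx = select_chains(cplx, pchains + rchains)
        results.append((name, score_complex(cplx, pchains, rchains, lib)))
    with open(out_path, "w") as fh:
        for name, e in results:
            fh.write(f"{name} {e:.4f}\n")
    return results
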