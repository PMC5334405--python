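"""CAPRI-style assessment of docked decoys against a native complex.

Bound (native) and unbound (docked) structures rarely share residue
numbering, so residues are first put in correspondence by global
sequence alignment (Needleman-Wunsch: match +1, mismatch -1, gap open
-5, extend -1).  On the mapped residues the module computes the standard
decoy-quality metrics:

  R_rmsd  receptor backbone RMSD after superposing on the receptor
  L_rmsd  ligand (RNA) backbone RMSD measured in the receptor frame
  I_rms   backbone RMSD over native-interface residues after
          superposing on the interface
  fnat    fraction of native residue-nucleotide contacts reproduced
  fnon    fraction of the decoy's contacts that are non-native

Backbone atom sets: protein N, CA, C, O; RNA P, O5', C5', C4', C3', O3'.
Contacts use a 5 Angstrom minimum heavy-atom distance; the interface is
defined at 10 Angstrom.  All cutoffs are arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .fft_scan import read_gdata
from .grids import auto_grid_spec
from .pose_builder import apply_pose, combine
from .structure_io import Residue, Structure, normalize_nt, read_pdb, select_chains

__all__ = [
    "MetricsRecord",
    "ResidueMap",
    "kabsch_superpose",
    "map_residues",
    "receptor_ligand_rmsd",
    "interface_rmsd",
    "contact_fractions",
    "analyze_decoys",
    "METRICS_HEADER",
]

METRICS_HEADER = "#Decoy R_rmsd L_rmsd I_rms fnat fnon"

PROTEIN_BACKBONE = ("N", "CA", "C", "O")
RNA_BACKBONE = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class MetricsRecord:
    decoy_index: int
    r_rmsd: float
    l_rmsd: float
    i_rms: float
    fnat: float
    fnon: float


def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Least-squares rigid superposition of Q onto P (SVD/Kabsch).

    Returns (R, t, rmsd) with Q_fit = Q @ R.T + t and R a proper
    rotation (det +1).  Requires k >= 3 points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must both be k x 3, got {P.shape} and {Q.shape}")
    k = P.shape[0]
    if k < 3:
        raise ValueError(f"need at least 3 points, got {k}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    fitted = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - P) ** 2, axis=1))))
    return R, t, rmsd


def _one_letter(res: Residue) -> str | None:
    if res.res_name in _AA3TO1:
        return _AA3TO1[res.res_name]
    return normalize_nt(res.res_name)


def _chain_sequence(chain) -> tuple[str, list[Residue]]:
    letters, residues = [], []
    for r in chain.residues:
        c = _one_letter(r)
        if c is not None:
            letters.append(c)
            residues.append(r)
    return "".join(letters), residues


class ResidueMap:
    """One-to-one residue correspondences per paired chain."""

    def __init__(self):
        # (native_chain_id, decoy_chain_id, moltype, [(nat_res, dec_res), ...])
        self.chain_pairs: list[tuple[str, str, str, list[tuple[Residue, Residue]]]] = []

    def pairs(self, moltype: str | None = None):
        for ncid, dcid, mt, prs in self.chain_pairs:
            if moltype is None or mt == moltype:
                for nr, dr in prs:
                    yield ncid, nr, dcid, dr

    def decoy_to_native_keys(self) -> dict:
        out = {}
        for ncid, nr, dcid, dr in self.pairs():
            out[(dcid, dr.res_seq, dr.icode)] = (ncid, nr.res_seq, nr.icode)
        return out

    def __len__(self):
        return sum(len(p[3]) for p in self.chain_pairs)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -5
    al.extend_gap_score = -1
    return al


def map_residues(native: Structure, decoy: Structure,
                 min_identity: float = 0.3) -> ResidueMap:
    """Align paired chains (i-th native chain with i-th decoy chain) and
    turn aligned non-gap columns into residue correspondences.  Raises
    if chain counts, molecule types, or alignment identity disagree."""
    if len(native.chains) != len(decoy.chains):
        raise ValueError(f"chain count mismatch: native {len(native.chains)}, "
                         f"decoy {len(decoy.chains)}")
    al = _aligner()
    rmap = ResidueMap()
    for nc, dc in zip(native.chains, decoy.chains):
        if nc.moltype != dc.moltype:
            raise ValueError(f"molecule type mismatch for chains "
                             f"{nc.chain_id}/{dc.chain_id}: {nc.moltype} vs {dc.moltype}")
        nseq, nres = _chain_sequence(nc)
        dseq, dres = _chain_sequence(dc)
        if not nseq or not dseq:
            raise ValueError(f"chain {nc.chain_id} has no alignable residues")
        aln = al.align(nseq, dseq)[0]
        pairs = []
        matches = 0
        cols = 0
        for (ns, ne), (ds, de) in zip(*aln.aligned):
            for i, j in zip(range(ns, ne), range(ds, de)):
                cols += 1
                if nseq[i] == dseq[j]:
                    matches += 1
                pairs.append((nres[i], dres[j]))
        identity = matches / cols if cols else 0.0
        if identity < min_identity:
            raise ValueError(
                f"alignment identity {identity:.2f} for chains "
                f"{nc.chain_id}/{dc.chain_id} below minimum {min_identity:.2f}")
        rmap.chain_pairs.append((nc.chain_id, dc.chain_id, nc.moltype, pairs))
    return rmap


def _mapped_backbone(rmap: ResidueMap, moltype: str):
    """Paired backbone coordinates (native, decoy) over mapped residues."""
    names = PROTEIN_BACKBONE if moltype == "protein" else RNA_BACKBONE
    nat, dec = [], []
    for _, nr, _, dr in rmap.pairs(moltype):
        for name in names:
            na, da = nr.atom(name), dr.atom(name)
            if na is not None and da is not None:
                nat.append(na.coord)
                dec.append(da.coord)
    return np.array(nat), np.array(dec)


def receptor_ligand_rmsd(native_cplx: Structure, decoy_cplx: Structure,
                         rmap: ResidueMap) -> tuple[float, float]:
    """(R_rmsd, L_rmsd): receptor backbone fit RMSD, and ligand backbone
    RMSD in the receptor frame (after superposing on the receptor)."""
    natP, decP = _mapped_backbone(rmap, "protein")
    if len(natP) < 3:
        raise ValueError("fewer than 3 mapped receptor backbone atoms")
    R, t, r_rmsd = kabsch_superpose(natP, decP)
    natL, decL = _mapped_backbone(rmap, "rna")
    if len(natL) < 1:
        raise ValueError("no mapped ligand backbone atoms")
    decL_fit = decL @ R.T + t
    l_rmsd = float(np.sqrt(np.mean(np.sum((decL_fit - natL) ** 2, axis=1))))
    return r_rmsd, l_rmsd


def _heavy_coords(res: Residue) -> np.ndarray:
    return np.array([a.coord for a in res.atoms if a.element.upper() not in ("H", "D")])


def _contact_pairs(structure: Structure, cutoff: float) -> set:
    """Residue-nucleotide pairs with min heavy-atom distance <= cutoff.
    Keys are (chain_id, res_seq, icode)."""
    prot, rna = [], []
    for c in structure.chains:
        mt = c.moltype
        for r in c.residues:
            key = (c.chain_id, r.res_seq, r.icode)
            if mt == "protein" and r.is_amino_acid:
                prot.append((key, _heavy_coords(r)))
            elif mt == "rna" and r.is_nucleotide:
                rna.append((key, _heavy_coords(r)))
    if not prot or not rna:
        return set()
    rna_xyz = np.concatenate([x for _, x in rna])
    rna_owner = np.concatenate([[i] * len(x) for i, (_, x) in enumerate(rna)])
    tree = cKDTree(rna_xyz)
    contacts = set()
    for pkey, pxyz in prot:
        hits = tree.query_ball_point(pxyz, cutoff)
        owners = {int(rna_owner[j]) for lst in hits for j in lst}
        for i in owners:
            contacts.add((pkey, rna[i][0]))
    return contacts


def contact_fractions(native_cplx: Structure, decoy_cplx: Structure,
                      rmap: ResidueMap, contact_cutoff: float = 5.0,
                      ) -> tuple[float, float]:
    """fnat = |decoy ∩ native| / |native|; fnon = |decoy \\ native| /
    |decoy| (0 when the decoy has no contacts).  Decoy contacts are
    translated to native residue identity through the residue map;
    contacts involving unmapped residues count as non-native."""
    native_contacts = _contact_pairs(native_cplx, contact_cutoff)
    if not native_contacts:
        raise ValueError("native complex has no contacts at this cutoff")
    decoy_raw = _contact_pairs(decoy_cplx, contact_cutoff)
    d2n = rmap.decoy_to_native_keys()
    decoy_contacts = set()
    for pkey, rkey in decoy_raw:
        decoy_contacts.add((d2n.get(pkey, ("?",) + pkey),
                            d2n.get(rkey, ("?",) + rkey)))
    if not decoy_contacts:
        return 0.0, 0.0
    shared = decoy_contacts & native_contacts
    fnat = len(shared) / len(native_contacts)
    fnon = len(decoy_contacts - native_contacts) / len(decoy_contacts)
    return fnat, fnon


def _interface_residue_keys(structure: Structure, cutoff: float) -> set:
    """Keys of residues/nucleotides with any heavy atom within `cutoff`
    of the partner molecule."""
    keys = set()
    for pkey, rkey in _contact_pairs(structure, cutoff):
        keys.add(pkey)
        keys.add(rkey)
    return keys


def interface_rmsd(native_cplx: Structure, decoy_cplx: Structure,
                   rmap: ResidueMap, iface_cutoff: float = 10.0) -> float:
    """Backbone RMSD over mapped native-interface residues after
    superposing the decoy interface onto the native interface."""
    iface = _interface_residue_keys(native_cplx, iface_cutoff)
    if not iface:
        raise ValueError("native interface is empty at this cutoff")
    nat, dec = [], []
    for ncid, nr, _, dr in rmap.pairs():
        if (ncid, nr.res_seq, nr.icode) not in iface:
            continue
        names = PROTEIN_BACKBONE if nr.is_amino_acid else RNA_BACKBONE
        for name in names:
            na, da = nr.atom(name), dr.atom(name)
            if na is not None and da is not None:
                nat.append(na.coord)
                dec.append(da.coord)
    if len(nat) < 3:
        raise ValueError("fewer than 3 mapped interface backbone atoms")
    _, _, rmsd = kabsch_superpose(np.array(nat), np.array(dec))
    return rmsd


@dataclass
class AnalysisParams:
    resfile: str
    max_matches: int
    native_receptor: str
    native_ligand: str
    native_receptor_chains: str
    native_ligand_chains: str
    decoy_receptor: str
    decoy_ligand: str
    decoy_receptor_chains: str
    decoy_ligand_chains: str
    output: str
    grid_step: float = 1.0
    contact_cutoff: float = 5.0
    iface_cutoff: float = 10.0


def analyze_decoys(p: AnalysisParams) -> list[MetricsRecord]:
    """Rebuild the first `max_matches` decoys from a G_DATA result file
    and write the metrics table ('#Decoy R_rmsd L_rmsd I_rms fnat fnon')."""
    records = read_gdata(p.resfile)
    if p.max_matches > len(records):
        raise ValueError(f"max_matches={p.max_matches} exceeds "
                         f"{len(records)} records in {p.resfile}")
    native = combine(
        select_chains(read_pdb(p.native_receptor), p.native_receptor_chains),
        select_chains(read_pdb(p.native_ligand), p.native_ligand_chains))
    drec = select_chains(read_pdb(p.decoy_receptor), p.decoy_receptor_chains)
    dlig = select_chains(read_pdb(p.decoy_ligand), p.decoy_ligand_chains)
    spec = auto_grid_spec(drec, dlig, p.grid_step)

    rows = []
    for i, rec in enumerate(records[:p.max_matches], start=1):
        decoy = combine(drec, apply_pose(dlig, rec, spec))
        rmap = map_residues(native, decoy)
        r_rmsd, l_rmsd = receptor_ligand_rmsd(native, decoy, rmap)
        i_rms = interface_rmsd(native, decoy, rmap, p.iface_cutoff)
        fnat, fnon = contact_fractions(native, decoy, rmap, p.contact_cutoff)
        rows.append(MetricsRecord(i, r_rmsd, l_rmsd, i_rms, fnat, fnon))

    with open(p.output, "w") as fh:
        fh.write(METRICS_HEADER + "\n")
        for m in rows:
            fh.write(f"{m.decoy_index} {m.r_rmsd:.6g} {m.l_rmsd:.6g} "
                     f"{m.i_rms:.6g} {m.fnat:.6g} {m.fnon:.6g}\n")
    return rows
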