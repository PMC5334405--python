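"""Deterministic synthetic protein/RNA fixtures with known ground truth.

Structures here use idealized lattice geometry, not physical
conformations: the docking and scoring pipeline is pure geometry, so
correctness can be exercised with toy molecules whose contacts, pairs,
native pose, and perturbation RMSDs are all recorded (and brute-force
recomputed) at generation time.

`make_toy_complex` builds an RNA strand with an aperiodic cross
section and a protein shell molded around it, so the bound placement
maximizes surface complementarity by construction while shifted or
rotated placements lose contact or run into the shell's core.

All manifest quantities (contact and pair lists, counts, RMSDs) are
computed by direct brute-force distance geometry inside this module,
independent of the production code paths they are used to test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist

from .fft_scan import EulerAngles, PoseRecord
from .grids import GridSpec
from .structure_io import Atom, Chain, Residue, Structure, PURINES

__all__ = [
    "make_toy_complex",
    "make_decoy_set",
    "native_pose_record",
    "make_planted_contact_pair",
    "make_training_set",
    "make_library_decoy",
    "make_stacked_complex",
    "TRAINING_GEOMETRIES",
]

_ROD_SPACING = 3.2       # Angstrom between rod axes (overlapping vdW -> solid core)
_RES_RISE = 3.0          # Angstrom per residue along a rod
_NT_RISE = 3.0           # Angstrom per nucleotide
_JITTER = 0.12           # uniform coordinate jitter amplitude

_NT_BACKBONE_OFFSETS = {
    "P": (0.3, 0.8, -1.6), "OP1": (1.2, 1.4, -1.7), "OP2": (-0.6, 1.5, -1.8),
    "O5'": (0.2, 0.4, -0.9), "C5'": (0.5, 0.9, -0.2), "C4'": (0.3, 0.6, 0.6),
    "O4'": (-0.8, 0.7, 0.8), "C3'": (0.9, 0.4, 1.4), "O3'": (0.6, 0.9, 2.0),
    "C2'": (0.2, -0.5, 1.3), "O2'": (0.6, -1.3, 1.8), "C1'": (-0.5, -0.6, 0.6),
}
_PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def _element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _make_residue(res_name: str, res_seq: int, atom_pos: dict[str, np.ndarray],
                  rng=None) -> Residue:
    atoms = []
    for name, pos in atom_pos.items():
        p = np.asarray(pos, dtype=float)
        if rng is not None:
            p = p + rng.uniform(-_JITTER, _JITTER, 3)
        atoms.append(Atom(name=name, element=_element(name), coord=p))
    return Residue(res_name=res_name, res_seq=res_seq, atoms=atoms)


def _ala(res_seq: int, center: np.ndarray, cb_dir: np.ndarray, rng) -> Residue:
    """Compact alanine-like residue on a rod axis; only CB leaves the
    axis, along `cb_dir`."""
    c = np.asarray(center, dtype=float)
    d = np.asarray(cb_dir, dtype=float)
    perp = np.array([-d[1], d[0], 0.0])
    return _make_residue("ALA", res_seq, {
        "N": c + (0.0, 0.0, -1.2),
        "CA": c,
        "C": c + (0.0, 0.0, 1.2),
        "O": c + 0.9 * perp + (0.0, 0.0, 1.6),
        "CB": c + 1.5 * d,
    }, rng)


def _nucleotide(base: str, res_seq: int, center: np.ndarray,
                base_dir: np.ndarray, rng, base_offset: float = 2.6) -> Residue:
    c = np.asarray(center, dtype=float)
    d = np.asarray(base_dir, dtype=float)
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0], 0.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.array([1.0, 0.0, 0.0])
    zhat = np.array([0.0, 0.0, 1.0])
    pos = {name: c + np.array(off) for name, off in _NT_BACKBONE_OFFSETS.items()}
    ring = _PURINE_RING if base in PURINES else _PYRIMIDINE_RING
    ring_center = c + base_offset * d
    for i, name in enumerate(ring):
        ang = 2.0 * math.pi * i / len(ring)
        pos[name] = ring_center + 1.15 * (math.cos(ang) * zhat + math.sin(ang) * perp)
    return _make_residue(base, res_seq, pos, rng)


def _heavy_coords(res: Residue) -> np.ndarray:
    return np.array([a.coord for a in res.atoms if a.element.upper() not in ("H", "D")])


def _brute_force_pairs(protein: Structure, rna: Structure, cutoff: float):
    """Direct double-loop residue-nucleotide pairs with min heavy-atom
    distance <= cutoff.  Ground truth for contact/pair manifests."""
    pairs = []
    for pc in protein.chains:
        for pr in pc.residues:
            pxyz = _heavy_coords(pr)
            for rc in rna.chains:
                for rr in rc.residues:
                    d = cdist(pxyz, _heavy_coords(rr)).min()
                    if d <= cutoff:
                        pairs.append(((pc.chain_id, pr.res_seq, pr.icode),
                                      (rc.chain_id, rr.res_seq, rr.icode)))
    return pairs


_SHELL_INNER = 2.0   # Angstrom: closest protein-atom distance to any RNA atom
_SHELL_OUTER = 7.0   # Angstrom: shell thickness bound (two atom layers -> core)
_SHELL_LATTICE = 1.7  # Angstrom: lattice spacing of shell atom sites


def _shell_sites(rna_xyz: np.ndarray) -> np.ndarray:
    """Atom sites for a protein shell molded around the RNA strand.

    Sites are the points of a cubic lattice whose distance to the
    nearest RNA atom lies in [_SHELL_INNER, _SHELL_OUTER]: a closed
    two-atom-thick pocket wrapping the RNA.  The engulfed native pose
    therefore touches the receptor surface layer around every RNA atom
    simultaneously, while any other placement can press against the
    shell's outside only locally - so the planted pose maximizes the
    geometric-complementarity score by construction.  (Rigid-body
    docking scores placements, not entry paths, so an enclosed native
    pose is legitimate.)
    """
    from scipy.spatial import cKDTree
    s = _SHELL_LATTICE
    lo = rna_xyz.min(axis=0) - _SHELL_OUTER - s
    hi = rna_xyz.max(axis=0) + _SHELL_OUTER + s
    axes = [np.arange(math.floor(lo[i] / s), math.ceil(hi[i] / s) + 1) * s
            for i in range(3)]
    pts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    d, _ = cKDTree(rna_xyz).query(pts)
    return pts[(d >= _SHELL_INNER) & (d <= _SHELL_OUTER)]


_SHELL_ATOM_NAMES = ("N", "CA", "C", "O", "CB")


def make_toy_complex(seed: int, n_res: int | None = None, n_nt: int = 5):
    """Toy bound protein/RNA complex with a known native pose.

    Returns (protein, rna, native_pose, manifest).  The native pose is a
    PoseRecord with identity rotation and the SIGNED integer grid offset
    of the RNA centroid from the protein centroid (step 1 Angstrom);
    convert it for a concrete grid with `native_pose_record`.

    The protein is a pocket shell molded around the RNA (see
    `_shell_sites`); its atom sites are grouped five at a time into
    alanine-labelled residues.  By default all shell residues are kept;
    passing a smaller `n_res` truncates the shell (degrading shape
    specificity but keeping the object well-formed).
    """
    if n_nt < 3:
        raise ValueError("n_nt must be >= 3")
    rng = np.random.default_rng(seed)

    bases = ["A", "U", "G", "C"]
    rchain = Chain(chain_id="R")
    for j in range(n_nt):
        z = (j - (n_nt - 1) / 2.0) * _NT_RISE
        # base directions rotate by 120 degrees per nucleotide: the
        # strand cross-section is aperiodic along its axis, so rotated
        # placements cannot re-fit the molded pocket
        phi = 2.0 * math.pi * j / 3.0
        rchain.residues.append(_nucleotide(
            bases[j % 4], j + 1, np.array([0.0, 0.0, z]),
            np.array([math.sin(phi), -math.cos(phi), 0.0]), rng))
    rna = Structure(chains=[rchain], source=f"toy-rna-seed{seed}")

    sites = _shell_sites(rna.coords())
    n_groups = len(sites) // len(_SHELL_ATOM_NAMES)
    if n_res is None:
        n_res = n_groups
    if n_res < 5:
        raise ValueError("n_res must be >= 5")
    if n_res > n_groups:
        raise ValueError(f"shell provides only {n_groups} residues")
    pchain = Chain(chain_id="P")
    for seq in range(1, n_res + 1):
        block = sites[(seq - 1) * 5:seq * 5]
        pchain.residues.append(_make_residue(
            "ALA", seq, dict(zip(_SHELL_ATOM_NAMES, block)), rng))
    protein = Structure(chains=[pchain], source=f"toy-protein-seed{seed}")

    # The docking engine anchors the ligand by an integer cell shift, so
    # the bound input pose is exactly an integer grid translation.
    p_cent = protein.coords().mean(axis=0)
    r_cent = rna.coords().mean(axis=0)
    native_offset = tuple(int(v) for v in np.round(r_cent - p_cent))

    contacts = _brute_force_pairs(protein, rna, 5.0)
    pairs10 = _brute_force_pairs(protein, rna, 10.0)
    min_sep = min(
        cdist(protein.coords(), rna.coords()).min(axis=0).min(), 99.0)
    manifest = {
        "seed": seed,
        "n_res": n_res,
        "n_nt": n_nt,
        "protein_chain": "P",
        "rna_chain": "R",
        "n_chains": 2,
        "n_protein_atoms": protein.n_atoms,
        "n_rna_atoms": rna.n_atoms,
        "native_offset": list(native_offset),
        "contacts": [list(map(list, c)) for c in contacts],
        "n_contacts": len(contacts),
        "n_pairs": len(pairs10),
        "min_separation": float(min_sep),
    }
    native_pose = PoseRecord(rotation_index=0, score=0.0,
                             translation=native_offset,
                             rotation=EulerAngles(0.0, 0.0, 0.0))
    return protein, rna, native_pose, manifest


def native_pose_record(native_pose: PoseRecord, spec: GridSpec) -> PoseRecord:
    """Wrap the signed native translation into the [0, n) grid range."""
    t = tuple(int(v) % spec.n for v in native_pose.translation)
    return PoseRecord(rotation_index=native_pose.rotation_index,
                      score=native_pose.score, translation=t,
                      rotation=native_pose.rotation)


_RNA_BACKBONE = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")


def make_decoy_set(protein: Structure, rna: Structure, transforms, seed: int = 0):
    """Decoys = native with a rigid transform applied to the RNA.

    `transforms` is a list of (R, t): 3x3 rotation applied about the RNA
    centroid, then translation t (Angstrom).  Returns a list of
    (decoy_protein, decoy_rna, manifest) where the manifest's l_rmsd and
    fnat are computed by direct geometry from the applied transform.
    """
    native_contacts = set(map(_freeze, _brute_force_pairs(protein, rna, 5.0)))
    if not native_contacts:
        raise ValueError("native complex has no contacts")
    out = []
    for R, t in transforms:
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        decoy_rna = rna.copy()
        xyz = decoy_rna.coords()
        cent = xyz.mean(axis=0)
        decoy_rna.set_coords((xyz - cent) @ R.T + cent + t)
        bb_old, bb_new = [], []
        for c_old, c_new in zip(rna.chains, decoy_rna.chains):
            for r_old, r_new in zip(c_old.residues, c_new.residues):
                for name in _RNA_BACKBONE:
                    a_old, a_new = r_old.atom(name), r_new.atom(name)
                    if a_old is not None and a_new is not None:
                        bb_old.append(a_old.coord)
                        bb_new.append(a_new.coord)
        bb_old = np.array(bb_old)
        bb_new = np.array(bb_new)
        l_rmsd = float(np.sqrt(np.mean(np.sum((bb_new - bb_old) ** 2, axis=1))))
        decoy_contacts = set(map(_freeze, _brute_force_pairs(protein, decoy_rna, 5.0)))
        fnat = len(decoy_contacts & native_contacts) / len(native_contacts)
        out.append((protein.copy(), decoy_rna, {
            "l_rmsd": l_rmsd,
            "fnat": fnat,
            "n_decoy_contacts": len(decoy_contacts),
        }))
    return out


def _freeze(pair):
    return (tuple(pair[0]), tuple(pair[1]))


def make_planted_contact_pair(seed: int = 0, n_native: int = 20,
                              n_kept: int = 14, n_novel: int = 6):
    """Native/decoy complex pair with exactly planted contact overlap.

    The native complex has `n_native` residue-nucleotide contacts
    (nucleotide j next to residue j, partners 12 Angstrom apart so no
    cross-talk).  The decoy keeps the first `n_kept` nucleotides in
    place and moves the rest next to previously uncontacted residues,
    giving `n_kept` native and `n_novel` novel contacts.
    Returns (native_cplx, decoy_cplx, manifest).
    """
    if n_kept + n_novel != n_native:
        raise ValueError("decoy contact total must equal n_native here")
    rng = np.random.default_rng(seed)
    n_res = n_native + n_novel
    spacing = 12.0

    def build(nt_targets):
        pchain = Chain(chain_id="P")
        for i in range(1, n_res + 1):
            pchain.residues.append(_ala(
                i, np.array([spacing * i, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]), None))
        rchain = Chain(chain_id="R")
        for j, target in enumerate(nt_targets, start=1):
            rchain.residues.append(_nucleotide(
                "AUGC"[j % 4], j, np.array([spacing * target, 4.6, 0.0]),
                np.array([0.0, 1.0, 0.0]), None))
        return Structure(chains=[pchain, rchain], source="planted")

    native_targets = list(range(1, n_native + 1))
    decoy_targets = list(range(1, n_kept + 1)) + \
        list(range(n_native + 1, n_native + n_novel + 1))
    native = build(native_targets)
    decoy = build(decoy_targets)

    nat = _brute_force_pairs(
        Structure(chains=[native.chains[0]]), Structure(chains=[native.chains[1]]), 5.0)
    dec = _brute_force_pairs(
        Structure(chains=[decoy.chains[0]]), Structure(chains=[decoy.chains[1]]), 5.0)
    manifest = {
        "n_native_contacts": len(nat),
        "n_decoy_contacts": len(dec),
        "n_shared": len(set(map(_freeze, nat)) & set(map(_freeze, dec))),
        "fnat": n_kept / n_native,
        "fnon": n_novel / (n_kept + n_novel),
    }
    return native, decoy, manifest


# Residue reduced-frame template shared by the training fixtures.
_TRAIN_RES = {
    "N": (0.0, 0.0, -1.2), "CA": (0.0, 0.0, 0.0), "C": (0.0, 0.0, 1.2),
    "O": (1.0, 0.0, 1.8), "CB": (1.5, 0.3, 0.0),
}

# Three nucleotide placements (reduced atoms P, C4', C1', N9) relative
# to the residue with distinct internal shapes: a line, a flat spread,
# and a tetrahedron.  Compact placements that differ only in direction
# are nearly absorbed by the superposition, so shape differences are
# what pushes the pairwise superposed RMSD well above the 6 A
# clustering threshold (verified > 7 A in the tests).
TRAINING_GEOMETRIES = [
    {"P": (4.0, 0.0, 0.0), "C4'": (9.0, 0.0, 0.0), "C1'": (14.0, 0.0, 0.0),
     "N9": (19.0, 0.0, 0.0)},
    {"P": (-14.9, 10.5, 14.9), "C4'": (-9.2, 12.4, 7.6),
     "C1'": (-4.5, 5.7, -0.9), "N9": (5.9, -14.6, -7.6)},
    {"P": (11.9, 5.1, 7.9), "C4'": (-13.1, 10.7, 1.3),
     "C1'": (-1.0, -7.7, 7.6), "N9": (4.9, 5.8, -3.4)},
]

# A fourth geometry far (superposed RMSD > 7 A) from all three cluster
# centers; pairs built from it must never match a standard pair.
_FAR_GEOMETRY = {"P": (2.7, -12.9, 11.8), "C4'": (5.7, 0.2, -1.9),
                 "C1'": (-13.6, 10.9, -13.1), "N9": (-9.7, 12.8, 11.7)}


def _pair_complex(nt_geometry: dict, jitter: np.ndarray | None,
                  z_shift: float = 0.0, res_seq: int = 1) -> tuple[Residue, Residue]:
    shift = np.array([0.0, 0.0, z_shift])
    res = _make_residue("ALA", res_seq,
                        {k: np.array(v) + shift for k, v in _TRAIN_RES.items()})
    nt_pos = {}
    for i, (k, v) in enumerate(nt_geometry.items()):
        p = np.array(v) + shift
        if jitter is not None:
            p = p + jitter[i]
        nt_pos[k] = p
    nt = _make_residue("A", res_seq, nt_pos)
    return res, nt


def make_training_set(seed: int = 0, sizes: tuple[int, ...] = (9, 3, 3)):
    """Synthetic native complexes whose extracted (ALA, A) pairs form
    clusters of exactly the requested sizes.

    Each complex holds one residue-nucleotide pair; cluster members are
    their cluster's center geometry plus a small (< 0.5 A RMSD) jitter.
    Returns a list of (Structure, "P", "R") training inputs.
    """
    if len(sizes) > len(TRAINING_GEOMETRIES):
        raise ValueError(f"at most {len(TRAINING_GEOMETRIES)} cluster geometries available")
    rng = np.random.default_rng(seed)
    complexes = []
    for ci, size in enumerate(sizes):
        for m in range(size):
            jitter = rng.normal(0.0, 0.1, (4, 3)) if m > 0 else None
            res, nt = _pair_complex(TRAINING_GEOMETRIES[ci], jitter)
            cplx = Structure(chains=[Chain("P", [res]), Chain("R", [nt])],
                             source=f"train-c{ci}-m{m}")
            complexes.append((cplx, "P", "R"))
    return complexes


def make_library_decoy(energies: list[float], picks: list[int],
                       include_far: bool = True):
    """Decoy complex assembled from copies of the training cluster
    geometries, placed 40 Angstrom apart so each contributes exactly one
    pair.  `picks` indexes TRAINING_GEOMETRIES; the expected score is
    the sum of `energies[p]` over picks.  With `include_far`, one extra
    pair using a geometry far (> 6 A RMSD) from every cluster center is
    appended; it must contribute nothing.
    Returns (cplx, expected_energy, n_pairs_placed).
    """
    pres, rres = [], []
    for k, p in enumerate(picks):
        res, nt = _pair_complex(TRAINING_GEOMETRIES[p], None,
                                z_shift=40.0 * k, res_seq=k + 1)
        pres.append(res)
        rres.append(nt)
    n = len(picks)
    if include_far:
        res, nt = _pair_complex(_FAR_GEOMETRY, None,
                                z_shift=40.0 * n, res_seq=n + 1)
        pres.append(res)
        rres.append(nt)
        n += 1
    cplx = Structure(chains=[Chain("P", pres), Chain("R", rres)],
                     source="library-decoy")
    expected = float(sum(energies[p] for p in picks))
    return cplx, expected, n


def make_stacked_complex(k: int = 3, distance: float = 5.0, n_far: int = 2):
    """Complex with exactly k aromatic/base ring pairs at the given
    centroid distance plus `n_far` pairs far beyond any stacking cutoff.
    Returns (cplx, "P", "R", k)."""
    phe_ring = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    pres, rres = [], []
    total = k + n_far
    for i in range(total):
        x0 = 40.0 * i
        sep = distance if i < k else 20.0
        phe_pos = {"N": (x0, 0.0, -2.5), "CA": (x0, 0.0, -2.0),
                   "C": (x0, 0.5, -1.5), "O": (x0, 1.0, -1.0), "CB": (x0, -1.0, -2.0)}
        for j, name in enumerate(phe_ring):
            ang = 2.0 * math.pi * j / len(phe_ring)
            phe_pos[name] = (x0 + 1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0)
        pres.append(_make_residue("PHE", i + 1, phe_pos))
        nt_pos = {"C4'": (x0, 0.0, sep + 3.0), "C1'": (x0, 1.0, sep + 2.5),
                  "O5'": (x0, -1.0, sep + 3.5)}
        for j, name in enumerate(_PURINE_RING):
            ang = 2.0 * math.pi * j / len(_PURINE_RING)
            nt_pos[name] = (x0 + 1.15 * math.cos(ang), 1.15 * math.sin(ang), sep)
        rres.append(_make_residue("A", i + 1, nt_pos))
    cplx = Structure(chains=[Chain("P", pres), Chain("R", rres)],
                     source="stacked-fixture")
    return cplx, "P", "R", k
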