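import numpy as np
import pytest

from rpcdock import fixtures
from rpcdock.analysis import (AnalysisParams, METRICS_HEADER, analyze_decoys,
                              contact_fractions, interface_rmsd,
                              kabsch_superpose, map_residues,
                              receptor_ligand_rmsd)
from rpcdock.fft_scan import EulerAngles, PoseRecord, write_gdata
from rpcdock.grids import auto_grid_spec
from rpcdock.pose_builder import combine
from rpcdock.structure_io import write_pdb

from conftest import random_rotation


def nw_align_score(a, b, match=1, mismatch=-1, open_=-5, extend=-1):
    """Independent affine-gap Needleman-Wunsch (first gap position costs
    the open penalty, later positions the extend penalty)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)   # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)   # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend)
    return max(M[n, m], X[n, m], Y[n, m])


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        P = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_rigid_transform(self, rng):
        P = rng.normal(size=(12, 3)) * 4
        Rm = random_rotation(rng)
        t0 = rng.normal(size=3) * 10
        Q = P @ Rm.T + t0
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(Q @ R.T + t, P, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_optimal_against_random_rotations(self, rng):
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(P, Q)
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        for _ in range(2000):
            Rr = random_rotation(rng)
            trial = float(np.sqrt(np.mean(np.sum((Qc @ Rr.T - Pc) ** 2, axis=1))))
            assert rmsd <= trial + 1e-9

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestMapResidues:
    def test_identical_sequences_identity_map(self, toy):
        cplx = combine(toy[0], toy[1])
        rmap = map_residues(cplx, cplx.copy())
        assert len(rmap) == cplx.n_residues
        for _, nr, _, dr in rmap.pairs():
            assert (nr.res_seq, nr.res_name) == (dr.res_seq, dr.res_name)

    def test_truncated_decoy_omits_missing_positions(self, toy):
        native = combine(toy[0], toy[1])
        decoy = native.copy()
        del decoy.chains[0].residues[:2]   # drop 2 N-terminal residues
        rmap = map_residues(native, decoy)
        mapped_native_seqs = {nr.res_seq for _, nr, _, _ in rmap.pairs("protein")}
        assert 1 not in mapped_native_seqs and 2 not in mapped_native_seqs
        assert len(rmap) == native.n_residues - 2

    def test_alignment_score_matches_dp_oracle(self, rng):
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -1
        for _ in range(5):
            a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
            b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
            assert aligner.score(a, b) == pytest.approx(nw_align_score(a, b))

    def test_low_identity_raises(self, toy):
        native = combine(toy[0], toy[1])
        decoy = native.copy()
        for r in decoy.chains[0].residues:
            r.res_name = "TRP"   # all-ALA chain becomes all-TRP
        with pytest.raises(ValueError, match="identity"):
            map_residues(native, decoy)


class TestReceptorLigandRmsd:
    def test_native_is_zero(self, toy):
        cplx = combine(toy[0], toy[1])
        rmap = map_residues(cplx, cplx.copy())
        r, l = receptor_ligand_rmsd(cplx, cplx.copy(), rmap)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert l == pytest.approx(0.0, abs=1e-9)

    def test_pure_ligand_shift_measured_in_receptor_frame(self, toy):
        protein, rna = toy[0], toy[1]
        shifted = rna.copy()
        shifted.set_coords(rna.coords() + [5.0, 0.0, 0.0])
        native = combine(protein, rna)
        decoy = combine(protein, shifted)
        rmap = map_residues(native, decoy)
        r, l = receptor_ligand_rmsd(native, decoy, rmap)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert l == pytest.approx(5.0, abs=1e-6)

    def test_decoy_set_manifest_l_rmsd_recovered(self, toy, rng):
        protein, rna = toy[0], toy[1]
        Rm = random_rotation(rng)
        decoys = fixtures.make_decoy_set(protein, rna,
                                         [(Rm, np.array([1.0, -2.0, 0.5]))])
        dprot, drna, manifest = decoys[0]
        native = combine(protein, rna)
        decoy = combine(dprot, drna)
        rmap = map_residues(native, decoy)
        _, l = receptor_ligand_rmsd(native, decoy, rmap)
        assert l == pytest.approx(manifest["l_rmsd"], abs=1e-6)


class TestInterfaceRmsd:
    def test_native_zero_and_oracle_on_shift(self, toy):
        protein, rna = toy[0], toy[1]
        native = combine(protein, rna)
        rmap = map_residues(native, native.copy())
        assert interface_rmsd(native, native.copy(), rmap) == \
            pytest.approx(0.0, abs=1e-9)
        shifted = rna.copy()
        shifted.set_coords(rna.coords() + [2.0, 0.0, 0.0])
        decoy = combine(protein, shifted)
        rmap = map_residues(native, decoy)
        got = interface_rmsd(native, decoy, rmap, iface_cutoff=10.0)
        # oracle: single Kabsch call over the concatenated mapped
        # interface backbone
        from rpcdock.analysis import (_interface_residue_keys,
                                      PROTEIN_BACKBONE, RNA_BACKBONE)
        iface = _interface_residue_keys(native, 10.0)
        nat, dec = [], []
        for ncid, nr, _, dr in rmap.pairs():
            if (ncid, nr.res_seq, nr.icode) not in iface:
                continue
            names = PROTEIN_BACKBONE if nr.is_amino_acid else RNA_BACKBONE
            for nm in names:
                if nr.atom(nm) is not None and dr.atom(nm) is not None:
                    nat.append(nr.atom(nm).coord)
                    dec.append(dr.atom(nm).coord)
        _, _, want = kabsch_superpose(np.array(nat), np.array(dec))
        assert got == pytest.approx(want, abs=1e-12)

    def test_cutoff_growth_is_monotone(self, toy):
        from rpcdock.analysis import _interface_residue_keys
        native = combine(toy[0], toy[1])
        small = _interface_residue_keys(native, 5.0)
        large = _interface_residue_keys(native, 12.0)
        assert small <= large


class TestContactFractions:
    def test_native_against_itself(self, toy):
        native = combine(toy[0], toy[1])
        rmap = map_residues(native, native.copy())
        fnat, fnon = contact_fractions(native, native.copy(), rmap)
        assert (fnat, fnon) == (1.0, 0.0)

    def test_planted_overlap_is_exact(self):
        native, decoy, manifest = fixtures.make_planted_contact_pair()
        rmap = map_residues(native, decoy)
        fnat, fnon = contact_fractions(native, decoy, rmap)
        assert fnat == manifest["fnat"] == 0.70
        assert fnon == manifest["fnon"] == 0.30

    def test_far_decoy_has_no_contacts(self, toy):
        protein, rna = toy[0], toy[1]
        far = rna.copy()
        far.set_coords(rna.coords() + 100.0)
        native = combine(protein, rna)
        decoy = combine(protein, far)
        rmap = map_residues(native, decoy)
        assert contact_fractions(native, decoy, rmap) == (0.0, 0.0)

    def test_lost_plus_kept_fractions_sum_to_one(self, toy, rng):
        protein, rna = toy[0], toy[1]
        decoys = fixtures.make_decoy_set(
            protein, rna, [(random_rotation(rng), rng.normal(size=3) * 3)])
        dprot, drna, manifest = decoys[0]
        native = combine(protein, rna)
        decoy = combine(dprot, drna)
        rmap = map_residues(native, decoy)
        fnat, _ = contact_fractions(native, decoy, rmap)
        assert fnat == pytest.approx(manifest["fnat"], abs=1e-12)


def test_metrics_invariant_under_global_rigid_motion(toy, rng):
    protein, rna = toy[0], toy[1]
    native = combine(protein, rna)
    shifted = rna.copy()
    shifted.set_coords(rna.coords() + [3.0, 0.0, 0.0])
    decoy = combine(protein, shifted)
    moved = decoy.copy()
    Rm = random_rotation(rng)
    moved.set_coords(decoy.coords() @ Rm.T + [20.0, -5.0, 8.0])
    rmap1 = map_residues(native, decoy)
    rmap2 = map_residues(native, moved)
    r1, l1 = receptor_ligand_rmsd(native, decoy, rmap1)
    r2, l2 = receptor_ligand_rmsd(native, moved, rmap2)
    assert (r1, l1) == pytest.approx((r2, l2), abs=1e-6)
    assert contact_fractions(native, decoy, rmap1) == \
        pytest.approx(contact_fractions(native, moved, rmap2))
    assert interface_rmsd(native, decoy, rmap1) == \
        pytest.approx(interface_rmsd(native, moved, rmap2), abs=1e-6)


class TestAnalyzeDecoys:
    def _setup(self, toy, tmp_path, n_records=3):
        from rpcdock.fft_scan import ligand_anchor_shift
        from rpcdock.structure_io import read_pdb
        protein, rna = toy[0], toy[1]
        rec_pdb = str(tmp_path / "prot.pdb")
        lig_pdb = str(tmp_path / "rna.pdb")
        write_pdb(protein, rec_pdb)
        write_pdb(rna, lig_pdb)
        # native record computed from the file-read structures (PDB
        # precision), exactly as the analysis stage will re-derive them
        fprot, frna = read_pdb(rec_pdb), read_pdb(lig_pdb)
        spec = auto_grid_spec(fprot, frna, 1.0)
        t0 = tuple(int(v) % spec.n for v in -ligand_anchor_shift(frna, spec))
        native_rec = PoseRecord(0, 0.0, t0, EulerAngles(0.0, 0.0, 0.0))
        shift = PoseRecord(0, -1.0, ((t0[0] + 5) % spec.n, t0[1], t0[2]),
                           EulerAngles(0.0, 0.0, 0.0))
        records = [native_rec, shift, shift][:n_records]
        resfile = str(tmp_path / "toy.out")
        write_gdata(records, resfile)
        return AnalysisParams(
            resfile=resfile, max_matches=n_records,
            native_receptor=rec_pdb, native_ligand=lig_pdb,
            native_receptor_chains="P", native_ligand_chains="R",
            decoy_receptor=rec_pdb, decoy_ligand=lig_pdb,
            decoy_receptor_chains="P", decoy_ligand_chains="R",
            output=str(tmp_path / "toy.rmsd.dat"), grid_step=1.0)

    def test_row_count_header_and_native_row(self, toy, tmp_path):
        p = self._setup(toy, tmp_path)
        rows = analyze_decoys(p)
        assert len(rows) == 3
        lines = open(p.output).read().splitlines()
        assert lines[0] == METRICS_HEADER
        assert len(lines) == 4
        first = lines[1].split()
        # decoy 1 rebuilt at the native pose: all-zero RMSDs, fnat 1
        assert first[0] == "1"
        assert [float(v) for v in first[1:]] == pytest.approx(
            [0.0, 0.0, 0.0, 1.0, 0.0], abs=5e-3)
        # decoy 2 is a pure 5 A ligand shift
        second = lines[2].split()
        assert float(second[2]) == pytest.approx(5.0, abs=5e-3)

    def test_rerun_is_byte_identical(self, toy, tmp_path):
        p = self._setup(toy, tmp_path)
        analyze_decoys(p)
        first = open(p.output, "rb").read()
        analyze_decoys(p)
        assert open(p.output, "rb").read() == first

    def test_max_matches_overflow_raises(self, toy, tmp_path):
        p = self._setup(toy, tmp_path)
        p.max_matches = 99
        with pytest.raises(ValueError, match="max_matches"):
            analyze_decoys(p)
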