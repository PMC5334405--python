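# Methods

## Scope and model

`rpcdock` implements a two-stage rigid-body protocol for RNA–protein
complex structure prediction plus a decoy-assessment stage:

1. **Docking**: exhaustive rigid-body search over SO(3) × T(3) with an
   FFT translation scan per orientation, scored by geometric
   complementarity (GC) plus electrostatics (ELEC).
2. **Ranking**: a knowledge-based potential over residue–base pairs,
   classified by RMSD rather than by distance bins.
3. **Assessment**: CAPRI-style metrics (R_rmsd, L_rmsd, I_rms, fnat,
   fnon) with sequence-alignment-based bound/unbound residue mapping.

Both molecules are treated as rigid; conformational change on binding
is out of scope, as are solvent, desolvation terms, and any
minimization of the docked poses.

## Stage 1: grids and the docking score

**Shape grids.**  A cell is occupied when its center lies within an
atom's van der Waals radius (C 1.7, N 1.55, O 1.52, P 1.8, S 1.8 Å;
1.7 Å for unknown elements).  Receptor occupied cells within
`surface_thickness` (default 1.5 Å, Euclidean distance transform) of an
empty cell carry `surface_weight` (+1); deeper cells carry
`core_penalty` (−15).  The ligand grid is binary occupancy.  The GC
score of a translation is the correlation of the two grids: surface
overlap rewards contact, core overlap penalizes penetration.  With the
surface defined on the occupied boundary, "contact" means vdW
interpenetration of up to `surface_thickness` — the conventional
soft-surface treatment in FFT docking.  These parameter values follow
the FTDOCK lineage and are all exposed as arguments.

**Electrostatics.**  Partial charges come from an embedded AMBER-style
table for the 20 amino acids and 4 ribonucleotides.  Structures used in
docking are typically hydrogen-free, so hydrogen charges are folded
into their bonded heavy atoms, and each residue's total is renormalised
to exactly its formal charge (0, ±1 for charged side chains, −1 per
nucleotide).  The receptor potential at a cell is
`φ(c) = Σ_j q_j / (ε(r)·r)` truncated at 12 Å, with r clamped below at
2 Å (soft core) and the continuous piecewise-linear dielectric
ε = 4 (r ≤ 6), 38r − 224 (6 < r < 8), 80 (r ≥ 8).  Ligand charges are
spread trilinearly onto the 8 surrounding cells, conserving total
charge.  The ELEC score term is the **negated** interaction energy
Σ q·φ, so the combined score `GC + elec_weight·ELEC` (default weight
1.0) is maximized: both good shape fit and favourable electrostatics
raise it.  Because the sign convention of the original outputs is not
fixed by their format, `write_gdata` accepts a `negate_output` flag.

**Search.**  Orientations sweep an intrinsic z-y-z Euler lattice
(α, γ ∈ [0°, 360°), β ∈ [0°, 180°]) at `rotation_step` (default 15°;
the protocol-level checks use 30°, which keeps a full scan of a small
complex under a minute).  Rotation is about the ligand centroid.  Per
orientation the FFT scan evaluates all n³ translations at once;
`keep_per_rotation` (default 3) best translations are retained, ties
broken by lexicographic translation order so reruns are byte-identical.

**Grid geometry.**  The grid is centered on the receptor centroid with
the smallest FFT-friendly size covering receptor extent + ligand extent
+ 2 Å clearance margin per side, which makes circular wraparound
harmless.  Before the sweep the ligand is anchored by an **integer**
cell shift toward the grid center rather than an exact recentering;
poses then relate to the input ligand placement by integer cell
translations only, so a bound input pose is exactly representable and
`apply_pose` reproduces scanned placements with no sub-cell residual.
This is the invariant behind the scan/build consistency check
(rebuilt poses re-score to the scanned value within ~1e-14 relative).

## Stage 2: the RMSD-clustered pair potential

A residue–base pair is an (amino acid, nucleotide) pair whose minimum
heavy-atom distance is ≤ 10 Å (boundary inclusive).  The reduced-atom
representation is N, CA, C, O, CB (CA substitutes for CB in glycine)
plus P (O5′ when P is absent), C4′, C1′, and the glycosidic nitrogen
(N9 purine / N1 pyrimidine) — a fixed 9-point set that makes RMSD
between pairs of the same (residue type, base type) class well defined.
Coordinates are stored centered on the pair centroid; comparisons use
optimal rigid superposition, so the potential is invariant under any
global motion of a complex.

Training pools pairs per type class and clusters them by deterministic
greedy leader clustering (first pair seeds the first cluster; each pair
joins the first leader within 6 Å RMSD, else seeds a new cluster;
source order fixes the outcome).  A cluster of size n_c among k
clusters of mean size n̄ gets the energy **E_c = −ln(n_c / n̄)** — an
inverse-Boltzmann form in which frequently observed geometries are
favourable and a lone cluster scores exactly 0.  A decoy pair inherits
the energy of the *nearest* standard pair of identical type when that
RMSD is strictly below 6 Å, otherwise 0 (cross-type matches are never
allowed); the complex score is the sum.  The library serializes to
versioned JSON and round-trips bit-stably.

The match threshold (6 Å, strict) mirrors the clustering threshold;
the 10 Å extraction boundary is inclusive.  No trained library ships
with the package — the scoring stage takes a `library` path produced by
`train_potential` on whatever native set the user assembles.

## Assessment

Residue correspondence between native (bound) and decoy (unbound)
chains is a global Needleman–Wunsch alignment of one-letter sequences
(match +1, mismatch −1, gap open −5, extend −1; the opening penalty is
charged on the first gapped position).  Chains pair positionally and
must agree in molecule type; alignments under 30% identity are
rejected.  Backbone atom sets are N, CA, C, O (protein) and P, O5′,
C5′, C4′, C3′, O3′ (RNA).

* **R_rmsd** — backbone RMSD after least-squares superposition on the
  mapped protein backbone (Kabsch, SVD, proper rotation enforced).
* **L_rmsd** — RNA backbone RMSD measured *after* that receptor-frame
  superposition, with no further fitting: a pure k Å ligand shift gives
  exactly k.
* **I_rms** — backbone RMSD over native-interface residues (any heavy
  atom within 10 Å of the partner) after superposing on that same set.
* **fnat / fnon** — contacts are residue–nucleotide pairs with minimum
  heavy-atom distance ≤ 5 Å; fnat is the fraction of native contacts
  present in the decoy, fnon the fraction of the decoy's contacts that
  are non-native (decoy-count denominator; 0 when the decoy has no
  contacts).  Decoy contacts involving unmapped residues count as
  non-native.

The 5 Å and 10 Å cutoffs follow CAPRI assessment conventions and are
arguments.  The analysis stage rebuilds decoys from a G_DATA file; it
re-derives the same deterministic grid from the decoy structures and
the `RPDock.grid_step` key (default 1), so no extra state needs to be
carried between the dock and analyze runs.

## Synthetic fixtures

`rpcdock.fixtures` generates every test structure programmatically and
records ground truth (contact lists, pair counts, native pose,
closed-form RMSDs) computed by direct brute-force geometry, independent
of the production code paths under test.

* `make_toy_complex(seed)` builds an RNA strand (full sugar–phosphate
  atom names, base rings, base directions rotating 120° per nucleotide
  so the cross-section is aperiodic) and a protein shell *molded around
  it*: alanine-labelled residues on a 1.7 Å lattice restricted to the
  2.0–7.0 Å offset band around the RNA.  The engulfed bound pose
  touches the receptor surface layer around every RNA atom at once,
  while any other placement presses on the shell only locally and
  deeper penetration hits core — so the planted pose maximizes the
  docking score by construction, which is exactly what a recovery test
  needs.  Rigid docking scores placements, not binding pathways, so the
  enclosed geometry is legitimate; it is also the fixture's main
  *unrealism*: real interfaces bury ~1/4 of the ligand surface, not all
  of it, so passing recovery here validates the search and scoring
  machinery, not expected success rates on real complexes.
* `make_decoy_set` applies rigid transforms to the RNA and reports
  each decoy's L_rmsd and fnat in closed form from the transform.
* `make_planted_contact_pair` plants an exact contact overlap
  (20 native contacts, 14 kept + 6 novel) on a 12 Å-spaced lattice so
  fnat = 0.70 and fnon = 0.30 hold exactly.
* `make_training_set` produces one-pair complexes whose nucleotide
  geometries form clusters of requested sizes: three center shapes
  (a line, a flat spread, a tetrapod) verified to sit > 7 Å superposed
  RMSD apart, members jittered ~0.2 Å; `make_library_decoy` assembles
  decoys from copies of those centers 40 Å apart, plus an optional
  geometry > 7 Å from every center that must contribute nothing.

Structures use idealized lattice geometry, not stereochemistry: bond
lengths, chirality, and Ramachandran/pucker realism are irrelevant to
the pipeline's mathematics and are not attempted.

## Numerical choices and degenerate inputs

* Grid sizes come from `scipy.fft.next_fast_len`; correlations use
  real FFTs.  FFT and direct-sum correlation agree to ~1e-14 relative.
* Occupancy stamping floors cell indices from jittered continuous
  coordinates; exact cell-boundary coincidences are measure-zero but
  would be the first suspect if scan/build consistency ever degraded.
* The Euler lattice contains equivalent triples (β = 0 with equal
  α + γ, β = 180 with equal α − γ); they are scanned as-is —
  deduplication would save ~15% of a sweep and is deliberately not done
  to keep the lattice definition trivial.
* Kabsch superposition needs ≥ 3 non-degenerate points; reflections are
  excluded by the determinant correction.  Pair RMSD on 9-point sets
  agrees with a quaternion closed form to 1e-9.
* Alternate locations resolve to highest occupancy (ties prefer blank
  then 'A'); only the first MODEL is read; HETATM waters and monatomic
  ions are dropped; non-standard residues survive parsing but are
  ignored by type-specific stages (pair extraction, contacts,
  alignment).
* Empty charge sets produce a zero electrostatic grid with a warning
  rather than an error, so shape-only docking still works.

## Known limitations

* The GC surface/core weights, dielectric form, electrostatic weight,
  and rotation step are literature-lineage defaults, not fitted values;
  absolute scores are meaningful only for ranking within a run.
* The pair-potential energy formula and its thresholds are one
  defensible choice among several ("statistics by cluster population");
  swapping the formula only requires replacing `train_potential`'s
  energy assignment.
* The aromatic-stacking term is a centroid-distance count available as
  an optional rescoring column (`stacking_bonus`), off by default; no
  orientation dependence is modelled.
* Success-rate benchmarks on curated unbound docking sets require those
  datasets and a library trained on a large native corpus; neither is
  bundled, and the test suite makes no claims about them.
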