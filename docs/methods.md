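# Methods

This note documents the models and procedures `tg2screen` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Thermodynamic conversion and outlier rules

Potency is converted with ΔG = RT ln(K_d/c°), c° = 1 M, R = 1.987×10⁻³
kcal/(mol·K). The temperature default is 298.15 K; assay temperatures are
rarely reported, so the value used is recorded in every report header. K_d
is taken equal to IC50 by default — the usual shortcut when comparing assay
potencies with docking energies; a Cheng–Prusoff divisor is available
(`cheng_prusoff_factor`) but off by default since the substrate
concentration needed to apply it is typically unknown. The activity filter
is a strict inequality (IC50 < 500 nM keeps 499 and drops 500).

Ligand efficiency is ΔG divided by the heavy-atom count. Group outliers are
flagged by two complementary rules, both reported: (a) deviation of a
member from the *leave-one-out median* of its group by more than 1.0
kcal/mol in ΔG or 0.5 kcal/mol in LE — the thresholds used to call a
binder exceptional; (b) Tukey boxplot whiskers at 1.5×IQR, the graphical
convention for boxplot outliers. The LOO-median operationalisation makes
"deviating from the other compounds" precise without assuming
distributional shape. One caveat is worth recording: "all values within t
of the group median" does *not* imply no LOO flags at tolerance t (for
[m−t, m, m+t] the extreme member deviates 1.5t from the median of the
others); the guaranteed-quiet region is values within t/2 of the group
median, and that is the property the test suite asserts.

Quartiles use linear interpolation (`numpy.percentile` default), matching
pandas and matplotlib, so whisker positions agree with what a standard
boxplot would draw.

## Fingerprints, similarity, clustering

Fingerprints are Morgan (ECFP-style) circular fingerprints of radius 3
folded to 2048 bits, computed by RDKit; folding collisions are accepted
as-is, and both parameters are exposed. The largest covalent fragment is
kept before fingerprinting and descriptor computation (library SMILES often
carry counterions); this salt-stripping is the default and is visible in
the molecule's canonical SMILES. Stereochemistry is preserved in SMILES but
the fingerprints are not stereo-aware.

Butina sphere-exclusion clustering is implemented from its definition: with
neighbour lists at Tanimoto distance ≤ cutoff, the unassigned item with the
most unassigned neighbours seeds a cluster and absorbs those neighbours;
ties break by input order; the loop repeats until everything is assigned,
singletons becoming their own clusters. Neighbour counts are recomputed
over the surviving items each round, which makes the output a true
partition and the procedure straightforward to verify against brute-force
enumeration. The distance cutoff is not fixed by the screening protocol;
the pipeline default is 0.4 (common practice for 2048-bit circular
fingerprints) and the planted-series recovery tests use 0.65, which suits
series that share a core but vary two substituents (recovery is stable
across 0.6–0.7). Representatives are the sphere centroids of the largest
clusters — the protocol does not specify how representatives were chosen,
and the centroid is the member that defined the cluster.

Similarity search reports a candidate as a hit when its best Tanimoto
similarity over the references reaches the threshold (default 0.3,
inclusive), with the best-matching reference attached.

## Scaffolds

Bemis–Murcko scaffolds are computed by iterative pruning: delete terminal
(degree-1) heavy atoms until fixed point, which leaves rings plus linkers;
then restore atoms attached to that framework through double or triple
bonds (exocyclic carbonyls and the like), which is the original framework
convention and matches RDKit's reference implementation — used as an
independent oracle in the tests, not as the implementation. Aromatic
nitrogens that lose an N-substituent get their hydrogen back so the pruned
ring remains kekulizable. Acyclic molecules have no scaffold and are
excluded from frequency tables but counted separately. Scaffold identity is
exact canonical-SMILES equality on the atom-typed framework; a generic
(all-carbon, single-bonded) mode exists behind a flag. The frequency
threshold is inclusive (≥ min_count), recorded in table metadata.

## Structure profiling

Geometric criteria (all configurable, defaults embedded in every report):

| quantity | default | rationale |
|---|---|---|
| hydrogen-bond distance | ≤ 3.5 Å, both atoms N/O/S | donor/acceptor geometry is unchecked because hydrogens are usually absent from the inputs |
| close contact | ≤ 4.0 Å heavy-atom pair | conventional vdW contact range |
| stacking centroid distance | ≤ 5.5 Å | upper end of observed π-stacks |
| parallel vs T-shaped angle | ≤ 30° / ≥ 60° | interplanar angle folded into [0°, 90°]; 30–60° reported as unclassified |
| parallel-displaced offset | > 1.5 Å | lateral centroid separation in the protein ring plane |
| cavity capture radius | 4.0 Å | contact range from cavity-defining residues |

Protein rings come from side-chain templates (Phe/Tyr/His, two rings for
Trp); ligand rings are 5/6-membered cycles of the ligand bond graph
(explicit bonds when available, otherwise covalent-radius inference) that
pass a 0.15 Å planarity check. Ring planes are least-squares (SVD) fits.

Superposition is the Kabsch least-squares rigid-body fit with a
determinant-sign correction, pairing atoms by (chain, residue id, atom
name). Cross-structure residue deviations superpose on shared Cα atoms
first, then report per-residue heavy-atom RMSD against the reference
structure; missing residues yield NaN rather than failure, mirroring
unresolved loops in experimental structures. Residue numbering follows the
canonical full-length sequence (1-based); the catalytic-residue default set
is C277, H335, D358, W241, H305, E363, N333, W332, Q169.

The three-cavity occupancy model marks a cavity occupied when any ligand
heavy atom is within the capture radius of any heavy atom of its defining
residues (defaults: catalytic = {C277, W241, W332, H335}, surface =
{Q169}; the wide pocket's membership is structure-dependent and left to the
user), and reports whether the ligand occupies at least two of the three —
the binding criterion for this saddle-shaped site. A ligand sulfur
covalently bridging to C277's SG (the leftover of covalent peptidomimetic
inhibition) can be detected and removed before profiling.

## Docking-result statistics

Pose RMSD is direct (non-superposed), since docked and reference poses
share the receptor frame; pairing is strictly by atom name, with no
symmetry correction (a recorded limitation, acceptable when pose and
reference come from the same topology). Scores are treated as ΔG in
kcal/mol. When multiple poses per ligand exist, the best-ranked pose is the
default (a mean-of-top-k option exists). Score-vs-experiment comparison
flags compounds whose |dock − exp| exceeds 2.0 kcal/mol.

## MSA masking

Alignments are FASTA or A3M; in A3M, lowercase letters are per-sequence
insertion states and form no columns. Target residues are numbered over the
target's non-gap positions; the columns mapping to the window (default
276–336) are rewritten to alanine. Masking applies to all sequences'
residues in those columns by default — the stronger conformational bias —
and can be restricted to the target. Gaps and insertions are never touched,
so exactly end−start+1 columns change when the target has no insertions in
the window. Guard letters (Q at the start, C at the end for the canonical
TG2 numbering) are checked before any rewriting to catch off-by-one errors;
the real target sequence is not bundled, so tests exercise the guard
mechanism on synthetic stand-ins labelled as such.

## Synthetic data: what it emulates, and what it does not

`gen_library` emulates a focused screening extract as a set of congeneric
series: each planted scaffold (default: three large, drug-like, two- and
three-ring frameworks, sulfonamide-containing first — the group that
dominates real TG2-targeted chemotypes) gets two attachment sites fixed per
series, and members carry random small substituents there (bare with
probability 0.15). This is the R-group-enumeration structure of real
med-chem series and gives within-series fingerprint similarity well above
the between-series background. IC50s are log-normal (median 150 nM,
geometric SD 2.5), so most but not all members pass the 500 nM cut.
It does **not** emulate: activity cliffs, assay noise or inter-assay
disagreement, stereochemistry, tautomers, or the long-tailed scaffold
distribution of a real vendor library. Passing the recovery tests shows the
pipeline machinery is correct, not that real libraries cluster this
cleanly.

`gen_complex` places each planted interaction at an isolated site (25 Å
spacing): serine OG ↔ ligand oxygen for hydrogen bonds (2.7–3.2 Å), alanine
CB ↔ ligand carbon for apolar contacts (3.2–3.7 Å), and phenylalanine rings
with analytically placed ligand benzene rings for stacks, sampled at least
5° / 0.3 Å inside the class regions. Planted ring stacks can produce
incidental carbon–carbon contacts (a T-shaped pair below ~5.2 Å necessarily
does); the generator counts these with plain pairwise geometry at build
time and includes them in the planted truth, so summary counts are exact.
The fragments are not folded proteins; backbone geometry, solvent and
electrostatics are absent.

`gen_docking_table` draws inlier scores on evenly spaced symmetric offsets
around each group mean (scaled by the noise SD, shuffled, small jitter)
rather than raw Gaussian noise: this bounds each group's spread so Tukey
whiskers can never flag an inlier, making planted-outlier recovery a
property of the construction rather than a statistical accident. Outliers
are displaced by −3 kcal/mol (ΔG kind) or given an anomalously small
heavy-atom count (LE kind). Real docking-score noise is heavier-tailed.

## Problem sizes

The bundled tests and the acceptance script run on deliberately small
problems — libraries of 75–600 compounds, complexes of a few dozen atoms,
200 random clustering instances of ≤ 10 items, 50 planted complexes, 20
score tables — chosen so the whole validation completes in seconds while
still exercising every code path and every planted-truth recovery the
design guarantees.

## Known limitations

- Fingerprints ignore stereochemistry; tautomers are not enumerated.
- Hydrogen-bond detection is distance-and-element only (no angles).
- Pose RMSD has no graph-symmetry correction.
- The packaged PAINS file is a curated subset of the classic interference
  families (quinones, catechols, rhodanines, hydrazones, azo dyes, Michael
  acceptors and related); supply a full published SMARTS set via
  `load_patterns(path)` for production filtering.
- Butina clustering is O(n²) in memory and time; it is intended for
  reference sets of hundreds to a few thousand compounds, not millions.
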