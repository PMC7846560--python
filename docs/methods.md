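# Methods

This note documents the models, algorithms and numerical choices behind
`pvrscan`, in the order the pipeline applies them, together with what the
synthetic benchmark does and does not establish about real data.

## Structure model and parsing

Coordinate files (PDB or mmCIF, via gemmi) are reduced to a light model:
ordered chains of residues with explicit heavy atoms, hetero metal ions
(default element set Zn, Ni, Fe, Mn, Cu, Co, Mg, Ca), and the biological
assembly operators (mmCIF `pdbx_struct_assembly`/`pdbx_struct_oper_list`
or PDB `REMARK 350`). Residues are identified by *author* numbering plus
insertion code, matching how sites are discussed in the literature on
metalloenzymes (His54, Asp144, ...). Alternate conformations are resolved
to the highest-occupancy conformer, first on ties; this never changes the
residue count. Only model 1 of multi-model files is used. Missing
(unresolved) residues are simply absent from the CA trace and become
alignment gaps; a warning is logged so users can audit. Waters are never
carried into assemblies; metals are. The total non-hydrogen atom count of
the file (macromolecule + ligands + solvent) is retained for parser
sanity checks. For multi-chain entries the first polymer chain is used
unless configured otherwise.

## Pairwise alignment

Superposition is closed-form least squares (Kabsch, SVD of the 3×3
cross-covariance) with the reflection corrected so the result is always a
proper rotation; degenerate (rank < 2, i.e. collinear) point sets are
rejected. The aligner then follows the TM-align family scheme:

* **Seeding.** All (window_a × window_b) ungapped 40-residue window pairs
  (stride 5) are superposed in closed form on batched covariances; the
  three lowest-RMSD window pairs each seed an independent run and the
  best final TM-score wins. Any seed achieving the documented invariants
  would do; exhaustive window search is simple and deterministic.
* **Iteration.** Alternate (i) Needleman–Wunsch over the per-pair score
  `1/(1 + (d_ij/d0)²)` on the current superposition, gap penalty 0.6,
  terminal gaps free (so length-variable termini stay unaligned), and
  (ii) a Kabsch refit on the aligned pairs. Convergence is *identity of
  the aligned set* between iterations, capped at 30; a non-converged best
  iterate is returned with `converged=False`.
* **Scores.** TM-score `(1/L) Σ 1/(1+(d_i/d0)²)` with
  `d0 = 1.24 (L−15)^⅓ − 1.8` (the standard form), normalised by the
  reference length by default (`norm="shorter"` is available); the d0
  used inside the DP score is floored at 0.5 Å. RMSD is over all aligned
  CA pairs. Sequence identity is the percentage of aligned pairs with
  identical residue names — a structure-based quantity, not a sequence
  alignment.

The DP fill runs in a numba-compiled kernel (a plain-Python fallback
keeps the package functional without numba). Gap penalty 0.6 was chosen
to reproduce self- and rigid-case exactness and is exposed in the
configuration.

## Star multiple alignment

All statistics downstream are reference-relative, so a star topology
(every structure aligned pairwise to the reference) is sufficient and a
progressive MSA would add nothing but ambiguity. Columns are exactly the
reference residues. Target residues without a reference partner are kept
as **insertions attached between the two flanking columns** rather than
as ragged gap columns; this makes region length bookkeeping exact and
independent of any column-ordering convention. Residues before the first
or after the last reference-aligned residue attach to virtual N-/C-
terminal anchors, which is what makes terminal variable regions
representable. An externally produced gapped FASTA (e.g. from an MSA
server) can be imported instead, after exact sequence validation;
transforms into the reference frame are then recomputed by Kabsch on
fully occupied columns.

## Anchors and PVRs

For each fully occupied column the **column RMSD** is the root mean
square distance of the per-structure CA positions (each mapped by its
structure's one global transform into the reference frame) to the column
centroid. Measuring spread about the centroid treats all structures
symmetrically; pairwise-to-reference spread is the obvious alternative
and differs only by a constant factor under isotropic noise. Columns
missing any structure get +∞: a position absent from one structure is
not structurally aligned across all of them.

**Anchors** are columns with full occupancy and column RMSD strictly
below `rmsd_cut` (default 2.0 Å), optionally thinned to runs of at least
`min_run` consecutive columns (default 1; raising it suppresses isolated
anchors inside mobile loops). Under per-axis Gaussian noise σ the column
RMSD concentrates near `σ·√3·√((n−1)/n)`, about 0.46 Å at the benchmark
σ = 0.3 Å with n = 5 — comfortably below the 2 Å cut, which is why the
default is robust for genuinely rigid cores.

**PVR delineation.** Candidate regions are the maximal stretches strictly
between consecutive anchors — non-anchor columns plus the insertions
attached in that interval — and the two terminal regions bounded by a
single anchor. Per-structure lengths count that structure's own residues
and exclude the bounding anchor residues themselves. A region is reported
when its length range (max − min) strictly exceeds `range_cut` (default
10 residues). PVRs are numbered 1..k from N to C. Both thresholds being
strict follows directly from their definitions ("smaller than", "bigger
than"); boundary cases are covered by tests. Two monotonicity laws follow
from the definitions and are enforced by tests: raising `rmsd_cut` never
removes anchors, and raising `range_cut` never adds PVRs.

**Σ_abs** is, per structure, the sum over reported PVRs of the absolute
length difference to the reference's segment. It is zero for the
reference by construction and invariant under rigid motion of any input,
since it depends only on alignment topology.

Whether published per-family PVR lengths count the bounding anchor
residues inclusively is generally ambiguous; this implementation counts
exclusively, which can differ by a residue or two per boundary from
inclusive conventions.

## Subset selection

Before the multiple alignment, structures may be filtered by the rule
*keep if aligned length > 220 residues OR RMSD < 3 Å* versus the
reference (strict inequalities, both configurable). The pipeline records
dropped structures in the provenance rather than failing, and errors only
if nothing passes.

## Site geometry

* **Metal coordination.** For each metal, all polymer N/O/S atoms within
  the cutoff (default 3.0 Å, *inclusive*), grouped by residue. Typical
  Zn–N/O bonds are 1.9–2.3 Å; 3.0 Å tolerates refinement error without
  picking up second-shell atoms. The ligand element set is configurable.
* **SASA / interface area.** Shrake–Rupley with a deterministic Fibonacci
  sphere of 960 points per atom, probe 1.4 Å, over a pinned Bondi-style
  radius table (C 1.70, N 1.55, O 1.52, S 1.80, ...; default 1.80 for
  unlisted elements). Interface area is `(SASA(A) + SASA(B) −
  SASA(A∪B))/2` — half the buried surface, the PISA convention, which is
  the magnitude quoted for oligomer interfaces. The sampler is validated
  against the analytic two-intersecting-spheres cap formula (≤ 2% error
  at 960 points) and is rotation-invariant to within sampling drift.
* **Interface hydrogen bonds.** Heavy-atom criterion only: a
  donor-capable N/O in one chain within `d_max` (default 3.5 Å) of an
  acceptor-capable N/O in the other, capability from a fixed
  residue/atom dictionary (backbone N donor except proline, backbone
  O/OXT acceptor, standard side-chain assignments; Ser/Thr/Tyr hydroxyls
  and His ring nitrogens are amphoteric). No angle term is applied
  because X-ray models carry no hydrogens; each unordered atom pair
  counts once. Counts from distance-only criteria are inherently
  sensitive to `d_max` by ±1–2 bonds around typical interface sizes,
  which is why the cutoff is part of every report.

## Synthetic ensembles

The generator emulates exactly the statistical structure the PVR analysis
assumes, with known ground truth:

* **Core:** a smooth self-avoiding walk with exact 3.8 Å CA spacing
  (persistent direction, 2.5 Å excluded volume, restart on dead ends),
  shared by all structures; per-structure isotropic Gaussian noise
  (default σ = 0.3 Å per axis) is added to core CAs only.
* **Planted regions:** a segment of n residues between two consecutive
  core residues is laid on a circular arc of n+1 equal 3.8 Å chords
  joining its flanks — the unique circle through both flanks with the
  required chord subdivision — in a plane rotated about the flank–flank
  axis. Orientations are scanned from a random start until the arc keeps
  ≥ 2.5 Å clearance from the non-local core (the ±2 residues around the
  junction are the loop's own chain neighbours and are exempt); closure
  and spacing are exact by construction, and the arcs of different
  structures differ in both length and orientation, making the regions
  structurally divergent the way real inserted loops are. If no
  orientation is clash-free the generator raises rather than emitting a
  clashed ensemble.
* **Extras:** optional planted metal ions (at the centroid of chosen core
  CAs) and C_n-symmetric multimer copies; structures are emitted CA-only
  (valid PDB, and all the alignment stack consumes). Atom-level analyses
  (H-bonds, SASA, coordination) are tested on separately constructed
  micro-fixtures with real atom types instead.
* **Determinism:** one seeded PRNG drives everything; the same spec and
  seed give bit-identical files.

Default benchmark conditions: 5 structures, 250-residue core in four
blocks, three planted regions with per-structure lengths (0,4,8,11,15),
(0,6,12,19,25), (0,10,20,30,40) — ranges 15/25/40 — σ = 0.3 Å, random
rigid motions. These sizes mirror a realistic single-domain comparison
(MβL-fold chains are ~230–300 residues; inserted specialisation loops and
domains range from ~10 to >200 residues).

**What passing the synthetic benchmark shows — and does not.** It shows
the pipeline recovers planted indel blocks exactly when the core is truly
rigid, noise is isotropic and homogeneous, and variable segments are
compact loops. Real ensembles violate all three in degree: cores flex
(hence the configurable `rmsd_cut`), noise is structured (domain hinges,
crystal contacts), variable regions can be structured domains that
partially superpose, and alignment servers differ in their treatment of
ambiguous registers. Reproduction of published PVR tables on real
structure sets is therefore validated separately
(`scripts/pdb_validation.py`) with tolerances, not asserted by the unit
suite.

## Pipeline, determinism, provenance

`run_pipeline` chains parse → pairwise align → subset filter → star MSA →
anchor profile → PVR table → Σ_abs → geometry reports. Given the same
configuration the outputs are byte-identical. Every run writes a
provenance record (package version, thresholds, input checksums, dropped
structures and reasons); per-structure failures do not abort the batch,
but a reference failure is fatal. The geometry stage runs when an
assembly id or explicit chain pairs are configured.

## Known limitations

* The aligner is rigid-body: hinge-bent homologs superpose on the larger
  rigid part and the smaller domain inflates column RMSDs; align domains
  separately or raise `rmsd_cut`.
* Star topology means residues aligned between two non-reference
  structures but not to the reference are treated as independent
  insertions; PVR statistics are unaffected (they are reference-relative
  by definition), but the MSA is not a general-purpose multiple
  alignment.
* TM-scores of external servers are reproduced only approximately; their
  heuristics (seeding, gap schemes, final-superposition subsets) are not
  published to the digit.
* Hydrogen-bond counts without hydrogens or angle terms overcount
  non-linear contacts slightly; treat counts as criterion-conditional.
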