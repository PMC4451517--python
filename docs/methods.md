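# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `lipidsite`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Profile construction

A profile (PSSM) over the 20 canonical residues (fixed column order
`ACDEFGHIKLMNPQRSTVWY`) is built from an aligned family as

    score[p][a] = log2( (c_pa + w·b_a) / ((N_p + w)·b_a) ),

where `c_pa` counts residue `a` at column `p`, `N_p` counts non-gap rows
there, `w` is the pseudocount weight and `b` the background distribution.

* **Pseudocount** `w = 1.0` by default, with BLOSUM62 marginal background
  frequencies. One unit of background mass keeps zero-count cells finite
  without dominating observed counts; `w` and `b` are both arguments.
* **Storage resolution** 0.5 bit, halves rounded away from zero. This
  mimics integer-like PSSM files while preserving the sign of weak
  preferences, which the identity/positive column classification depends
  on.
* **Floor.** With `w = 0` a zero count gives log2(0); cells are floored at
  −16 half-bit units so every cell stays finite. −16 bits is far below any
  score that could participate in a positive local alignment, so the floor
  only regularizes, never ranks.
* **Gaps.** Gap characters are excluded from counts; all-gap columns are
  dropped and positions compacted. The profiles model ungapped binding
  regions, so a column nobody occupies carries no information.
* **Ambiguity codes** (B, Z, X) are rejected rather than redistributed:
  the downstream classification needs definite residues.
* Consensus is the per-position arg-max of the score row, ties broken by
  alphabet order.

The ASCII library format is one header (`>name length`) plus one
tab-separated row per position (`pos consensus 20 scores`, 1-based
positions, one decimal). Write∘read is the identity at that precision.

## Library scanning

The query is aligned against every profile by Smith–Waterman with affine
gaps; the substitution score of query residue `q` at profile position `p`
is the PSSM cell itself. The two named parameter sets — (BLOSUM62,
GOP 10, GEP 0.5) and (BLOSUM45, GOP 11, GEP 1) — contribute their gap
penalties and label the two passes; the PSSM already encodes substitution
preferences, so the BLOSUM matrices are not used as substitution scores.
A gap of length `k` costs `GOP + k·GEP`.

Design choices that were genuinely open:

* **Gap-state transitions.** The dynamic program allows opening a gap in
  one sequence immediately after closing one in the other. Adjacent
  insertion/deletion pairs are legal (if rarely optimal) local alignments,
  and the exhaustive enumeration oracle in the test suite scores them, so
  the DP searches the same space.
* **Tie-breaks** are fully deterministic: among equal-scoring end cells
  the smallest (query_end, profile_end) wins; traceback prefers stop >
  diagonal > gap-in-query > gap-in-profile, and closing a gap run over
  extending it. Determinism matters because downstream scores sum over
  alignment columns.
* **Column classes.** *Identity* means the query residue equals the
  profile consensus; *positive* means a strictly positive PSSM score for
  a non-identity residue — the profile analogue of a BLOSUM-positive pair.
* **Threshold.** The original screen's positivity criterion is not
  reproducible, so the score threshold is exposed (default 0) and empty
  score-0 alignments are never reported: "positive alignment" means a
  strictly positive local score.
* One optimal alignment per (profile, parameter set); no suboptimal
  alignments are enumerated.

## Positional scoring and region calling

Raw scores accumulate 2 per identity column and 1 per positive column
over all reported alignments. Normalization follows three steps: mean
centring (`NS = SC_raw − total/length`), the mean over positively
normalized residues (`ASC = SUM_PNS / NR`), and length normalization
(`NORM = ASC·100/length`). Two conventions are fixed here:

* The second and third steps are treated as consuming the same quantity
  (the average query score), although the defining and consuming symbols
  differ in the source notation.
* When no residue scores above the mean (a constant raw track) the
  positive count is zero and both summary scores are defined as 0 rather
  than NaN — constant tracks are legitimate degenerate inputs.

Region calling takes maximal runs of `NS > 0`, merges runs separated by
at most `merge_gap` (default 2) non-positive residues, and drops merged
runs shorter than `min_length` (default 5). The defaults are artifact
choices sized so that a ~20-residue enriched stretch with small internal
dips is reported as one region; both are configurable. Regions are ranked
by mean normalized score; the peak is the arg-max (smallest index on
ties).

Internally all coordinates are 0-based half-open; every file export and
report is 1-based inclusive (BED exports excepted, which follow the BED
convention) to match structure residue numbering. Structure painting
writes `NS` into PDB B-factor columns 61–66, clamped to the printable
range [−99.99, 999.99], touching nothing else; every ATOM record of the
selected chain must map into the track via the explicit residue-number
offset, otherwise the unmatched residues are listed in the error.

## Pose clustering

In-place RMSD (atoms matched by list order, no superposition, no symmetry
mapping — fatty-acid chains are asymmetric, and the docking convention
this mirrors clusters without refitting). Clustering is greedy in
ascending energy order: the best unassigned pose seeds a cluster and
absorbs every unassigned pose with RMSD strictly below the cutoff
(default 2 Å). The seed, being the cluster's energy minimum, is its
representative. Energy ties break by pose id, which makes the whole
procedure invariant to input order. Occupancies are member counts over
the total and sum to 1 exactly.

## Trajectory metrics

Trajectories are ordered frames over a fixed atom table, read from
multi-model PDB or XYZ. Atom-count or element drift across frames is a
parse error naming the frame. Named selections (protein, ligand, heme,
dioxygen, water-oxygen) are derived from residue names for PDB input;
XYZ carries no residue information and gets empty selections.

* **Superposition** is a per-frame Kabsch least-squares fit of the
  protein heavy atoms (configurable selection, ≥ 3 atoms) onto a
  reference frame. Ligand metrics presuppose a protein-fixed frame, so
  the pipeline superposes by default; the flag is exposed because
  generated trajectories are already protein-fixed and refitting onto
  jittered atoms adds lever-arm noise for distant atoms.
* **RMSF** uses heavy atoms only by default; coordinates are taken
  relative to the first frame before averaging so a static trajectory
  yields exact zeros. A single-frame trajectory is an error, not zero:
  silent zeros mask truncated inputs. Per-residue values are means over
  the residue's atoms.
* **H-bonds.** Default criteria: donor–acceptor heavy-atom distance
  ≤ 3.5 Å and D–H···A deviation from linearity ≤ 30°, common MD practice;
  both are configurable and echoed in output headers. When the topology
  has no hydrogens the check is distance-only; when it has, a hydrogen
  within 1.25 Å of the donor must satisfy the angle. Occupancy is the
  percentage of frames with at least one satisfied pair.
* **Contacts**: per protein residue, the percentage of frames with any
  heavy-atom pair (residue, ligand) within the cutoff (default 4 Å).
* **Penetration depth** is the displacement of a named terminal carbon
  (e.g. C16 for palmitate) between first and last frame. The atom is
  named by the user, not inferred from connectivity, because PDB-level
  topologies lack reliable bond records. This metric is deliberately
  order-sensitive; all others are frame-order invariant.
* **Pocket hydration** counts water oxygens within a radius (default
  3.5 Å) of any site atom, per frame.
* **Neutralizing ions**: `n_Na = pairs + max(0, −q)`,
  `n_Cl = pairs + max(0, q)` for solute charge `q`, which always yields
  net charge zero.

## Synthetic data

The generators produce inputs whose target values are planted, so tests
compare estimator output against a recorded ground truth rather than
against published numbers that depend on undeposited data.

* **Sequence side.** A family is `n` noisy copies of a motif, each
  position independently substituted with probability `rate` (< 0.5 so
  the motif stays the expected column majority). The benchmark defaults —
  motif 20, 50 sequences, substitution rate 0.1, background 150 — are the
  study conditions for the recovery property; the 50-row family is
  partitioned into 10 disjoint 5-row sub-alignments, one PSSM each, so
  the scan exercises a multi-profile library rather than a single matrix.
* **Pose side.** Two-blob sets (90/10 members, centers 10 Å apart, spread
  0.1 Å) mirror a dominant-plus-minor docking landscape; exact recovery
  is guaranteed when centers are farther apart than 2·(cutoff+3·spread).
* **Trajectory side.** Frames are a template plus per-atom Gaussian
  jitter; planned atoms are excluded from jitter and placed exactly, so
  occupancies and displacements are constructed, not sampled. The H-bond
  plan has two variants: exact (`round(f·n)` bound frames — separates
  estimator correctness from sampling error) and Bernoulli (independent
  per-frame binding — the stochastic two-state case, subject to binomial
  error). Each generator is a pure function of its seed; one random
  stream per call, no global state. Reproducibility means "same seed,
  same output within this implementation".

What the generators do **not** emulate: physically consistent geometry,
correlated motions, force-field energetics, solvent structure, or
realistic sequence phylogeny. Passing tests therefore demonstrate that
the estimators recover planted values under idealized noise, not that
the pipeline's biological predictions are correct on real data.

## Problem sizes and tolerances

The suite's problem sizes are chosen to make the statistical checks sharp
at desk scale: 200 random ≤8×8 instances for the alignment oracle (exact
equality); 1000 random tracks for normalization conservation (1e-9·L) and
summary recomputation (1e-12); 100 seeded replicates for motif recovery
(top-region Jaccard ≥ 0.5 in ≥ 95); 20 000 frames × 50 atoms for the RMSF
σ√3 check (2%); 1000-frame trajectories × 100 seeds for occupancy
recovery (exact for constructed, 3 binomial SE for Bernoulli); 100 random
sets for clustering invariants and file round-trips; 1e-6 Å for
constructed penetration depths.

## Known limitations

* The scanner aligns the query against PSSM cell scores; a variant that
  aligns against the consensus under BLOSUM scores is conceivable from
  the method's description and is noted but not implemented.
* No statistical significance is attached to enriched regions; the score
  track is descriptive, as in the original screening approach.
* Pose RMSD has no symmetry correction; symmetric ligands would need one.
* Binary MD formats (DCD/XTC) are out of scope; convert to multi-model
  PDB or XYZ first (MDAnalysis reads this package's PDB output directly).
* The greedy energy-ordered clustering reproduces the documented
  behaviour of the docking tool it mirrors, but that tool's exact
  reclustering linkage is not published; only the cutoff criterion is
  guaranteed to match.
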