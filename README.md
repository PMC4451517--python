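# lipidsite

Profile-library prediction of fatty-acid-binding sites on globins, with the
quantitative post-processing used around it: docking-pose RMSD clustering
and MD-trajectory metrics.

## The problem

Myoglobin (Mb) binds long-chain fatty acids such as palmitate and oleate,
but Mb is an all-helical heme protein while the canonical fatty-acid
binders (the FABP family) are beta-barrels, so structure superposition
cannot locate the binding site. A sequence-profile route works instead:
a library of position-specific scoring matrices (PSSMs) built from the
fatty-acid-binding regions of FABP-family proteins is scanned against the
globin sequence, and residues that keep being hit by high-scoring local
alignments mark the candidate pocket. `lipidsite` implements that scanning
and scoring machinery, plus the desk-side analyses applied to docking and
molecular-dynamics output around such a site: pose clustering at an RMSD
cutoff, heavy-atom RMSF, hydrogen-bond and contact occupancies, alkyl-tail
penetration depth, pocket hydration, and the neutralizing-ion bookkeeping
for solvated systems.

It is a library first: the importable API plus the narrative scripts in
`examples/` are the main interface, with a thin `lipidsite` CLI for shell
use.

## The method

**Profiles.** A PSSM is built from an aligned family by the standard
count → pseudocount → log-odds construction,

```
score[p][a] = log2( (c_pa + w·b_a) / ((N_p + w)·b_a) )
```

with counts `c_pa`, pseudocount weight `w` (default 1.0), BLOSUM62
background frequencies `b_a`, and `N_p` non-gap rows at position `p`;
scores are stored at 0.5-bit resolution.

**Scanning.** The query is locally aligned (Smith–Waterman, affine gaps;
a gap of length k costs `gap_open + k·gap_extend`) against every profile
under two parameter sets, (BLOSUM62, GOP 10, GEP 0.5) and (BLOSUM45,
GOP 11, GEP 1), scoring each query residue against the PSSM column.
Aligned columns are classed *identity* (query equals the profile
consensus) or *positive* (PSSM score for the query residue > 0).

**Positional score.** Each residue accumulates 2 per identity and 1 per
positive substitution over all alignments (`SC_raw`), then:

```
NS_residue    = SC_raw − SUM_totalscore / LEN_query        (centre on the mean)
ASC_query     = SUM_PNS / NR_residue                       (mean positive score)
NORM_avgscore = ASC_query · 100 / LEN_query                (length-normalized)
```

Runs of positively normalized residues are called as enriched regions;
the top region is the predicted binding stretch and its peak the key
residue.

**Pose clustering.** Docked poses are grouped greedily in ascending-energy
order: each unassigned lowest-energy pose seeds a cluster and absorbs all
poses within the cutoff (default 2 Å, in-place RMSD, no refitting); cluster
occupancies summarize the docking landscape.

**Trajectory metrics.** Frames are superposed on protein heavy atoms
(Kabsch), then: `RMSF_i = sqrt(⟨|r_i(t) − ⟨r_i⟩|²⟩)` over heavy atoms;
H-bond occupancy is the percentage of frames with donor–acceptor distance
≤ 3.5 Å (and D–H···A within 30° of linear when hydrogens are present);
contact occupancy is per-residue any-heavy-atom-pair within a cutoff;
penetration depth is the first-to-last-frame displacement of the ligand's
terminal carbon; pocket hydration counts water oxygens within a radius of
the site.

Every stage has a seeded synthetic generator with known ground truth
(planted motifs, two-blob pose sets, trajectories with constructed
occupancies and displacements), so the whole pipeline is testable without
external data.

## Worked example

`python examples/02_site_scan.py` runs the full planted-motif pipeline:

```
query length 170, planted motif at residues 4-23 (1-based)
alignments above threshold: 20 (library of 10 profiles x 2 parameter sets)
total raw score 788; normalized average score 20.45
top enriched region: residues 4-23 (mean normalized score 34.76), peak at residue 4
peak inside the planted interval: True
```

The 20-residue motif spliced into a 170-residue random query is recovered
exactly as the top enriched region — the synthetic analogue of the
enriched 31–50 stretch (peak Lys45) seen when Mb is scanned against an
FABP profile library. `python examples/04_trajectory_metrics.py` does the
same for the trajectory side:

```
H-bond occupancy        : 22.4%  (planted 22.4%)
tail penetration depth  : 6.92 A  (planted 6.92 A)
contact LEU1            : 60.0% of frames
contact VAL3            : 30.0% of frames
...
neutralizing ions       : 26 Na+ / 25 Cl-  (25 salt pairs, -1 e solute)
```

Each printed value is an estimator's output next to the value the
generator planted; agreement shows the metric recovers its target. The
other examples cover profile construction and file round-trips (01), pose
clustering (03), and structure painting (05).

## CLI

```
lipidsite build-library FAM1.fasta FAM2.fasta -o library.pssm
lipidsite scan --query mb.fasta --library library.pssm -o alignments.tsv
lipidsite score --query mb.fasta --library library.pssm --out-dir out/
lipidsite cluster-poses --poses poses.pdb --energies energies.tsv -o clusters.tsv
lipidsite traj --trajectory run.pdb --tail-atom name:C16 --out-dir out/
lipidsite simulate --kind trajectory --seed 1 --out-dir sim/
```

Exit codes: 0 success, 2 input error, 3 parse error, 4 degenerate input.
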