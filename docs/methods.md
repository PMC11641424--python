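# Methods

This note documents the models, parameter choices and numerical decisions
behind `rass`, in the spirit of a methods appendix: what each stage
computes, why its defaults are what they are, and what the synthetic test
system does and does not establish.

## Randomized alanine sequence scanning

The scan is a two-stage stochastic process applied independently to every
replica: for each eligible position *i*, draw
*p_i* ~ Uniform(p_low, p_high), then substitute position *i* with alanine
with probability *p_i*. The marginal substitution indicator is therefore
Bernoulli with success probability (p_low + p_high)/2 — 0.10 at the
defaults p_low = 0.05, p_high = 0.15. Alanine is the canonical choice for
mutagenesis-style perturbation: small enough to avoid fold disruption
while still degrading the coevolutionary couplings an MSA-based predictor
reads.

Decisions:

* **Replica count** defaults to 45. The protocol calls for "multiple"
  scans in the low tens; 45 sits in the middle of that range and the
  count is exact and configurable.
* **Alanines in the source stay eligible.** An A→A substitution is
  recorded but is a string no-op; this keeps the process uniform over
  positions rather than conditioning on sequence content.
* **`X` (unknown residue) is never substituted** — replacing an unknown
  with alanine would fabricate sequence identity.
* **Region-restricted scans** are supported as an explicit 0-based
  position set, for perturbing only a functional region.
* **Reproducibility**: replica *r* uses its own PRNG stream seeded
  `base_seed + r` (NumPy PCG64), so partial re-runs regenerate identical
  replicas.

## MSA handling and shallow subsampling

A3M convention: lowercase letters are insertions relative to the query
and occupy no alignment column; `-` is a deletion. After removing
lowercase states all rows must have equal length (validated on read);
lowercase states survive a read→write round trip byte-identically.

Subsampling draws the `max_seqs:extra_seqs` partition uniformly without
replacement over non-query rows; the query is always forced into the
attention set, since a prediction without the query row is meaningless.
If the MSA is no deeper than `max_seqs`, the attention set is all rows
and the extra set is empty. The default preset is 16:32, the shallow
setting that maximizes ensemble diversity; deeper presets
(32:64 … 512:1024) are plain configuration values.

Each masked replica can either be substituted as the query row of one
shared MSA (default — gap structure of the original query row is
preserved) or be given its own pre-built per-replica MSA from disk. Both
are legitimate readings of the protocol; the switch is
`replica_msa_mode`.

## Predictor backend contract

One request yields exactly
`num_models × num_seeds × (num_recycles + 2)` conformers: intermediate
structures at recycles 0…R plus one final refined structure per model and
seed. With the production settings (5 models, 12 recycles, 1 seed) that
is 5 × 14 = 70 structures. The final structure is flagged distinctly in
provenance and, in the mock, is an independent draw rather than a copy of
the last recycle (whether real predictors duplicate it is
implementation-defined; treating it as independent is the conservative
choice for count bookkeeping).

The mock backend samples a two-component mixture: basin A with
probability `weight_a` (default 0.5), else basin B, plus isotropic
Gaussian coordinate noise (`noise_scale`, default 0.3 Å). Synthetic
confidence is `pLDDT_i = clip(100·exp(−d_i/σ), 30, 100)` with *d_i* the
Cα displacement from the basin and σ = 2.0 Å, making confidence
anti-correlated with displacement the way real predictor confidence
tracks local mobility. Note the scale this implies: at noise 0.3 Å the
typical Cα displacement is ~0.5 Å, so mock pLDDT sits in the high 70s —
below the strict 85/70% reranking gate. The gate is meant for real
predictor output, where confident cores genuinely sit at pLDDT 85–90;
applying it to a noisy mock ensemble legitimately retains nothing.

The external adapter shells out to `colabfold_batch` with the subsampled
A3M and the run options, and surfaces subprocess diagnostics in the
raised error; no weights are bundled and the pipeline is mock-first.

## Structures, correspondence, pocket

Structures are biotite `AtomArray`s read from PDB/mmCIF with altlocs
resolved to highest occupancy, heteroatoms retained but flagged, and
insertion codes preserved. pLDDT is read from the Cα B-factor (one value
per residue; out-of-range values are reported as-is with a warning, and
residues without Cα are skipped with a warning).

Residue correspondence between two structures is by **author residue
number + insertion code** with an optional declared offset, restricted to
residues with Cα resolved in both. Sequence-alignment-based matching is
deliberately out of scope: apo/holo benchmark pairs share constructs, and
numbering + offset covers them auditable-y. Fewer than 30 matched
residues raises an error (a superposition on fewer is unreliable); the
floor is a parameter for small synthetic systems.

The binding pocket is defined on the holo structure: residues with any
protein heavy atom within **4.5 Å (inclusive)** of any ligand heavy atom.
Waters are never ligands; `ligand="auto"` picks the largest non-water
heteroatom group. The cutoff is recorded in every analysis summary so
pocket-dependent numbers are auditable.

## Superposition and similarity metrics

* **Kabsch superposition**: SVD of the cross-covariance matrix with a
  determinant sign correction, so reflections are never returned.
  Degenerate (rank < 3) point sets are solved but flagged. The test suite
  cross-checks against an independent Horn quaternion-eigenvalue solver
  to 1e-8 Å.
* **RMSD** is fitted and reported on the same atom selection (`ca`,
  `backbone` = N/CA/C/O, or `pocket_sidechain_heavy`); atoms missing on
  either side are dropped pairwise. `backbone` is the default atom set
  for pair characterization.
* **TM-score** uses `d0 = 1.24(L_ref − 15)^{1/3} − 1.8`, floored at
  0.5 Å. Because the residue equivalence is given, no alignment search is
  needed; the maximization over superpositions is fragment-seeded
  (full length, halves, sliding windows of ~L/8 with half-window stride),
  each seed refined by iteratively re-fitting on residues within d0
  (relaxed in 0.5 Å steps until ≥ 3 residues qualify) until the selected
  set repeats. Ties across seeds resolve to the highest score. This
  reproduces TM-align behaviour on rigid-plus-hinge comparisons.
  Normalization defaults to the holo reference length; both
  normalizations are reported in pair characterization since either
  convention appears in practice.

## Ensemble analysis

* **Reranking**: keep conformers whose fraction of residues at
  pLDDT ≥ 85 exceeds 0.70, ordered by descending fraction, ties by mean
  pLDDT. With threshold 0 every conformer qualifies (the retained *set*
  is the identity; ordering is still by the tie-break).
* **State labels**: apo if `rmsd_to_apo + margin < rmsd_to_holo`, holo in
  the mirrored case, else intermediate. The margin (0.5 Å) sits below
  typical coordinate noise, so "intermediate" genuinely means
  no clear preference rather than measurement jitter.
* **Clustering**: all-vs-all RMSD with each pair independently superposed,
  then agglomerative clustering with Ward linkage on that matrix, and
  silhouette scores (on the same distances) for k = 2…10; chosen k
  maximizes silhouette, ties toward smaller k (parsimony). Caveat, stated
  deliberately: Ward linkage assumes Euclidean geometry and pairwise RMSD
  is not a Euclidean embedding; this follows standard conformer-clustering
  practice and is validated here against a threshold-cut partition oracle
  on separated basins. An all-identical ensemble (max distance < 1e-6 Å)
  raises a degenerate-ensemble error advising k = 1.
* **Distributions** use fixed grids so runs are comparable: histogram bin
  widths 0.25 Å (RMSD, anchored at 0), 0.025 (TM on [0,1]), 2.5 (pLDDT on
  [0,100]); KDE is Gaussian with Silverman bandwidth on a 512-point grid,
  omitted when fewer than two distinct values exist. Box plots use the
  Tukey convention (1.5 × IQR whiskers).
* Spearman correlations between mean pLDDT and RMSD-to-reference are
  flagged undefined (NaN) for constant inputs or single conformers.

## Synthetic two-basin system

`rass.synthetic` builds an idealized hinge protein: Cα positions on an
α-helical curve (1.5 Å rise, 2.3 Å radius, 100°/residue), N/C/O/CB placed
in a local chain frame, poly-alanine, one chain, and a closed form
produced by rotating the second domain about an axis through the hinge
Cα. The closing angle is solved by bisection so the open/closed backbone
RMSD equals a requested value (3.5 Å default, the large-hinge regime of
real apo/holo pairs) to 0.001 Å. The closed form optionally carries a
4-atom pseudo-ligand in the interdomain cleft so pocket definition and
pocket side-chain RMSD are exercised end to end.

What it emulates: a two-state conformational equilibrium with rigid
domains, per-residue confidence that decays with displacement, and exact
ground-truth basin labels. What it does not: real secondary-structure
packing, side chains beyond CB, missing residues or altlocs in
references, correlated (non-isotropic) coordinate error, and any
relationship between sequence content and structure (the mock ignores
the masked sequences). Tests passing on this system therefore establish
the *machinery* — superposition, metrics, classification, clustering,
bookkeeping — not predictive performance of any real backend on real
proteins.

## Problem sizes

Default test and acceptance runs use 50–80-residue synthetic systems,
60–70-conformer ensembles and 3–5 scan replicas in the end-to-end
pipeline tests; these sizes exercise every code path with comfortably
separated basins. Metric cross-checks run on random point sets up to
N = 500. Published crystal-pair comparisons (the `pairchar` tests) need
RCSB downloads and are the one part of the suite that cannot run
offline.

## Known limitations

* Residue matching by numbering + offset does not handle apo/holo pairs
  deposited with unrelated numbering schemes; those need an external
  renumbering step first.
* TM-score here assumes the correspondence is correct; it will not rescue
  a misassigned equivalence the way full TM-align's alignment search can.
* The ColabFold adapter parses the conventional output file naming; exotic
  layouts may need the provenance fields corrected downstream.
* Ensembles are analyzed in memory; tens of thousands of conformers would
  need a streaming pairwise-RMSD implementation.
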