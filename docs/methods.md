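# Methods

This note documents the models, conventions and numerical choices behind
`tcrpmhc_eval`, and what the synthetic cohorts do and do not establish.

## Structure model and correspondence

A complex is a list of chains with roles TCRA, TCRB, PEPTIDE, MHC_A and
(class II only) MHC_B. Parsing keeps every residue that has a Cα atom, in
file order; waters and Cα-free ligands are dropped, hetero or modified
residues with a Cα are kept as amino acid `X`. Alternate locations resolve
to the first occurrence. Chains are never renumbered and coordinates are
in Å throughout.

Native↔prediction correspondence is ordinal within each role and requires
identical sequences (`X` matches only `X`). Because the pairing is
ordinal, author numbering and insertion codes never enter metric math;
residues are ordered by (author number, insertion code) as encountered.
IMGT numbers for the TCR chains are always supplied as an input table —
produced by an external numbering tool or by the synthetic generator —
never computed internally, since germline-alignment numbering is a
separate problem with its own tooling.

pLDDT arrives by two routes: the B-factor column of prediction PDBs (the
folding-model convention) and an optional JSON sidecar. Both 0–1 and
0–100 dialects circulate, so values that are all ≤ 1.0 are multiplied by
100 with a warning; values outside [0, 100] after that are an error. When
both sources are present the JSON wins, with a consistency warning if
they disagree by more than 1.0 anywhere.

## Superposition metrics

Kabsch superposition is the closed-form SVD solution with the determinant
correction that excludes reflections. Fewer than three points, or
(near-)collinear point sets (second singular value below 1e-8 of the
first), are rejected as degenerate rather than silently returning one of
the infinitely many optima.

TM-score uses d0 = 1.24·(L_N − 15)^⅓ − 1.8 with a 0.5 Å floor (the
formula is negative for L_N ≤ 21; short regions such as 9-mer peptides
would otherwise be undefined). L_N defaults to the native region length.
The score is maximised over superpositions by seeding with Kabsch on all
pairs and then, for each cutoff in {d0, 2d0, 4d0, 8d0}, repeatedly
re-fitting on the residues within the cutoff until the kept set is stable
(at most 20 iterations), scoring all residues each round and keeping the
best score seen. Correspondence is fixed, so no alignment search is
involved; this mirrors the refinement loop of the reference TM-score
procedure at fixed alignment.

Region metrics support three frames, because "CDR3 RMSD" is ambiguous
without one: `local` superposes on the region itself (used by default for
whole-component regions: TCR, peptide, MHC — component modelling
accuracy); `framework` superposes on the non-CDR residues of the
containing TCR chains and then measures the loop without re-fitting (the
default for CDR regions — it measures loop placement relative to a
correctly-posed framework); `global` superposes on all Cα. The frame per
region is a configuration knob, since the right choice depends on the
question being asked.

## DockQ and quality classes

The two-body reduction is receptor = TCR (α+β), ligand = peptide + MHC,
the natural docking interface for these complexes; the split is
configurable, and scoring the pMHC sub-complex (MHC vs peptide) uses the
same code path with a different split. Fnat contacts use all-atom < 5 Å
when full atoms are present on both sides, and Cα-only < 8 Å otherwise —
both modes are first-class and the mode used is recorded in every output
row, because Cα-only synthetic data and mixed-completeness real data must
not be silently compared at different cutoffs. The iRMS interface is
defined on the native structure only (10 Å cross-body cutoff, both pair
members kept), which makes iRMS comparable across candidates of the same
complex. The combination constants 1.5 Å (iRMS) and 8.5 Å (LRMS) and the
class thresholds 0.23 / 0.49 / 0.80 follow the standard DockQ/CAPRI
calibration; all class intervals are half-open with the boundary value
belonging to the better class.

## Confidence aggregation, reranking, concordance

Regional pLDDT is an unweighted mean over the region's residues. CDR3
pLDDT pools CDR3α and CDR3β residues into a single mean rather than
averaging the two per-loop means; with unequal loop lengths these differ,
and the pooled form is the definition adopted here.

Reranking sorts candidates descending by the chosen signal with ties
broken by the source model's original rank — deterministic, and
conservative in that a tie never demotes the model's own choice. Top-1
success is defined as the first-ranked candidate reaching the class lower
bound (0.49 medium, 0.80 high). The rank/quality consistency statistic is
the mean over complexes of Kendall τ-b between candidate rank and −DockQ;
τ-b is chosen for its tie handling, and is this package's
operationalisation of "ranking aligns with quality" — no canonical
statistic exists for that phrase. Pearson p-values are the standard
two-sided t-test with n − 2 degrees of freedom (scipy's implementation).

Mutation concordance uses ΔΔG = ΔG_mut − ΔG_wt (negative = affinity
gain). A pair is concordant when the confidence signal moves against
ΔΔG. Δsignal = 0 counts as non-concordant — a flat signal has failed to
reflect the change, and applying the same standard to every signal keeps
comparisons fair. ΔΔG = 0 pairs are excluded with a warning (no defined
direction). Summaries carry per-direction counts so that several datasets
pool by summing counts, which is how the pooled percentage is defined.

## Curation rules

All inequalities are strict exactly as stated: resolution > 3.5 Å
excluded, release date must be strictly after 2021-09-30, sequence
exclusion needs > 40 % identity on every chain against one single
training complex (not mixed across several), structure exclusion needs
TM-score > 0.9. Queries with no TM rows are kept with a warning (absence
of evidence). Redundancy removal keeps the first complex per unique
chain-sequence tuple in input order — a deliberate, reproducible tie
rule, since none is prescribed. Cross-class (query, train) pairs with no
corresponding chains are treated as non-matching and logged. The external
alignment tools that produce similarity tables are never invoked; their
outputs are inputs.

## Synthetic generator

The generator's defaults are the study conditions for every statistical
test in the suite, chosen once:

| parameter | default | rationale |
|---|---|---|
| chain sizes | TCRα/β 50, peptide 9, MHC 60 | variable-domain-scale chains; 9-mers are the most prevalent peptide length in class I benchmarks |
| K candidates | 5 | the candidate count of the folding models being emulated |
| rigid perturbation | rotation 0–15°, translation 0–10 Å | spans the full quality range from high to incorrect |
| per-residue jitter σ | 0.25 Å | sub-Å local noise on top of the rigid error |
| CDR3 distortion | 0.4 × rigid shift | couples loop error to docking error, as observed for real predictors |
| c_plddt / c_rank | 0.9 / 0.5 | pLDDT is modelled as the better-calibrated signal; the ranking score is noisier |
| mutation plant | n = 81, p = 0.753, ties 5 % | cohort-scale mutation set with a recoverable concordance rate |

Geometry: all chains are ideal helical Cα traces (2.3 Å radius, 1.5 Å
rise, 100°/residue → ≈ 3.8 Å spacing) — an MHC groove of two antiparallel
strands at y = ±8, the peptide between them, the TCR framework helices
above at z ≈ 13.5, and the two 13-residue CDR3 loops (IMGT 105–117) on
circular arcs dipping to ≈ 5.3 Å above the peptide, so the native
TCR–pMHC interface has ≥ 10 Cα contacts (verified at generation time).
TCR chains of ≥ 41 residues also cover the CDR1 (27–38) and CDR2 (56–65)
IMGT windows. A 0.05 Å seeded jitter breaks exact symmetries.

Candidates apply a rigid rotation (random axis through the TCR centroid)
plus translation to the TCR body, a CDR3-local displacement proportional
to the drawn translation magnitude, and i.i.d. Gaussian jitter. Per-residue
confidence is `plddt_i = clip(100·exp(−e_i/2)·c + 100·u_i·(1−c), 0, 100)`
with e_i the residue's true displacement; the ranking score is
`c_rank·exp(−E/5) + (1−c_rank)·u` with E the RMS displacement of native
interface residues. Exponential decay maps error to a bounded score with
the right monotonicity; it is a modelling choice, not a claim about any
real confidence head.

**What passing tests show — and don't.** The synthetic cohorts establish
that the pipeline's arithmetic and orderings are correct and that the
analyses recover planted structure (correlations, reranking gains,
concordance rates). They do not establish anything about real folding
models: synthetic pLDDT is coupled to error by construction, the decoys
are rigid-body perturbations rather than genuine misfolds, the traces are
Cα-only (so DockQ runs in its documented Cα mode), and there is no
side-chain packing or energetics. Real-cohort magnitudes (correlation
strengths, success-rate gains) require real predictor outputs.

## Problem sizes and numerical details

Cohort-level tests use 100-complex single-candidate cohorts for the
correlation analyses and 100 replicates of 12-complex × 5-candidate
cohorts for the reranking property; the acceptance script uses the same
cohort sizes with 20 reranking replicates. Degenerate inputs fail loudly:
empty regions, missing pLDDT on a selected residue, zero native contacts,
< 3 interface residues, zero-variance correlation inputs, and all-tied
candidate sets are all explicit errors or logged skips, never silent
zeros. TSV is the interchange format for every table; evaluation records
round-trip losslessly through their TSV form at 6-decimal precision.

## Known limitations

* No mmCIF parsing, no automatic chain-role inference, no automatic IMGT
  numbering, no structure repair.
* TM-score is computed at fixed correspondence; it is not an
  alignment-searching TM-align, and no lDDT is computed.
* Multi-interface assemblies beyond the two-body reduction (and per-chain-
  pair DockQ averaging) are out of scope.
* The ranking-score field is treated as an opaque comparator; no attempt
  is made to reproduce any model's internal ranking formula.
* Concordance is a direction statistic only; the package deliberately
  does not regress ΔΔG magnitudes from confidence signals.
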