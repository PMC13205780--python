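# Methods

`cmcpminer` reimplements, at desk scale, a discovery pipeline for
bacterial proteins that carry sequence motifs resembling human
cytokines (CMCPs): profile-HMM family models with cross-validated
curation, six-frame ORF mining with E-value filtering and redundancy
clustering, per-cohort negative-binomial differential abundance, and a
sample-size-weighted-Z meta-analysis across eight case/control cohorts.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic data do and do not establish.

## Profile HMMs and scoring

Each cytokine family is modelled as a Plan-7-style profile HMM: one
match state per consensus column with 20-way emission distributions,
insert states emitting at background frequency, and delete states for
skipped columns. Alignment columns with gap fraction ≤ 0.5 become
match states (the usual heuristic); emissions and transitions are
estimated from the observed per-row state paths with a single
background-weighted pseudocount component,

    P(a | k) = (n_ka + w · bg_a) / (N_k + w),

with weight `w = 1` by default (`w = 20` with a uniform background
reproduces +1 Laplace smoothing). HMMER's mixture-Dirichlet priors are
deliberately not replicated; at the family sizes involved (tens of
sequences) a single component is adequate and easier to reason about.
The background is the Robinson–Robinson amino-acid composition.

Scoring is glocal: the full model must be traversed, but the target may
carry unmodelled flanking residues absorbed by self-looping N/C states
whose emissions cancel against the null, with loop probability
`n/(n+2)` for a length-`n` target. Scores are log-odds in bits against
an i.i.d. background null. The forward score sums over all paths and
Viterbi takes the best path (tie-break M > D > I); both run in log2
space with log-sum-exp, scores clamped at −1e6 bits. Residues outside
the 20-letter alphabet (X and friends) emit at background, contributing
zero bits. Correctness is established against an exhaustive
path-enumeration oracle on small models (|Δ| ≤ 1e−9 in log space).

### E-values

Hits are ranked by `E(s) = n_eff · P(S ≥ s)` with `n_eff` the number of
proteins scanned (recorded in every output; the threshold E < 0.01 is
the retention rule throughout). The tail law is calibrated per model
from i.i.d. background decoys of length matched to the scan set. A
full-sample Gumbel ML fit proved badly conservative deep in the tail —
forward-score tails decay faster than the bulk-fitted Gumbel, so at the
E = 1 threshold over 10⁴ decoys it predicted ~0 hits where ~1 should
appear. The default calibration is therefore a peaks-over-threshold
fit: the exceedances over the upper 10% quantile give an
exponential-ML rate (equivalently the Gumbel λ, with μ placed so the
Gumbel CDF matches the tail mass at the threshold), and a
generalized-Pareto ML fit on the same exceedances supplies a shape
correction `ξ` above it (`ξ = 0` recovers the pure Gumbel tail; fitted
values are typically mildly negative, i.e. lighter than exponential).
Below the threshold the closed Gumbel form holds exactly, so
`P(S ≥ μ) = 1 − e^{−1}`. Measured false-positive counts at E = 1 over
10⁴ decoys average ≈ 1 per model. `calibrate(..., method="gumbel")`
restores the plain full-sample fit.

## Alignment

The progressive aligner is a compact stand-in for MUSCLE, which the
original protocol used only instrumentally: 3-mer count distances feed
a UPGMA guide tree, and profiles are merged by global affine-gap
Needleman–Wunsch over expected BLOSUM62 column scores (gap open 10,
extend 0.5, a length-L gap costing `open + (L−1)·extend`; ties prefer
diagonal, then up, then left). Pre-aligned FASTA is accepted to bypass
the stage. Downstream model quality is tested for the recovery
behaviour that matters (cross-validation recall, mining recall), not
for alignment-benchmark fidelity.

Percent similarity to the human counterpart uses Smith–Waterman with
BLOSUM62 and BLASTp-default affine gaps (open 11, extend 1), identity
being matches over alignment columns. The family representative is the
member whose length is closest to the human reference (ties broken by
higher identity, then input order); "closest length" was chosen over
"highest identity" as the reading of length-based selection, and the
identity criterion remains available via `mode="identity"`.

## Cross-validation and curation

Family eligibility requires more than 5 members. Model quality is
measured by 10-fold cross-validation: members are evenly and randomly
partitioned; each fold's model is built from the other nine subsets,
calibrated, and applied to the held-out members; fold accuracy is
`A_i = C_i / T_i` with `C_i` the held-out members retrieved at
E < 0.01 (with `n_eff` = held-out set size), and `A_avg` is the mean
over folds. Retrieval is recall-only — no decoy set — because the
E-value cut-off is the only stated decision rule; a decoy-aware
variant can be layered on by scanning negatives explicitly.

Curation iterates: cross-validate, then prune the worst-fitting
members and repeat. The loop stops when `A_avg` strictly exceeds the
target (0.5) **and** no member scores below 0 bits (worse than
background) against the model built from the whole current family.
The second condition is this package's own design: confounders that
are few relative to the family barely dent `A_avg` (five random
sequences among thirty coherent members still leave `A_avg ≈ 0.86`),
yet they are exactly the members a careful curator would remove, and
they are cleanly separable — unrelated sequences score tens of bits
below zero while genuine members score far above. Each iteration
removes the ⌈5%⌉ (at least one) lowest-scoring members, restricted to
sub-background members once the accuracy target is met. Families that
exhaust `max_iter` (20), shrink to ≤ 5 members, or fall below K
members are flagged non-converged and excluded from mining. One master
seed derives all per-iteration fold seeds; the full audit trail
(per-fold C, T, A; removals; seeds) is serialised with the report.

The 0-bit outlier threshold is deliberately coarse. In families whose
true members are highly diverged, a genuine member could dip below
background and be over-pruned; the audit trail makes such removals
visible, and the threshold is a parameter in all but name (module
constant `OUTLIER_BITS`).

## ORF mining

ORFs are extracted stop-to-stop in all six frames (no initiator
required), retaining runs ≥ 150 nt (50 aa) under genetic code table
11; codons containing N translate to X and do not terminate a run.
Contig-edge partial runs are included by default (`include_edges`
switches them off) since the emulated extractor's behaviour at edges
is not documented. Coordinates are 1-based inclusive on the forward
strand.

Translated ORFs are forward-scored against every curated model;
E < 0.01 hits are kept, with `n_eff` = number of ORFs scanned.
Redundancy clustering is greedy incremental in the CD-HIT style
(longest first; join the best-matching cluster at ≥ 95% identity over
local-alignment columns with ≥ 90% coverage of the shorter sequence,
else found a new one). The word-size pre-filter of CD-HIT is a speed
heuristic and is not reproduced — identities come from actual
alignments, which at this scale is affordable and strictly more
accurate. Best-cluster assignment (not first-cluster) is the default,
mirroring `-g 1`.

## Quantification and differential abundance

Read assignment is a deliberately simple stand-in for an aligner: a
read is credited to the contig sharing the most exact 21-mers on
either strand; ties and no-hits are dropped. Counts aggregate over
each family's contigs. Depth normalisation uses median-of-ratios size
factors (reference = per-feature geometric mean over samples, zero-free
features only, with a positive-counts-only fallback). Size factors are
defined up to a common scale — the GLM intercept absorbs any overall
constant — and the exact invariance is therefore stated on factor
*ratios*: scaling one sample's counts by c multiplies its factor
relative to every other sample by exactly c.

Per cohort, each feature is tested with a negative-binomial GLM (log
link, case/control design, log size factors as offset) with
per-feature method-of-moments dispersion (variance = μ + α·μ², pooled
across the two conditions, floored at 1e−8) and a Wald test on the
condition coefficient; BH adjustment is applied within the cohort, and
the volcano highlight flag is |LFC| > 2 with padj < 0.05. Dispersion
shrinkage and LFC moderation à la DESeq2 are intentionally absent: the
meta-analysis consumes only the sign, the p-value and the sample
sizes. Measured operating characteristics at n = 20+20, dispersion
0.2: type-I error ≈ 0.05 at α = 0.05; a planted log2FC of ±2 among
mostly-null features is recovered with ≈ 0.01 mean bias. Note the
identifiability caveat of ratio normalisation: an effect shared by
*all* features is absorbed into the size factors and is undetectable
by construction; recovery statements assume most features are not
differential and effects are roughly balanced in direction.

All-zero features are reported flagged with p = 1; features whose GLM
fit fails (perfect separation, divergence) fall back to a
pseudocount-based LFC with p = 1, flagged.

## Meta-analysis

Per cohort, each feature's two-sided p and LFC sign give a signed
`Z = sign · Φ⁻¹(1 − p/2)` (p = 0 clamped at 1e−300 with a warning).
Cohorts combine by the sample-size scheme,
`Z_meta = Σ w_i Z_i / sqrt(Σ w_i²)` with `w_i = sqrt(N_i)`,
`N_i = n_case + n_control`; the inverse-variance scheme is available
as an option. A feature absent from a cohort contributes "?" to the
direction string and is excluded from the sum. Per-cohort symbols:
"+" for padj < 0.05 with positive LFC, "−" for padj < 0.05 with
negative LFC, "?" otherwise. Classes at the raw meta-p 0.05 cut-off
(no meta-level multiplicity correction by default; a BH option
exists): case-enriched (Z_meta > 0), control-enriched (Z_meta < 0),
or not significant.

Before combination, each cohort's Z column receives a robust
location/scale empirical-null calibration (subtract the median, divide
by 1.4826 × MAD, skipped when a cohort contributes fewer than 10
finite Z values). This is the genomic-control tradition applied to
the cohort stage: ratio-based normalisation is mildly compositional,
so genuinely differential features shift every null feature's Z by a
small common per-cohort offset which the weighted combination then
amplifies by sqrt(#cohorts). With 10% planted features the raw scheme
showed null exceedance at the edge of its nominal level (~0.08 at
α = 0.05) driven by exactly this offset (~−0.18 per cohort);
calibration restores ~0.04 while leaving power at |log2FC| = 2
unchanged (measured 1.0). `empirical_null=False` restores the raw
scheme.

## Synthetic data

The generators produce the statistical structure the analysis assumes,
with exact machine-readable truth tables:

- **Families**: members derive from one random root protein by
  independent per-site substitution (substitute with a
  background-weighted *different* residue, so the divergence parameter
  is exactly the expected fraction of changed sites); confounders are
  i.i.d. background proteins. Defaults: 30 members, length 60,
  divergence 0.10 — coherent but non-trivial families.
- **Genomes**: uniform-random background DNA (default 10 contigs of
  3 kb) with planted ORFs: family members reverse-translated with
  uniform synonymous codons (codon bias is irrelevant to the claims
  tested), TAA-flanked, placed at random non-overlapping positions and
  strands. The truth table carries exact forward-strand coordinates.
- **Cohorts**: eight case/control cohorts (default 20+20 per cohort,
  mirroring the multi-cohort case/control design) of NB counts,
  variance μ + α·μ² with dispersion α = 0.2, per-feature lognormal
  baselines (median 100), per-sample depth factors uniform in
  [0.5, 2], and planted log2 fold changes applied multiplicatively to
  case means.

What the synthetic data do **not** emulate: sequencing error, real
codon usage, genome composition, assembly artefacts, compositional
community structure, or correlated features. Passing recovery tests
therefore demonstrates the pipeline's statistical machinery under its
own assumptions, not performance on real metagenomes.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run everything on small
problems chosen to exercise the full machinery: toy models (L ≤ 3)
against exhaustive enumeration; 5 models × 10⁴ decoys for calibration
consistency; 20 curation replicates of 30+5 members; 3 mining
replicates of 3 families × 10 contigs; 10³–2×10³ features for
differential-abundance operating characteristics; 50 end-to-end
meta-analysis replicates. Every random draw flows from an explicit
seed; reruns with the same configuration and seed are byte-identical,
and the pipeline writes a provenance record (parameters, seed, input
checksums, record counts) per stage.

## Known limitations

- The glocal-only architecture has no multi-domain envelope handling;
  a protein containing two motif copies yields one score.
- No null2-style biased-composition correction; low-complexity targets
  can score high against low-complexity models.
- The POT E-value fit extrapolates roughly two orders of magnitude in
  tail probability at mining scale; E-values deep below ~1e−6 are
  order-of-magnitude statements.
- The NB Wald test is slightly liberal at very small n; with fewer
  than ~10 samples per arm its p-values should not be taken at face
  value.
- The k-mer read counter discards multi-mapping reads entirely, which
  underestimates abundance of families with near-identical contigs.
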