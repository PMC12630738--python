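# Methods note

This note records the statistical model behind `spotsig`, the
parameter choices of the synthetic cohort generator, and the numerical
conventions and known limitations of the implementation.

## 1. Spot model and annotation

A spot is the atomic unit: a circular capture area containing a small
number of cells. Cells are counted as nucleus centroids with center
distance ≤ spot radius (boundary inclusive). Histopathology classes
are assigned from pathologist area fractions by a fixed cascade,
evaluated in order:

1. exclusion: tissue < 50%, folded/low-quality tissue > 50%, or
   lumen > 80%;
2. combined stroma (stroma + lymphocyte-enriched stroma) > 55% →
   the larger sub-fraction decides (tie → plain stroma);
3. a single class among {ISUP1–5, ISUPX, ISUPY, PNI, lymphocytes}
   > 50% of the tissue area (two such classes simultaneously are
   contradictory annotations and raise an error);
4. non-cancerous glands (NCG) ≥ 30%;
5. otherwise excluded.

All thresholds are strict inequalities except the gland rule. The
acceptance suite checks the cascade against an independent rule oracle
on an exhaustive fraction grid (step 0.05).

## 2. Normalization and QC

Counts are normalized per spot by the number of cells,
`c = raw / n_cells`, and log-transformed as
`log10(raw / n_cells · 10⁴ + 1)`. Spot QC keeps spots with normalized
total ≥ 100 and ≥ 40 detected genes (exclusion is strict "less than",
so exact-boundary spots are kept). The gene filter keeps genes with a
nonzero total and ≥ 10 raw counts in ≥ 10 spots (the literal
per-spot reading; a `mode="total"` alternative requires total ≥ 10
across ≥ 10 expressing spots). Both QC masks are computed on the full
post-classification matrix and applied together; the suite verifies
that the two masks commute and that QC is idempotent on a filtered
cohort with clear margins.

## 3. Discovery statistics

Candidate genes come from three tracks, each per histopathology class:

- top-5 relative standard deviation (sample sd / mean; a constant
  zero gene has RSD 0), ties at the cut kept;
- top-5 bin-standardized dispersion z-score. Dispersion is
  mean/variance (with a `var_mean` alternative); genes are binned by
  mean into 20 equal-width bins, bins with fewer than two genes are
  merged into the nearest populated bin, and z-scores are taken
  within bins. Zero-variance genes are unselectable (NaN);
- deregulated genes: |Δ mean log₁₀| > 1 between patient groups
  (exactly a ten-fold linear change) with RSD ≤ 20% in the
  non-aggressive group of that class.

A provenance filter removes genes with ≥ 75% of expressing spots from
one sample or patient, or expressed in ≤ 2.5% of spots. An optional
user panel (in practice: gland-associated chemokine-like genes) is
appended before a second pass of the same filter.

Two sparsity-aware statistics rank the survivors on normalized counts:

- **ZFCMD** = |median of positive values, aggressive − median of
  positive values, non-aggressive| (an empty group contributes
  median 0, preserving group-exclusive signal);
- **NZCSCD** = |n₁ − n₂| / (n₁ + n₂) over expressing-spot counts,
  in [0, 1].

Each statistic is min-max scaled over the candidate list (a constant
vector maps to the neutral 0.5 so it does not reorder the other
statistic) and the rank score is their mean; genes below the median
rank score are pruned (ties at the median kept).

Signature assembly uses per-class mean log differences (classes with
fewer than 10 spots in either patient group are omitted as
underpowered): APC-like membership requires the same sign and
|Δ| ≥ 0.1 in every class; CEG-like requires |Δ| ≥ 0.1 in NCG and
< 0.1 in every other class. The 0.1 per-class threshold is a
practical stability margin, not an inferential test — see
Limitations.

## 4. ssGSEA scoring and significance

The expression matrix is centered per gene (refused for a single
unit), so a zero count in a spot for a gene expressed elsewhere ranks
below genes that are near zero everywhere. For a unit, genes are
sorted by decreasing value (ties broken by index, stable) and the
enrichment score accumulates, over all ranks, the difference between
the weighted in-set ECDF and the uniform out-set ECDF. With weight
exponent w = 0 (default) this reduces to the closed form

    ES = Σ_{g∈S} (G − r_g + 1)/m − Σ_{g∉S} (G − r_g + 1)/(G − m),

a pure rank statistic. Up and down parts are scored separately and
combined as (up − down)/2 (one-sided signatures use the present side,
negated for down-only); combined scores are min-max scaled to
[−1000, 1000] per signature per dataset (a degenerate column maps
to 0).

Because the w = 0 score depends only on which ranks land in the set,
one permutation null per signature — 1000 unique random rankings,
uniqueness enforced by rejection with a factorial guard for tiny
universes — serves every unit; the up and down null scores come from
disjoint slices of the same permutation, mirroring real scoring.
One-sided empirical p-values use the add-one convention
(exceed + 1)/(N + 1) so Fisher's method never sees p = 0. A unit is
HIGH when the Fisher combination of P(null_up ≥ up) and
P(null_down ≤ down) passes the mode threshold (0.05/n_signature_genes
for spot data; 0.05 for bulk) **and** the scaled score exceeds 200;
LOW symmetrically.

## 5. Pseudo-bulk groups and metabolites

Spots aggregate over three levels — sample class (C = cancer or
normal-adjacent, N = normal), patient status (A = aggressive,
I = non-aggressive), spot class (c = any certain ISUP grade,
g = NCG, s = stroma) — giving the ten codes {CAc, CAg, CAs, CIc, CIg,
CIs, NAg, NAs, NIg, NIs}. ISUPX/ISUPY are excluded by default (a flag
folds them into 'c'); lymphocyte-enriched stroma, PNI, lymphocyte and
excluded spots join no group, and a cancer spot inside a normal
sample is dropped with a warning. Metabolite summaries report median
and quartiles per score group; bulk-mode integrals are min-max scaled
to [0, 1] first. Spearman tables use mid-ranked ties and report NaN
for constant columns.

## 6. Synthetic cohort generator

Defaults are the package's reference study conditions: 5 aggressive +
3 non-aggressive patients, 4 samples each (2 cancer, 1
normal-adjacent, 1 normal), 400 spots/sample (12,800 spots), 1,500
genes, effect fold 10, target zero fraction 0.90.

- **Cells**: per spot 1 + Poisson(mean − 1), mean 5 — never zero.
- **Classes**: drawn from sample-type-specific mixtures; normal
  samples contain no cancer classes. Annotation fractions are drawn
  per class with margins over the rule thresholds, so the classifier
  recovers the generating class essentially always; an "excluded"
  archetype covers the low-tissue / folded / lumen / no-criterion
  cases.
- **Counts**: NB(mean = cells × rate_g, dispersion r = 2). Baseline
  per-cell rates are a two-component log-normal mixture: 12% of genes
  "expressed" (median 0.3/cell, σ = 1.0) and the rest sparse (median
  5·10⁻⁴/cell, σ = 1.5). These defaults were tuned analytically —
  before any recovery evaluation — so that NB sparsity alone sits at
  the 90% target; the residual Bernoulli dropout, calibrated as
  p = (target − zf_NB)/(1 − zf_NB), is then ≈ 0. This matters for
  realism: a generator reaching 90% zeros through heavy uniform
  dropout would make even strongly expressed genes fail the
  RSD ≤ 20% detectability requirement that real signature genes
  satisfy. At seed 1 the realized zero fraction is 0.9038. Note the
  calibration is specific to the default gene-count regime: shrinking
  `n_genes` drastically changes the mixture's realized sparsity and
  re-activates dropout.
- **Planted programs**: 10 global-up genes at 3/cell (×10 in
  aggressive patients), 10 global-down at 30/cell (÷10), and 10
  gland genes at 3/cell in NCG spots of everyone (×10 in aggressive
  NCG), with a near-silent 0.002/cell off-gland baseline — gland-
  restricted chemokine-like genes are essentially absent outside
  glands, which keeps their per-class background means quiet enough
  for the "exclusively in NCG" assembly rule.
- **Metabolites**: per-spot activity = log₁₀(fold)·[aggressive] +
  log₁₀(fold)·[aggressive ∧ NCG]; citrate-like and zinc-like channels
  decrease with activity, choline-like increases; Gaussian noise (sd
  0.3 × activity range) is added before min-max scaling to a
  relative 0–100 intensity (clipped to absorb float rounding).
- **Bulk**: exact per-sample sums of spot counts, for the public-bulk
  scoring mode.

## 7. Numerical conventions

- Ranks are 1-based; ties in sorting are broken by gene index via
  stable argsort, making scores deterministic.
- Min-max of a constant vector: 0.5 in ranking (neutral midpoint),
  0 in score scaling (flagged with a warning).
- Sample sd uses ddof = 1 throughout; single-observation vectors get
  sd 0.
- Sparse matrices are used for counts and normalization; the log
  transform preserves the sparsity pattern exactly (log10(0·10⁴+1)=0).
- All randomness flows from explicit seeds through
  `numpy.random.default_rng`; cohorts, nulls and the acceptance
  script are bit-reproducible.

## 8. Limitations

- **Null calibration is mildly anti-conservative.** On null cohorts
  the fraction of spots with p_high ≤ 0.05 for random 20-gene sets
  averages ≈ 0.06 (seed 1: 0.070; seed 2: 0.055 over ~58k draws).
  Two causes: Fisher's method treats the up and down p-values as
  independent although the two disjoint sets of one ranking carry
  positively dependent evidence, and the random-ranking null ignores
  gene–gene correlation in real spots. Per-signature rates are
  heavy-tailed (single signatures range 0.01–0.30), so calibration
  estimates need averaging over many signatures, not many spots.
- **The per-class Δ ≥ 0.1 assembly threshold is descriptive.** It is
  a fixed margin on noisy class means, not a significance test;
  underpowered classes are omitted rather than tested.
- **Dispersion is mean/variance.** The conventional dispersion is
  variance/mean; the default follows the mean/variance form the
  pipeline was specified with, and `dispersion="var_mean"` provides
  the conventional alternative. For the z-score ranking within bins
  the two give similar (reversed-tail) selections.
- **The generator is a caricature.** Flat per-class rate structure
  (no cell-type mixtures within spots), independent genes given the
  rate, a single NB dispersion, and idealized annotation fractions.
  It is designed to make recovery claims checkable, not to emulate
  tissue biology.
- **Recovery guarantees hold at the default scale.** Discovery
  performance was validated at ~1,500 genes and ≥ 50 spots/sample;
  far smaller universes change both the dropout calibration and the
  stability of per-class means.
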