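# Methods

This note documents the statistical machinery implemented in `grnbench`, the
choices made where the design was genuinely open, and what the synthetic
benchmark can and cannot show about real data.

## Regulon processing

All regulon dialects are normalised to edges `(regulator, target, weight,
mor)` with `weight ≥ 0` and `mor ∈ [−1, 1]`; the effective signed weight used
everywhere downstream is `weight · mor`.

- **ARACNe-like** tables carry a likelihood and a raw signed MOR; the
  normalised edge is `(weight = likelihood, mor = sign(raw MOR))`, i.e. the
  signed weight is the likelihood multiplied by the sign of the MOR. Since
  `sign(0) = 0`, an edge with raw MOR exactly 0 contributes nothing to any
  activity score; it is flagged rather than dropped so regulon sizes are
  unchanged.
- **GRNdb-like** tables carry an unsigned GENIE3 weight. The sign is inferred
  as the sign of the Spearman correlation (midranks for ties) between
  regulator and target expression across a reference cohort — at least three
  samples required, constant vectors dropped with a logged reason. Being
  rank-based, the inference is invariant to strictly monotone transforms of
  either expression vector.
- **DoRothEA-like** tables are curated: weight 1.0, sign from the table
  (defaulting to +1 where unsigned), optionally filtered to confidence
  classes (the conventional high-confidence choice is {A, B, C}).

Open choices, fixed here: duplicate `(regulator, target)` rows keep the
max-|weight| edge (conservative and deterministic); regulators absent from
the paired expression matrix are dropped at pairing time with a logged count.

Stratification labels each regulon by size — small (≤ 20 targets), medium
(21–100), large (> 100) — and by its fraction of unique targets (targets in
no other tested regulon): none (0), low (≤ 10%), high (> 10%).

## Expression and sensitivity wrangling

Two zero conventions coexist deliberately, mirroring how cell-line and
bulk-cohort data are usually treated:

- Cell-line-style expression: zeros are real values; genes with **> 20%**
  zeros across samples are dropped (strict inequality — a gene at exactly
  20% stays).
- Bulk-cohort-style expression (the reference set for GRNdb sign inference):
  genes with zeros in **more than half** the samples are removed; remaining
  zeros are treated as missing and imputed by the mean of the k nearest gene
  rows (Euclidean distance over mutually observed columns, rescaled to the
  full column count; k = 10 by default, the convention of the classic
  nearest-neighbour imputation routine). Fewer than k complete candidate
  rows triggers a row-mean fallback with a warning. Observed entries are
  never altered.

Alignment keeps the intersection of genes and of sample/cell-line
identifiers, sorted lexicographically for run-to-run determinism; the
operation is idempotent.

## Activity methods

Normative definitions (per sample `s`, regulator `r`, `G` genes):

- **ULM**: t-value of the slope of `x_s ~ a + b·(w·mor)_r`, `G − 2` df.
  Computed via `t = ρ√(G−2)/√(1−ρ²)` with `ρ` the Pearson correlation of the
  weight vector and the expression profile — algebraically identical to
  slope/SE.
- **MLM**: one joint OLS per sample on all regulators plus intercept;
  activity is the coefficient t-value, `G − (p+1)` df. Rank deficiency
  raises an error naming the most correlated regulator pair.
- **VIPER-style aREA** (single layer): midranks → two-tail and one-tail
  normal quantiles; `ES = [Σ w·mor·q2 + Σ w(1−|mor|)·q1]/Σ w`;
  `NES = ES·√(Σ w/max w)`. Pleiotropy and shadow corrections are
  deliberately not implemented: they are orthogonal to the evaluation
  contract here, and the single-layer score is the comparable core.
- **W. Sum / W. Mean**: signed-weight projection, the latter normalised by
  `Σ|w·mor|`. They differ by a positive per-regulator constant, so every
  correlation-based downstream statistic is provably identical between them
  (the suite asserts this to 1e−12).
- **Consensus**: per method and sample, z-score across regulators (zero
  variance → all zeros), then an unweighted mean of z-scores across methods,
  missing cells excluded with the effective n tracked. This is a transparent
  definition of "consensus"; it does not chase any particular external
  implementation bit-for-bit.

Numerical choices: perfect fits (zero residual variance) cap t at ±1e6 and
are flagged, keeping downstream correlations finite; constant expression
profiles score 0 under ULM and aREA by convention; degenerate weight vectors
yield missing scores with a recorded reason, never silent values.

## Essentiality

A gene is essential in a line when its gene-effect score is **strictly below
−0.6** (a score exactly at the threshold is non-essential; missing scores
propagate). "Sometimes essential" means:

- per cancer type: ≥ 1 essential and ≥ 1 non-essential line within the type;
- pan-cancer at q%: at least `max(1, floor(q·N/100))` lines on *both* sides,
  with `N` the gene's non-missing lines. The floor is used throughout; note
  that for N = 973 and q = 5 the floor gives 48 (neither 47 nor 49 — the
  count sometimes quoted for this setting does not match either rounding,
  and this implementation simply documents the floor rule it uses). The
  `max(1, ·)` guard keeps the "sometimes" semantics meaningful at tiny N.

Binary (CLES) evaluation additionally requires ≥ 3 lines in each group.

## Evaluation statistics

- **Pearson with p**: product-moment `R`, p from
  `t = R√(n−2)/√(1−R²)` (two-sided, `n − 2` df), pairwise-complete, `n ≥ 3`,
  constant vectors → missing record. Absolute-`R` evaluation is the default
  because both directions of coupling are biologically meaningful (amplified
  activity can sensitise, as can lost activity); the sign is kept as a field.
  The `p < 0.05` gate is uncorrected by default (a Benjamini–Hochberg option
  can be applied downstream on the stored p-values).
- **CLES**: `[#(e > n) + 0.5·#(e = n)] / (|E|·|N|)` over all cross-group
  pairs, computed via midranks; numerically the trapezoidal AUROC (asserted
  to 1e−10 against an independent integration).
- **Rank-sum test**: exact enumeration when the pooled sample is ≤ 12 and
  tie-free, otherwise the normal approximation with tie and continuity
  corrections.
- **Matched vs mismatched regulons**: within each cancer type, regulons are
  ranked by mean `|R|`, rank 1 = highest (chosen so "matched better" reads
  as lower rank; the direction is a convention, the test is invariant to
  it). Matched = diagonal cells. The rank-sum test defaults to two-sided;
  a one-sided alternative is exposed since the choice is a judgment call.
  Within-row ranking makes the whole procedure invariant to any monotone
  transform applied per cancer-type row.
- **Variance decomposition**: nested OLS in a stated term order; the share
  of a term is the adjusted-R² gained when it enters. Shares are
  order-dependent by construction and the output records the order used;
  adjusted R² can decrease, so slightly negative shares are legitimate.
- **Gene-set enrichment**: one-sided (greater) Fisher's exact test on the
  2×2 hit × annotation table over a user-supplied universe.

## Synthetic cohorts

The generator plants, per cancer type: a regulon set (target counts uniform
in a configured range, inhibitory edges with probability `inhibitory_prob`,
weights uniform on (0.5, 1)); latent activities `A ~ N(0,1)`; target
expression `Σ β_t·w·mor·A + N(0, σ_e²)`; regulator mRNA
`α·A + √(1−α²)·N(0,1)`, so `corr(mRNA, A) = α` exactly in expectation; and
gene-effect scores `−β_s·D + N(0, σ_s²)` with `D` the standardised driver
(latent activity, own mRNA, a convex mixture, or nothing). Non-reference
cancer types rewire a configured fraction of each regulon's targets, which
is what makes "matched" networks genuinely better when the fraction is
large. Expression is affinely mapped onto a nonnegative log2(TPM+1)-like
range and scores are shifted per gene so a configurable fraction of calls
falls below −0.6 — both monotone operations that change no rank or
correlation statistic. With `driver = expression`,
`corr(mRNA, score) → −β_s/√(β_s² + σ_s²)`, which the suite verifies at
n = 2000.

Reference conditions (the generator defaults): 10 cancer types × 30
samples, 2000 genes, 50 regulators × 30 targets, `σ_e = 1`, `σ_s = 0.5`,
`β_t = β_s = 1`, `α = 0.6`, essential fraction 0.3. These sizes make a full
replicate sweep (10 seeds × both drivers, plus 10 seeds × two rewiring
settings for the cross-regulon grid) complete in minutes on one CPU while
leaving the planted contrasts unambiguous; the cross-regulon grid is scored
with a single method (ULM by default) because the matched-vs-mismatched
contrast in these cohorts is method-independent and the 10 × 10 grid is the
expensive part.

What the generator does *not* emulate: RNA-seq count noise (negative
binomial, library-size effects), copy number, mutation, off-target CRISPR
artefacts, or correlated regulator programs. Passing benchmarks on these
cohorts therefore demonstrates that the pipeline's mathematics and decision
logic are correct and unbiased — that it recovers whichever planted driver
is true and detects planted network specificity — not that any particular
real-data conclusion holds.

## Known limitations

- The consensus score is a z-mean, not a reimplementation of any specific
  external ensemble; results that depend on consensus minutiae may differ
  from other toolkits.
- MLM requires more genes than regulators and non-collinear weight vectors;
  very dense, overlapping regulon collections may need pruning before MLM is
  applicable.
- The kNN imputer is O(rows² · columns) in the worst case; it is intended
  for the moderate matrices of sign inference, not for genome-scale
  imputation.
- Pan-cancer filters use floor-based counts; cohorts assembled with other
  rounding conventions will differ at the margin.
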