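# Methods

## The trial model

The package analyses multi-environment trials laid out as a randomized
complete block design (RCBD) within each environment: every genotype present
at a location appears exactly once in each of that location's r blocks. The
data model is a tidy table, one row per plot, with sparsity (a genotype not
grown at a location) represented by absent rows. The reference design is the
nine-genotype, nine-location, three-block Burkina Faso hybrid-maize network;
nothing in the code depends on those dimensions.

## Yield standardization

Plot ear weight is converted to grain yield at standard moisture by

    yield [t/ha] = PE (100 − H) / (100 − Hr) · (S·100) / (NPA·10)

The formula is implemented exactly as printed in the source protocol after a
dimensional check (1 kg grain-equivalent on 1 m² at standard moisture with
S = 1 gives 10 t/ha). Defaults: Hr = 15 %, S = 0.8. NPA is deliberately
**mandatory configuration**: the protocol's "gross plot size 0.80 m × 0.40 m"
reads as planting spacing (0.32 m² is implausible as a harvest plot), and
NPA enters the formula as an independent symbol, so no value is inferred.
The bundled default used by the simulator is 8 m² (ten 0.8 m × 1 m rows), a
typical net harvest plot for such trials.

## Per-environment ANOVA and genetic parameters

Sums of squares are computed from first principles on the balanced
genotype × block cell matrix; the error SS is obtained by subtraction and
clipped at zero against floating cancellation. F tests use the pooled error;
blocks are fixed effects (the choice is inert downstream: only MS_g and
MS_e feed the genetics). Unbalanced data policy: genotypes missing from some
block of an environment are dropped with a warning (mirroring how sparse
trial tables simply omit entries); a strict mode raises instead.

Variance components follow the moment estimators

    σ²g = (MS_g − MS_e)/r,  σ²e = MS_e/r,  σ²p = MS_g/r,

so σ²p = σ²g + σ²e holds exactly before truncation. The printed source
formula set ("σg² = MS_p − MS_e/r") is internally inconsistent; the adopted
form is the standard one, reproduces every verifiable published H² =
σ²g/σ²p ratio, and treats MS_p as an alias of MS_g. Negative σ²g estimates
are truncated at zero **with an explicit flag** (synthetic data will produce
them; published tables never show them). H² is the ratio σ²g/σ²p, clipped
to [0, 1], NaN when σ²p = 0. GCV and PCV read "√σg" as the genotypic
standard deviation √(σ²g).

Two published per-location rows are knowingly not reproduced as printed:
the "LSD (5 %)" row carries values (0.0001 …) that are genotype-effect
p-values, and the printed "CV (%)" cannot be reconciled with
100·√MS_e/mean from the printed variances. The package therefore reports
the genotype p-value (4 decimals, "<0.0001" below that), a true
LSD = t(α/2, df_e)·√(2 MS_e/r) as its own column, and the standard residual
CV, without claiming to match those two printed rows.

## SNK means separation

Critical range for a stretch of p ordered means: W_p = q(α, p, df_e)·√(MS_e/r),
with q the upper-α studentized range quantile (scipy's
`studentized_range`). Ranges are tested largest first; a non-significant
range protects all sub-ranges. Letters mark maximal non-significant
stretches; a genotype accumulates the letter of every stretch containing it,
which yields the overlapping "ab/bc" patterns of published tables. Lettering
direction is configurable (`letters_from="top"|"bottom"`, default top =
highest mean is "a"; some published tables letter from the bottom up — the
choice is cosmetic, the stretch partition is identical). Degenerate case
MS_e = 0: all critical ranges are zero, so distinct means get distinct
letters and exact ties share one. SNK assumes a common r; unequal
replication within an environment is out of scope after the drop policy.

## Combined G×E ANOVA

Strata: environment (e−1), block within environment (e(r−1)), genotype
(g−1), G×E ((g−1)(e−1)), error (e(g−1)(r−1)); all F tests are against the
pooled error. Sparse trials break balance, so the default
`complete_cases` policy restricts to genotypes fully observed in every
environment (the exclusion list is always reported); `listwise` instead
keeps only environments containing every genotype. Under the generating
model used for calibration the interaction F test is exact, which the
type-I simulation confirms.

## Stability and environment ranking

No specific stability statistic is standard for small sparse networks, and
the source analysis names only its plotting tool, so the package defines an
assumption-free rank-based score: within each environment genotypes are
ranked by mean yield (1 = best, ties mid-ranked); a genotype's score is its
mean rank plus the sample SD of its ranks over the environments it covers
(default coverage threshold: half the environments). Lower is better — the
score punishes both mediocrity and inconsistency. It is invariant to adding
a constant to any single environment's yields. AMMI, GGE biplots,
Finlay–Wilkinson and Shukla's variance are explicitly not implemented.
Environment means average genotype means (not plots), matching how the
published location-mean row reproduces the published matrix's column means.

## Synthetic trials

`simulate_met` draws y_ijk = μ + g_i + e_j + ge_ij + b_k(j) + ε_ijk with
independent normal effects. Normality is a stand-in — the source states no
distributions — chosen because the estimators are moment-based. Defaults
emulate the reference network: 9 × 9 × 3; for grain yield μ = 5.3 t/ha
(the network's overall level), σ²g = 2.5, σ²e = 1.5, σ²ge = 0.5 (non-zero
so G×E tests are non-trivial by default), σ²b = 0.1, σ²ε = 0.8, giving
expected per-environment H² = r(σ²g+σ²ge)/(σ²ε + r(σ²g+σ²ge)) ≈ 0.92, in
the >0.80 band the reference trial reports. Six further traits carry models
at realistic agronomic magnitudes (e.g. ~14 rows/ear, ~500 grains/ear).
Grain moisture is drawn independently (mean 18 %, SD 2, clipped to
[1, 40]), and ear weight is **back-solved** through the standardization
formula from the latent yield, so deriving yields recovers the latent draw
exactly and the standardization path is exercised end to end. Plot values
of non-negative traits are clipped at zero; calibration experiments
therefore use a high mean (20 t/ha) where the clip must stay inactive so
the linear model holds exactly. One seed feeds a `SeedSequence`-spawned
stream per environment, so an environment's draws do not depend on how many
environments follow it.

What the generator does **not** emulate: spatial field trend, non-normal
errors, moisture–yield correlation, measurement rounding. Passing recovery
tests therefore shows the estimators are correct under the stated model,
not that real field data meet that model.

## Numerical and testing choices

- All SS computed as deviations from means (not raw-score shortcut
  formulas) and clipped at −0 after subtraction; additivity asserted at
  1e−9 relative in tests, oracle equivalence at 1e−10.
- F with MS_e = 0: +inf with p = 0 when the numerator SS is positive, NaN/NaN
  for fully constant data.
- Monte-Carlo problem sizes: heritability recovery uses 500 trials of one
  environment each (the estimator is per-environment, so extra environments
  only duplicate draws); the type-I calibration uses 200 four-environment
  trials with a 3σ binomial tolerance; the bias and spread experiments use
  150–200 replicates per setting. The mean recovered H² sits ≈ 0.03 below
  its expectation 0.904 at g = 9 — the Jensen bias of the mean-square ratio
  (E[MS_e/MS_g] ≈ (df_g/(df_g−2))·σ²ε/(σ²ε+rσ²g)), vanishing by g = 100,
  which the bias test checks.
- Published-table checks round the recomputed ratio to 2 decimals because
  the published variances are themselves printed rounded; two locations
  whose printed means contradict their own matrix columns are excluded and
  documented.
- CSV I/O accepts decimal commas (source tables use them), always emits
  points, at 6 significant digits; round-tripping is property-tested.

## Known limitations

- Method-of-moments only; no REML/mixed models, no narrow-sense
  heritability or combining-ability analysis.
- The stability score is ordinal: it ignores yield margins between ranks.
- SNK controls error per stretch size, not family-wise; that is inherent to
  the procedure, not a bug.
- Weather metadata are carried but never modelled.
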