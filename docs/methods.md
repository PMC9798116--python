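# Methods

## Measurement model and derived measures

A MeRIP microarray splits each RNA sample by anti-m⁶A immunoprecipitation and
hybridizes the modified (IP) and unmodified (Sup) fractions as the two dye
channels of one array. If a gene has true transcript abundance *T* (arbitrary
intensity units) of which a fraction *m* carries the mark, the channels
measure, up to multiplicative noise,

    IP  = T·m·ε,      Sup = T·(1−m)·ε′.

The three derived measures follow directly: the methylation **level**
100·IP/(IP+Sup) estimates 100·m, the m⁶A **quantity** IP estimates T·m, and
the **expression** IP+Sup estimates T. All three are computed on normalized
*linear* intensities; a percentage of modification is meaningless on a log
scale, so log₂ enters only inside the statistical tests and the fold-change
bookkeeping. Genes with IP+Sup = 0 in a sample get a missing level, never 0%.

Multi-probe genes are aggregated channel-first (per-channel, per-sample median
across probes, then the ratio), not by averaging per-probe percentages; the
median is robust and scale-preserving. Aggregation rule is configurable
(median/mean/sum).

## Preprocessing

**Spike-in normalization.** Each sample × channel is rescaled by the single
factor that brings its median spike-in intensity to a common target (default
1000, arbitrary). This is scale-equivariant: it removes array-to-array and
dye-channel scale differences exactly and preserves all relative structure
within a channel. No background subtraction, loess or quantile step is
applied — those address spatial/intensity-dependent artifacts the two-fraction
design does not rely on.

**Detection filter.** A probe is retained when it carries a Present or
Marginal flag in at least `min_pm` samples (default 3 of the 9 in the
three-group × three-replicate design). Flags are per sample, not per channel,
so a sample either supports a probe or not; the filter is monotone (upgrading
a flag never removes a probe) and ignores intensities, so it commutes with
normalization. Spike-ins are always retained for audit but excluded from gene
statistics.

## Differential screening

Fold changes are geometric-mean ratios on linear values, equivalently
2^(mean log₂ difference). The p-value comes from a two-sample test on log₂
values:

- **`t_student` (default)** — pooled-variance two-sample t. With three
  replicates per group, Welch's unequal-variance t is markedly conservative
  (its Satterthwaite df approximation gives a true size near 3.5% at nominal
  5%, measured here on 2·10⁵ simulated null genes), while the pooled test is
  exactly sized under the shared noise model. Since the generative model — and
  two-channel array noise generally — has a common per-gene variance across
  groups, the pooled test is the calibrated default.
- **`t_welch`** — Welch t, for unequal-variance settings.
- **`mannwhitney`** — exact Mann–Whitney null for combined n ≤ 16 without
  ties, tie-corrected normal approximation otherwise. At n = 3 + 3 its
  smallest achievable two-sided p is 0.1, so it cannot reach significance in
  the study design; it is provided for larger designs.

Degenerate inputs never crash: if both groups have zero variance the t tests
return p = 1 for equal means and p = 0 otherwise (the natural limit, and what
makes the noise-free pipeline classify planted genes exactly); all-tied
Mann–Whitney input returns p = 1. One-way ANOVA is available for three-group
comparisons of scalar summaries.

**Significance semantics.** The screen flag (`significant` in a contrast
table) is p < α AND fold change beyond the cutoff (default 2). The cutoff
applies to the quantity and expression screens; methylation-level contrasts
use the test alone, because a difference of percentages is not naturally a
fold change. The arrow notation used in candidate tables is coded
independently: one arrow below the 2-fold magnitude threshold, two at or
beyond it, and a star for *test* significance alone (p < α) — a sub-2-fold
change can legitimately carry a star. No multiple-testing correction is
applied by default, matching the per-gene p < 0.05 screening convention at
n = 3; this inflates the family-wise error and is a screening, not an
inferential, choice.

**Tendency.** The ordered trend of a gene's expression means across
OA → HP → SOMA is `decreasing` when OA ≥ HP ≥ SOMA with OA > SOMA (non-strict
interior, strict ends), `increasing` symmetrically, otherwise `unordered`.
The non-strict interior is deliberate: a candidate with equal-magnitude drops
in both impaired groups still reflects a monotone loss.

## The five-evidence classifier

Candidate genes (methylation level down in the impaired groups) are triaged by
a total, deterministic decision tree over the feature tuple (quantity
direction/significance, the two expression contrasts HP/OA and SOMA/OA, the
expression tendency), evaluated in order:

1. quantity up, not significant, level lower in impaired groups → **i**
   (mark diluted by enhanced transcription);
2. quantity significantly up → **ii** (transcription strengthened, m⁶A
   function attenuated);
3. quantity down, not significant → **iii**;
4. quantity significantly down ∧ both expression contrasts down ∧ SOMA/OA
   significant ∧ tendency decreasing → **v**;
5. quantity significantly down ∧ both down ∧ SOMA/OA *not* significant →
   **iv**;
6. anything else → **iii** (unordered change without coherent significance).

Mechanism = "Yes" exactly for iv and v. The hierarchy is keyed on the quantity
column's direction and significance: this is the unique reading that
reproduces all fourteen rows of the packaged worked example, including the
gene with a significant single-arrow expression increase that is nonetheless
category iii. The level columns carry no independent role beyond rule 1's
inequality — in the worked example significance is marked only on the
quantity column, and the candidate universe is already conditioned on a
significant level drop.

When the classifier runs on pipeline output, the iNOA level column is the mean
level over the pooled HP+SOMA samples, quantity is the pooled iNOA/OA
contrast with the screen flag, expression significance is p-only (see above),
and tendency is computed from the three expression group means. When it runs
on a printed candidate table, stars are taken at face value and tendency is
derived from the two arrows (both down with the SOMA magnitude class at least
the HP one → decreasing).

## Synthetic data

The generator draws IP = T·m·ε and Sup = T·(1−m)·ε′ with ε, ε′ independent
log-normal (standard deviation `noise_sigma` in log₂ units, default 0.15 — a
moderate two-channel-array noise level; the screening calibration studies use
0.2), the standard multiplicative intensity-noise model, which keeps
intensities positive. The default design is the study layout: three groups ×
three replicates. Spike-ins (default 10 per array at true intensity 1000 in
both channels) receive the same noise. Flags are Present by default, Marginal
at rate 0.05, Absent for the dimmest 2% of probe/sample totals plus 2% random
dropout; spike-ins are always Present. Null genes dominate any cohort not
explicitly planted; their (m, T) are drawn once per gene (m uniform on
(0.1, 0.7), T log-uniform over 10^1.5–10^3) and shared across groups, so the
type-I behavior of the screen is directly measurable.

Planted profiles realize each evidence category with an `effect_size`
parameter (default 4) scaling the changes that must clear the 2-fold cutoff;
the deliberately sub-cutoff changes (category i's 1.5× quantity rise,
iii's 0.9× drift, iv's 0.9× SOMA expression dip) are fixed constants, since
they must stay inside the cutoff window for the category to be expressible at
all. In the noise-free idealization used for round-trip checks, a change is
"significant" exactly when it clears the fold-change cutoff (an
infinite-precision test detects any such effect); category iv is the one
profile whose recovery intrinsically needs *non*-significance of a real
effect, so its recovery under noise is the lowest by construction.

What the simulator does **not** emulate: probe-sequence effects and
affinities, dye bias, spatial artifacts, correlated biological replicates,
cell-composition differences between histological grades, and IP efficiency
below 100%. Passing tests therefore demonstrate the correctness and
calibration of the computations under the stated model, not robustness to
those real-data artifacts.

## Calibration record

- Type-I error of the default screen test: on 2 500 simulated null genes
  (n = 3/group, σ = 0.2), the fraction with p < 0.05 lies within 3 binomial
  standard errors of 0.05 for every seed tried. The check runs on the
  un-normalized table and the quantity measure: spike-in rescaling shares one
  estimated factor per sample across all genes, which correlates gene-level
  p-values (a real phenomenon — normalization noise acts like a per-array
  batch shift) and voids the independence the binomial band assumes.
- Planted-category recovery through the full pipeline at σ = 0.15, effect 4,
  n = 3, over 200 seeded replicates: i 1.00, ii 1.00, iii 0.935, iv 0.74,
  v 1.00. The category-v acceptance threshold (≥ 0.95) derives from this run.

## Bench assays

- qPCR relative expression: 2^−(Ct_target − Ct_reference), technical
  duplicates arithmetically averaged on the Ct scale before the formula.
- ELISA percent m⁶A: slope-ratio kit convention,
  `[(OD_s − OD_nc)/S] / [(OD_pc − OD_nc)/P] × 100`, with S the sample RNA
  input (default 200 ng) and P the positive-control amount (kit-specific, a
  required input); negative blank-subtracted signal is clipped to zero with a
  warning. No amplification-efficiency or plate-layout correction is applied.

## Known limitations

- With n = 3 per group, per-gene variance estimates are weak; a moderated
  (empirical-Bayes) variance model would gain power but is out of scope, and
  the plain pooled t keeps the screen's stated calibration.
- The decision tree formalizes an under-determined printed rule set; rows
  outside the patterns seen in the worked example fall back to category iii
  by construction.
- Problem sizes in the test and acceptance suites (hundreds to a few thousand
  genes, 200 recovery replicates) were chosen as the smallest giving stable
  statistics for the properties asserted.
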