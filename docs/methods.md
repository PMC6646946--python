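# Methods

This note documents the statistical model behind `isascore`, the choices
made where conventions diverge, and what the synthetic generator does and
does not emulate.

## Scoring model

A trial table is long format: one row per trial with `subject`, `block`,
`trial` (1-based order within block), `rt` (ms, > 0), `acc` (0 = error,
1 = correct), and one column per design factor. All scores are computed per
subject × design cell.

**Correct-RT stream.** `RT_c` and `S_RT` are computed after excluding
incorrect trials and the trial immediately following an error within the
same block (the standard latency filter for task-switching data, where
post-error slowing contaminates the latency of interest). The first trial
of a block has no predecessor and is kept when correct. `RT_a` (for RCS)
and `PE` use all trials unfiltered. Consequently LISAS, IES and RCS-c
inherit the filter through `RT_c`/`S_RT`, while RCS does not.

**S_PE.** The accuracy spread that weights PE inside LISAS is the sample
standard deviation (n − 1 denominator) of the per-trial 0/1 accuracy
indicator within the subject × cell, computed in closed form as
`sqrt(p(1−p)·n/(n−1))`. This matches the aggregation level of `S_RT`
(per-trial spread within the same cell). Cells with one trial, or with
`PE ∈ {0, 1}`, get `S_PE = 0`, in which case LISAS degenerates to `RT_c`
by definition (not an error).

**Missing values.** A cell with no usable correct RTs has `RT_c`, `S_RT`,
LISAS, IES and RCS-c flagged missing (NaN) with a warning; RCS and PE
remain defined (an all-error cell has RCS = 0 correct responses per
second). Subjects missing a whole cell are listed in a missing-cell report;
`strict=True` raises instead. Analyses apply listwise deletion per measure
with a logged count.

**Units.** RT is stored in ms throughout. RCS and RCS-c convert to seconds
internally so their values read as correct responses per second; with IES
in ms this makes `RCS_c × IES = 1000` an exact identity, which the tests
exploit.

**Bin score.** The pooled correct switch-cost differences of all subjects
define the decile edges: linear-interpolation quantiles at probabilities
0.1 … 0.9 (the numpy default; the defining sources do not state a quantile
rule). A difference falling exactly on an edge counts toward the lower
decile. Each subject's score is `Σ i·n_i + penalty·n_e` with the error
penalty defaulting to 20. Deciles are formed once per comparison from one
pooled set. At least 10 pooled differences are required.

## Within-subject effect sizes

All designs handled here are fully within-subject. To avoid sphericity
assumptions, each effect is tested multivariately: orthonormal contrast
rows over the design cells (Kronecker products of Helmert bases for
involved factors and normalized constant vectors for the rest) turn each
subject's cell means into `p` contrast scores, and a one-sample Hotelling
T² tests them against zero:

    T² = N · z̄' S⁻¹ z̄
    F  = T² (N − p) / (p (N − 1)),  df = (p, N − p)
    η²p = T² / (T² + N − 1) = 1 − Λ   (Wilks)

For 1-df effects this reduces exactly to the paired t test, with
`η²p = F/(F + df_err)`; the test suite verifies both identities and checks
the multirow case against a brute-force Λ computed from SSCP determinants.
η²p is invariant to affine rescaling of the dependent measure, so ms-vs-s
conventions cannot change any conclusion.

Degenerate inputs: zero-variance contrast scores with nonzero mean give
η²p = 1 with the p-value floored at 1e-300; all-zero scores give F = 0.
`N ≤ p` is an error.

**Planned contrasts.** A contrast is a zero-sum weight vector over the
cells of a factorial building block (e.g. cue repetition vs. switch, task
repetition vs. switch, and their product over four transition types). Each
contrast is normalized, optionally Gram-Schmidt-orthogonalized (with a
warning) when a supplied set is not orthogonal, spread over the full design
grid, and interacted with any subset of the remaining factors via Helmert
rows. When the contrast set spans the same space as the factorial effects,
results coincide with the full ANOVA — a tested identity.

## Signal-detection evaluation

Per experiment, the detection criterion is the η²p of a 1-df effect exactly
at α: `F_crit/(F_crit + df_err)` with `df_err = N − 1`. This is the
natural threshold because every 1-df effect with η²p at or above it is
significant at α. An effect is *large* when RT or PE reaches the criterion
(ties count as detections); composites are scored hit/miss within the large
set and false-alarm/correct-rejection within the small set.

`d′ = Φ⁻¹(H) − Φ⁻¹(FA)`. The default correction adds 0.5 to all four cells
(`H = (hits+0.5)/(n_large+1)`), which keeps corrected rates strictly inside
(0, 1) for any finite counts and is less biased than boundary replacement;
the `half_count` alternative replaces only boundary proportions 0 and 1 by
`1/(2N)` and `1 − 1/(2N)`.

Correlation analyses use Pearson r with Fisher-z confidence intervals
(variance `1/(n−3)`; `1/(n−4)` for first-order partials) and the standard
partial-correlation formula. Differences between dependent correlations
sharing one variable are tested with Steiger's (1980) Z using the pooled-r̄
covariance term; the suite validates it by symmetry/monotonicity properties
and a seeded Monte-Carlo null calibration, since no independent
implementation is available in the dependency set.

Decile variability: effects are ranked on the RT η²p within each data set;
decile d of rank k among n is `ceil(10k/n)`. Deciles group into effect
levels 1–3, 4–6 and 7–10 (the overlapping grouping sometimes quoted for
this analysis repeats decile 3 and is treated as a typo). Per-decile means
and SDs of each composite's η²p feed a Data Set × Effect Level × Measure
ANOVA.

Category comparisons (composite η²p vs. `max(η_RT, η_PE)` within
hit/miss/FA/CR) use a split-plot ANOVA: the 2-level within factor (measure)
is tested through difference scores, the between factor (category) through
subject means, and category-contrast × measure interactions against the
within-error mean square. With unequal category sizes the within main
effect uses the weighted grand mean (Type-I style). Empty categories are
reported as missing and excluded with a warning. The Yates-corrected χ²
(`Σ(|obs−exp|−0.5)²/exp`, 1 df) serves the 2×2 count comparisons.

No multiple-testing correction is applied anywhere; the evaluation treats
each effect's η²p as one observation.

## Synthetic generator

The generator emulates multi-factorial within-subject task-switching
experiments. Defaults are chosen as typical values for two-choice RT tasks
and are deliberately fixed:

| parameter | default | meaning |
|---|---|---|
| `rt_mu, rt_sigma, rt_tau` | 500, 50, 150 ms | ex-Gaussian RT (mean 650 ms) |
| `error_base` | logit(0.07) | base error rate, inside the 0.05–0.09 band typical of these designs |
| `trials_per_cell` | 60 | per subject × cell |
| `subject_sd_rt` | 40 ms | between-subject speed intercept SD |
| `subject_sd_pe` | 0.3 | between-subject error-logit SD |
| `sat_coupling` | 0 | speed→accuracy intercept coupling (trade-off) |
| `error_rt_shift` | 0 | offset of error-trial RTs |

Effects are injected as shifts on the cell RT mean (ms) and on the cell
error logit. Factor levels are coded on a centered unit-range scale, so a
main-effect shift equals the difference between extreme levels and an
interaction shift equals the double difference. Accuracy is Bernoulli per
trial; each subject's trials are one block with cell order randomly
interleaved, so the post-error filter operates as it would on real data.
Everything is driven by one `numpy` Generator seed; identical seeds give
identical trial tables.

Thirteen named fixtures mirror the designs and sample sizes of two
task-switching data sets (8 experiments crossing Task × Dimension
transition, with CSI/CCI factors in the larger ones; 5 crossing Cue or
Response type × Transition, partly × Congruency), with same-direction RT
and PE switch costs by default.

Helpers convert a target η²p into a shift through the closed-form relation
`δ_z = sqrt(η/(1−η))` on contrast scores, using the cell-mean SDs
`sqrt((σ²+τ²)/t)` and `sqrt(p₀(1−p₀)/t)`.

**Balance construction.** `balanced_opposite_shifts` produces opposite
RT/PE shifts that cancel inside LISAS. The LISAS penalty term as a function
of the error rate is `g(p) = S_RT·sqrt((t−1)/t)·sqrt(p/(1−p))`, which is
concave in p; the default construction therefore sizes the proportion shift
as `−rt_shift/g'(p₀)` rather than as an equal number of trial-level SDs.
The equal-SD variant (`equal_sd=True`) implements the textbook statement of
the balance property; because `g' < S_RT/S_PE` at small error rates it
under-compensates, leaving a residual LISAS effect — an instructive
property in its own right, asserted in the tests as strong attenuation
rather than full cancellation.

**What the generator does not emulate.** No sequential dependencies beyond
the error structure needed by the filter (no post-error slowing, no task-set
inertia across trials), no RT-accuracy coupling at the *trial* level (fast
guesses), no diffusion-model mechanics, no trial-count attrition. Passing
calibration tests on this generator therefore shows that the pipeline's
statistics behave as designed under a clean ex-Gaussian/Bernoulli world; it
does not certify behavior under trade-offs that interact with the design,
which is exactly the situation flagged as an open question for composite
measures generally.

## Problem sizes used in validation

The statistical acceptance checks run at sizes chosen to give tight Monte
Carlo error while staying desk-scale: null false-alarm calibration uses 500
replicate 20-subject 2×2 experiments (1500 null effects per measure,
compared to the central 95% interval of Binomial(1500, 0.05)); the balance
simulations use 300 and 150 replicates; oracle-agreement checks use 8–14
subjects and 100 random bin-score inputs. Deterministic identities (IES
example, d′ reconstructions from published count patterns, RCS-c × IES
duality) are exact to the stated tolerances.

## Known limitations

- The multivariate engine requires more subjects than contrast rows; very
  small samples with many-level factors are out of reach by construction.
- The split-plot category ANOVA uses weighted means under unbalanced
  categories; with strongly unequal category sizes a Type-III convention
  would differ slightly.
- Steiger's Z is asymptotic; at n below ~20 its calibration drifts, which
  the Monte-Carlo test documents at n = 60.
- The bin score is defined for a single two-condition comparison; the
  multi-factor generalizations of binning are intentionally not provided.
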