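# Methods

## Scope and model

`depthfuse` implements a cooperative diagnostic procedure for the binary
invasion-depth call in early gastric cancer — intramucosal (M) versus
submucosal (SM), with SM the positive class — combining two sources:

1. an AI classifier summarised by a per-case probability `p_SM` in [0, 1];
2. a panel of endoscopists, each contributing one binary vote per case.

The image classifier itself (a fine-tuned CNN in the original workflow) is
deliberately outside the package: everything *around* it — confidence
stratification, panel selection, decision fusion, evaluation protocol — is
the procedure of interest, and it is classifier-agnostic. The
leave-one-out harness accepts any object with `fit(records, seed)` /
`predict_proba(record)`, and the package ships simple reference
classifiers (stored-probability pass-through, k-NN on a feature map,
prevalence/constant baselines, and a memorizing leakage canary).

## Decision rules

**AI stratification.** Label SM iff `p_SM > 0.5`. The diagnostic
probability is `q = max(p_SM, 1 − p_SM)` — the probability of the *chosen*
class, so M calls also carry a confidence. `q > 0.75` is high confidence,
otherwise low. Two boundary choices are conventions of this package:
`p_SM = 0.5` yields the negative class M (a `tie_positive` flag flips
this), and the band (0.50, 0.51) is low confidence — the published band
"51–75%" is read continuously as (0.5, 0.75] because a probability scale
has no holes. The unit interval therefore partitions into exactly four
bands: M-high [0, 0.25), M-low [0.25, 0.5], SM-low (0.5, 0.75], SM-high
(0.75, 1].

**Panel aggregation.** Panels are odd-sized so a strict majority always
exists; unanimity is high confidence, anything else low. Single-rater
panels are allowed (always unanimous) as a degenerate but useful case.

**Fusion.** Agreement is final regardless of confidence. Label
disagreement at different confidence goes to the higher-confidence source.
Label disagreement at *equal* confidence — whether high/high or low/low,
which are deliberately not distinguished — is mismatch 1 (AI: SM,
panel: M) or mismatch 2 (AI: M, panel: SM) and is resolved by one of four
fixed patterns (I: AI/AI, II: panel/AI, III: AI/panel, IV: panel/panel,
listing the mismatch-1/mismatch-2 winners). Pattern selection maximises F1
on training data; ties break to the lowest-numbered pattern for
determinism. Pattern scoring uses whatever AI probabilities the cohort
carries; the documented default is out-of-sample probabilities (e.g. from
the leave-one-out harness), so training-stage selection is not optimistic.

**Panel selection.** All C(n, k) odd subsets of the rater pool are
enumerated in lexicographic id order and scored by majority-vote F1; ties
break to the lexicographically first subset. Any k over any pool is
supported, not only 3-of-4 experts.

**Metrics.** Sensitivity, specificity, PPV, NPV, accuracy from the 2×2
table; `F1 = 2·sens·PPV/(sens + PPV)`. A ratio with a zero denominator is
reported as `None` (undefined), never silently 0 — a classifier that makes
no positive calls must not appear to have perfect PPV. F1 is 0 when there
are no true positives but positives exist somewhere, and undefined only
when the positive class is absent from truth and predictions alike.
Published tables are reconstructed from printed operating points with
`tp = round(sens·n_pos)`, `tn = round(spec·n_neg)` (round half away from
zero), the convention under which every internally consistent published
cell reproduces to its last printed digit. The confidence-strata
comparison uses the uncorrected Pearson chi-square on the 2×2
(confidence × correctness) table; a flag enables the Yates correction.

## Synthetic cohort generator

No per-case reads or images are publicly deposited for this problem, so
the generator emulates the statistical structure the pipeline consumes.

**AI score.** Binormal latent: `s | M ~ N(0, 1)`, `s | SM ~ N(δ, 1)`, with
`t = Φ⁻¹(spec)` and `δ = t + Φ⁻¹(sens)` so thresholding `s` at `t` hits
the target operating point exactly in expectation. The published
probability is `p_SM = expit(δ·(s − t))` — the equal-prior binormal
posterior recentred so its 0.5 boundary coincides with `t`, hence
thresholding `p_SM` at 0.5 is equivalent to thresholding `s` at `t`. For
degenerate targets with `δ ≤ 0` (at- or below-chance operating points) a
unit slope replaces `δ` to keep `p_SM` monotone in `s`; no preset hits
this branch.

**Rater votes.** One-factor latent Gaussian model: per case a shared
factor `c ~ N(0, 1)`; rater r's latent is `√ρ·c + √(1−ρ)·e_r`. Rater r
votes SM when their latent exceeds `Φ⁻¹(1 − sens_r)` on SM cases and
`Φ⁻¹(spec_r)` on M cases, which pins every rater's marginal operating
point exactly for *any* ρ; ρ alone controls beyond-chance agreement. A
full copula could represent richer dependence but would add parameters
the data could never identify; one interpretable correlation is enough
for the properties the pipeline exploits.

**Covariates.** Tumour diameter ~ lognormal(log 18, 0.45) mm (median
18 mm with a realistic right tail for depressed-type early gastric
cancer) and a 30% undifferentiated-histology rate. With
`covariate_effect > 0`, truth-M lesions that are large (> 30 mm) or
undifferentiated have their AI latent shifted toward SM — emulating the
classifier's documented failure mode of over-calling depth on exactly
those lesions. The effect is off (0) by default and touches only the AI,
not the raters. SM cases are annotated SM1/SM2 by a Bernoulli split
(training preset 95/250, test preset 26/100); the annotation has no effect
on generation.

**Presets.** `training_like`: 250 M / 250 SM, AI at (0.76, 0.78), four
expert raters A–D at (0.616, 0.760), (0.544, 0.892), (0.432, 0.900),
(0.600, 0.696). `test_like`: 100/100, AI at (0.74, 0.71), three raters
each at the panel-level point (0.52, 0.88) — the individual test-cohort
operating points are not identifiable, so identical correlated raters
stand in for them. The default correlation is ρ = 0.5 ("moderate"): true
inter-rater agreement is unreported, so no default claims fidelity to any
particular reader study.

**What passing tests show.** Generated cohorts have exactly calibrated
marginals, Gaussian-factor dependence, and no case-mix drift between
train and test beyond the configured operating points. Real reader data
has none of these guarantees — heterogeneous difficulty, rater drift,
non-Gaussian dependence, site effects. Tests on generated cohorts
therefore validate the *procedure* (selection, fusion, evaluation
plumbing, calibration machinery), not the clinical effect size; the
qualitative ordering (cooperation F1 above either source, high-confidence
accuracy above low) is asserted, exact cohort values are not.

## Evaluation harness

Leave-one-out runs n sequential folds; fold seeds come from a
`SeedSequence` schedule derived from the master seed, so reports are
bit-reproducible. A fold whose training part lacks a class aborts with
the fold index. Harness integrity is guarded by the memorizing-classifier
canary: it predicts 0.5 for any case it has not seen, so a leak of the
held-out case into training is immediately visible. Train/test evaluation
requires disjoint case ids. Strata with an empty confidence band skip the
chi-square (reported as null) rather than fabricating a statistic.

## Problem sizes and numerical choices

Default analysis cohorts are 500 (training-like) and 200 (test-like)
cases, matching the study design the presets emulate; generator
calibration is checked at 10⁵ cases against 3 binomial standard errors,
a size at which target recovery is sharp while generation stays
vectorised and fast. Comparisons against printed values use one unit in
the last printed digit (±0.05 percentage points, ±0.0005 F1). CSV
round-trips preserve floats exactly via `repr`. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

* The fusion rule is fixed to two sources, two labels and two confidence
  levels; no continuous fusion weights are learned.
* Probabilities are taken as given — no calibration step; per-rater
  weighting is out of scope.
* The generator's one-factor dependence cannot represent, e.g., two
  cliques of raters agreeing within but not across cliques.
* One published reference cell (the cooperation NPV on the external test
  design) is internally inconsistent with its own operating point under
  balanced reconstruction and is excluded from comparisons.
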