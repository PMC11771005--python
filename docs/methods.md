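# Methods

## Scoring systems

The three scores are deterministic point sums over categorical and
thresholded continuous items; every cut-off lives in a single frozen
configuration object (`ScoreThresholds`) whose defaults are the published
clinical values:

| threshold | default | used by |
|---|---|---|
| age cut-off | 50 years, strict `>` | preoperative score |
| BMI cut-off | 30 kg/m², strict `>` | all three scores |
| time to identify cystic artery/duct | 90 min, strict `>` | both intraoperative scores |
| binarization boundary | preop ≥ 3, standard ≥ 3, modified ≥ 4 | easy/difficult collapse |

Decisions taken where the source material is ambiguous:

* **Age boundary.** The score table awards the point for age *greater than*
  50 while prose summaries elsewhere use "greater than or equal to". The
  table is the score's contract, so strict `>` is the default;
  `age_inclusive=True` switches to `>=`.
* **Distension sub-items.** Distended/contracted gallbladder, ungraspable
  with forceps, and stone ≥ 1 cm impacted in Hartmann's pouch are additive
  (1 each, max 3). The printed maxima of 10 and 16 are attainable only
  under this reading.
* **Isolated arterial injury.** The modified grade lists only "duct only: 1"
  and "both: 2". An isolated cystic-artery injury scores 1 by symmetry with
  the listed single-structure case, configurable, and emits a warning when
  scored.
* **Time exactly at 90 min** scores 0 (strict inequality, per the "> 90 min"
  wording); the generator never emits a value at exactly the cut-off on the
  slow side.
* **Outcome reference standard.** No published rule defines an operatively
  "difficult" LC. The default is standard (Sugrue) total ≥ 3 — the
  mild/moderate band boundary, the only rule consistent with the reported
  outcome counts — and it is configurable
  (`outcome_label(..., difficult_min=...)`, CLI `--outcome`).

## Diagnostic validation

Metrics are plain ratios of the 2×2 counts with *difficult* as the positive
class; a zero denominator yields NaN plus an explicit `undefined` flag,
never a silent 0. Confidence intervals are Wilson score intervals
(statsmodels), chosen over Wald for their behavior at proportions near 1 —
exactly where a usable clinical score lives. Reports round to 3 decimals;
the underlying objects keep full precision.

The ROC curve uses one operating point per distinct observed score under
the rule "predict difficult when score ≥ t", plus a +∞ sentinel, so it
always spans (0,0) to (1,1). The AUC is the trapezoidal area, which for
this step curve equals the Mann–Whitney concordance statistic with ties
counted ½ — asserted against a brute-force pair-counting oracle and against
scikit-learn in the test suite. Reversing score orientation maps AUC to
1 − AUC; an AUC below 0.5 is labelled Fail with an orientation warning.

## Synthetic cohort model

The generator emulates a 200-patient elective LC series (symptomatic
cholelithiasis, acute cholecystitis excluded):

1. **Preoperative draw.** Sex, admission history, palpable gallbladder,
   scar location and impacted stone are independent draws from their
   marginal frequencies. Age is truncated-normal (mean 47.3, SD 11,
   lower bound 18, rounded to years). BMI is log-normal with log-scale SD
   0.18 and median solved so that P(BMI > 30) equals its configured
   marginal (0.235).
2. **Latent propensity.** η = Σ effect_logit over the patient's active
   risk factors. Default effects are the logs of the published adjusted
   odds ratios, capped at log 20 ≈ 3.0 because the published fit is
   near-separated (odds ratios in the hundreds with intervals spanning
   four orders of magnitude); sex carries 0 (not significant in the
   adjusted analysis); the scar effects (0.7 / 2.0 on the log-odds scale)
   are the package's own choice, as the published fit excluded them.
3. **Intraoperative draw.** Each binary finding follows a logistic model
   p_i = σ(c + γ·η_i) with shared slope γ (`link_strength`, default 1.0)
   and intercept c solved by root-finding so that the *realized-cohort
   mean* of p_i equals the finding's marginal target exactly. The
   three-level adhesion grade uses the proportional-odds analogue (both
   cumulative exceedances calibrated, shared slope, comonotone draw);
   injury calibrates the any-injury indicator and splits severities by
   their conditional proportions. Times are drawn on the correct side of
   the 90-minute cut-off (uniform 15–90 below; 90 + exponential(30)
   above). Operative duration is an unscored pass-through (log-normal
   around 60 min, +45 min under conversion).

This makes every marginal match its target up to binomial noise at any
effect size (the calibration degenerates to p_i = target when γ·η is
constant), while higher-risk patients receive stochastically worse
findings, so the preoperative score discriminates the emergent operative
outcome (AUC ≈ 0.88 at defaults, n = 2000).

**What the generator does not reproduce.**

* The published *difficult* rate. The published per-item marginals imply a
  mean standard score of ≈ 1.26 points, and under *any* monotone
  single-latent dependence preserving those marginals, P(total ≥ 3)
  saturates near 0.17–0.21 (we measured ≈ 0.17 at defaults and in the
  strong-dependence limit). The published 29.5 % difficult rate is jointly
  inconsistent with the published marginals under this model family. The
  marginals win; the default cohort is ≈ 17 % difficult.
* Full preop/outcome independence at null effects. The preoperative score
  and the intraoperative grades share the same patient's BMI > 30 item by
  definition, so even with all effect logits zero the preoperative score
  retains AUC ≈ 0.55 against the outcome; excluding the BMI item from the
  predictor restores chance (0.50) exactly. A green discrimination test
  therefore establishes the latent-propensity pathway *given* this known
  structural coupling.
* Joint distributions beyond the single latent factor: real comorbidity
  patterns (e.g., age–BMI correlation) are not modelled; fields are
  conditionally independent given η.

## Association analysis

Screening fits one single-predictor logistic model per candidate and
retains Wald p < α (default 0.05). The joint fit is Newton maximum
likelihood (statsmodels `Logit`); adjusted odds ratios are exponentiated
coefficients with Wald intervals, matching the convention of standard
statistical packages. Separation is declared when a fitted |coefficient|
exceeds 15 on the log-odds scale (odds ratio > 3 × 10⁶) or the likelihood
is degenerate; a separated screen still *includes* the variable (separation
is overwhelming evidence of association, flagged p = 0) but the
multivariable fit refuses to report Wald estimates for it — without
`penalized=True` it raises an error naming the offending variable, with it
a ridge (L2, α = 1/n) refit supplies stabilized point estimates and the
result is marked penalized, intervals withheld. Firth's penalized
likelihood would be the textbook remedy; no implementation is available in
the dependency set, and the ridge refit is deliberately labelled as the
weaker substitute it is.

Note that under the default outcome rule, separation in `adhesion_burying`
is *expected*, not pathological: a buried gallbladder scores 3 points by
itself and thus deterministically makes the operation difficult — mirroring
the source series, in which every buried gallbladder converted to open.

## Numerical choices

* Intercept calibration solves mean σ(c + x) = p by Brent's method on
  c ∈ [−60, 60] (xtol 1e−12); degenerate targets 0/1 short-circuit.
* Trapezoidal integration via `numpy.trapezoid` on the (FPR, TPR) grid.
* Metric comparisons in tests use exact rational expectations
  (`64/67`-style) rather than re-rounded decimals; rounded presentation is
  confined to the report layer.
* The CSV reader validates cell-by-cell and reports the 1-based row and
  column of the first offending value; record construction aggregates
  row-level invariant violations.

## Known limitations

* Single-latent-factor dependence cannot represent findings that are
  negatively associated given risk, nor the published difficult-rate /
  marginal inconsistency noted above.
* Wald intervals undercover slightly at small n with rare exposures; the
  coverage test (planted log-odds 1.5, n = 5000) measures ≈ 95 %, but no
  small-sample correction is applied.
* The intraoperative grades are scored from recorded findings; the package
  does not model observer subjectivity in, e.g., adhesion grading.
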