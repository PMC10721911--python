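# Methods

## The statistical problem

In depression trials the measured treatment effect confounds a drug-specific
response with a non-specific (placebo) response. Writing the population as a
mixture of three latent classes — D−P− (responds to nothing), D+P+ (responds
to anything), D+P− (responds to drug only) — only D+P− carries drug-specific
information at end of study (EOS). When D+P+ dominates, the arm contrast is
diluted toward zero and a real drug effect is missed (a false-negative,
"failed" trial); when low-propensity subjects dominate, chance imbalances can
inflate the contrast. Propensity-score weighting (PSW) estimates each
subject's probability *p* of showing a placebo response from pre-randomization
data only, and reweights the longitudinal analysis by 1/*p* so the
low-propensity subjects — the only ones able to reveal a drug-specific
signal — carry commensurately more weight, while every randomized subject
stays in the analysis (ITT is preserved; this is weighting, not enrichment).

## Pipeline

1. **Labeling** (placebo arm only). Responder = 100·(B − Y_EOS)/B ≥ 50%,
   where B is the week-0 (randomization) total score — not screening — and
   Y_EOS the EOS total. The threshold is inclusive. Subjects with missing
   EOS are excluded from labeling (no imputation, no LOCF) and tallied;
   B = 0 is flagged as an undefined denominator and excluded.
2. **Split.** Deterministic stratified 75/25 train/validation split of the
   labeled placebo subjects (per-class floors, largest-remainder rounding).
3. **Model.** Features are per-item changes baseline − screening (direction
   is a labeled constant; improvement is negative). Min–max scaling to [0,1]
   learned on the training split only; zero-variance columns dropped. The
   classifier is a fully connected feed-forward network with logistic
   activations and a logistic output (scikit-learn `MLPClassifier`, lbfgs),
   architecture grid-searched over 1–3 layers × {1, 3, 5, 7} nodes/layer by
   stratified 5-fold cross-validated AUC on the training split, ties broken
   toward fewer total nodes, then fewer layers. L2 penalty 1.0 by default:
   placebo training sets here are ~75–130 subjects with 10–17 features, and
   held-out ranking (AUC) is markedly more stable under strong shrinkage
   (mean validation AUC ≈ 0.89 at 160 subjects/arm in the simulator) than at
   weak penalties. Non-convergence restarts with an incremented seed up to 3
   times, then errors.
4. **Validation.** AUC on the held-out 25% by the Mann–Whitney pairwise
   formulation; 95% CI by stratified bootstrap of the held-out (score, label)
   pairs (percentile 2.5/97.5, default 2000 resamples; the model is *not*
   refit per resample — refitting is available behind a flag). The weighted
   analysis is gated on CI lower bound > 0.5, strictly.
5. **Scoring and weights.** The validated model scores all randomized
   subjects with observed screening and baseline; w_raw = 1/max(p, p_floor)
   with p_floor = 0.05, then renormalized to mean 1 (default). Clipping
   bounds the influence of near-zero predicted propensities; mean-1
   rescaling is harmless because the weighted MMRM is invariant to a common
   weight factor (proved as a test invariance). Both defaults can be turned
   off to recover raw 1/p behavior.
6. **Weighted MMRM.** Change from baseline at post-baseline visits, fixed
   effects visit + baseline×visit + treatment×visit (equivalently, a free
   intercept, baseline slope and arm contrast per visit), unstructured T×T
   covariance Σ, subject covariance Σ/wᵢ (the SAS WEIGHT convention —
   weights act as precisions; the mechanism is stated here because the
   originating analyses do not spell it out). REML on the log-Cholesky
   parameterization of Σ, L-BFGS-B with relative objective tolerance 1e-12
   followed by damped Newton polish on numerical derivatives (the polish
   removes finite-difference gradient noise, giving agreement with
   closed-form weighted least squares to ~1e-10 on single-visit data).
   Subjects contribute their observed visits only (direct-likelihood MAR).
   Starting values: pairwise-complete covariance of OLS residuals, ridged to
   positive definite.
7. **Summaries.** LS means = arm means at the overall (unweighted) mean
   baseline, delta-method SEs. TE = placebo − active LS-mean difference at
   EOS (positive when the active arm improves more, since improvement is a
   negative change). Degrees of freedom: Satterthwaite via numerical
   gradient/Hessian of the REML surface, falling back to a between-within
   style n_subjects − n_arms when the numerical information is degenerate
   (differences are immaterial at these sizes; the cheap fallback can also
   be selected directly). p-values are two-sided t, Tukey-adjusted with the
   all-pairwise studentized-range family over all arms (reported only for
   active-vs-placebo rows); with two arms the adjustment reduces exactly to
   the plain t-test and is computed as such. Pooled SD = √Σ̂[EOS,EOS]
   ("model estimate of the pooled SD" admits several readings; the EOS
   diagonal is the default, an across-visit average variance is available
   behind a flag). Effect size = |TE| / pooled SD.

The reference (unweighted) analysis is the same model with wᵢ ≡ 1 and is
bit-identical to the weighted path run at unit weights. A single master seed
fans out to named sub-seeds (split, grid, network, bootstrap); all analysis
choices are frozen in a run manifest before data are read — post-hoc
flexibility in responder definitions or model selection is a type-I-error
machine, so the pipeline makes every such choice explicit and fixed. A
persisted propensity model records its scale definition, and the pipeline has
no codepath for transferring it to another dataset: propensity models are
trial-specific.

## Design statistics

* `two_sample_n`: smallest per-group n whose exact noncentral-t power of the
  two-sided pooled t-test reaches the target (e.g. δ=3, σ=7.5, 80% power,
  α=0.05 → 100/group; d=0.5 → 64/group).
* `truncated_hochberg`: step-up with c_i = (γ/(m−i+1) + (1−γ)/m)·α for the
  i-th smallest p-value — the gatekeeping-literature convention; γ=1 is
  Hochberg, γ=0 is Bonferroni.
* `hochberg_power_sim`: draws all three arms per replicate (n=93, both
  actives shifted d=0.44 SD by default) so the shared-control correlation
  between the two t-tests arises from the trial mechanics rather than an
  analytic bivariate shortcut; reports P(≥1 rejection) and P(both), with
  binomial Monte-Carlo SEs, plus the per-comparison unadjusted rejection
  rate for cross-checking against the noncentral-t closed form.

## Synthetic-trial generator

Each subject draws a latent class from the design's mixture. Screening item
scores are allocated around a typical severity (HAMD-17 total ≈ 22 of 52,
MADRS ≈ 30 of 60) proportionally to item maxima with jitter, clamp-rounded to
instrument bounds (HAMD-17: nine 0–4 items, eight 0–2 items; MADRS: ten 0–6
items). Pre-randomization change adds a class-shifted i.i.d. normal delta per
item (D+P+: −0.50·signal points/item, i.e. early non-specific improvement;
D−P− and D+P−: +0.15·signal; SD 0.8) before clamp-rounding;
`propensity_signal = 0` removes all class information from the deltas.
Post-baseline totals follow a linear ramp to EOS: D+P+ improves by 85% of its
baseline total in *every* arm, D+P− by the arm's drug-specific effect in
active arms only, D−P− not at all. Residual noise is a subject slope (SD
0.6·noise_sd, scaled by the ramp) plus occasion noise (SD 0.8·noise_sd), so
the EOS SD is exactly noise_sd and visits are positively correlated — an
unstructured-covariance target. Item scores at each visit scale the baseline
profile to the target total, with jitter and clamp-rounding. Dropout is
monotone and outcome-independent by default (MAR, matching the MMRM
assumption), with an optional MNAR tilt for stress tests; screening and
baseline are never removed.

`true_propensity` returns the generative probability of a ≥50% EOS
improvement under placebo from the pre-rounding normal model — the recovery
oracle for tests; the analysis pipeline never sees it or the latent class.

**Calibration.** The class mix defaults to D−P− 0.30 / D+P+ 0.55 / D+P− 0.15:
the literature ranges are 30–50% for D−P− and "over 40%" for D+P+, and the
propensity histograms of the motivating trials put the large majority of
subjects above p = 0.8, so the presets sit D+P+ above one half (documented
here as a midpoint-style choice, not a literature constant). The
pre-randomization shift constants were set so a large-sample classifier
reaches validation AUC ≈ 0.88–0.90, the level reported for the real trials,
and the 85% D+P+ improvement fraction yields placebo-arm response rates near
50% — the "extraordinarily high placebo response" regime. The two presets
mirror the motivating designs: `sep360029-like` (4 arms, HAMD-17, EOS week 8,
n=118/arm, two null actives + one effective comparator) and `sep380201-like`
(3 arms, MADRS, EOS week 6, n=93/arm, two equally effective doses). The
default drug-specific effect (22 points among D+P− subjects) makes the
*reference* analysis of a masked-effect trial land near effect size 0.3 —
the published failed-trial pattern — which the weighting roughly doubles.

**What the generator does not emulate:** site effects, dose–response within
drug, adverse-event-driven (outcome-dependent) dropout by default, item-level
factor structure beyond a common severity dimension, and rater drift.
Passing tests therefore show the method's behavior under a faithful but
idealized mixture model, not under every failure mode of real rating data.

## Operating characteristics

`operating_characteristics` reruns the entire pipeline (simulate → label →
split → train → validate → score → weighted + reference MMRM) per replicate
and tabulates rejection rates at adjusted α = 0.05, mean TE, mean effect
size, and the fraction of replicates with weighted effect size above the
reference. The default scenarios cross null/true drug effect with low/high
placebo-propensity mixtures using two-arm trials (60/arm, three post-baseline
visits, no dropout) and a fixed single-hidden-layer (3-node) network with no
validation gate — the harness measures the weighted estimator itself, and
conditioning replicates on validation success would bias the tabulated
rates. Problem sizes here (replicate counts, arms, visits) are chosen to
keep a full run in minutes on one CPU; measured at 500 replicates/scenario,
the weighted analysis holds the null rejection rate at the nominal level and
clearly outpowers the reference analysis when a true effect is masked by a
high-propensity majority.

## Numerical notes and limitations

* Probabilities from the network are clipped to (1e-12, 1−1e-12); weights are
  bounded by the p_floor clip; REML failures (non-PD covariance, optimizer
  abort) raise typed errors rather than returning silent garbage.
* AUC uses the tie-aware pairwise count (ties count ½) and is exactly the
  brute-force concordance on any instance.
* The bootstrap CI is a percentile interval on same-sample re-estimates; its
  lower bound can exceed the point AUC only in pathological tiny samples —
  the result object enforces only lower ≤ upper.
* Satterthwaite df from numerical second derivatives can be fragile for
  near-singular covariance estimates; the implementation guards with a
  pseudo-inverse and the residual-df fallback.
* With very few validation subjects (<~15 per class) the CI-based gate is
  noisy; prospective users should size the placebo arm with the validation
  split in mind (≥150 placebo subjects gives a reliable gate in the
  simulator).
* The weighted model's variance assumption Var(yᵢ) = Σ/wᵢ is a working
  model: weights are estimated, and residual variance in truth need not
  scale with 1/w. The operating-characteristics harness is the empirical
  check that the resulting tests hold their level under the intended
  conditions; no sandwich/robust variance option is currently provided.
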