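# Methods

## The estimation problem

Small training trials in strength athletes (4–8 per arm) cannot support
dichotomous hypothesis testing. The approach implemented here is
estimation-based: posterior distributions of adjusted mean changes in 1RM
(squat SQ, bench press BP, deadlift DL, and their total) are compared
against a *distributional* region of practical equivalence (ROPE) — the
posterior of the mean elicited "meaningful change over six weeks" from a
survey of athletes and coaches. Because the ROPE is a distribution, the
comparison statistics are probabilistic: a probability of superiority and a
probability of equivalence, rather than interval containment.

## Models

### ROPE (intercept-only) model

`Y_i = a + e_i` on elicited changes (kg). Default priors are
weakly-informative in the style of mainstream Bayesian regression defaults:
`a ~ Student-t(3, median(y), 2.5·MAD_n(y))` and a half-t(3, 2.5·MAD_n(y))
residual scale, where MAD_n is the normal-consistent median absolute
deviation floored at 1 kg (floor relevant only for degenerate inputs). The
4,000 retained intercept draws define the ROPE density.

A closed-form oracle (`conjugate_oracle`) gives the vague-limit posterior of
the mean, `mu | y ~ t_{n-1}(ȳ, s/√n)`; it is independent of the sampler and
used to validate it in the tests.

### Change-score ANCOVA

`Y_change = β00 + β10·(Y_pre − mean(Y_pre)) + β20·Group + e` per outcome,
one row per athlete. Centring the pre score makes the intercept the
reference arm's adjusted mean change, so an informed prior "on the
intercept" acts exactly on that arm (treatment coding, informed arm as
reference). Informed priors are normal, built either from a reported
mean ± SD (`prior_from_summary`) or from a previous fit's posterior draws
(`prior_from_posterior`), enabling the chained-studies design (study 2
informs study 3's reference arm; study 3's posterior informs study 4's).
Slope prior: Normal(0, 10) — the change-on-pre slope is dimensionless and
empirically near zero. Group-contrast priors: Normal(0, 10·SD(y)), wide on
the kg scale.

EMM draws per arm are the linear predictor at the pooled mean pre score, so
`EMM(arm) − EMM(reference)` equals the contrast draws exactly (asserted).

A participant-level intercept `u_0i` is available (`include_participant`)
but off by default: with one observation per athlete it is exchangeable
with the residual and not separately identified. Both variants yield the
same EMMs within Monte-Carlo error (tested); when enabled, the convergence
gate applies only to the identified fixed effects.

### Nested meta-model

`Change ~ Pre + (1 | Study/Group/Participant)` pools daily-max-style arms
across studies. Random-intercept SDs carry half-t(3, 2.5·MAD_n(y)) priors.
The "overall" effect reported is the fixed intercept at the pooled mean pre
score. With two or three studies the study-level variance is weakly
identified and the posterior of the overall effect is appropriately wide;
the residual scale and the participant SD are mutually confounded (one
observation per athlete), so the gate covers the fixed effects only — the
confounded pair affects neither the intercept draws nor the reported
summaries.

## Sampler

All models are Gaussian linear models, sampled by a blocked conjugate Gibbs
scheme authored in-package:

* all location parameters (fixed coefficients **and** every random
  intercept) are drawn jointly from one multivariate normal per iteration —
  in small nested designs the intercept and random-effect means are highly
  correlated, and a joint draw removes that slow direction entirely;
* Student-t coefficient priors use the inverse-gamma scale-mixture
  representation; half-t scale priors use the inverse-gamma (Huang–Wand)
  augmentation. Each (variance, auxiliary) pair is swept four times per
  scan — a cheap inner chain that removes the autocorrelation the
  augmentation introduces when the likelihood for a scale is weak;
* variance draws are floored at (1e-4 × prior scale)²: on exactly
  degenerate data (zero residuals) the scale posterior is improper at zero,
  and the floor pins it there; parameters pinned by degenerate data are
  reported as converged with that value;
* chain `c` uses seed `base_seed + c`; defaults are 4 chains ×
  (1,000 warmup + 1,000 sampling) = 4,000 retained draws.

Convergence gate: split R-hat < 1.01 and bulk ESS > 400 (arviz), raising a
`ConvergenceError` naming the offending parameters. With small data and
informed priors, silent non-convergence would corrupt every downstream
AUC/overlap statistic, so failure is an error, not a warning.

## Posterior-vs-ROPE statistics

* **HDI**: shortest contiguous window containing ⌈mass·n⌉ *sorted draws*
  (empirical, not KDE-based) — the standard convention for MCMC output.
* **Mode**: argmax of a Gaussian KDE with Silverman bandwidth on a
  512-point grid over [min, max] of the draws.
* **AUC superiority**: P(effect > rope) + ½·P(effect = rope) via midranks
  (Mann–Whitney U / nm); exact under ties, and identical to brute-force
  pairwise enumeration (property-tested to n, m = 200).
* **Overlap**: ∫ min(f̂, ĝ) of the two Silverman KDEs on a shared 512-point
  grid spanning the union range padded by 3 bandwidths, trapezoid-integrated
  and clamped to [0, 1] (trapezoid error can marginally cross the bounds).

The kernel, bandwidth rule and grid size for mode/overlap are documented
package choices; the mode is deliberately not asserted to lie inside the
HDI (a multimodal posterior's shortest interval can exclude a secondary
mode).

## Synthetic data

The elicitation generator draws per-outcome responses from a normal
distribution at the published survey summary (defaults: SQ 7.1 ± 5.1,
BP 4.4 ± 3.3, DL 8.1 ± 5.0, Total 17.5 ± 12.1 kg; n = 137; role mix
99 athletes / 31 athlete-coaches / 7 coaches). Only means and SDs of the
real survey are published, so normality is an assumption. Options:

* `truncate_at_zero` — elicited meaningful changes are positive, and the
  published SDs imply a non-negligible negative tail under a plain normal;
* `moment_match` — standardize-then-affine transform making the realized
  sample mean/SD exactly equal to the configured values (to 1e-9), so
  summary-anchored checks do not depend on sampling luck. When combined
  with truncation, draws come from a zero-truncated normal whose *parent*
  parameters are solved numerically so the truncated moments already equal
  the target; the exact affine correction is then a near-identity and
  preserves positivity (with a clip-and-rescale fallback).

The cohort generator emulates the intervention studies' structure: per-arm
pre-1RM distributions (defaults from the published arm characteristics,
e.g. back-off arm pre total 535 ± 86.8 kg), additive true mean changes per
lift with configurable change-score SD and an optional slope of change on
pre, body mass for Wilks scoring, strength-class assignment on the
published Wilks bands (300–340 → class 1, …, 510–550 → class 5; gap values
to the nearest boundary, ties down), and per-session logs (main-set RPE
~9.2–9.4, back-off RPE ~6.6, next-day soreness on the 0–5 Likert scale,
AMRAP repetitions at the published means of 13.1/16.7/11.5 for SQ/BP/DL).
Arm-level true changes default to ~11 kg (daily-max only) and ~33 kg
(with back-off sets) in total, matching the magnitudes the studies
estimated. Dropout is participant-level, completely at random (the real
losses were facility closures, not treatment effects).

Not emulated: within-block session-to-session progression, attempt
selection at competitions, respondent-level correlation between outcomes,
and any systematic (non-random) dropout. Passing tests therefore certify
the *statistical machinery* — recovery of known truths under the studies'
structure — not distributional fidelity of real athletes' data.

## Protocol arithmetic and allocation

Weekly working repetitions count main and back-off sets only (warm-ups and
autoregulated AMRAP reps excluded): daily-max singles give 2/3/1 weekly
reps for SQ/BP/DL (6 total); adding 2×3 back-off sets contributes 12/18/6,
i.e. 600% more total weekly volume. Wilks points use the classic 5th-order
male/female polynomial (coefficient table swappable in code). Allocation is
quasi-randomized: athletes binned by strength class, shuffled within class
under a seed, dealt round-robin — whether the original allocation dealt
round-robin or re-drew freely within class is not documented anywhere, so
the deterministic round-robin is this package's choice (it guarantees the
intended between-arm strength matching).

## Problem sizes and numerical choices

Test-time fits use 4 chains × (300 warmup + 400 sampling); the Gibbs
sampler's near-iid draws make this ample for the gate (ESS ≳ 1,200 of
1,600). Recovery suites use 50 replicate cohorts at 8 athletes per arm and
study-like change-score SDs (per-lift 5–8 kg). The prior-influence property
is demonstrated from n = 10 to n = 1,000 per arm: with an informed
Normal(0, 3) prior 30 kg from the truth, the EMM shift decays from several
kg to < 0.5 kg, consistent with the analytic prior-weight calculation.
Degenerate inputs (zero scale, zero noise, constant draws) are routed
through documented floors rather than errors wherever an answer is still
well-defined.

## Known limitations

* The ROPE reflects the surveyed population's opinions; elicited
  "meaningfulness" varies with athlete level, and the model pools all
  respondents (role differences in the published summary are small).
* AUC and overlap treat the effect and ROPE posteriors as independent;
  both derive from the same modelling pipeline, and dependence induced by
  shared data is ignored (as in the original analysis design).
* The normal likelihoods are not robust to heavy-tailed change scores;
  with 4–8 athletes per arm a single outlier moves the posterior.
* The meta-model's variance components are prior-sensitive at 2–3 studies;
  only the fixed effects should be interpreted quantitatively.
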