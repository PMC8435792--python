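# metd

Bayesian evaluation of **minimal-dose strength training** interventions in
powerlifters: does a very low training dose (a few near-maximal singles per
week, with or without light back-off sets) produce 1RM strength gains that
*athletes and coaches themselves* would call meaningful?

The package is aimed at sport-science researchers analysing small two-arm
training trials, and at methodologists interested in elicitation-anchored
effect evaluation. Instead of a fixed smallest-worthwhile-change threshold,
the benchmark — the region of practical equivalence (ROPE) — is a full
probability distribution estimated from survey responses about what 1RM
change (kg) over six weeks counts as meaningful.

## The models

1. **ROPE model** — an intercept-only Bayesian model on elicited meaningful
   changes, `Y_i = a + e_i`, with weakly-informative defaults
   (`a ~ t(3, median(y), 2.5·MAD(y))`, half-t(3) residual scale). The 4,000
   posterior draws of `a` *are* the ROPE distribution.
2. **Change-score ANCOVA** — per study arm,
   `Y_change = (β00) + β10·Y_pre + β20·Group + e`, with the pre score centred
   at its pooled mean so an informed normal prior on the intercept acts on the
   reference arm's adjusted mean change (priors can be chained from a pilot
   summary or a previous fit's posterior). Per-group estimated-marginal-mean
   (EMM) draws are evaluated at the pooled mean pre score.
3. **Internal meta-analysis** —
   `Change ~ Pre + (1 | Study/Group/Participant)`, pooling daily-max-style
   arms across studies with nested random intercepts.

All three are fit by a blocked conjugate Gibbs sampler (4 chains ×
1,000 warmup + 1,000 sampling by default) with a hard convergence gate
(split R-hat < 1.01, bulk ESS > 400) that raises rather than warns.

Each group effect is then compared with the ROPE through four statistics:
the **KDE mode** (most probable change), the **95% HDI**, the **AUC
probability of superiority** P(effect draw > ROPE draw) computed exactly by
midranks, and the **overlap coefficient** ∫ min(f̂, ĝ) of the two densities
(probability of "equivalence").

Supporting modules encode the training protocols (daily-max singles at
RPE 9–9.5 on a 2-3-1 squat/bench/deadlift frequency; back-off sets of 3 at
80%; AMRAP at 70% 1RM), weekly-repetition volume accounting, classic Wilks
scoring, Wilks-class quasi-randomization, and synthetic generators for both
the elicitation survey and quasi-randomized training cohorts, so the whole
pipeline is testable offline.

## Worked example

```python
from metd import (ElicitationConfig, generate_elicitation, InterceptOnlyModel,
                  McmcConfig, CohortConfig, GroupConfig, generate_cohort,
                  ChangeScoreAncova, summarize_effect)

# ROPE from a survey sample moment-matched to the published summary
# (n=137, powerlifting total: 17.5 +/- 12.1 kg)
survey = generate_elicitation(ElicitationConfig(moment_match=True, seed=42))
rope_fit = InterceptOnlyModel.from_dataframe(survey, "Total").fit(McmcConfig(seed=42))
print(rope_fit.summary().round(2))
rope = rope_fit.rope()

# two-arm cohort with the published pre-score structure, 8 athletes per arm
cohort = generate_cohort(CohortConfig(study="study3", groups=(
    GroupConfig(label="MAX", protocol="MAX", n=8,
                true_change={"SQ": 4, "BP": 3, "DL": 4},
                change_sd={"SQ": 5, "BP": 4, "DL": 5},
                pre={"SQ": (182.5, 36.3), "BP": (126.5, 18.5), "DL": (215.0, 31.8)},
                body_mass=(85.8, 13.5)),
    GroupConfig(label="MAX_BOFF", n=8,
                true_change={"SQ": 12, "BP": 9, "DL": 12},
                change_sd={"SQ": 5, "BP": 4, "DL": 5})), seed=42))

res = ChangeScoreAncova(cohort, "Total", reference="MAX").fit(McmcConfig(seed=42))
for group, draws in res.emm_draws.items():
    s = summarize_effect(draws, rope, group=group, outcome="Total")
    print(f"{group:9s} mode {s.mode:5.1f} kg  95% HDI [{s.hdi_low:.1f}, {s.hdi_high:.1f}]"
          f"  AUC {s.auc_vs_rope:.3f}  overlap {s.overlap_vs_rope:.3f}")
```

Output:

```
            mean    sd   mode  hdi_95%_low  hdi_95%_high  rhat  ess_bulk
parameter
intercept  17.53  1.04  17.53        15.51         19.53   1.0   3962.42
sigma      12.21  0.76  12.18        10.64         13.60   1.0   4181.66
MAX       mode   9.6 kg  95% HDI [0.1, 18.6]  AUC 0.055  overlap 0.127
MAX_BOFF  mode  33.9 kg  95% HDI [25.2, 43.3]  AUC 0.999  overlap 0.005
```

Reading: respondents consider a total gain of about 17.5 kg (95% HDI
15.5–19.5) meaningful. The daily-max-only arm's most probable gain is
~10 kg with only a 5.5% probability of exceeding the ROPE, while adding two
back-off sets yields ~34 kg with a 99.9% probability of exceeding it and
essentially no overlap with the ROPE — a clearly meaningful effect.

## Command line

```bash
metd simulate --seed 1 --out data/            # synthetic survey + cohort
metd rope --elicitation data/elicitation.csv  # ROPE draws + summary
metd fit  --cohort data/cohort.csv            # ANCOVA EMM draws
metd compare --draws emm_draws.csv --rope rope_draws.csv
metd meta --cohort data/cohort.csv            # nested meta-analysis
metd report --sessions data/sessions.csv      # RPE/soreness descriptives
metd all --config run.yaml --seed 1           # full pipeline
```

Exit codes: 0 success, 2 configuration error, 3 convergence failure.
`summary.json` holds one record per group and outcome with the fields
`mode, hdi_low, hdi_high, hdi_mass, auc_vs_rope, overlap_vs_rope,
n_effect_draws, n_rope_draws, rope_source, source`.

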