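# priorcox

Bayesian subgroup analysis of two-arm survival trials using elicited expert
opinion. Expert quantile answers ("how many of 100 treated patients recover
within the horizon?") are transformed to the log hazard-ratio scale, fitted
with normal distributions, pooled across experts, and assembled into a
bivariate normal prior on the two subgroup treatment effects
`(theta1, theta2)`. A community of priors — clinical, sceptical, interaction,
interaction-variance and vague — is derived by re-centring and by
re-parameterising onto (mean effect, interaction effect). Each prior is
combined with the trial data in a Bayesian Cox proportional-hazards model and
compared against the frequentist MLE.

## Modules

| module | role |
|---|---|
| `priorcox.elicitation` | quantile answers → normal log-HR distributions; linear opinion pooling |
| `priorcox.priors` | bivariate prior construction and the community of priors |
| `priorcox.cox` | Efron partial likelihood, Cox MLE, MCMC posterior, summaries, shrinkage report |
| `priorcox.simulate` | synthetic trial tables and expert-answer fixtures with known ground truth |
| `priorcox.pipeline` | end-to-end orchestration and report rendering |

The Bayesian model uses the Efron-corrected partial log-likelihood directly as
the likelihood, a bivariate normal prior on `(theta1, theta2)` and vague
`N(0, L)` priors on the subgroup main effect and adjustment covariates.
Sampling is by independence Metropolis from a multivariate-t proposal centred
at the posterior mode with scale from the observed information; convergence is
gated on split R-hat and bulk ESS.

## CLI

```sh
# synthetic trial + expert fixture
priorcox simulate --scenario qualitative_interaction --n 121 --seed 7 --outdir out/

# full analysis: pooled elicitation, five priors, MLE + Bayesian fits, report
priorcox run-all --trial out/trial.csv --answers out/answers.csv \
    --seed 7 --outdir out/analysis

# individual stages
priorcox elicit-fit --answers out/answers.csv --factor renal_risk --out elicited.json
priorcox build-priors --answers out/answers.csv --out priors.json
priorcox fit --trial out/trial.csv --answers out/answers.csv --prior interaction --outdir fits/
priorcox report --bundle out/analysis/report.json --outdir rerendered/
```

`run-all` writes `report.json`, `report.txt`, `priors.json`, `forest.svg` and
`posteriors/<label>.json` into the output directory.

## Data formats

- Elicitation CSV: `expert_id,subgroup_factor,question,q025,q50,q975,usual_care_ref`
  with `question` in `{uncond_less_severe, uncond_more_severe, cond_null,
  cond_benefit}`; counts are integers out of 100.
- Trial CSV: `id,arm,subgroup,age_gt70,female,creat_gt160,ef_lt50,angio_5d,time_days,event`
  with `arm` 0/1 (1 = intervention), `subgroup` 0/1/NA (1 = more severe),
  `event` 0/1.
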