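# igc-induction

Bayesian analysis pipeline for the development of participation in
intergroup conflict (IGC) by non-adult vervet monkeys — and a synthetic
cohort generator that makes every stage of that analysis testable with
known ground truth.

Intergroup conflict is costly and cooperative, and how young animals are
drawn into it speaks directly to how group-level behaviour is socially
transmitted. This package implements, end to end, the statistical
machinery for asking that question with field data from a multi-group,
multi-year study design: which infants and juveniles join a given
conflict, how aggressively they behave once joined, whether they are
groomed between conflict bouts, and whether the groomer is their mother.
It is aimed at behavioural ecologists who want the full chain — covariate
construction from raw observation streams through hierarchical Bayesian
models to diagnostics — as reusable, tested code.

## What it computes

From three observation streams (scan samples, agonistic records, IGC
records) plus a life-history roster and a neophilia index, the pipeline
builds, for every non-adult × IGC of its group:

- **Elo rank** on the event date (sequential ratings from dyadic contests,
  Gaussian expectation curve, k = 100, start 1000; standardized within
  group-date);
- **eigenvector centrality** in annual troop-level grooming (directed,
  weighted) and spatial (undirected) networks, computed by power iteration
  per connected component and max-normalized;

and fits four models with a logit link, normal(0, 1) priors on
standardized fixed effects and half-normal(0, 1) priors on random-effect
SDs, sampled by an in-package No-U-Turn sampler with analytic gradients:

1. **Participation** (yes/no) — Bernoulli GLMM with age, sex, rank,
   neophilia, both centralities, maternal participation, participant
   counts of both sides and their interaction, group sizes; random
   intercepts for individual-in-focal-group crossed with opposing group.
2. **Aggression level** (1–4, participants only) — cumulative-ordinal
   GLMM in which maternal aggression level (0–4) enters as a monotonic
   predictor `mo(x; ζ) = D Σ_{j≤x} ζ_j` with a Dirichlet simplex ζ.
3. **Grooming receipt** (yes/no, all non-adults) — Bernoulli GLMM with
   participation among the predictors.
4. **Nested double hurdle** (participants only) — hurdle 1: was the
   participant groomed; hurdle 2, defined only if groomed: was the groomer
   the mother; separate coefficients and nested random intercepts
   (individual ⊂ mother ⊂ group) per hurdle, with the row likelihood
   `(1−y₁)log(1−p₁) + y₁[log p₁ + y₂ log p₂ + (1−y₂)log(1−p₂)]`.

Reported per model: posterior means, 95 % credible intervals, probability
of direction, split-chain R-hat and ESS; conditional and marginal
Bayesian R² (latent-scale convention for the ordinal model); tie-corrected
ROC AUC for the hurdle submodels; posterior-predictive tables and residual
autocorrelation reports.

The synthetic generator (`igc_induction.synthetic`) emulates the study
design — seasonal cohorts, mothers with offspring, scan sampling at a
10-minute window every 30 minutes, latent-strength agonism, Poisson IGC
streams — and draws all outcomes from exactly the model families above,
with ranks and centralities produced by running the real pipeline stages
on the synthetic streams. Its defaults are calibrated to the study
system's headline descriptives (≈79 % of IGCs with non-adult
participation; levels ≈76/9/13/1 %; maternal co-participation ≈42 %; mean
participant age ≈2.5 y).

## Worked example

Generate a scaled study window (68 non-adults, 240 days, reduced event
rate), build the panel, and fit the participation model at test-scale
sampler settings:

```python
import json
from igc_induction import generate_dataset, load_tables, build_event_panel
from igc_induction.config import study_window_config
from igc_induction.pipeline import build_model, describe_dataset, model_r2

cfg = study_window_config(seed=1, igc_rate=0.1)
generate_dataset(cfg, out_dir="demo")
panel = build_event_panel(load_tables("demo"))

print(json.dumps(describe_dataset(panel), indent=1))
res = build_model("m1", panel, chains=2, iterations=600).fit(seed=1)
print(res.summary(ess=False).round(2))
```

prints (abridged):

```
 "n_igcs": 70,
 "pct_igcs_with_nonadult_participation": 80.0,
 "pct_mother_coparticipation": 40.6,
 "mean_participant_age_years": 2.5
                           mean  ci_2.5  ci_97.5    pd  rhat
b_age                      0.74    0.52     1.00  1.00   1.0
b_mother_participated      0.71    0.29     1.10  1.00   1.0
b_n_focal_participants     0.70    0.51     0.91  1.00   1.0
b_sex_male                 0.11   -0.27     0.48  0.72   1.0
```

80 % of the 70 synthetic conflicts involved at least one non-adult, and
the posterior recovers the generating regime: participation rises with
age (`b_age`, generating value 0.9), with maternal participation (0.85)
and with the number of focal-group participants (0.6), while the sex
effect (truth 0) straddles zero with pd ≈ 0.7. `model_r2(res,
"conditional")` adds the explained-variance summary (here ≈ 0.16 against
0.23 marginal — see `docs/methods.md` on why the ordering can invert when
group intercepts are collinear with group-size covariates).

A CLI wraps the same stages:

```bash
igc-induction simulate --out demo --seed 1 --cohort 12 --days 120
igc-induction panel --data-dir demo --out panel.csv
igc-induction describe --data-dir demo
igc-induction fit --data-dir demo --model m1 --chains 2 --iterations 600
igc-induction run-all --out run --seed 3
```

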