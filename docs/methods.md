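# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `igc_induction`, at the level of detail a user
needs to judge what a passing test suite does and does not establish.

## The scientific setting

Wild vervet monkeys (*Chlorocebus pygerythrus*) engage in frequent
aggressive intergroup conflicts (IGCs). The package models how infants and
juveniles ("non-adults") come to take part: whether a non-adult joins a
given conflict, how aggressively it behaves once joined, whether it is
groomed between conflict bouts, and whether the groomer is its mother.
The data streams are those of a long-term field study: instantaneous scan
samples (activity, grooming partner, neighbours within 3 m, collected in a
10-minute window every 30 minutes), ad-libitum agonistic records
(aggressor, victim, outcome), and per-IGC records of participants, their
maximum aggression level, and within-conflict grooming dyads. Aggression
intensity uses a five-level ordinal scale: 0 non-participant,
1 non-aggressive (present at the site), 2 stationary (facial/vocal
threats), 3 active (lunge/charge/chase), 4 physical (slap/grab/bite).

## Covariate construction

**Elo ranks.** Dominance rank is the Elo rating on the day of each IGC.
Each decided contest transfers `k (1 - E)` points from loser to winner,
where `E` is the winner's expected score; the default expectation curve is
the Gaussian form `E = Phi((r_w - r_l) / (200 sqrt 2))` with `k = 100` and
start value 1000 — the defaults of the reference R implementation common
in animal-dominance work, since no overrides are documented for this
system. Draws score 0.5 for both parties; `unknown` outcomes are skipped.
Ratings are piecewise constant between contests; the model covariate is
the rating standardized (mean 0, SD 1) across the group members alive on
the event date. Between-group aggression carries no within-group rank
information and is ignored by the rating run.

**Social networks.** Per group and calendar year (365-day blocks of the
integer day index), a directed weighted grooming network (edge weight =
number of scans with that groomer-to-groomee dyad) and an undirected
spatial network (weight = number of scan records placing the pair within
3 m) are built over all roster members; unobserved individuals are
isolates. Eigenvector centrality is the leading eigenvector of the
weighted adjacency, computed per connected component by shifted power
iteration (shift = max row sum, which makes the spectrum non-negative so
bipartite components cannot cause oscillation; tolerance 1e-10) and
normalized to max 1 per component; isolates score 0. The default
symmetrizes the grooming digraph (weight = in + out), matching the common
default of graph libraries; a directed variant (left eigenvector, i.e.
centrality from being groomed by the well-groomed) is available because
the choice is not documented for the original analysis.

**Panel.** One row per non-adult alive in the focal group per IGC, with
age in days, a male dummy, rank, neophilia (an externally supplied index
in [0, 1]; missing values are imputed at the population mean and flagged),
year-matched grooming and spatial EC, maternal participation (0/1) and
maternal level (0-4) read off the event's participant map, participant
counts of both sides, both group sizes, and the four responses
(participation, level, groomed, groomed-by-mother). Continuous covariates
are scaled and mean-centred; binary dummies are not. The participant
subsets used by Models 2 and 4 inherit the full panel's scaling so that
coefficients are comparable across models. "Independent juveniles" are
available as a filter at a configurable weaning threshold (default 365
days; the original cut-off is not printed anywhere we could verify).

## The four models

All responses use a logit link. Fixed effects and monotonic coefficients
carry normal(0, 1) priors on the standardized scale; random-intercept SDs
half-normal(0, 1); ordinal thresholds normal(0, 5); monotonic simplexes
Dirichlet(1, ..., 1). The first two priors follow the original analysis'
"weakly informative normal(0, 1)"; the latter two are this package's
declared defaults, as the originals are not documented.

- **Model 1 (participation, Bernoulli).** Age, sex, rank, neophilia,
  grooming EC, spatial EC, maternal participation, focal and opposing
  participant counts with their interaction, both group sizes; random
  intercepts for individual nested in focal group, crossed with opposing
  group. Full-scale default: 4 chains x 2500 iterations.
- **Model 2 (aggression level 1-4 of participants, cumulative ordinal).**
  Same structure, with maternal participation replaced by maternal level
  (0-4) as a monotonic predictor: `mo(x; zeta) = D * sum_{j<=x} zeta_j`,
  `zeta` a simplex of per-step increments, so the coefficient is the
  average per-step effect and the dose-response is constrained monotone.
  4 chains x 4000 iterations.
- **Model 3 (groomed during the IGC, Bernoulli, all non-adults).**
  Participation plus sex, age, rank, neophilia, both ECs, focal group
  size and participant counts; individual nested in focal group.
  4 chains x 3500 iterations.
- **Model 4 (nested double hurdle, participants only).** Hurdle 1: was
  the participant groomed (groomee in at least one within-IGC dyad;
  grooming others does not count). Hurdle 2, defined only for groomed
  rows: was any groomer the mother. Both hurdles share covariates (sex,
  age, rank) but carry separate coefficients and separate random-intercept
  SDs for individual in mother in focal group; the joint likelihood

      log L = (1-y1) log(1-p1) + y1 [log p1 + y2 log p2 + (1-y2) log(1-p2)]

  factorizes, so the two hurdles are sampled as independent Bernoulli
  posteriors and reported as a pair. 8 chains x 500 iterations.
  Performance is summarized by in-sample ROC AUC (tie-corrected
  Mann-Whitney rank statistic) of posterior-mean probabilities, with
  random effects included ("full") or zeroed ("main_only").

## Sampling

No probabilistic-programming backend is assumed: the package ships a
No-U-Turn sampler with dual-averaging step-size adaptation (target
acceptance 0.9, max tree depth 8) and diagonal mass-matrix estimation
from the middle 60 % of warmup, operating on analytic gradients of the
log posterior. All parameters are sampled on an unconstrained scale: log
SDs (half-normal prior plus Jacobian), non-centered random effects
(`b = sigma z`), anchored-softmax simplexes (Dirichlet(1) prior reduces
to the softmax Jacobian `sum log zeta`), and thresholds as a free first
cut plus log increments. Gradients are verified against finite
differences to ~1e-9 relative error in the test suite, and the sampler is
validated on Gaussian targets with known moments. Chains start from a
data-informed point (empirical threshold frequencies, SDs at 0.3) with
uniform jitter, so split-R-hat is meaningful. The fit gate warns when any
parameter's split R-hat exceeds 1.01; test-scale runs use far fewer
iterations than the full-scale defaults and may warn without invalidating
the checks they support.

## Diagnostics conventions

- **pd** (probability of direction): `max(P(theta > 0), P(theta < 0))`
  over draws, zeros counted to the majority side.
- **R-hat**: split-chain PSRF (each chain halved); constant chains return
  1 by convention. Cross-checked against arviz, which also supplies bulk
  ESS.
- **Bayesian R²**: draw-wise. Bernoulli models use
  `Var(p_s) / (Var(p_s) + mean(p_s (1 - p_s)))`; conditional includes the
  sampled random intercepts, marginal zeroes them ("main effects"). The
  ordinal model uses the latent-logit convention with residual variance
  `pi^2 / 3`, and is labelled as such — the variance scale of a cumulative
  model is not comparable to the Bernoulli one, so its R² should be read
  qualitatively. Note that conditional R² can drop below marginal when
  few-level group intercepts are collinear with group-constant covariates
  (group sizes); this is a property of the decomposition, not an error.
- **Residual autocorrelation**: lag-1..k autocorrelation of date-ordered
  posterior-mean Pearson residuals within individual, averaged across
  individuals.
- **Posterior-predictive check**: a table of observed vs replicated
  response shares (participation rate, level distribution) with 95 %
  replication intervals, rather than a purely visual check.

## The synthetic cohort generator

The generator emulates the study's structure so that every stage is
testable without field data: three groups, seasonal birth cohorts one
year apart (configurable anchor), mothers in the same group with one or
two offspring each, adult group cores, scan sampling (20 windows/day at
the default 10 h and 30-min interval, 5 observation days per week),
ad-libitum agonism driven by static latent strengths (aggressor wins with
probability `logistic(s_agg - s_vict)`), and IGC events as a per-group-day
Poisson stream with a uniformly sampled opposing group.

Crucially, the covariates that drive the outcome models are *not* drawn
independently: ranks come from running the package's Elo stage on the
synthetic agonism stream, and centralities from running the network stage
on the synthetic scans, so integration bugs surface in recovery tests.
Maternal participation is drawn first from an adult propensity model;
offspring outcomes condition on it. Outcomes are then drawn from exactly
the model families fitted: participation from the Model-1 logistic,
participant levels from the Model-2 cumulative-ordinal with the monotonic
maternal term, grooming from the hurdle-1 logistic (with a participation
coefficient so the same draw also serves Model 3), and groomer-is-mother
from hurdle 2. Random intercepts are drawn independently per model
family. The recorded per-event participant counts are the adult
participant counts (drawn before non-adult outcomes), which keeps the
recorded covariate identical to the generating one.

**Default conditions.** The defaults are the study system's conditions:
cohort sizes (23, 23, 22) (68 non-adults), 1460 study days, 0.765 IGCs
per group-day (~3350 events at full scale), 11.6 agonistic records per
group-day, and an 8x grooming-kernel multiplier for mother-offspring
dyads. The participation intercept (-3.2), ordinal thresholds
(2.05, 2.78, 5.35) and maternal participation propensity (0.235) were
calibrated once by forward simulation so the generated cohort reproduces
the study's headline descriptives — ~79 % of IGCs with at least one
non-adult participant, participant levels ~76/9/13/1 %, maternal
co-participation ~42 %, near-even sex split, mean participant age
~2.5 years — and then frozen. `study_window_config()` provides a
scaled-down 240-day window late in the cohorts' development (birth anchor
-950) that preserves the age structure and per-event statistics at a
fraction of the runtime; descriptive checks and the acceptance script use
it.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: spatially explicit movement and home-range
geometry (opposing groups are sampled uniformly), demography during the
study (no births after the three cohorts, no deaths or migration),
observation error other than optional uniform missingness, IGC duration
or multiple bouts (one grooming opportunity per non-adult per event),
temporal autocorrelation beyond what the shared random intercepts induce,
and any feedback from conflict outcomes to subsequent behaviour.

## Problem sizes in tests and the acceptance script

Simulation sizes are chosen to make the statistical checks informative at
interactive runtimes: parameter-recovery uses 20 replicate cohorts of
roughly 1300-1500 panel rows (24 non-adults, 70 days, elevated IGC rate,
moderate effect sizes on every covariate, individual RE SD 0.5) fitted
with 2 chains x 500 iterations at target acceptance 0.85; the null
calibration uses 5 replicates with all coefficients at zero. Coverage counts at 20 replicates are binomial(20, ~0.95) per effect, so
across the ~33 fixed effects checked an occasional count of 17 is the
expected behaviour of a calibrated sampler, not a defect; and
group-constant covariates (the group sizes) are nearly collinear with the
three-level group intercepts, so their interval calibration is governed
by three group draws rather than the row count. The
acceptance script runs the study-window cohort with the IGC rate reduced
to 0.3 (per-event statistics are rate-invariant) so the four models fit
in minutes at 2 chains x 500 iterations, and reports descriptives, R²,
AUCs, oracle-agreement errors and a reduced recovery coverage rate.
Full-scale sampler settings (the per-model chain/iteration defaults
above) remain the package defaults for real analyses.

## Known limitations

- The sampler is single-machine and pure NumPy; full-scale runs (4 chains
  x 2500+ iterations on tens of thousands of rows) are feasible but slow
  (tens of minutes). The fit contract is deliberately small so a faster
  backend can be slotted in.
- Ordinal R² and the monotonic-transform scaling (`D * sum zeta`, making
  the coefficient the average per-step effect) follow documented
  conventions of the R ecosystem the original analysis used; an unscaled
  variant differs only by rescaling.
- AUCs are in-sample, as reported in the source analysis; they will be
  optimistic relative to cross-validated values, especially with random
  effects included.
- Elo parameters (k, start, curve) are assumptions, exposed in the
  configuration; a sensitivity sweep against deposited data is the
  appropriate check if exact replication is attempted.
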