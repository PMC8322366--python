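# sensormiss

Quantifying **sensor non-collection** in duty-cycled smartphone
digital-phenotyping studies.

Smartphone sensors in research apps alternate between an *on-cycle*
(recording) and an *off-cycle* (sleeping), so the expected data volume
is known at the design stage: a schedule with `on` and `off` seconds
implies `E = floor(86400 / (on + off))` collection attempts — *measurement
groupings* — per day (1 min on / 9 min off ⇒ 10% coverage, 2.4 h of
data per 24 h, E = 144). Everything short of that expectation is
non-collection: the phone was off, the sensor disabled, or the OS
suppressed collection. `sensormiss` is for study teams and
methodologists who need to measure that missingness from raw timestamp
logs and model who is missing data and how it evolves.

The package

1. **segments** raw sensor timestamps into measurement groupings
   (maximal runs separated by gaps ≥ half the off-cycle),
2. **builds** a participant-day panel of missing vs expected groupings
   `y = max(0, E − observed)` joined to demographic covariates, and
3. **fits** a Bayesian hierarchical negative-binomial regression

       y_ij ~ NegBin(mu_ij, omega)
       log(mu_ij) = log(E_j) + alpha0 + beta_1 X_1ij + ... + beta_p X_pij
                    + gamma_0ij + delta_0j
       gamma_0ij ~ Normal(0, sigma_gamma^2)     (participant)
       delta_0j  ~ Normal(0, sigma_delta^2)     (study)

   with offset `log E`, participant and study random intercepts, NUTS
   sampling, rank-normalized split/folded R-hat and bulk/tail ESS
   convergence gates, and WAIC / PSIS-LOO / Bayes R² model comparison.

Because raw clinical sensor logs cannot be redistributed, the package
ships a first-class synthetic-data module that emulates duty-cycled
event streams and cohorts with realistic demographic margins, with
full ground truth for every downstream stage. See `docs/methods.md`
for models, priors, the sampling parameterization, and limitations.

## Worked example

Simulate a six-study GPS cohort (180 participants, 90 days each) from
published point estimates and refit the model:

```python
from sensormiss import *
from sensormiss.simulate import GPS_TRUE_PARAMS

cfg = SimConfig(n_studies=6, participants_per_study=30,
                days_per_participant=90, seed=0)
cohort = generate_cohort(cfg)
panel, truth = simulate_panel(cohort, GPS_TRUE_PARAMS, cfg)
model = NonCollectionModel.from_dataframe(panel)
res = model.fit(McmcSpec(n_chains=4, n_warmup=500, n_samples=750,
                         seed=1, target_accept=0.92))
print(res.summary())
```

Output (about a minute on one core):

```
Hierarchical negative-binomial model of sensor non-collection
==============================================================
Observations: 16200   Participants: 180   Studies: 6
Chains: 4   Draws/chain: 750   Divergences: 17
Converged (R-hat <= 1.01, ESS >= 100/chain): True

Fixed effects (exponentiated, rate ratios):
                 estimate  ci_low  ci_high  sd_log  significant
term
intercept          0.2458  0.1437   0.4317  0.2753         True
week               1.0034  0.9984   1.0082  0.0025        False
os_ios             0.9309  0.7018   1.2385  0.1430        False
...

                              median  ci_low  ci_high
parameter
sd participant (sigma_gamma)  0.7660  0.6909   0.8541
sd study (sigma_delta)        0.4125  0.1904   1.0136
NB shape (omega)              0.7389  0.7227   0.7552
```

Reading it: the `intercept` row, 0.246 (95% CI 0.144–0.432), is the
conditional non-collection *rate* — the expected fraction of a day's
144 scheduled GPS groupings that go missing at week 0 for the
reference covariate pattern (here the simulation truth was 0.269).
`week` is the rate ratio per week in study (1.0034 ⇒ +0.34% per week);
`os_ios` the iOS-vs-Android ratio. A row is flagged significant when
its 95% interval excludes 1. `sigma_gamma` > `sigma_delta` says
participants differ far more than studies do. About 10% of simulated
participant-days hit the design ceiling `y = E` (`truth.clip_rate`),
the bounded reality an unbounded count model cannot express — which is
why the recovered participant SD (0.77) sits slightly below the
generating value (0.888).

The same pipeline runs from the shell:

```bash
sensormiss simulate --seed 7 --out run/          # events, panel, covariates, truth
sensormiss panel --events run/events.csv --covariates run/covariates.csv \
                 --design design.yaml --sensor gps --out run/panel.csv
sensormiss fit --panel run/panel.csv --chains 4 --seed 7 --out run/fit/
sensormiss pipeline --config study.yaml --out run/   # all stages + manifest
sensormiss recovery --replicates 20 --seed 7 --out run/recovery/
```

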