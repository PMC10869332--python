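# autrel — cognitive models of learning automation reliability

Human operators working with automated decision aids continuously judge how
reliable the automation is, and revise that judgment with every observed
success or failure. `autrel` implements and compares eight cognitive models
of that learning process, fitted to trial-by-trial 0–100 reliability
judgments from individual participants:

| model | idea | learning parameters |
|---|---|---|
| `bayesian` | beta-binomial belief in a single fixed reliability | p, q |
| `delta` | prediction-error update r_t = r_{t−1} + α(AC_t − r_{t−1}) | r0, α |
| `two_kernel` | slow + fast delta learners; fast reported when they diverge beyond a threshold | r0, α_slow, α_fast, T |
| `sampling_recency` | one memory sampled with delta-rule (recency) weights | r0, α_sampling |
| `sampling_last_average` | samples the last outcome or the running average | r0, weight_r0, prob_last |
| `contingent` | predicts from outcomes that followed matching m-histories | r0, m |
| `iiab` | "if it ain't broke": re-estimates only at detected change points | T1, T2, p, q, p_cp, q_cp |
| `no_update` | constant intercept (no learning baseline) | r0 |

Every model additionally estimates a response-noise parameter σ. Judgments
y_t are modelled as y_t/100 ~ TruncNormal(r_t, σ; 0, 1), where r_t is the
model's latent reliability estimate after contact t (for memory-sampling
models, a finite mixture). Models are fitted per participant by multi-start
bounded maximum likelihood and compared with BIC = k·ln(n) − 2·loglik;
individual participants are classified by the BIC-best model, with
approximate Bayes factors exp(ΔBIC/2) below 3.2 treated as inconclusive.

The package also ships the automation-correctness schedules of the three
experiments this paradigm comes from (eight between-subjects conditions with
stepped reliability changes, e.g. 90% → 30% → 90%), a synthetic-cohort
generator with disengaged-responder styles and the matching engagement
exclusion rules, and parameter-/model-recovery studies. It is aimed at
researchers in human–automation teaming and probability learning who want to
fit these models to their own judgment series (a flat CSV, one row per
contact) or to simulated data.

## Worked example

Simulate one participant who learns by the delta rule (r0 = 0.8, α = 0.3,
σ = 0.12) on the large-drop design (90% reliability, then 30%, then 90%),
then fit and compare three models:

```python
import autrel as ar

schedule = ar.make_schedule(3, "large_drop", seed=7)
series = ar.simulate_participant(
    "delta", {"r0": 0.8, "alpha": 0.3, "sigma": 0.12}, schedule, seed=42,
)
fits = ar.fit_all_models(series, models=("delta", "bayesian", "no_update"),
                         settings=ar.FitSettings(n_restarts=10), seed=0)
for name, fit in sorted(fits.items(), key=lambda kv: kv[1].bic):
    pars = ", ".join(f"{k}={v:.2f}" for k, v in fit.params.items())
    print(f"{name:10s} BIC={fit.bic:8.1f}  loglik={fit.loglik:7.1f}  k={fit.k}  {pars}")
result = ar.classify_participant(fits, series.participant_id)
print(f"best model: {result.best_model}  (Bayes factor vs runner-up: {result.bayes_factor:.2g})")
```

```
delta      BIC=  -359.5  loglik=  187.4  k=3  r0=0.94, alpha=0.30, sigma=0.10
no_update  BIC=   -59.8  loglik=   35.0  k=2  r0=1.00, sigma=0.42
bayesian   BIC=   -47.3  loglik=   31.3  k=3  p=50.00, q=0.10, sigma=0.36
best model: delta  (Bayes factor vs runner-up: 1.2e+65)
```

The delta rule wins decisively and recovers the generating learning rate and
noise (α̂ = 0.30, σ̂ = 0.10). The start point r0 is only weakly identified
from a single series — it is down-weighted geometrically after the first few
contacts — which is why recovery is assessed over whole cohorts
(`ar.parameter_recovery`, `ar.model_recovery`). The static Bayesian model
cannot produce recency effects (it weights all experiences equally), so it
falls behind even the no-learning baseline here.

Learners also come as scikit-learn-style estimators when that is more
convenient:

```python
learner = ar.DeltaRuleLearner(n_restarts=10, random_state=0)
learner.fit(series.bits(), series.judgments)
learner.params_, learner.bic_          # fitted parameters, BIC
learner.predict(series.bits())          # expected 0-100 judgment per contact
```

Cohort-level outputs live in `autrel.report`: summed-BIC comparison tables
(winner subtracted to 0), per-trial fit curves split by whether the previous
automation decision was correct, M (SE) parameter summaries, and
individual-difference percentage tables. A `click` CLI exposes the pipeline
(`autrel simulate-design / simulate-cohort / fit / compare / report /
recover`).

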