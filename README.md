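# camtrigger

Tools for estimating a camera trap's **trigger probability** — the chance
that an animal passing through the field of view actually fires the
camera — from experimental detection trials.

Camera-trap studies lose animals to false negatives: an animal is present
but no image is recorded. The overall probability of recording an animal
over `N` visits factors as

```
p = 1 - [1 - (r_e * r_t * r_p)]^N
```

where `r_e` is the probability of encountering the camera's sample unit,
`r_t` the probability of triggering the camera given an encounter, and
`r_p` the probability that a triggered image is usable. This package
implements an experimental framework for `r_t`: scored pass-by trials
(body-size proxies walked past cameras at known distances under a
balanced factorial layout) are analysed in two stages.

**Stage 1 — distance response.** Trial outcomes are Bernoulli with
success probability declining in distance `y` according to one of three
detection-function families,

```
exponential   p(y) = exp(-y / α)
half-normal   p(y) = exp(-y² / (2α²))
hazard-rate   p(y) = 1 - exp(-(y/α)^(-γ))
```

each optionally multiplied by a logistic term
`1 / (1 + exp(-(y - loc) · steep))` that lets detection collapse
immediately in front of the camera, where an animal can pass beneath the
PIR sensor cone. All six candidates are fit by maximum likelihood and
ranked by AIC.

**Stage 2 — deployment covariates.** Outcomes are regressed with a
logit-link binomial GLM on body size, camera model, lens height, aiming
distance, vertical angle, speed and sun position, plus the selected
stage-1 fitted probability as a `distance_model` covariate (with
body-size × distance-model and camera × distance-model interactions),
with backwards stepwise selection under the marginality rule and ROC/AUC
evaluation. Because the vertical camera angle is strongly rank-correlated
with lens height and aiming distance, covariates are organised into an
angle suite and a height + aiming suite.

A full-factorial design generator, a two-stage trial simulator and a
solar-position utility make the entire pipeline testable without field
data.

## Worked example

Simulate trials whose trigger outcomes follow a known half-normal–logistic
mixture (α = 6 m, dip centred at 1.5 m), then fit and rank all six
candidates:

```python
import camtrigger as ct

cfg = ct.default_simulation_config(seed=1)
cfg.coefficients = None            # detection mode: P(trigger) = p(y)
trials = ct.simulate_trials(cfg)   # 3780 balanced trials

fits, labels = [], []
for family, mixture in ct.candidate_labels():
    fits.append(ct.fit_detection_function(trials, family, mixture))
    labels.append(f"{family}{' + mixture' if mixture else ''}")
table = ct.select_model(fits, labels)
print(table)
```

```
                model  K      LL    AIC  dAIC
half_normal + mixture  3 -1902.6 3811.2   0.0
     hazard + mixture  4 -1922.4 3852.8  41.5
          half_normal  1 -1994.4 3990.9 179.6
          exponential  1 -2024.8 4051.5 240.3
exponential + mixture  3 -2024.5 4055.1 243.8
               hazard  2 -2077.5 4158.9 347.7
```

The generating family wins by 41.5 AIC units, and its parameters land on
the truth (`alpha = 6.03 m` against 6.0). `K` counts estimated
parameters, `LL` is the maximized Bernoulli log-likelihood, and `dAIC`
is each candidate's AIC above the best model — 0 marks the selected one.

Conditioning the stage-2 regression on the fitted stage-1 model (here on
trials simulated with covariate effects switched on):

```python
stage1 = ct.fit_detection_function(trials, "half_normal", mixture=True)
covariate_trials = ct.simulate_trials(ct.default_simulation_config(seed=1))
model = ct.TriggerGLM(terms=ct.ANGLE_SUITE_TERMS, detection_function=stage1,
                      stepwise=True).fit(covariate_trials)
print(model.coefficient_table())          # Estimate, SE, z, p per term
roc = ct.roc_auc(covariate_trials["outcome"], model.predict_proba(covariate_trials)[:, 1])
print(f"AUC = {roc.auc:.3f}")             # AUC = 0.895
```

```
                         Covariate  Estimate    SE      z     p
                         Intercept    -1.889 0.343 -5.513 0.000
                 body_size[medium]    -2.396 0.488 -4.907 0.000
                  body_size[large]    -0.472 0.354 -1.333 0.183
               camera_model[PC900]    -1.162 0.335 -3.472 0.001
                    distance_model     6.243 0.421 14.825 0.000
                             speed    -0.950 0.161 -5.884 0.000
                      sun_altitude    -0.330 0.152 -2.162 0.031
                       sun_azimuth    -0.427 0.088 -4.848 0.000
  body_size[medium]:distance_model     2.387 0.716  3.332 0.001
   body_size[large]:distance_model     0.139 0.554  0.251 0.802
camera_model[PC900]:distance_model     1.664 0.507  3.283 0.001
```

Negative coefficients (e.g. `body_size[medium]`, `speed`) lower the
log-odds of a trigger relative to the large-ungulate / HP2X baselines; a
positive `body_size[medium]:distance_model` interaction means the
medium-proxy penalty shrinks where the distance response is strong.
Estimates here sit close to the simulator's true values (e.g. 6.243
against a true `distance_model` effect of 6.5).

The same workflow is available from the shell:

```sh
camtrigger run-all --seed 1 --out-dir out/
# out/: selection.tsv, selected_fit.json, glm_angle.tsv, glm_height.tsv,
#       roc_*.csv, marginal_distance_*.csv, manifest.json
```

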