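# renresp

Longitudinal logistic modeling of binary renal response with informative
dropout, exposure–response covariates, and clinical-trial simulation.

## The problem

In lupus nephritis trials, efficacy is often summarized as a binary composite
renal response (e.g., PERR — Primary Efficacy Renal Response, or the stricter
CRR — Complete Renal Response) assessed every four weeks over two years.
Patients drop out, and dropout is informative: non-responders leave the study
faster than responders. The common composite ("dropout = non-responder")
imputation conflates staying in the study with responding, which can bias
covariate effects — in particular apparent exposure–response relationships for
a drug whose clearance is increased by the very proteinuria that also predicts
poor response.

`renresp` is for pharmacometricians and trial statisticians who want to

- fit a longitudinal logistic model of per-visit responder probability,
- jointly model dropout with responder-status-dependent constant hazards
  (a while-on-treatment estimand) or use the composite imputation,
- test baseline proteinuria and early average drug concentration
  (Cavg4/Cavg12) as covariates via likelihood-ratio tests,
- simulate responder-probability bands under parameter uncertainty and
  compare them to observed rates with exact (Clopper–Pearson) intervals, and
- generate fully synthetic trials with the same statistical structure, so
  every analysis step is runnable and testable without any patient data.

## The model

On-treatment responder probability at time `t` (days since first dose):

    logit P_RESP(t) = RR_SS − Δ_RR · exp(−K_RR · t) + θ_BEL · TRT

with covariate sub-models (natural logs, each term vanishing at its reference)

    RR_SS  = θ1 + θ5 · log(PROT_BL / 2.5)
    Δ_RR   = θ2
    K_RR   = θ3 + θ6 · log(PROT_BL / 2.5)
    θ_BEL  = θ4 + θ7 · log(PROT_BL / 2.5) [+ θ8 · log(Cavg12 / 90) or log(Cavg4 / 95)]

Dropout follows a piecewise-constant hazard that is `HZ_R` while the
carried-forward status is responder and `HZ_NR` while non-responder. A subject
with last on-treatment visit at `T1` and dropout at `T2` contributes

    L = [ Π_i P_RESP(t_i)^y_i (1 − P_RESP(t_i))^(1−y_i) ] × P_SURV(T1) × P_DROP(T2)

with `P_SURV(T1) = exp(−∫₀^T1 HZ(t) dt)` and
`P_DROP(T2) = 1 − exp(−(T2−T1)·HZ)`; completers are right-censored at day 728.
Fits minimize OBJ = −2 log L; nested-model OBJ drops are χ² likelihood-ratio
statistics (one added parameter needs ≈ 10.8 points at P = 0.001). Simulated
all-comers response multiplies `P_RESP(t)` by survival under the
response-weighted hazard `HZ(t) = HZ_R·P_RESP(t) + HZ_NR·(1−P_RESP(t))`.

## Worked example

```python
from renresp import GeneratorConfig, ResponderDropoutModel, simulate_trial

trial = simulate_trial(GeneratorConfig(seed=7))       # 224 placebo + 224 treated
model = ResponderDropoutModel(n_starts=1).fit(trial)  # joint efficacy-dropout fit
print(model.result_.report())
```

prints

```
endpoint=PERR dropout=joint cavg=none
OBJ = 12304.75  (n = 448, converged = True)
parameter         estimate      %RSE
theta1              0.1512      27.7
theta2                5.04       6.9
theta3             0.01276       7.0
theta4              0.2121      22.9
theta5             -0.2292      20.5
theta6           -0.005139       8.4
theta7             -0.5932      10.7
log_hz_r            -8.459       2.5
log_hz_ratio         1.662      13.4
```

The generating truth for this synthetic trial was θ = (0.161, 4.61, 0.0117,
0.212, −0.316, −0.00448, −0.577) with log hazards (−8.46, 1.64): every
estimate lands within about two standard errors of it. `log_hz_ratio ≈ 1.66`
says non-responders drop out at roughly `e^1.66 ≈ 5×` the responder rate.
Testing whether 12-week average concentration adds anything on top of
proteinuria (it should not — this trial was generated with θ8 = 0):

```python
from renresp import ModelSpec, exposure_model_comparison
res = exposure_model_comparison(
    trial,
    ModelSpec(dropout_strategy="joint"),
    ModelSpec(dropout_strategy="joint", cavg_metric="cavg12"),
    n_starts=1,
)
print(f"exposure LRT: delta OBJ = {res.delta_obj:.2f}, p = {res.p_value:.3f}")
# exposure LRT: delta OBJ = 0.44, p = 0.509
```

The same workflow is available from the shell:

```
renresp generate --seed 7 --out-dir out
renresp fit --data out/trial_on_treatment.csv --out-dir out
renresp compare-exposure --data out/trial_on_treatment.csv --cavg cavg12 --out-dir out
renresp vpc --data out/trial_on_treatment.csv --n-samples 500 --out-dir out
```

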