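# cardiotd

Cellular toxicodynamic (TD) modelling of doxorubicin (DOX)-induced
cardiomyocyte toxicity and dexrazoxane (DEX) cardioprotection, with
in vitro-to-clinical translation.

DOX is a highly effective anthracycline whose cumulative, dose-limiting
cardiotoxicity restricts its clinical use; DEX is the only approved
cardioprotectant. `cardiotd` is for pharmacometricians and quantitative
pharmacologists who want to (i) describe the time course of AC16 human
cardiomyocyte viability under DOX, DEX, and their combination with a
mechanistic ODE model, (ii) estimate the model's parameters from plate-assay
viability data, and (iii) extrapolate the fitted cellular model to clinical
dosing regimens to rank DEX:DOX dose ratios and dosing schedules by an
integrated toxicity metric.

## The model

Untreated cells grow exponentially; each drug inhibits growth linearly in
its medium concentration; DOX additionally stimulates cell death through a
saturable (Hill/Emax) function whose effect is delayed by a chain of three
transit compartments; DEX antagonizes the DOX death signal through a second
Hill function acting on the input of the chain:

```
K_DOX  = Kmax · C_DOX / (KC50 + C_DOX)
K_DEXi = Imax · C_DEX / (IC50 + C_DEX)

dK1/dt = ktr · ((K_DOX − K_DEXi) − K1)        K1(0) = 0
dK2/dt = ktr · (K1 − K2)                      K2(0) = 0
dK3/dt = ktr · (K2 − K3)                      K3(0) = 0
dR/dt  = (1 − (S_DOX·C_DOX + S_DEX·C_DEX)) · kg · R − K3 · R,   R(0) = R0
```

with R the % viability, ktr the transit rate (mean transit time per
compartment τ = 1/ktr ≈ 8 h), and medium concentrations decaying as
C(t) = C₀·e^(−k_deg·t) (k_deg,DOX = 0.022/h, k_deg,DEX = 0.054/h). Setting
C_DEX = 0 gives the single-agent DOX model; a DEX-only arm reduces to
growth inhibition (no kill chain).

For clinical translation, plasma concentrations from a three-compartment
DOX model (CL 53.3 L/h, V 17.7 L for a 1.8 m² subject) and a two-compartment
DEX model (kel = k12 = k21 = 1/h, V 14.6 L) drive the same cellular model
(converted to µM by molar mass; initial viability 100%). Toxicity of a
regimen is the area under the viability-time curve (AUEC, %·h);
cardioprotection is AUEC(DOX+DEX)/AUEC(DOX).

Estimation is naive-pooled weighted least squares with a proportional error
model on log-transformed parameters; precision is reported as %RSE from the
Gauss-Newton Hessian, with a seeded bootstrap cross-check. Because the
original raw data are not publicly deposited, the package ships a seeded
synthetic-data generator that emulates the published study designs, and the
estimator is validated by simulate-and-refit parameter recovery.

## Worked example

```python
import cardiotd as ct

p, d = ct.DEFAULT_TD, ct.DEFAULT_DEGRADATION
v = ct.simulate_invitro(ct.InVitroCondition(0.5, 100.0), p, d)
print(v)          # viability (%) at 0, 12, 24, 48, 72 h
```

```
[101.  103.  103.4  84.8  55.1]
```

0.5 µM DOX alone leaves 19.9% viability at 72 h; co-incubation with 100 µM
DEX (above: 55.1%) rescues most of the kill while mildly slowing growth.
Fitting a synthetic noisy experiment recovers the generating parameters
(`examples/02_fit_synthetic_experiment.py`):

```
parameter      estimate    %RSE       truth
kg             0.011617     2.2      0.0115
kmax_dox       0.068838     1.9      0.0697
kc50_dox         0.1016     7.4       0.107
imax_dexi      0.057496    10.9      0.0625
ic50_dexi        32.237    21.2          39
```

and the clinical ratio scan (`examples/03_clinical_translation.py`) ranks
DEX:DOX dose ratios at DOX 50 mg/m² Q3W ×3:

```
ratio  auec_ratio      1 -> 1.091,  5 -> 1.344,  10 -> 1.512,
                      20 -> 1.584, 50 -> 1.426
```

Protection rises steeply to ~10:1, plateaus over 10–20:1, and declines by
50:1, where DEX's own growth inhibition outweighs its saturated anti-kill
benefit.

The `examples/` scripts cover each capability; a thin CLI
(`cardiotd generate|fit|translate|scan`) wraps the same functions for
shell pipelines. Modelling details, assumptions, and numerical choices are
documented in `docs/methods.md`.

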