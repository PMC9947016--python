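# Methods

## Cellular toxicodynamic model

The package models % viability R(t) of AC16 human cardiomyocytes (an
immortalized line, hence exponential growth rather than a homeostatic
baseline) under DOX and DEX exposure. The structure combines four
mechanistically motivated pieces:

* **Growth.** dR/dt = kg·R with baseline R0. kg = 0.0115/h doubles viability
  about every 60 h; R0 ≈ 101% is a fitted assay baseline, not physiology.
* **Linear growth inhibition.** Each drug scales kg by
  (1 − S·C): S_DOX = 0.167/µM, S_DEX = 0.00968/µM. The linear form is an
  empirical description valid over the tested concentration ranges
  (DOX 0.5–10 µM, DEX 5–100 µM); nothing prevents the bracket from going
  negative at concentrations far outside them, which matters for clinical
  extrapolation (below).
* **Delayed DOX kill.** A Hill function K_DOX = Kmax·C/(KC50 + C)
  (Kmax = 0.0697/h, KC50 = 0.107 µM) feeds a chain of three first-order
  transit compartments with rate ktr = 0.126/h (mean transit time
  τ = 1/ktr ≈ 8 h per compartment); the last compartment's signal K3 acts as
  a second-order loss term K3·R. The chain reproduces the observed ~1–2 day
  lag between exposure and cell death.
* **DEX anti-kill interaction.** In combination arms a second Hill function
  K_DEXi = Imax·C_DEX/(IC50 + C_DEX) (Imax = 0.0625/h, IC50 = 39 µM) is
  subtracted from the chain input. This is an empirical lump of all
  cardioprotective mechanisms (TOP2β catalytic inhibition, iron chelation
  by the hydrolysis product), none of which are modelled individually.

Single-agent arms are special cases: C_DEX = 0 recovers the DOX model
exactly; a DEX-only arm has no death signal to antagonize, so its kill
chain is identically zero and only growth inhibition remains. The
simulators dispatch on whether the condition contains DOX; the raw
right-hand side (`td_rhs`) also exposes the literal combination equations,
in which a DEX excess would make the chain input negative.

**Net-kill clamping.** The combination equations allow K_DOX − K_DEXi < 0,
i.e. surplus DEX would *stimulate* growth through the kill chain. In vitro
this barely occurs (concentrations decay together); clinically, DEX plasma
concentrations transiently exceed the in vitro regime ~10-fold. Simulators
therefore accept `clamp_net_kill`, flooring the chain input at zero.
In vitro fitting defaults to the literal equations (faithfulness to the
fitted model); clinical simulation defaults to clamped (guarded
extrapolation), and the ratio scan reports both modes side by side. The
choice is recorded on every simulation result.

**Medium degradation.** Both drugs degrade mono-exponentially in culture
medium (k_deg,DOX = 0.022/h, k_deg,DEX = 0.054/h), concentration-independent
and mutually non-interacting. The closed form C₀e^(−kt) is evaluated
directly as a time-varying forcing rather than co-integrated — fewer
states with no accuracy loss; a test verifies agreement with co-integration
to 1e-8 relative.

## Pharmacokinetics

DOX: linear three-compartment mammillary model, clearance parameterization
(CL 53.3, V 17.7, Q2 58.7, V2 1830, Q3 21.8, V3 71.6; L and L/h for a
1.8 m² subject). The printed source table concatenates compartment labels
and values; the adopted pairing (Q2 with the 1830 L compartment) follows
the table's own ordering. DEX: two-compartment model in rate-constant form,
kel = k12 = k21 = 1/h exactly as printed (whether these are rounded is
unknowable) and V = 14.6 L.

Both models are linear ODE systems with piecewise-constant infusion input,
solved exactly per segment via eigendecomposition of the rate matrix
(superposition, dose proportionality, and AUC = Dose/CL then hold to
solver-independent accuracy); a stiff-ODE fallback covers numerically
defective rate matrices. Doses are mg/m² × BSA (default 1.8 m²) given as
15-min (0.25 h) constant-rate infusions.

**Unit bridge.** Plasma mg/L is converted to µM with molar masses
DOX 543.52 and DEX 268.27 g/mol (free base / parent compound). Total plasma
concentration is assumed to drive the cellular model — no protein-binding
or tissue-distribution correction; both choices are configurable and are
the main caveat on absolute clinical numbers.

## Estimation

All fits are naive-pooled weighted least squares with proportional
residuals (obs − pred)/pred — appropriate for pooled in vitro plate data
with no subject structure; the residual-error model of the original
analysis is unstated, so proportional is this package's choice.
Parameters are optimized on the log scale (positivity by construction;
log-scale SEs read directly as relative errors), within broad positivity
boxes, using trust-region-reflective least squares. Multi-start (default
10 starts, ±3-fold log-uniform jitter, seeded) guards against local
minima. %RSE = 100·SE(log θ) from the inverse Gauss-Newton Hessian at the
optimum with residual-variance scaling; if the Hessian is singular the fit
is flagged non-identifiable instead of reporting standard errors. A seeded
replicate-level bootstrap (default 200 resamples) is available as a
cross-check.

Degradation rates are fitted separately (log-linear regression on each
decay series) and then fixed during the TD fit, mirroring their sequential
use. The nine TD parameters are fitted simultaneously to all condition
classes; parameters a missing class cannot inform (e.g. Imax/IC50 without
combination arms, S_DEX without any DEX exposure) are held at their
starting values and flagged rather than silently estimated. Default
starting values: kg from a control-only log-linear prefit, R0 = 100%,
half-max constants at the midpoint of the tested concentration ranges,
slopes 0.01/µM, rate constants at generic hour-scale magnitudes
(Kmax 0.05/h, Imax 0.03/h, ktr 0.1/h).

The DEX PK fit estimates kel, k12, k21, V jointly across dose levels
(each modelled as a single 15-min infusion); a k12 estimate collapsing
below 1e-3·kel is flagged as one-compartment behavior.

## Synthetic data

The generators emulate the study designs so that every pipeline stage is
testable without the undeposited raw data:

* viability: 16 conditions (control; DOX 0.5/1/2.5/5/10 µM;
  DEX 5/10/25/50/100 µM; 0.5 µM DOX × each DEX level — DEX:DOX ratios
  10:1–200:1), t = 0/12/24/48/72 h, triplicates → 240 records. The range
  endpoints are the study's; interior levels are a fixed package choice.
* degradation: mono-exponential series on 0–72 h.
* DEX PK: single-infusion profiles at 50–2500 mg/m², sampled at
  0.25–24 h post infusion start.

Noise is multiplicative lognormal, obs = pred·exp(σz) with σ = ln(1 + cv)
(small-cv approximation; empirical CV ≈ cv, verified in tests). The default
cv = 7.5% is a stand-in chosen to resemble typical CCK-8 replicate scatter
— the true replicate variance is unpublished. Generators are pure
functions of (inputs, seed); identical seeds reproduce byte-identical
datasets. Not emulated: plate-position/batch effects, the CCK-8 absorbance
signal chain, and any real-data outliers — so recovery results demonstrate
estimator correctness under the assumed error model, not robustness to
assay artifacts.

## Translation and regimen optimization

A clinical simulation starts at 100% viability with an empty kill chain,
integrates the TD system driven by the plasma concentration curves
(piecewise integration across infusion boundaries; LSODA with rtol 1e-8,
atol 1e-10, the package-wide solver contract chosen because AUEC
differences between dose ratios are small), and reports a dense profile on
a 0.25 h grid. AUEC is the trapezoidal integral of that profile
(grid-refinement changes it by <0.01%); windows are one cycle [0, 504] h
and three cycles [0, 1512] h.

The ratio scan co-administers DEX at r× the DOX dose on the same Q3W
schedule for r ∈ {0, 1, 5, 10, 20, 50} and computes
AUEC(DOX+DEX)/AUEC(DOX) per ratio. The optimum is the smallest ratio
within 1% of the maximal AUEC ratio, resolving near-ties toward the lowest
DEX burden. Under the reference parameters the clamped scan yields
1 / 1.091 / 1.344 / 1.512 / 1.584 / 1.426: a steep rise to 10:1, a shallow
plateau across 10–20:1 (4.6% apart — wider than the 1% tie band, so the
rule as parameterized selects 20:1), and a decline at 50:1 driven by
S_DEX·C_DEX growth inhibition once the anti-kill Hill term has saturated.
The mechanism, not the exact tie resolution, is the robust finding: the
protective optimum sits in the 10–20:1 range, and fractionating DOX weekly
reduces rather than improves nine-week protection, with Q3W + 10:1 DEX the
best arm.

Virtual populations draw per-subject TD parameters lognormally with median
equal to the typical value and CV = 10% (σ² = ln(1 + cv²)), seeded; PK
parameters stay at typical values. Population scans use paired per-subject
AUEC ratios (same subject in numerator and denominator) and report the
median with 5/95 percentiles.

## Numerical and design notes

* Canonical units: hours; µM in vitro; mg and L clinically; % viability.
  Conversions only at module boundaries.
* The transit parameter is stored as the rate ktr (as estimated);
  τ conversions are provided (`TDParams.tau_dox`, `TDParams.with_tau`).
* The pooled-fit objective simulates all conditions as one stacked ODE
  system per evaluation, keeping a full nine-parameter fit ~1 s.
* Proportional residuals guard against division blow-up with a 1e-9 floor
  on predictions (active only far from any optimum).
* AUEC windows outside the simulated profile, negative concentrations,
  non-positive molar masses, unsorted dose events, and missing t = 0
  records are rejected with explicit errors.
* Known limitations: no intracellular mechanism (ROS, TOP2β, iron
  chelation), no PBPK heart compartment, no protein binding, no clinical
  endpoint (LVEF/biomarker) prediction — the clinical simulations rank
  regimens by a cellular surrogate, they do not predict patient outcomes.

## Validation problem sizes

The shipped validation uses 50 simulate-and-refit replicates for the TD
model (median recovery of kg/Kmax/KC50 within ~1%, Imax ~5%, IC50 ~7%;
%RSE medians reproduce the expected precision ordering, IC50 weakest) and
100 replicates for degradation-rate recovery; both sizes give Monte-Carlo
error comfortably inside the asserted tolerances while keeping the full
suite around ten minutes on one CPU.
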