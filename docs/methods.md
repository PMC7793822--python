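# Methods note

This document records the model structure, the assumptions behind the packaged
defaults, the numerical choices, and the known limits of the synthetic data.
Units are fixed throughout: amounts in nmol, concentrations in ng/mL (µM at the
PD boundary), volumes in L, flows and clearances in L/h, intrinsic clearances
in µL/min/mg protein, doses in mg, times in h.

## 1. Model structure

### 1.1 Minimal PBPK topology

Each orally dosed parent drug (vicagrel, clopidogrel) carries four states:
lumen, portal vein, liver, and a single lumped systemic compartment.
Metabolites (2-oxo-clopidogrel, AM-H4) carry portal/liver/systemic states only.
One extra bookkeeping state per compound accumulates eliminated moles so mole
balance can be checked at every output time.

Absorption is first-order (`ka`) out of the lumen with bioavailable fraction
`fa` applied at dosing. Gut-wall first pass is algebraic: the absorbed flux is
split by

    Fg = Q_gut / (Q_gut + fu_gut * CLint_gut,scaled),   fu_gut = 1

with the extracted fraction handed mole-for-mole to the gut metabolites in
proportion to their pathway clearances (CES2 and AADAC for vicagrel;
clopidogrel has no gut pathways, so Fg = 1).

Organ disposition is flow-limited: portal inflow `Q_portal` from the systemic
pool, hepatic arterial inflow `Q_ha`, venous outflow `Q_h = Q_portal + Q_ha`.
Hepatic metabolism removes drug from the liver compartment at
`fu_blood x CLint_scaled x C_liver`, which recovers the well-stirred clearance
`Q fu CLint/(Q + fu CLint)` at steady state. Metabolized moles transfer to the
product compound's liver state. A first-order systemic clearance (`renal_cl`)
covers non-organ routes: the labile AM-H4 thiol (300 L/h) and the rapidly
hydrolyzed vicagrel ester (100 L/h).

The system is linear: Michaelis–Menten saturation is deliberately not modeled,
because therapeutic concentrations of these substrates sit far below the Km of
the esterase and CYP routes involved.

### 1.2 In-vitro-to-in-vivo scaling

`CLint_scaled (L/h) = clint (µL/min/mg) x protein (mg) x 60 / 1e6`, with liver
protein = MPPGL (40 mg/g) x liver weight (1,500 g Chinese, 1,650 g Caucasian)
and a fixed intestinal enzyme-bearing protein pool of 3,000 mg.

### 1.3 Anchor constraints in the default configuration

The supplementary parameter tables of the source work are unavailable, so the
packaged defaults are constrained exactly by the printed anchors:

- clopidogrel CES1 clint 300 µL/min/mg (so the 428 G/A factor 0.8 gives the
  printed 240), with the CYP sum fixed at 300 x 0.15/0.85 so the oxidative
  fraction is exactly 15% (CYP2C19 60%, CYP1A2 and CYP2B6 20% each);
- vicagrel CES2 clint 46,100 µL/min/mg (so /20 gives the printed 2,305), with
  AADAC at 53/47 of CES2 so its gut-hydrolysis share is exactly 53%;
- 2-oxo-clopidogrel CES1 clint 20 (0.8 x 20 = the printed 16) and a total CYP
  sum of 16, so the static formation-fraction arithmetic
  (16/36)/(16/32) = 8/9 ≈ 0.889 reproduces the published CES1 G/G-to-G/A
  AM-H4 exposure ratio of 0.89. The CYP sum is a calibration constraint, not a
  measured value.

All other values (molecular weights, fu, volumes, ka, flows) are standard
literature or documented package defaults; each line of
`src/vicasim/data/default.yaml` carries a provenance tag.

### 1.4 Pharmacogenetics

CYP2C19 phenotypes scale the enzyme's abundance multiplicatively: EM 1.0,
IM 0.5 (gene-dose assumption), PM 0.0 (null alleles). CES1 428 G>A retains 80%
activity; defective CES2 retains 1/20. Genotype factors multiply every clint
of that enzyme across compounds.

### 1.5 Platelet PD

The platelet pool P obeys `dP/dt = kin − P kout − P C kirre` with P normalized
to baseline 1 (`kin = kout` enforced by the schema), C the total plasma AM-H4
concentration in µM, `MPA(t) = MPA0 x P(t)` and `IPA = (1 − P) x 100`. After
washout, P relaxes at `kout` alone, so recovery from inhibition IPA0 to the
10% threshold takes `ln(IPA0/10)/kout`.

Defaults: `kout = kin = 0.0124 1/h` (ln(8)/kout ≈ 168 h ≈ 7 days from ~80%
inhibition), `kirre = 55 1/(µM·h)` calibrated once so the maintenance-dose
population-mean IPA sits in the documented 60–90% band (~74% at the last
dose), `MPA0 = 60%`. Because `kin = kout` is a structural normalization, a
single shared turnover multiplier is sampled per subject and applied to both;
`kirre` and `MPA0` get independent multipliers.

### 1.6 Virtual populations

Inter-individual variability is log-normal with median 1
(`sigma^2 = ln(1 + CV^2)`): CV 0.4 on every intrinsic clearance, 0.3 on
ka/v_sys, 0.2 on PD constants. 100 subjects in a 10 x 10 trial layout, with
CYP2C19 phenotype frequencies Chinese {EM 0.42, IM 0.45, PM 0.13} and
Caucasian {EM 0.73, IM 0.25, PM 0.02}. Scenario comparisons use a paired-arm
design: the identical sampled subjects are simulated in both arms with only
the phenotype/genotype/inhibitor factor changed, so ratio-of-means estimates
are nearly noise-free at n = 100.

### 1.7 Perpetrators

Perpetrator drugs are deterministic one-compartment oral models with
closed-form (Bateman superposition) kinetics; no variability. Omeprazole
(80 mg/day) acts by mechanism-based inactivation of CYP2C19
(`dE/dt = k_deg(1−E) − k_inact I/(KI+I) E`, k_i_app 1.7 µM, k_inact 2.5 1/h);
simvastatin (80 mg/day) inhibits CES1/CES2 competitively (Ki 0.11/0.67 µM,
factor `1/(1 + I_u/Ki)`). Hepatic enzymes see the unbound plasma
concentration; intestinal enzymes see the enterocyte surrogate
`I_gut(t) = ka x A_lumen(t) / Q_gut`, i.e. the absorption flux diluted into
the villous flow. A naive "dose over gut volume" surrogate yields mM-scale
levels that would shut gut CES2 down completely, contradicting the modest
published parent-exposure shift, so the flux-based surrogate is used and
documented here.

The CYP2C19 degradation constant is `k_deg = 0.02 1/h` (pool half-life ≈
35 h), the standard hepatic CYP turnover value; much smaller published-table
values would imply implausible month-long enzyme half-lives.

## 2. Numerical choices

- Integration: LSODA (stiff-capable) piecewise between dose events, relative
  tolerance 1e-8, absolute 1e-10 nmol. Without a perpetrator the system is
  time-invariant and the constant Jacobian is supplied analytically; with a
  perpetrator the right-hand side evaluates the closed-form inhibition factors
  at solver time (memoized per time point).
- Output grids: 0.1 h spacing during dosing days, 1 h during washout.
- PD integration: LSODA, rtol 1e-8, atol 1e-12, with the driving concentration
  interpolated piecewise-linearly and the step size capped so doses are not
  stepped over.
- AUC/Cmax: linear trapezoid on the output grid with exact endpoint
  interpolation; interval AUCs only (no extrapolation). Ratios are ratios of
  arithmetic means, matching the published table footnote.
- Determinism: all sampling uses a single seeded generator with a fixed draw
  order, so identical seeds reproduce byte-identical outputs.

## 3. Synthetic "observed" data

The published verification compared predictions against concentration and IPA
time courses digitized from six trials; those data are not redistributable.
The synthetic stand-ins mirror only the *structure*: sparse sampling times
(0.25–24 h), multiplicative log-normal residual error on concentrations
(default CV 20%, median-preserving) and additive normal error on IPA (default
SD 5 percentage points, clipped to [0, 100]). They are generated *from the
model itself*, so fold-error verification against them demonstrates the
workflow, not clinical accuracy; no claim is made of matching the real trial
values. The residual magnitudes are package defaults — the source work reports
no residual model.

## 4. Known limitations and honest deviations

- **Vicagrel parent exposure under CES2 deficiency.** The published table
  implies a several-hundred-fold rise in intact vicagrel for CES2-defect
  carriers. With AADAC fixed at a 53% share of gut hydrolysis, total gut
  extraction falls by at most about half when CES2 drops 20-fold, so this
  model yields a wild/defect parent ratio of roughly 0.5–0.6, not ~0.003.
  The two printed claims (53% AADAC share; ~300-fold parent shift) are not
  jointly reproducible in any Fg-type gut model; the AM-H4 ratio (the
  clinically relevant quantity, ≈ 1.00) is unaffected.
- **CES2-axis Ki sensitivity is nearly flat, with a tiny reversed drift.**
  Stronger CES2 inhibition under AADAC compensation marginally *reduces* AM-H4
  (CES2 flux reroutes to AADAC at almost the same total extraction, while the
  remaining CES2 share shrinks). The drift is ~1e-4 on the AUC ratio across
  the whole Ki range; tests bound it at 1e-3 rather than asserting a strict
  sign. The CES1 axis is strictly monotone and dominates, as published.
- **IM activity (0.5) and PM activity (0.0)** are point assumptions; real
  CYP2C19 abundance distributions are proprietary to the original simulator.
- **Perpetrator PK carries no variability**; under the paired-arm design the
  victim variability dominates ratio noise.
- **Scenario sizes** (100 subjects, 10 x 10; 7-day phenotype regimens; 4-day
  genotype/DDI regimens; 5-day perpetrator pretreatment; 14-day washout) are
  package defaults mirroring the published designs and can be overridden per
  run.
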