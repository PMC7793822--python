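# vicasim

Minimal physiologically based pharmacokinetic/pharmacodynamic (PBPK/PD)
simulation of the antiplatelet prodrugs **vicagrel** and **clopidogrel** in
virtual populations.

## Background

Both prodrugs form the same active thiol metabolite, AM-H4, through the same
inactive intermediate, 2-oxo-clopidogrel — but by different first steps:

- **clopidogrel** is oxidized in the liver by CYPs (mainly CYP2C19; only 15%
  of the dose takes this route, the rest is hydrolyzed to an inactive acid by
  hepatic CES1);
- **vicagrel** is hydrolyzed in the gut wall by CES2 and AADAC, bypassing
  CYP2C19 for its first activation step.

This difference predicts that vicagrel's active-metabolite exposure should be
robust to CYP2C19 poor-metabolizer phenotypes, CYP2C19 inhibitors such as
omeprazole, and even loss-of-function CES2 alleles (AADAC compensates),
whereas clopidogrel's is not. AM-H4 binds the platelet P2Y12 receptor
irreversibly, so inhibition of platelet aggregation (IPA) persists after the
drug is gone and recovers only at the platelet turnover rate (about 7 days).

The package implements:

- a minimal PBPK core (lumen → algebraic gut extraction → portal →
  well-stirred liver → one systemic compartment; mole-conserving metabolite
  hand-off; linear kinetics) with in-vitro-to-in-vivo scaling of enzyme
  intrinsic clearances;
- a turnover PD model with irreversible platelet inactivation,
  `dP/dt = kin − P·kout − P·C·kirre`, `IPA = (1 − P) × 100`;
- log-normal virtual populations with CYP2C19 phenotypes (EM/IM/PM) and
  carboxylesterase genotypes (CES1 428 G>A, defective CES2);
- perpetrator models (omeprazole mechanism-based CYP2C19 inactivation;
  simvastatin reversible CES1/CES2 inhibition with Ki 0.11/0.67 µM);
- paired-arm virtual-trial campaigns with Table-style AUC/Cmax summaries, a
  Ki sensitivity grid, washout-recovery analysis, and a synthetic-data
  fold-error verification workflow.

See `docs/methods.md` for the full model description, parameter provenance,
numerical choices, and known limitations.

## Worked example

Simulate the reference Chinese subject on vicagrel 24 mg loading / 6 mg
maintenance for 4 days and summarize AM-H4 exposure and platelet response:

```python
import numpy as np
from vicasim import (
    DosingRegimen, build_system, default_fixture, make_time_grid,
    simulate_individual, simulate_platelet_inhibition,
)
from vicasim.metrics import auc_interval, cmax_interval
from vicasim.population import reference_individual

registry = default_fixture()
subject = reference_individual(registry)
system = build_system(registry, subject, ethnicity="chinese", drugs=["vicagrel"])
regimen = DosingRegimen.loading_maintenance("vicagrel", 24.0, 6.0, n_days=4)
profile = simulate_individual(system, regimen, make_time_grid(96.0, 96.0))

print(auc_interval(profile, "am-h4", 0.0, 24.0))   # 29.348 ng·h/mL
print(cmax_interval(profile, "am-h4", 0.0, 24.0))  # 4.084 ng/mL

pd = simulate_platelet_inhibition(profile, registry.pd)
print(np.interp(24.0, pd.times, pd.ipa))           # 86.1 % after the loading dose
print(np.interp(96.0, pd.times, pd.ipa))           # 74.2 % on maintenance
```

The same campaigns are available from the command line:

```
vicasim list-scenarios
vicasim simulate --scenario genotype_ces2 --seed 42 --out results/genotype_ces2
vicasim report --dir results/genotype_ces2
```

## Headline results

With the packaged defaults (100 paired virtual subjects, seed 20201208), the
model reproduces the published comparison ratios of mean AM-H4 AUC over the
first dosing interval:

| Comparison                                   | Ratio  | Reading                            |
|----------------------------------------------|--------|------------------------------------|
| CES2 wild type / defect allele (vicagrel)    | ≈ 1.00 | AADAC compensates fully            |
| CES1 428 G/G / G/A (vicagrel)                | ≈ 0.89 | slight AM-H4 rise in carriers      |
| without / with simvastatin (vicagrel)        | ≈ 0.99 | no meaningful esterase DDI         |
| IPA recovery after stopping vicagrel         | ≈ 7 d  | platelet turnover-limited          |

and the qualitative contrasts: clopidogrel AM-H4 falls EM > IM > PM while
vicagrel is only slightly affected, and omeprazole depresses clopidogrel's
AM-H4 far more than vicagrel's.

## Repository layout

- `src/vicasim/` — the library (configuration, PBPK engine, PD engine,
  populations, interactions, metrics, scenario campaigns, synthetic data);
  packaged defaults in `src/vicasim/data/default.yaml` with per-value
  provenance comments.
- `analysis/` — numbered thin drivers that run each campaign and write
  CSV/JSON outputs under `results/`.
- `scripts/acceptance.py` — recomputes the four headline results from scratch.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — methods note.

## Reproduction

Run the full test suite (≈ 3 minutes; the end-to-end file runs the 100-subject
campaigns):

```
python -m pytest -q tests/
```

Recompute the headline numbers with a seed of your choice:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes `{"t1"|"t4"|"t6"|"t7": {"value": ..., "n": 100}}` — the three
AUC ratios above and the recovery time in days.

Regenerate all campaign outputs:

```
for f in analysis/0*.py; do python "$f"; done
```

Each driver accepts `--seed`, `--n-subjects` (where applicable) and `--out`;
outputs land in one directory per scenario (`summary.csv`, `profiles.csv`,
`pd.csv`, `manifest.json` with the configuration hash and seed). Identical
seeds reproduce byte-identical outputs.
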