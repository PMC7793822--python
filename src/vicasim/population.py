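"""Virtual-subject sampling and pharmacogenetic scaling factors.

Inter-individual variability is log-normal with median 1: a multiplier with
coefficient of variation CV is drawn as ``exp(N(0, sigma))`` with
``sigma^2 = ln(1 + CV^2)``.  CYP2C19 metabolizer phenotypes scale the enzyme's
abundance by a gene-dose factor (EM 1.0, IM 0.5, PM 0.0); the CES1 428 G>A
genotype retains 80% activity and defective CES2 alleles 1/20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .parameters_config import PopulationSpec, Registry

PHENOTYPE_MULTIPLIERS = {"EM": 1.0, "IM": 0.5, "PM": 0.0}

GENOTYPE_FACTORS: dict[str, tuple[str, float]] = {
    # label -> (enzyme, multiplicative factor on every clint of that enzyme)
    "CES1_428GA": ("CES1", 0.8),
    "CES2_defect": ("CES2", 1.0 / 20.0),
}


@dataclass(frozen=True)
class VirtualIndividual:
    """One sampled subject: IIV multipliers plus phenotype/genotype labels."""

    id: int
    trial: int
    phenotype: str
    pathway_multipliers: dict[tuple[str, str, str], float]  # (compound, enzyme, site)
    ka_multipliers: dict[str, float]
    v_sys_multipliers: dict[str, float]
    pd_multipliers: dict[str, float]  # turnover, kirre, mpa0
    enzyme_multipliers: dict[str, float] = field(default_factory=dict)
    genotype_flags: dict[str, bool] = field(default_factory=dict)
    seed_token: int = 0

    def enzyme_multiplier(self, enzyme: str) -> float:
        return self.enzyme_multipliers.get(enzyme, 1.0)


def lognormal_sigma(cv: float) -> float:
    """Standard deviation of log-multiplier for a given CV."""
    return math.sqrt(math.log1p(cv * cv))


def _draw_multiplier(rng: np.random.Generator, cv: float) -> float:
    if cv == 0.0:
        return 1.0
    return float(np.exp(rng.normal(0.0, lognormal_sigma(cv))))


def sample_population(pop: PopulationSpec, registry: Registry) -> list[VirtualIndividual]:
    """Sample ``pop.n_subjects`` virtual subjects, deterministic given the seed.

    Subjects are grouped into ``pop.n_trials`` equal-size trials (the default
    layout is 10 trials of 10).  Draws are made in a fixed key order so the
    result is bit-identical across runs with the same seed.
    """
    pop.validate()
    if pop.n_subjects % pop.n_trials != 0:
        raise ValueError("n_subjects must be a multiple of n_trials")
    per_trial = pop.n_subjects // pop.n_trials

    rng = np.random.default_rng(pop.seed)
    labels = sorted(pop.phenotype_frequencies)
    probs = np.array([pop.phenotype_frequencies[k] for k in labels])

    pathway_keys = [
        (c.name, p.enzyme, p.site)
        for c in registry.compounds.values()
        for p in c.pathways
    ]
    pathway_cvs = {
        (c.name, p.enzyme, p.site): p.cv
        for c in registry.compounds.values()
        for p in c.pathways
    }
    parent_names = sorted(
        c.name for c in registry.compounds.values() if c.is_parent
    )
    compound_names = sorted(registry.compounds)

    individuals: list[VirtualIndividual] = []
    for i in range(pop.n_subjects):
        phenotype = labels[int(rng.choice(len(labels), p=probs))]
        pathway_multipliers = {
            key: _draw_multiplier(rng, pathway_cvs[key])
            for key in sorted(pathway_keys)
        }
        ka_multipliers = {
            name: _draw_multiplier(rng, registry.cv_ka) for name in parent_names
        }
        v_sys_multipliers = {
            name: _draw_multiplier(rng, registry.cv_v_sys)
            for name in compound_names
        }
        pd_multipliers = {
            # One shared turnover multiplier keeps kin = kout per subject.
            "turnover": _draw_multiplier(rng, registry.pd.cv_kout),
            "kirre": _draw_multiplier(rng, registry.pd.cv_kirre),
            "mpa0": _draw_multiplier(rng, registry.pd.cv_mpa0),
        }
        individual = VirtualIndividual(
            id=i,
            trial=i // per_trial,
            phenotype=phenotype,
            pathway_multipliers=pathway_multipliers,
            ka_multipliers=ka_multipliers,
            v_sys_multipliers=v_sys_multipliers,
            pd_multipliers=pd_multipliers,
            seed_token=pop.seed,
        )
        individuals.append(apply_phenotype(individual, registry))
    return individuals


def apply_phenotype(individual: VirtualIndividual, registry: Registry) -> VirtualIndividual:
    """Set the CYP2C19 abundance multiplier from the metabolizer phenotype."""
    try:
        factor = PHENOTYPE_MULTIPLIERS[individual.phenotype]
    except KeyError:
        raise ValueError(f"unknown phenotype {individual.phenotype!r}") from None
    multipliers = dict(individual.enzyme_multipliers)
    multipliers["CYP2C19"] = factor
    return replace(individual, enzyme_multipliers=multipliers)


def apply_genotype(
    individual: VirtualIndividual, label: str, registry: Registry
) -> VirtualIndividual:
    """Apply a carboxylesterase genotype factor on top of existing multipliers."""
    try:
        enzyme, factor = GENOTYPE_FACTORS[label]
    except KeyError:
        raise ValueError(f"unknown genotype label {label!r}") from None
    multipliers = dict(individual.enzyme_multipliers)
    multipliers[enzyme] = multipliers.get(enzyme, 1.0) * factor
    flags = dict(individual.genotype_flags)
    flags[label] = True
    return replace(
        individual, enzyme_multipliers=multipliers, genotype_flags=flags
    )


def reference_individual(registry: Registry, phenotype: str = "EM") -> VirtualIndividual:
    """A single subject with every multiplier at 1 (all CVs zero)."""
    individual = VirtualIndividual(
        id=0,
        trial=0,
        phenotype=phenotype,
        pathway_multipliers={
            (c.name, p.enzyme, p.site): 1.0
            for c in registry.compounds.values()
            for p in c.pathways
        },
        ka_multipliers={
            c.name: 1.0 for c in registry.compounds.values() if c.is_parent
        },
        v_sys_multipliers={name: 1.0 for name in registry.compounds},
        pd_multipliers={"turnover": 1.0, "kirre": 1.0, "mpa0": 1.0},
    )
    return apply_phenotype(individual, registry)


def population_frame(individuals: list[VirtualIndividual]):
    """Audit dump: one row per subject, one column per multiplier."""
    import pandas as pd

    rows = []
    for ind in individuals:
        row: dict[str, object] = {
            "id": ind.id,
            "trial": ind.trial,
            "phenotype": ind.phenotype,
        }
        for (compound, enzyme, site), value in sorted(
            ind.pathway_multipliers.items()
        ):
            row[f"clint:{compound}:{enzyme}:{site}"] = value
        for name, value in sorted(ind.ka_multipliers.items()):
            row[f"ka:{name}"] = value
        for name, value in sorted(ind.v_sys_multipliers.items()):
            row[f"v_sys:{name}"] = value
        for name, value in sorted(ind.pd_multipliers.items()):
            row[f"pd:{name}"] = value
        for enzyme, value in sorted(ind.enzyme_multipliers.items()):
            row[f"enzyme:{enzyme}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
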