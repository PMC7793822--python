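"""The simulation campaigns: phenotype, genotype, DDI, Ki-sensitivity, washout.

Every campaign follows the same paired-arm recipe: sample one virtual
population with a fixed seed, simulate the regimen once per arm on the
*identical* subjects (only the phenotype/genotype/inhibitor factor differs),
and summarize AM-H4 (and parent) exposure as interval AUC/Cmax with ratios of
arm means.  Pairing makes the ratio estimates nearly noise-free at 100
subjects.

Regimens follow the published designs: vicagrel 24 mg loading / 6 mg
maintenance, clopidogrel 300 mg / 75 mg; perpetrators are pre-treated for
five days and continued during victim dosing, with the time axis anchored at
the first perpetrator dose.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .interactions import coadminister
from .parameters_config import PopulationSpec, Registry, registry_to_dict
from .pbpk_engine import (
    ConcentrationProfile,
    DosingRegimen,
    build_system,
    make_time_grid,
    simulate_individual,
)
from .pd_engine import AMH4, PDResult, recovery_time, simulate_platelet_inhibition
from .population import (
    VirtualIndividual,
    apply_genotype,
    apply_phenotype,
    reference_individual,
    sample_population,
)

REGIMENS = {
    "vicagrel": {"loading": 24.0, "maintenance": 6.0},
    "clopidogrel": {"loading": 300.0, "maintenance": 75.0},
}

RECOVERY_THRESHOLD_IPA = 10.0  # percentage points


@dataclass
class ScenarioResult:
    name: str
    summary: pd.DataFrame
    profiles: pd.DataFrame
    pd_frame: Optional[pd.DataFrame]
    extras: dict = field(default_factory=dict)
    seed: int = 0
    config_hash: str = ""

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        self.profiles.to_csv(outdir / "profiles.csv", index=False)
        if self.pd_frame is not None:
            self.pd_frame.to_csv(outdir / "pd.csv", index=False)
        manifest = {
            "scenario": self.name,
            "seed": self.seed,
            "config_hash": self.config_hash,
            **{
                k: v
                for k, v in self.extras.items()
                if isinstance(v, (int, float, str, bool))
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def config_hash(registry: Registry) -> str:
    doc = yaml.safe_dump(registry_to_dict(registry), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _population(
    registry: Registry,
    tag: str,
    n_subjects: Optional[int],
    seed: Optional[int],
) -> tuple[PopulationSpec, list[VirtualIndividual]]:
    pop = registry.populations[tag]
    if n_subjects is not None:
        n_trials = min(pop.n_trials, n_subjects)
        while n_subjects % n_trials:
            n_trials -= 1
        pop = replace(pop, n_subjects=n_subjects, n_trials=n_trials)
    if seed is not None:
        pop = replace(pop, seed=seed)
    return pop, sample_population(pop, registry)


def _simulate_arm(
    registry: Registry,
    individuals: Sequence[VirtualIndividual],
    ethnicity: str,
    drug: str,
    regimen: DosingRegimen,
    t_grid: np.ndarray,
    arm: str,
    genotype: Optional[str] = None,
    phenotype: Optional[str] = None,
    perpetrator: Optional[str] = None,
    perpetrator_dose_times: tuple[float, ...] = (),
    ki_overrides: Optional[dict[str, float]] = None,
    compute_pd: bool = False,
) -> tuple[list[ConcentrationProfile], list[PDResult]]:
    profiles: list[ConcentrationProfile] = []
    pd_results: list[PDResult] = []
    for ind in individuals:
        subject = ind
        if phenotype is not None:
            subject = apply_phenotype(replace(subject, phenotype=phenotype), registry)
        if genotype is not None:
            subject = apply_genotype(subject, genotype, registry)
        system = build_system(registry, subject, ethnicity, drugs=[drug])
        # an empty schedule is dynamically the no-perpetrator system; keep the
        # fast time-invariant path in that case
        if perpetrator is not None and perpetrator_dose_times:
            system = coadminister(
                system,
                registry.perpetrators[perpetrator],
                perpetrator_dose_times,
                ki_overrides=ki_overrides,
            )
        profile = simulate_individual(
            system, regimen, t_grid, subject=ind.id, arm=arm
        )
        profiles.append(profile)
        if compute_pd:
            pd_results.append(
                simulate_platelet_inhibition(
                    profile,
                    registry.pd,
                    kin_kout_multiplier=ind.pd_multipliers["turnover"],
                    kirre_multiplier=ind.pd_multipliers["kirre"],
                    mpa0_multiplier=ind.pd_multipliers["mpa0"],
                )
            )
    return profiles, pd_results


def _mean_profile_frame(
    profiles_by_arm: dict[str, list[ConcentrationProfile]],
    compounds: Sequence[str],
    downsample_h: float = 1.0,
) -> pd.DataFrame:
    frames = []
    for arm, profiles in profiles_by_arm.items():
        times = profiles[0].times
        keep = np.isclose(times / downsample_h, np.round(times / downsample_h))
        for compound in compounds:
            mean = np.mean([p.conc[compound] for p in profiles], axis=0)
            frames.append(
                pd.DataFrame(
                    {
                        "arm": arm,
                        "compound": compound,
                        "time_h": times[keep],
                        "mean_conc_ng_ml": mean[keep],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _mean_pd_frame(
    pd_by_arm: dict[str, list[PDResult]], downsample_h: float = 1.0
) -> pd.DataFrame:
    frames = []
    for arm, results in pd_by_arm.items():
        times = results[0].times
        keep = np.isclose(times / downsample_h, np.round(times / downsample_h))
        mean_ipa = np.mean([r.ipa for r in results], axis=0)
        mean_pool = np.mean([r.pool for r in results], axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "time_h": times[keep],
                    "mean_P": mean_pool[keep],
                    "mean_ipa_pct": mean_ipa[keep],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _dose_intervals(regimen: DosingRegimen) -> tuple[tuple[float, float], tuple[float, float]]:
    first = regimen.dose_times[0]
    last = regimen.last_dose_time
    return (first, first + 24.0), (last, last + 24.0)


# ---------------------------------------------------------------------------
# Campaigns


def run_phenotype_comparison(
    drug: str,
    registry: Registry,
    n_subjects: Optional[int] = None,
    seed: Optional[int] = None,
    n_days: int = 7,
    compute_pd: bool = True,
) -> ScenarioResult:
    """EM vs IM vs PM arms in Chinese subjects, LD day 1 + MD days 2..n_days.

    Each phenotype arm forces the metabolizer frequency to one on the same
    sampled subjects, mirroring the paired design.
    """
    pop, individuals = _population(registry, "chinese", n_subjects, seed)
    doses = REGIMENS[drug]
    regimen = DosingRegimen.loading_maintenance(
        drug, doses["loading"], doses["maintenance"], n_days
    )
    first_iv, last_iv = _dose_intervals(regimen)
    t_grid = make_time_grid(last_iv[1], last_iv[1])

    profiles_by_arm: dict[str, list[ConcentrationProfile]] = {}
    pd_by_arm: dict[str, list[PDResult]] = {}
    rows = []
    for phenotype in ("EM", "IM", "PM"):
        profiles, pd_results = _simulate_arm(
            registry,
            individuals,
            pop.ethnicity,
            drug,
            regimen,
            t_grid,
            arm=phenotype,
            phenotype=phenotype,
            compute_pd=compute_pd,
        )
        profiles_by_arm[phenotype] = profiles
        if compute_pd:
            pd_by_arm[phenotype] = pd_results
        summary = metrics.pk_summary(profiles, AMH4, first_iv, last_iv)
        rows.append(
            {
                "arm": phenotype,
                "analyte": AMH4,
                "auc_first_mean": summary["auc_first"].mean(),
                "auc_first_sd": summary["auc_first"].std(ddof=1),
                "cmax_first_mean": summary["cmax_first"].mean(),
                "auc_last_mean": summary["auc_last"].mean(),
                "cmax_last_mean": summary["cmax_last"].mean(),
            }
        )
    summary = pd.DataFrame(rows)
    em = summary.loc[summary["arm"] == "EM", "auc_first_mean"].iloc[0]
    pm = summary.loc[summary["arm"] == "PM", "auc_first_mean"].iloc[0]
    return ScenarioResult(
        name=f"phenotype_{drug}",
        summary=summary,
        profiles=_mean_profile_frame(profiles_by_arm, [AMH4]),
        pd_frame=_mean_pd_frame(pd_by_arm) if compute_pd else None,
        extras={"pm_over_em_auc_first": pm / em},
        seed=pop.seed,
        config_hash=config_hash(registry),
    )


def run_genotype_scenario(
    label: str,
    registry: Registry,
    n_subjects: Optional[int] = None,
    seed: Optional[int] = None,
    n_days: int = 4,
    compute_pd: bool = False,
) -> ScenarioResult:
    """Wild-type vs variant carboxylesterase arms on identical subjects.

    CES1 428 G>A is evaluated in Caucasian subjects (the variant is virtually
    absent in East Asians); defective CES2 in Chinese subjects.  Ratios are
    wild over variant, matching the published table orientation.
    """
    if label == "CES1_428GA":
        tag, wild, variant = "caucasian", "CES1 G/G", "CES1 G/A"
    elif label == "CES2_defect":
        tag, wild, variant = "chinese", "CES2 wild type", "CES2 defect allele"
    else:
        raise ValueError(f"unknown genotype label {label!r}")
    pop, individuals = _population(registry, tag, n_subjects, seed)
    regimen = DosingRegimen.loading_maintenance("vicagrel", 24.0, 6.0, n_days)
    first_iv, last_iv = _dose_intervals(regimen)
    t_grid = make_time_grid(last_iv[1], last_iv[1])

    arms = {}
    pd_by_arm: dict[str, list[PDResult]] = {}
    for arm, genotype in ((wild, None), (variant, label)):
        profiles, pd_results = _simulate_arm(
            registry,
            individuals,
            pop.ethnicity,
            "vicagrel",
            regimen,
            t_grid,
            arm=arm,
            genotype=genotype,
            compute_pd=compute_pd,
        )
        arms[arm] = profiles
        if compute_pd:
            pd_by_arm[arm] = pd_results

    summaries = {
        arm: pd.concat(
            [
                metrics.pk_summary(profiles, "vicagrel", first_iv, last_iv),
                metrics.pk_summary(profiles, AMH4, first_iv, last_iv),
            ],
            ignore_index=True,
        )
        for arm, profiles in arms.items()
    }
    table = metrics.paired_summary_table(
        summaries[wild], summaries[variant], wild, variant, population=tag
    )
    amh4_ratio = table.loc[
        (table["analyte"] == AMH4) & (table["group"] == wild), "auc_first_ratio"
    ].iloc[0]
    parent_ratio = table.loc[
        (table["analyte"] == "vicagrel") & (table["group"] == wild),
        "auc_first_ratio",
    ].iloc[0]
    return ScenarioResult(
        name=f"genotype_{label}",
        summary=table,
        profiles=_mean_profile_frame(arms, ["vicagrel", AMH4]),
        pd_frame=_mean_pd_frame(pd_by_arm) if compute_pd else None,
        extras={
            "amh4_auc_first_ratio": float(amh4_ratio),
            "parent_auc_first_ratio": float(parent_ratio),
        },
        seed=pop.seed,
        config_hash=config_hash(registry),
    )


def _perpetrator_schedule(
    pretreatment_days: int, victim_days: int, continue_perpetrator: bool
) -> tuple[tuple[float, ...], float]:
    """Daily perpetrator dose times and the victim start time (h)."""
    times = [24.0 * d for d in range(pretreatment_days)]
    victim_start = 24.0 * pretreatment_days
    if continue_perpetrator:
        times += [victim_start + 24.0 * d for d in range(victim_days)]
    return tuple(times), victim_start


def run_ddi_scenario(
    perpetrator: str,
    victim: str,
    registry: Registry,
    n_subjects: Optional[int] = None,
    seed: Optional[int] = None,
    victim_days: int = 4,
    pretreatment_days: int = 5,
    continue_perpetrator: bool = True,
    compute_pd: bool = False,
    ki_overrides: Optional[dict[str, float]] = None,
) -> ScenarioResult:
    """Victim drug with vs without a perpetrator, on identical subjects.

    The time axis is anchored at the first perpetrator dose; the victim
    loading dose falls on the day after the pretreatment block.
    """
    pop, individuals = _population(registry, "chinese", n_subjects, seed)
    perp_times, victim_start = _perpetrator_schedule(
        pretreatment_days, victim_days, continue_perpetrator
    )
    doses = REGIMENS[victim]
    regimen = DosingRegimen.loading_maintenance(
        victim, doses["loading"], doses["maintenance"], victim_days,
        start_h=victim_start,
    )
    first_iv, last_iv = _dose_intervals(regimen)
    t_grid = make_time_grid(last_iv[1], last_iv[1])

    arms: dict[str, list[ConcentrationProfile]] = {}
    pd_by_arm: dict[str, list[PDResult]] = {}
    for arm, dose_times in (
        (f"without_{perpetrator}", ()),
        (f"with_{perpetrator}", perp_times),
    ):
        profiles, pd_results = _simulate_arm(
            registry,
            individuals,
            pop.ethnicity,
            victim,
            regimen,
            t_grid,
            arm=arm,
            perpetrator=perpetrator,
            perpetrator_dose_times=dose_times,
            ki_overrides=ki_overrides,
            compute_pd=compute_pd,
        )
        arms[arm] = profiles
        if compute_pd:
            pd_by_arm[arm] = pd_results

    without, with_ = f"without_{perpetrator}", f"with_{perpetrator}"
    summaries = {
        arm: pd.concat(
            [
                metrics.pk_summary(profiles, victim, first_iv, last_iv),
                metrics.pk_summary(profiles, AMH4, first_iv, last_iv),
            ],
            ignore_index=True,
        )
        for arm, profiles in arms.items()
    }
    table = metrics.paired_summary_table(
        summaries[without], summaries[with_], without, with_, population="chinese"
    )
    amh4_ratio = table.loc[
        (table["analyte"] == AMH4) & (table["group"] == without),
        "auc_first_ratio",
    ].iloc[0]
    return ScenarioResult(
        name=f"ddi_{perpetrator}_{victim}",
        summary=table,
        profiles=_mean_profile_frame(arms, [victim, AMH4]),
        pd_frame=_mean_pd_frame(pd_by_arm) if compute_pd else None,
        extras={"amh4_auc_first_ratio_without_over_with": float(amh4_ratio)},
        seed=pop.seed,
        config_hash=config_hash(registry),
    )


def run_ki_sensitivity(
    registry: Registry,
    n_per_axis: int = 4,
    victim_days: int = 4,
    pretreatment_days: int = 5,
) -> pd.DataFrame:
    """AM-H4 AUC ratio (with/without simvastatin) over a (Ki_CES1, Ki_CES2) grid.

    One representative subject (all CVs collapsed to multipliers of 1) keeps
    the grid deterministic.  Grids are log-spaced from 0.001 µM up to the
    default Ki values (0.11 and 0.67 µM), so the grid corner reproduces the
    default-DDI ratio exactly.
    """
    perp = registry.perpetrators["simvastatin"]
    perp_times, victim_start = _perpetrator_schedule(
        pretreatment_days, victim_days, continue_perpetrator=True
    )
    regimen = DosingRegimen.loading_maintenance(
        "vicagrel", 24.0, 6.0, victim_days, start_h=victim_start
    )
    first_iv, last_iv = _dose_intervals(regimen)
    t_grid = make_time_grid(last_iv[1], last_iv[1])
    subject = reference_individual(registry)

    def amh4_auc(dose_times, ki1, ki2) -> float:
        system = build_system(registry, subject, "chinese", drugs=["vicagrel"])
        if dose_times:
            system = coadminister(
                system, perp, dose_times, ki_overrides={"CES1": ki1, "CES2": ki2}
            )
        profile = simulate_individual(system, regimen, t_grid)
        return metrics.auc_interval(profile, AMH4, *first_iv)

    ki1_default = perp.inhibition.ki["CES1"]
    ki2_default = perp.inhibition.ki["CES2"]
    baseline = amh4_auc((), ki1_default, ki2_default)
    ki1_grid = np.geomspace(0.001, ki1_default, n_per_axis)
    ki2_grid = np.geomspace(0.001, ki2_default, n_per_axis)
    rows = []
    for ki1 in ki1_grid:
        for ki2 in ki2_grid:
            ratio = amh4_auc(perp_times, float(ki1), float(ki2)) / baseline
            rows.append(
                {"ki_ces1_um": float(ki1), "ki_ces2_um": float(ki2),
                 "auc_ratio_with_over_without": ratio}
            )
    return pd.DataFrame(rows)


def run_washout_recovery(
    registry: Registry,
    n_subjects: Optional[int] = None,
    seed: Optional[int] = None,
    dosing_days: int = 7,
    washout_days: int = 14,
    threshold_ipa: float = RECOVERY_THRESHOLD_IPA,
) -> ScenarioResult:
    """Population-mean IPA recovery after stopping vicagrel.

    LD day 1, MD through ``dosing_days``, then a washout window; reports the
    time (days) from the last dose until the mean IPA first drops below the
    threshold.
    """
    pop, individuals = _population(registry, "chinese", n_subjects, seed)
    regimen = DosingRegimen.loading_maintenance("vicagrel", 24.0, 6.0, dosing_days)
    last_dose = regimen.last_dose_time
    t_end = last_dose + 24.0 * washout_days
    t_grid = make_time_grid(last_dose + 24.0, t_end)

    profiles, pd_results = _simulate_arm(
        registry,
        individuals,
        pop.ethnicity,
        "vicagrel",
        regimen,
        t_grid,
        arm="vicagrel_washout",
        compute_pd=True,
    )
    mean_ipa = np.mean([r.ipa for r in pd_results], axis=0)
    rec_h = recovery_time(
        t_grid, mean_ipa, last_dose, threshold_ipa, pd=registry.pd
    )
    ipa_at_last_dose = float(np.interp(last_dose, t_grid, mean_ipa))
    summary = pd.DataFrame(
        [
            {
                "recovery_time_days": rec_h / 24.0,
                "threshold_ipa_pct": threshold_ipa,
                "mean_ipa_at_last_dose_pct": ipa_at_last_dose,
                "n_subjects": len(individuals),
            }
        ]
    )
    return ScenarioResult(
        name="washout_recovery",
        summary=summary,
        profiles=_mean_profile_frame({"vicagrel_washout": profiles}, [AMH4]),
        pd_frame=_mean_pd_frame({"vicagrel_washout": pd_results}),
        extras={
            "recovery_time_days": rec_h / 24.0,
            "mean_ipa_at_last_dose_pct": ipa_at_last_dose,
        },
        seed=pop.seed,
        config_hash=config_hash(registry),
    )
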