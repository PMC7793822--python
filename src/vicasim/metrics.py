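"""Non-compartmental summaries and verification statistics.

AUCs are interval AUCs (linear trapezoid on the simulation grid, with exact
interpolation at interval endpoints); group comparisons use the ratio of
arithmetic means (mean(a)/mean(b), not the mean of per-subject ratios); model
verification uses the fold-error max(pred/obs, obs/pred) against the
conventional 2-fold and 1.5-fold bands.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .pbpk_engine import ConcentrationProfile, DomainError


def _restrict(times: np.ndarray, conc: np.ndarray, t_start: float, t_end: float):
    if t_start < times[0] - 1e-9 or t_end > times[-1] + 1e-9:
        raise DomainError(
            f"interval [{t_start}, {t_end}] outside grid "
            f"[{times[0]}, {times[-1]}]"
        )
    if t_end <= t_start:
        raise DomainError("t_end must exceed t_start")
    inner = (times > t_start) & (times < t_end)
    t = np.concatenate(([t_start], times[inner], [t_end]))
    c = np.concatenate(
        (
            [np.interp(t_start, times, conc)],
            conc[inner],
            [np.interp(t_end, times, conc)],
        )
    )
    return t, c


def auc_interval(
    profile: ConcentrationProfile, compound: str, t_start: float, t_end: float
) -> float:
    """Linear-trapezoid AUC (ng·h/mL) of one analyte over [t_start, t_end]."""
    t, c = _restrict(profile.times, profile.conc[compound], t_start, t_end)
    return float(np.trapezoid(c, t))


def cmax_interval(
    profile: ConcentrationProfile, compound: str, t_start: float, t_end: float
) -> float:
    """Maximum concentration (ng/mL) of one analyte over [t_start, t_end]."""
    t, c = _restrict(profile.times, profile.conc[compound], t_start, t_end)
    return float(np.max(c))


def ratio_of_means(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """mean(a) / mean(b); raises on empty groups or a zero denominator mean."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be nonempty")
    mean_b = float(np.mean(b))
    if mean_b == 0.0:
        raise DomainError("denominator group has zero mean")
    return float(np.mean(a)) / mean_b


def fold_error(predicted: float, observed: float) -> float:
    """max(pred/obs, obs/pred); symmetric, >= 1."""
    if predicted <= 0 or observed <= 0:
        raise DomainError("fold_error requires positive inputs")
    return max(predicted / observed, observed / predicted)


def pk_summary(
    profiles: Sequence[ConcentrationProfile],
    compound: str,
    first_dose_interval: tuple[float, float],
    last_dose_interval: tuple[float, float],
) -> pd.DataFrame:
    """Per-subject first/last-dose AUC0-24 and Cmax for one analyte."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "subject": p.subject,
                "arm": p.arm,
                "compound": compound,
                "auc_first": auc_interval(p, compound, *first_dose_interval),
                "cmax_first": cmax_interval(p, compound, *first_dose_interval),
                "auc_last": auc_interval(p, compound, *last_dose_interval),
                "cmax_last": cmax_interval(p, compound, *last_dose_interval),
            }
        )
    return pd.DataFrame(rows)


def paired_summary_table(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    label_a: str,
    label_b: str,
    population: str = "",
) -> pd.DataFrame:
    """Mean ± SD per arm plus ratios of means (arm a over arm b).

    Mirrors the published comparison-table layout: one block per analyte with
    first-dose and last-dose AUC0-24 and Cmax, and each ratio computed as the
    upper (arm a) group mean divided by the lower (arm b) group mean.
    """
    rows = []
    for compound in sorted(summary_a["compound"].unique()):
        a = summary_a[summary_a["compound"] == compound]
        b = summary_b[summary_b["compound"] == compound]
        row_a: dict[str, object] = {
            "population": population,
            "analyte": compound,
            "group": label_a,
        }
        row_b: dict[str, object] = {
            "population": population,
            "analyte": compound,
            "group": label_b,
        }
        for metric in ("auc_first", "cmax_first", "auc_last", "cmax_last"):
            row_a[f"{metric}_mean"] = a[metric].mean()
            row_a[f"{metric}_sd"] = a[metric].std(ddof=1)
            row_b[f"{metric}_mean"] = b[metric].mean()
            row_b[f"{metric}_sd"] = b[metric].std(ddof=1)
            row_a[f"{metric}_ratio"] = ratio_of_means(a[metric], b[metric])
            row_b[f"{metric}_ratio"] = np.nan
        rows.extend([row_a, row_b])
    return pd.DataFrame(rows)
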