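"""Minimal PBPK engine: lumen -> gut first pass -> portal -> liver -> systemic.

Each orally dosed parent carries a lumen amount absorbed at a first-order rate
``ka``; an algebraic gut-extraction step splits the absorbed flux between the
parent (fraction ``Fg``) and its gut metabolites (mole-for-mole, in proportion
to the intestinal pathway clearances).  Portal vein, well-stirred liver and a
single systemic compartment are explicit for every compound; hepatic pathways
eliminate drug from the liver compartment at ``fu_blood x CLint`` and hand the
metabolized moles to the product compound's liver state.  All amounts are in
nmol so metabolite hand-off conserves moles exactly; molecular weight enters
only at the dosing and concentration-output boundaries.

The system is linear; Michaelis-Menten saturation is deliberately not modeled
(therapeutic doses sit far below saturation for these esterase and CYP
routes).  Time-varying enzyme-inhibition factors (and mechanism-based
inactivation states) may be attached by the interactions module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .parameters_config import PhysiologySpec, Registry
from .population import VirtualIndividual


class DomainError(ValueError):
    """Input outside the physical domain of an operation."""


class IntegrationError(RuntimeError):
    """The ODE solver failed."""


# ---------------------------------------------------------------------------
# Scaling primitives


def scale_clint(clint: float, protein_per_organ: float) -> float:
    """Scale an intrinsic clearance (µL/min/mg protein) to organ level (L/h)."""
    if clint < 0 or protein_per_organ < 0:
        raise DomainError("clint and protein amount must be >= 0")
    return clint * protein_per_organ * 60.0 / 1e6


def fraction_escaping_gut(
    clint_gut_scaled: float, q_gut: float, fu_gut: float = 1.0
) -> float:
    """Fraction of absorbed drug escaping gut-wall metabolism (Qgut-style)."""
    if q_gut <= 0:
        raise DomainError("q_gut must be > 0")
    return q_gut / (q_gut + fu_gut * clint_gut_scaled)


def wellstirred_hepatic_clearance(
    q_h: float, fu_blood: float, clint_u_total: float
) -> float:
    """Well-stirred hepatic clearance CLh = Q·fu·CLint / (Q + fu·CLint)."""
    if q_h <= 0:
        raise DomainError("q_h must be > 0")
    return q_h * fu_blood * clint_u_total / (q_h + fu_blood * clint_u_total)


# ---------------------------------------------------------------------------
# Dosing


@dataclass(frozen=True)
class DosingRegimen:
    """Oral bolus doses: (time h, compound name, dose mg)."""

    doses: tuple[tuple[float, str, float], ...]

    @staticmethod
    def loading_maintenance(
        compound: str,
        loading_mg: float,
        maintenance_mg: float,
        n_days: int,
        start_h: float = 0.0,
    ) -> "DosingRegimen":
        """LD on day 1 and daily MD on days 2..n_days."""
        doses = [(start_h, compound, loading_mg)]
        doses += [
            (start_h + 24.0 * day, compound, maintenance_mg)
            for day in range(1, n_days)
        ]
        return DosingRegimen(tuple(doses))

    @property
    def dose_times(self) -> list[float]:
        return sorted({t for t, _, _ in self.doses})

    @property
    def last_dose_time(self) -> float:
        return max(t for t, _, _ in self.doses)

    def validate(self) -> None:
        for t, _, mg in self.doses:
            if mg <= 0:
                raise DomainError("doses must be > 0 mg")
            if t < 0:
                raise DomainError("dose times must be >= 0")


def make_time_grid(
    dosing_end_h: float,
    t_end_h: float,
    dt_dosing: float = 0.1,
    dt_washout: float = 1.0,
    start_h: float = 0.0,
) -> np.ndarray:
    """Dense grid during dosing days, coarser during washout."""
    if t_end_h <= start_h:
        raise DomainError("t_end_h must exceed start_h")
    dosing_end_h = min(dosing_end_h, t_end_h)
    pieces = [np.arange(start_h, dosing_end_h, dt_dosing)]
    if t_end_h > dosing_end_h:
        pieces.append(np.arange(dosing_end_h, t_end_h, dt_washout))
    pieces.append(np.array([t_end_h]))
    grid = np.unique(np.concatenate(pieces))
    return grid


# ---------------------------------------------------------------------------
# Model system


@dataclass
class CompoundStates:
    name: str
    is_parent: bool
    mw: float
    ka: float  # 1/h (0 for metabolites)
    fa: float
    v_sys: float  # L
    renal_cl: float  # L/h
    fu_blood: float
    blood_plasma_ratio: float
    # state indices (-1 where absent)
    lumen: int
    portal: int
    liver: int
    sys: int
    elim: int
    # hepatic channels: (enzyme, fu_blood-adjusted clearance L/h, product index or -1)
    liver_channels: list[tuple[str, float, int]] = field(default_factory=list)
    # gut channels (parents): (enzyme, scaled clearance L/h, product index or -1)
    gut_channels: list[tuple[str, float, int]] = field(default_factory=list)


@dataclass
class ModelSystem:
    """Assembled linear ODE system for one subject."""

    compounds: list[CompoundStates]
    physiology: PhysiologySpec
    n_states: int
    n_core_states: int  # 4 per parent + 3 per metabolite (lumen/portal/liver/sys)
    index: dict[str, int]  # compound name -> position in `compounds`
    inhibition: Optional[object] = None  # duck-typed forcing, see interactions
    mbi_state_index: dict[str, int] = field(default_factory=dict)  # enzyme -> state

    # -- inhibition plumbing -------------------------------------------------
    def _factor(self, t: float, x: np.ndarray, enzyme: str, site: str) -> float:
        factor = 1.0
        if self.inhibition is not None:
            factor = self.inhibition.reversible_factor(t, enzyme, site)
            state = self.mbi_state_index.get(enzyme)
            if state is not None:
                factor *= x[state]
        return factor

    def has_time_varying_rates(self) -> bool:
        return self.inhibition is not None

    # -- right-hand side -----------------------------------------------------
    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        phys = self.physiology
        dx = np.zeros_like(x)
        q_p, q_ha, q_h = phys.q_portal, phys.q_hepatic_arterial, phys.q_hepatic_total

        for comp in self.compounds:
            c_portal = x[comp.portal] / phys.v_portal
            c_liver = x[comp.liver] / phys.v_liver
            c_sys = x[comp.sys] / comp.v_sys

            # absorption with algebraic gut first pass
            if comp.is_parent and comp.lumen >= 0:
                flux_abs = comp.ka * x[comp.lumen]
                dx[comp.lumen] -= flux_abs
                if comp.gut_channels:
                    cls = [
                        cl * self._factor(t, x, enzyme, "gut")
                        for enzyme, cl, _ in comp.gut_channels
                    ]
                    total_gut = sum(cls)
                    fg = phys.q_gut / (phys.q_gut + total_gut)
                    dx[comp.portal] += fg * flux_abs
                    if total_gut > 0.0:
                        escaped = (1.0 - fg) * flux_abs
                        for (enzyme, _, product), cl_i in zip(
                            comp.gut_channels, cls
                        ):
                            share = escaped * cl_i / total_gut
                            if product >= 0:
                                dx[self.compounds[product].portal] += share
                            else:
                                dx[comp.elim] += share
                else:
                    dx[comp.portal] += flux_abs

            # portal vein: mesenteric inflow from systemic, outflow to liver
            dx[comp.portal] += q_p * c_sys - q_p * c_portal
            # liver: portal + arterial inflow, venous outflow, metabolism
            dx[comp.liver] += q_p * c_portal + q_ha * c_sys - q_h * c_liver
            for enzyme, cl_u, product in comp.liver_channels:
                flux = cl_u * self._factor(t, x, enzyme, "liver") * c_liver
                dx[comp.liver] -= flux
                if product >= 0:
                    dx[self.compounds[product].liver] += flux
                else:
                    dx[comp.elim] += flux
            # systemic: hepatic outflow, splanchnic/arterial return, renal loss
            renal_flux = comp.renal_cl * c_sys
            dx[comp.sys] += q_h * c_liver - (q_p + q_ha) * c_sys - renal_flux
            dx[comp.elim] += renal_flux

        # mechanism-based inactivation states
        if self.inhibition is not None:
            for enzyme, state in self.mbi_state_index.items():
                k_deg, lam = self.inhibition.mbi_rates(t, enzyme)
                dx[state] = k_deg * (1.0 - x[state]) - lam * x[state]
        return dx

    def matrix(self) -> np.ndarray:
        """Constant coefficient matrix (only valid without inhibition)."""
        if self.inhibition is not None:
            raise ValueError("system with inhibition is not time-invariant")
        n = self.n_states
        a = np.zeros((n, n))
        eye = np.eye(n)
        for j in range(n):
            a[:, j] = self.rhs(0.0, eye[:, j])
        return a

    def initial_state(self) -> np.ndarray:
        x0 = np.zeros(self.n_states)
        for state in self.mbi_state_index.values():
            x0[state] = 1.0
        return x0

    def dose_vector(self, compound: str, dose_mg: float) -> np.ndarray:
        comp = self.compounds[self.index[compound]]
        if not comp.is_parent:
            raise DomainError(f"{compound} is a metabolite and cannot be dosed")
        bolus = np.zeros(self.n_states)
        bolus[comp.lumen] = comp.fa * dose_mg * 1e6 / comp.mw  # nmol
        return bolus


def build_system(
    registry: Registry,
    individual: VirtualIndividual,
    ethnicity: str = "chinese",
    drugs: Optional[Sequence[str]] = None,
) -> ModelSystem:
    """Assemble the ODE system for one subject.

    ``drugs`` selects the dosed parent(s); their downstream metabolites are
    included automatically.  Every pathway clint is multiplied by the
    subject's pathway IIV multiplier and the enzyme abundance multiplier
    (phenotype/genotype) before in-vitro-to-in-vivo scaling.
    """
    phys = registry.physiology[ethnicity]
    if drugs is None:
        drugs = sorted(
            name for name, c in registry.compounds.items() if c.is_parent
        )
    names: list[str] = []
    for drug in drugs:
        if registry.compounds[drug].ka is None:
            raise DomainError(f"{drug} has no absorption rate; not a parent")
        if drug not in names:
            names.append(drug)
        for met in registry.metabolites_of(drug):
            if met not in names:
                names.append(met)

    index = {name: i for i, name in enumerate(names)}
    compounds: list[CompoundStates] = []
    cursor = 0
    for name in names:
        spec = registry.compounds[name]
        is_parent = name in drugs
        lumen = cursor if is_parent else -1
        cursor += 1 if is_parent else 0
        portal, liver, sys_i = cursor, cursor + 1, cursor + 2
        cursor += 3
        compounds.append(
            CompoundStates(
                name=name,
                is_parent=is_parent,
                mw=spec.molecular_weight,
                ka=(spec.ka or 0.0) * individual.ka_multipliers.get(name, 1.0),
                fa=spec.fa,
                v_sys=spec.v_sys * individual.v_sys_multipliers.get(name, 1.0),
                renal_cl=spec.renal_cl,
                fu_blood=spec.fu_blood,
                blood_plasma_ratio=spec.blood_plasma_ratio,
                lumen=lumen,
                portal=portal,
                liver=liver,
                sys=sys_i,
                elim=-1,  # assigned below
            )
        )
    n_core = cursor
    # cumulative-elimination bookkeeping states
    for comp in compounds:
        comp.elim = cursor
        cursor += 1

    for comp in compounds:
        spec = registry.compounds[comp.name]
        for p in spec.pathways:
            multiplier = individual.pathway_multipliers.get(
                (comp.name, p.enzyme, p.site), 1.0
            ) * individual.enzyme_multiplier(p.enzyme)
            product = index.get(p.product, -1) if p.product else -1
            if p.product and product < 0:
                # downstream of an un-dosed parent; route not in this system
                continue
            if p.site == "gut":
                cl = scale_clint(p.clint * multiplier, phys.gut_protein)
                comp.gut_channels.append((p.enzyme, cl, product))
            else:
                cl = scale_clint(p.clint * multiplier, phys.liver_protein)
                comp.liver_channels.append((p.enzyme, cl * spec.fu_blood, product))

    return ModelSystem(
        compounds=compounds,
        physiology=phys,
        n_states=cursor,
        n_core_states=n_core,
        index=index,
    )


# ---------------------------------------------------------------------------
# Simulation


@dataclass
class ConcentrationProfile:
    """Plasma concentration-time courses (ng/mL) for one subject and arm."""

    times: np.ndarray  # h, strictly increasing
    conc: dict[str, np.ndarray]  # compound -> ng/mL
    subject: int = 0
    arm: str = ""
    states: Optional[np.ndarray] = None  # (n_states, n_times) nmol
    system: Optional[ModelSystem] = None
    absorbed: Optional[np.ndarray] = None  # cumulative fa x dose, nmol

    def interp(self, compound: str, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.conc[compound])

    def to_frame(self):
        import pandas as pd

        frames = []
        for name, values in self.conc.items():
            frames.append(
                pd.DataFrame(
                    {
                        "subject": self.subject,
                        "arm": self.arm,
                        "compound": name,
                        "time_h": self.times,
                        "conc_ng_ml": values,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate_individual(
    system: ModelSystem,
    regimen: DosingRegimen,
    t_grid: np.ndarray,
    subject: int = 0,
    arm: str = "",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationProfile:
    """Integrate the system over ``t_grid`` with bolus doses into the lumen.

    The integration is performed piecewise between dose events (LSODA,
    stiff-capable); for time-invariant systems the constant Jacobian is
    supplied analytically.
    """
    regimen.validate()
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be strictly increasing")
    if regimen.doses and (
        regimen.dose_times[0] < t_grid[0] or regimen.last_dose_time > t_grid[-1]
    ):
        raise DomainError("t_grid must cover all dose times")

    dose_times = regimen.dose_times
    boundaries = sorted({t_grid[0], *dose_times, t_grid[-1]})
    doses_at: dict[float, list[tuple[str, float]]] = {}
    for t, compound, mg in regimen.doses:
        doses_at.setdefault(t, []).append((compound, mg))

    if system.has_time_varying_rates():
        jac = None
        rhs = system.rhs
    else:
        a = system.matrix()
        rhs = lambda t, x: a @ x  # noqa: E731
        jac = lambda t, x: a  # noqa: E731

    x = system.initial_state()
    out = np.empty((system.n_states, len(t_grid)))
    absorbed = np.zeros(len(t_grid))
    cumulative_dosed = 0.0
    next_idx = 0

    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        for compound, mg in doses_at.get(seg_start, []):
            x = x + system.dose_vector(compound, mg)
            comp = system.compounds[system.index[compound]]
            cumulative_dosed += comp.fa * mg * 1e6 / comp.mw
        hi = int(np.searchsorted(t_grid, seg_end, side="right"))
        t_eval = t_grid[next_idx:hi]
        sol = solve_ivp(
            rhs,
            (seg_start, seg_end),
            x,
            method="LSODA",
            t_eval=t_eval if len(t_eval) else None,
            jac=jac,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed near t = {seg_start:.3f} h: {sol.message}"
            )
        if len(t_eval):
            out[:, next_idx:hi] = sol.y
            absorbed[next_idx:hi] = cumulative_dosed
            next_idx = hi
        x = sol.y[:, -1]

    conc = {}
    for comp in system.compounds:
        conc[comp.name] = out[comp.sys, :] / comp.v_sys * comp.mw / 1000.0
    return ConcentrationProfile(
        times=t_grid,
        conc=conc,
        subject=subject,
        arm=arm,
        states=out,
        system=system,
        absorbed=absorbed,
    )


def mole_balance_residual(profile: ConcentrationProfile) -> np.ndarray:
    """Relative conservation error |total - absorbed| / max(absorbed) per time."""
    if profile.states is None or profile.system is None or profile.absorbed is None:
        raise ValueError("profile lacks state bookkeeping")
    system = profile.system
    core = np.zeros(profile.states.shape[1])
    for comp in system.compounds:
        if comp.lumen >= 0:
            core += profile.states[comp.lumen]
        core += (
            profile.states[comp.portal]
            + profile.states[comp.liver]
            + profile.states[comp.sys]
            + profile.states[comp.elim]
        )
    scale = np.maximum(profile.absorbed, 1e-30)
    return np.abs(core - profile.absorbed) / scale
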