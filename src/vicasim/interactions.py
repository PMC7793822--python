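"""Perpetrator forcing functions and enzyme inhibition.

Perpetrator drugs (omeprazole, simvastatin) are modeled as deterministic
one-compartment oral compounds with closed-form (Bateman) kinetics; no ODE
states are spent on them.  Two inhibition mechanisms act on the victim system:

* reversible (competitive) inhibition: each affected intrinsic clearance is
  multiplied by 1 / (1 + I_u/Ki) at every solver step;
* mechanism-based inactivation (MBI): the active-enzyme fraction E obeys
  dE/dt = k_deg (1 - E) - k_inact * I_u/(K_I,app + I_u) * E and multiplies the
  affected clearances.

Inhibitor concentration at hepatic enzymes is the unbound plasma
concentration.  At intestinal enzymes it is the enterocyte surrogate
I_gut(t) = ka * A_lumen(t) / Q_gut (absorption flux over villous flow, with
the full dose depleting first-order from the lumen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters_config import InhibitionSpec, PerpetratorSpec
from .pbpk_engine import DomainError, ModelSystem


def _bateman_shape(ka: float, k: float, dt) -> np.ndarray:
    """(ka/(ka-k)) * (exp(-k dt) - exp(-ka dt)), with the ka -> k limit."""
    dt = np.atleast_1d(np.asarray(dt, dtype=float))
    positive = dt > 0
    out = np.zeros_like(dt)
    if math.isclose(ka, k, rel_tol=1e-9):
        out[positive] = k * dt[positive] * np.exp(-k * dt[positive])
    else:
        out[positive] = (
            ka / (ka - k)
            * (np.exp(-k * dt[positive]) - np.exp(-ka * dt[positive]))
        )
    return out


def perpetrator_concentration(
    spec: PerpetratorSpec, t, dose_times=(0.0,), unbound: bool = True
):
    """Plasma perpetrator concentration (µM) by Bateman superposition."""
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k = spec.cl / spec.v
    amount_factor = spec.fa * spec.dose * 1000.0 / (spec.molecular_weight * spec.v)
    total = np.zeros_like(t)
    for td in dose_times:
        total += amount_factor * _bateman_shape(spec.ka, k, t - td)
    if unbound:
        total = total * spec.fu_plasma
    return float(total[0]) if scalar else total


def gut_inhibitor_concentration(
    spec: PerpetratorSpec, t, dose_times=(0.0,), q_gut: float = 14.0
):
    """Enterocyte inhibitor surrogate I_gut = ka * A_lumen(t) / Q_gut, in µM."""
    if q_gut <= 0:
        raise DomainError("q_gut must be > 0")
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    dose_nmol = spec.dose * 1e6 / spec.molecular_weight
    lumen = np.zeros_like(t)
    for td in dose_times:
        dt = t - td
        lumen += np.where(dt >= 0, dose_nmol * np.exp(-spec.ka * np.maximum(dt, 0.0)), 0.0)
    conc = spec.ka * lumen / q_gut / 1000.0  # nmol/L -> µM
    return float(conc[0]) if scalar else conc


def reversible_inhibition_factor(i_u: float, ki: float) -> float:
    """Competitive-inhibition clearance factor 1 / (1 + I_u/Ki)."""
    if ki <= 0:
        raise DomainError("ki must be > 0")
    if i_u < 0:
        raise DomainError("inhibitor concentration must be >= 0")
    return 1.0 / (1.0 + i_u / ki)


def mbi_active_enzyme(
    i_u_of_t,
    k_inact: float,
    k_i_app: float,
    k_deg: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Integrate the active-enzyme fraction E(t) for a given I_u(t), E(0)=1."""
    from scipy.integrate import solve_ivp

    if k_inact < 0 or k_i_app <= 0 or k_deg <= 0:
        raise DomainError("k_inact >= 0, k_i_app > 0 and k_deg > 0 required")
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(t, y):
        i = float(i_u_of_t(t))
        lam = k_inact * i / (k_i_app + i)
        return [k_deg * (1.0 - y[0]) - lam * y[0]]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [1.0],
        method="LSODA",
        t_eval=t_grid,
        rtol=1e-8,
        atol=1e-12,
    )
    return sol.y[0]


@dataclass
class InhibitionForcing:
    """Time-dependent inhibition factors evaluated inside the victim ODE."""

    perpetrator: PerpetratorSpec
    dose_times: tuple[float, ...]
    q_gut: float
    inhibit_gut: bool = True
    inhibit_liver: bool = True
    ki_overrides: dict[str, float] = field(default_factory=dict)
    # memo of the last evaluation time (the ODE rhs queries several enzymes
    # at the same t)
    _cache_t: float = field(default=float("nan"), repr=False)
    _cache_plasma: float = field(default=0.0, repr=False)
    _cache_gut: float = field(default=0.0, repr=False)

    def _ki(self, enzyme: str) -> float | None:
        if enzyme in self.ki_overrides:
            return self.ki_overrides[enzyme]
        return self.perpetrator.inhibition.ki.get(enzyme)

    def _refresh(self, t: float) -> None:
        if t == self._cache_t:
            return
        object.__setattr__(self, "_cache_t", t)
        if self.dose_times:
            object.__setattr__(
                self,
                "_cache_plasma",
                perpetrator_concentration(
                    self.perpetrator, t, self.dose_times, unbound=True
                ),
            )
            object.__setattr__(
                self,
                "_cache_gut",
                gut_inhibitor_concentration(
                    self.perpetrator, t, self.dose_times, self.q_gut
                ),
            )

    def unbound_plasma(self, t: float) -> float:
        if not self.dose_times:
            return 0.0
        self._refresh(t)
        return self._cache_plasma

    def gut_concentration(self, t: float) -> float:
        if not self.dose_times:
            return 0.0
        self._refresh(t)
        return self._cache_gut

    def reversible_factor(self, t: float, enzyme: str, site: str) -> float:
        ki = self._ki(enzyme)
        if ki is None:
            return 1.0
        if site == "gut":
            if not self.inhibit_gut:
                return 1.0
            i = self.gut_concentration(t)
        else:
            if not self.inhibit_liver:
                return 1.0
            i = self.unbound_plasma(t)
        return reversible_inhibition_factor(i, ki)

    def mbi_rates(self, t: float, enzyme: str) -> tuple[float, float]:
        m = self.perpetrator.inhibition.mbi[enzyme]
        i = self.unbound_plasma(t)
        lam = m.k_inact * i / (m.k_i_app + i)
        return m.k_deg, lam


def coadminister(
    victim_system: ModelSystem,
    perpetrator: PerpetratorSpec,
    dose_times: tuple[float, ...],
    inhibit_gut: bool = True,
    inhibit_liver: bool = True,
    ki_overrides: dict[str, float] | None = None,
) -> ModelSystem:
    """Attach a perpetrator forcing function to a victim system.

    MBI enzymes gain one active-fraction state each (E(0) = 1).  With an empty
    dose schedule every inhibition factor is identically 1, so the victim
    system itself is returned unchanged.
    """
    if victim_system.inhibition is not None:
        raise ValueError("victim system already carries a perpetrator")
    if not dose_times:
        return victim_system
    forcing = InhibitionForcing(
        perpetrator=perpetrator,
        dose_times=tuple(sorted(dose_times)),
        q_gut=victim_system.physiology.q_gut,
        inhibit_gut=inhibit_gut,
        inhibit_liver=inhibit_liver,
        ki_overrides=dict(ki_overrides or {}),
    )
    mbi_state_index = {
        enzyme: victim_system.n_states + offset
        for offset, enzyme in enumerate(sorted(perpetrator.inhibition.mbi))
    }
    return ModelSystem(
        compounds=victim_system.compounds,
        physiology=victim_system.physiology,
        n_states=victim_system.n_states + len(mbi_state_index),
        n_core_states=victim_system.n_core_states,
        index=victim_system.index,
        inhibition=forcing,
        mbi_state_index=mbi_state_index,
    )
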