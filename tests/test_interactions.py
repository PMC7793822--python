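import math

import numpy as np
import pytest

from vicasim.interactions import (
    InhibitionForcing,
    coadminister,
    gut_inhibitor_concentration,
    mbi_active_enzyme,
    perpetrator_concentration,
    reversible_inhibition_factor,
)
from vicasim.metrics import auc_interval
from vicasim.parameters_config import InhibitionSpec, PerpetratorSpec
from vicasim.pbpk_engine import (
    DomainError,
    DosingRegimen,
    build_system,
    make_time_grid,
    simulate_individual,
)

HAND_SPEC = PerpetratorSpec(
    name="probe",
    molecular_weight=345.42,
    dose=80.0,
    ka=2.0,
    fa=1.0,
    v=20.0,
    cl=10.0,
    fu_plasma=1.0,
)


class TestPerpetratorConcentration:
    def test_zero_before_first_dose(self):
        assert perpetrator_concentration(HAND_SPEC, 0.0) == 0.0
        assert perpetrator_concentration(HAND_SPEC, 5.0, dose_times=(10.0,)) == 0.0

    def test_vanishes_long_after_single_dose(self):
        assert perpetrator_concentration(HAND_SPEC, 500.0) < 1e-12

    def test_matches_hand_evaluated_bateman(self):
        t, ka, k = 2.0, 2.0, 10.0 / 20.0
        expected = (
            80.0
            * 1000.0
            / (345.42 * 20.0)
            * ka
            / (ka - k)
            * (math.exp(-k * t) - math.exp(-ka * t))
        )
        assert math.isclose(
            perpetrator_concentration(HAND_SPEC, t), expected, rel_tol=1e-9
        )

    def test_degenerate_absorption_rate_limit(self):
        spec_eq = PerpetratorSpec(
            name="probe",
            molecular_weight=345.42,
            dose=80.0,
            ka=0.5,
            fa=1.0,
            v=20.0,
            cl=10.0,
            fu_plasma=1.0,
        )
        t = 2.0
        k = 0.5
        expected = 80.0 * 1000.0 / (345.42 * 20.0) * k * t * math.exp(-k * t)
        assert math.isclose(
            perpetrator_concentration(spec_eq, t), expected, rel_tol=1e-6
        )

    def test_unbound_scaling(self):
        spec = PerpetratorSpec(
            name="probe",
            molecular_weight=345.42,
            dose=80.0,
            ka=2.0,
            fa=1.0,
            v=20.0,
            cl=10.0,
            fu_plasma=0.05,
        )
        total = perpetrator_concentration(spec, 2.0, unbound=False)
        unbound = perpetrator_concentration(spec, 2.0, unbound=True)
        assert math.isclose(unbound, 0.05 * total, rel_tol=1e-12)

    def test_superposition_of_repeated_doses(self):
        single = perpetrator_concentration(HAND_SPEC, 26.0, dose_times=(24.0,))
        carry = perpetrator_concentration(HAND_SPEC, 26.0, dose_times=(0.0,))
        both = perpetrator_concentration(HAND_SPEC, 26.0, dose_times=(0.0, 24.0))
        assert math.isclose(both, single + carry, rel_tol=1e-12)


class TestGutSurrogate:
    def test_zero_before_dose(self):
        assert gut_inhibitor_concentration(HAND_SPEC, 5.0, dose_times=(10.0,)) == 0.0

    def test_decays_with_lumen_depletion(self):
        c1 = gut_inhibitor_concentration(HAND_SPEC, 0.5)
        c2 = gut_inhibitor_concentration(HAND_SPEC, 3.0)
        assert c1 > c2 > 0.0

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(DomainError):
            gut_inhibitor_concentration(HAND_SPEC, 1.0, q_gut=0.0)


class TestReversibleInhibition:
    def test_no_inhibitor(self):
        assert reversible_inhibition_factor(0.0, 0.11) == 1.0

    def test_half_inhibition_at_ki(self):
        assert reversible_inhibition_factor(0.11, 0.11) == 0.5

    def test_hand_value(self):
        assert math.isclose(
            reversible_inhibition_factor(0.22, 0.11), 1.0 / 3.0, rel_tol=1e-12
        )

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(DomainError):
            reversible_inhibition_factor(0.1, 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            reversible_inhibition_factor(-0.1, 0.11)


class TestMechanismBasedInactivation:
    def test_no_inhibitor_keeps_full_activity(self):
        t = np.linspace(0.0, 100.0, 101)
        e = mbi_active_enzyme(lambda _t: 0.0, 2.5, 1.7, 0.02, t)
        assert np.abs(e - 1.0).max() < 1e-9

    def test_saturating_inhibitor_steady_state(self):
        k_inact, k_deg = 2.5, 0.02
        t = np.linspace(0.0, 50.0, 501)
        e = mbi_active_enzyme(lambda _t: 1e6, k_inact, 1.7, k_deg, t)
        assert math.isclose(e[-1], k_deg / (k_deg + k_inact), rel_tol=1e-4)

    def test_zero_inactivation_rate(self):
        t = np.linspace(0.0, 100.0, 101)
        e = mbi_active_enzyme(lambda _t: 5.0, 0.0, 1.7, 0.02, t)
        assert np.abs(e - 1.0).max() < 1e-9

    def test_activity_bounded_in_unit_interval(self):
        t = np.linspace(0.0, 48.0, 481)
        e = mbi_active_enzyme(
            lambda s: perpetrator_concentration(HAND_SPEC, s, dose_times=(0.0, 24.0)),
            2.5,
            1.7,
            0.02,
            t,
        )
        assert np.all(e > 0.0) and np.all(e <= 1.0 + 1e-12)

    def test_invalid_constants_rejected(self):
        t = np.linspace(0.0, 10.0, 11)
        with pytest.raises(DomainError):
            mbi_active_enzyme(lambda _t: 1.0, 2.5, 1.7, 0.0, t)


class TestCoadministration:
    def test_empty_schedule_is_identity(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        combined = coadminister(system, registry.perpetrators["simvastatin"], ())
        assert combined is system
        regimen = DosingRegimen(((0.0, "vicagrel", 24.0),))
        t_grid = make_time_grid(24.0, 24.0)
        base = simulate_individual(system, regimen, t_grid)
        again = simulate_individual(combined, regimen, t_grid)
        for name in base.conc:
            assert np.abs(base.conc[name] - again.conc[name]).max() < 1e-12

    def test_infinite_ki_recovers_baseline(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        regimen = DosingRegimen(((0.0, "vicagrel", 24.0),))
        t_grid = make_time_grid(24.0, 24.0)
        kwargs = {"rtol": 1e-10, "atol": 1e-12}
        base = simulate_individual(system, regimen, t_grid, **kwargs)
        combined = coadminister(
            system,
            registry.perpetrators["simvastatin"],
            (0.0,),
            ki_overrides={"CES1": 1e12, "CES2": 1e12},
        )
        inhibited = simulate_individual(combined, regimen, t_grid, **kwargs)
        for name in base.conc:
            scale = base.conc[name].max()
            if scale == 0.0:
                continue
            assert (
                np.abs(inhibited.conc[name] - base.conc[name]).max() < 1e-9 * scale
            )

    def test_double_attachment_rejected(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        combined = coadminister(
            system, registry.perpetrators["simvastatin"], (0.0,)
        )
        with pytest.raises(ValueError, match="already"):
            coadminister(combined, registry.perpetrators["simvastatin"], (0.0,))

    def test_stronger_ces1_inhibition_raises_active_metabolite(
        self, registry, ref_individual
    ):
        """Smaller simvastatin Ki -> less CES1 hydrolysis of clopidogrel, 2-oxo
        and AM-H4 -> monotonically higher AM-H4 exposure ratio (with/without)."""
        regimen = DosingRegimen(((24.0, "clopidogrel", 300.0),))
        t_grid = make_time_grid(48.0, 48.0)

        def amh4_auc(ki_ces1):
            system = build_system(registry, ref_individual, drugs=["clopidogrel"])
            if ki_ces1 is not None:
                system = coadminister(
                    system,
                    registry.perpetrators["simvastatin"],
                    (0.0, 24.0),
                    ki_overrides={"CES1": ki_ces1, "CES2": 0.67},
                )
            profile = simulate_individual(system, regimen, t_grid)
            return auc_interval(profile, "am-h4", 24.0, 48.0)

        baseline = amh4_auc(None)
        ratios = [amh4_auc(ki) / baseline for ki in (0.01, 0.11, 1.0)]
        assert ratios[0] > ratios[1] > ratios[2] > 1.0

    def test_mbi_state_appended_and_initialized(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["clopidogrel"])
        combined = coadminister(
            system, registry.perpetrators["omeprazole"], (0.0,)
        )
        assert combined.n_states == system.n_states + 1
        assert combined.mbi_state_index == {"CYP2C19": system.n_states}
        assert combined.initial_state()[system.n_states] == 1.0


class TestForcingFactors:
    def test_factors_bounded(self, registry):
        forcing = InhibitionForcing(
            perpetrator=registry.perpetrators["simvastatin"],
            dose_times=(0.0, 24.0),
            q_gut=14.0,
        )
        for t in np.linspace(0.0, 48.0, 49):
            for enzyme in ("CES1", "CES2"):
                for site in ("gut", "liver"):
                    factor = forcing.reversible_factor(float(t), enzyme, site)
                    assert 0.0 < factor <= 1.0

    def test_uninhibited_enzyme_unaffected(self, registry):
        forcing = InhibitionForcing(
            perpetrator=registry.perpetrators["simvastatin"],
            dose_times=(0.0,),
            q_gut=14.0,
        )
        assert forcing.reversible_factor(1.0, "CYP3A4", "liver") == 1.0


def test_inhibition_spec_validation():
    with pytest.raises(Exception, match="ki"):
        InhibitionSpec(ki={"CES1": -1.0}).validate("probe")
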