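import math

import numpy as np
import pytest
from scipy.linalg import expm

from vicasim.parameters_config import parse_config
from vicasim.pbpk_engine import (
    DomainError,
    DosingRegimen,
    build_system,
    fraction_escaping_gut,
    make_time_grid,
    mole_balance_residual,
    scale_clint,
    simulate_individual,
    wellstirred_hepatic_clearance,
)
from vicasim.population import reference_individual

from conftest import perturbed_registry


class TestScaling:
    def test_zero_clint_scales_to_zero(self):
        assert scale_clint(0.0, 60_000.0) == 0.0

    def test_hepatic_unit_conversion(self):
        # 100 µL/min/mg over 40 mg/g x 1500 g liver protein -> 360 L/h
        assert math.isclose(scale_clint(100.0, 40.0 * 1500.0), 360.0, rel_tol=1e-12)

    def test_gut_unit_conversion(self):
        assert math.isclose(scale_clint(2305.0, 3000.0), 414.9, rel_tol=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            scale_clint(-1.0, 100.0)
        with pytest.raises(DomainError):
            scale_clint(1.0, -100.0)


class TestFractionEscapingGut:
    def test_no_gut_metabolism(self):
        assert fraction_escaping_gut(0.0, 14.0) == 1.0

    def test_large_clearance_limit(self):
        assert fraction_escaping_gut(1e12, 14.0) < 1e-10

    def test_hand_value(self):
        assert math.isclose(fraction_escaping_gut(56.0, 14.0, 1.0), 0.2, rel_tol=1e-12)

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(DomainError):
            fraction_escaping_gut(1.0, 0.0)


class TestWellStirred:
    def test_flow_limited_limit(self):
        assert math.isclose(
            wellstirred_hepatic_clearance(90.0, 1.0, 1e12), 90.0, rel_tol=1e-9
        )

    def test_no_unbound_drug(self):
        assert wellstirred_hepatic_clearance(90.0, 0.0, 1000.0) == 0.0

    def test_hand_value(self):
        assert math.isclose(
            wellstirred_hepatic_clearance(90.0, 0.02, 50_000.0),
            90_000.0 / 1090.0,
            rel_tol=1e-12,
        )

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(DomainError):
            wellstirred_hepatic_clearance(0.0, 0.5, 100.0)


class TestTopology:
    def test_clopidogrel_has_no_gut_pathways(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["clopidogrel"])
        parent = system.compounds[system.index["clopidogrel"]]
        assert parent.gut_channels == []

    def test_vicagrel_gut_pathways_are_ces2_and_aadac(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        parent = system.compounds[system.index["vicagrel"]]
        assert {enzyme for enzyme, _, _ in parent.gut_channels} == {"CES2", "AADAC"}

    def test_pm_zeroes_cyp2c19_channels(self, registry):
        pm = reference_individual(registry, phenotype="PM")
        system = build_system(registry, pm, drugs=["clopidogrel"])
        for comp in system.compounds:
            for enzyme, cl, _ in comp.liver_channels:
                if enzyme == "CYP2C19":
                    assert cl == 0.0

    def test_metabolites_cannot_be_dosed(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        with pytest.raises(DomainError):
            system.dose_vector("am-h4", 10.0)

    def test_metabolites_of_both_parents_are_shared(self, registry, ref_individual):
        system = build_system(registry, ref_individual)
        assert set(system.index) == {
            "clopidogrel",
            "vicagrel",
            "2-oxo-clopidogrel",
            "am-h4",
        }


class TestTimeGrid:
    def test_dense_then_coarse(self):
        grid = make_time_grid(24.0, 48.0, dt_dosing=0.1, dt_washout=1.0)
        assert grid[0] == 0.0 and grid[-1] == 48.0
        steps = np.diff(grid)
        assert np.allclose(steps[grid[:-1] < 24.0], 0.1)
        assert np.allclose(steps[grid[:-1] >= 24.0], 1.0)

    def test_degenerate_window_rejected(self):
        with pytest.raises(DomainError):
            make_time_grid(24.0, 0.0)


def _vicagrel_profile(registry, individual, dose_mg=24.0, t_end=24.0):
    system = build_system(registry, individual, drugs=["vicagrel"])
    regimen = DosingRegimen(((0.0, "vicagrel", dose_mg),))
    t_grid = make_time_grid(t_end, t_end)
    return simulate_individual(system, regimen, t_grid)


class TestSimulation:
    def test_zero_dose_gives_zero_profile(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        profile = simulate_individual(
            system, DosingRegimen(()), make_time_grid(24.0, 24.0)
        )
        for conc in profile.conc.values():
            assert np.all(conc == 0.0)

    def test_mole_conservation(self, registry, ref_individual):
        profile = _vicagrel_profile(registry, ref_individual, t_end=96.0)
        assert mole_balance_residual(profile).max() < 1e-6

    def test_states_nonnegative(self, registry, ref_individual):
        profile = _vicagrel_profile(registry, ref_individual, t_end=96.0)
        assert profile.states.min() > -1e-9

    def test_dose_linearity(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        t_grid = make_time_grid(24.0, 24.0)
        kwargs = {"rtol": 1e-10, "atol": 1e-13}
        low = simulate_individual(
            system, DosingRegimen(((0.0, "vicagrel", 24.0),)), t_grid, **kwargs
        )
        high = simulate_individual(
            system, DosingRegimen(((0.0, "vicagrel", 48.0),)), t_grid, **kwargs
        )
        for name in low.conc:
            scale = low.conc[name].max()
            if scale == 0.0:
                continue
            assert np.abs(high.conc[name] / 2.0 - low.conc[name]).max() < 1e-9 * scale

    def test_aadac_compensates_for_absent_ces2(self, registry_dict, registry):
        def mutate(doc):
            for p in doc["compounds"]["vicagrel"]["pathways"]:
                if p["enzyme"] == "CES2":
                    p["clint"] = 0.0

        no_ces2 = perturbed_registry(registry_dict, mutate)
        individual = reference_individual(no_ces2)
        system = build_system(no_ces2, individual, drugs=["vicagrel"])
        parent = system.compounds[system.index["vicagrel"]]
        total_gut = sum(cl for _, cl, _ in parent.gut_channels)
        fg = system.physiology.q_gut / (system.physiology.q_gut + total_gut)
        assert 0.0 < fg < 1.0  # AADAC alone still extracts drug in the gut wall
        profile = _vicagrel_profile(no_ces2, individual)
        assert profile.conc["2-oxo-clopidogrel"].max() > 0.0
        assert profile.conc["am-h4"].max() > 0.0

    def test_matrix_exponential_oracle(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        a = system.matrix()
        x0 = system.dose_vector("vicagrel", 24.0)
        t_grid = np.array([0.0, 1.0, 6.0, 24.0])
        profile = simulate_individual(
            system,
            DosingRegimen(((0.0, "vicagrel", 24.0),)),
            t_grid,
            rtol=1e-10,
            atol=1e-12,
        )
        scale = np.abs(x0).max()
        for j, t in enumerate(t_grid):
            exact = expm(a * t) @ x0
            assert np.abs(profile.states[:, j] - exact).max() < 1e-8 * scale

    def test_grid_must_cover_dose_times(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        with pytest.raises(DomainError):
            simulate_individual(
                system,
                DosingRegimen(((48.0, "vicagrel", 24.0),)),
                make_time_grid(24.0, 24.0),
            )

    def test_nonpositive_dose_rejected(self, registry, ref_individual):
        system = build_system(registry, ref_individual, drugs=["vicagrel"])
        with pytest.raises(DomainError):
            simulate_individual(
                system,
                DosingRegimen(((0.0, "vicagrel", -5.0),)),
                make_time_grid(24.0, 24.0),
            )


@pytest.fixture(scope="module")
def onecpt():
    doc = {
            "compounds": {
                "drug": {
                    "molecular_weight": 300.0,
                    "ka": 1.0,
                    "fa": 0.8,
                    "fu_plasma": 1.0,
                    "blood_plasma_ratio": 1.0,
                    "v_sys": 50.0,
                    "renal_cl": 5.0,
                    "pathways": [],
                }
            },
            "physiology": {
                "generic": {
                    "q_hepatic_total": 1e6,
                    "q_portal": 7.5e5,
                    "q_hepatic_arterial": 2.5e5,
                    "q_gut": 14.0,
                    "liver_weight": 1.0,
                    "mppgl": 1.0,
                    "gut_protein": 1.0,
                    "v_portal": 1e-6,
                    "v_liver": 1e-6,
                }
            },
            "pd": {"kin": 0.0124, "kout": 0.0124, "kirre": 1.0, "mpa0": 60.0},
            "populations": {
                "generic": {
                    "ethnicity": "generic",
                    "phenotype_frequencies": {"EM": 1.0},
                    "n_subjects": 1,
                    "n_trials": 1,
                    "seed": 1,
                }
            },
        }
    return parse_config(doc)


class TestOneCompartmentOracle:
    """Degenerate physiology (no liver/portal volume, huge flows) collapses
    the topology to a one-compartment oral model with a closed-form solution."""

    def test_matches_bateman_solution(self, onecpt):
        individual = reference_individual(onecpt)
        system = build_system(onecpt, individual, "generic", drugs=["drug"])
        t_grid = np.linspace(0.0, 48.0, 97)
        profile = simulate_individual(
            system,
            DosingRegimen(((0.0, "drug", 100.0),)),
            t_grid,
            rtol=1e-10,
            atol=1e-14,
        )
        ka, cl, v, fa, mw = 1.0, 5.0, 50.0, 0.8, 300.0
        k = cl / v
        a0 = fa * 100.0 * 1e6 / mw  # nmol
        amount = a0 * ka / (ka - k) * (np.exp(-k * t_grid) - np.exp(-ka * t_grid))
        exact = amount / v * mw / 1000.0  # ng/mL
        scale = exact.max()
        assert np.abs(profile.conc["drug"] - exact).max() < 1e-6 * scale
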