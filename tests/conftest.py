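import pytest

from vicasim.parameters_config import (
    default_fixture,
    parse_config,
    registry_to_dict,
)


@pytest.fixture(scope="session")
def registry():
    """The packaged default parameterization."""
    return default_fixture()


@pytest.fixture(scope="session")
def registry_dict(registry):
    """Mutable plain-dict copy of the default config for perturbation tests."""
    return registry_to_dict(registry)


def perturbed_registry(registry_dict, mutate):
    """Apply ``mutate`` to a deep copy of the config dict and re-parse."""
    import copy

    doc = copy.deepcopy(registry_dict)
    mutate(doc)
    return parse_config(doc)


@pytest.fixture(scope="session")
def zero_cv_registry(registry_dict):
    """Defaults with every inter-individual CV collapsed to zero."""

    def mutate(doc):
        for compound in doc["compounds"].values():
            for pathway in compound["pathways"]:
                pathway["cv"] = 0.0
        doc["iiv"] = {"cv_ka": 0.0, "cv_v_sys": 0.0}
        for key in ("cv_kin", "cv_kout", "cv_kirre", "cv_mpa0"):
            doc["pd"][key] = 0.0

    return perturbed_registry(registry_dict, mutate)


@pytest.fixture(scope="session")
def ref_individual(registry):
    from vicasim.population import reference_individual

    return reference_individual(registry)
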