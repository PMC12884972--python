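import pytest

from sbepanel import MassModel, ThermoParams, builtin_panel, builtin_profiles


@pytest.fixture(scope="session")
def model():
    return MassModel.default()


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture(scope="session")
def profiles_rules():
    return builtin_profiles()


@pytest.fixture(scope="session")
def thermo():
    return ThermoParams()


@pytest.fixture(scope="session")
def species_templates(panel, profiles_rules):
    """Synthetic reference templates per species, keyed by locus."""
    from sbepanel import generate_synthetic_templates

    profiles, _ = profiles_rules
    out = {}
    for i, prof in enumerate(profiles):
        recs = generate_synthetic_templates(
            panel, dict(prof.alleles), seed=100 + i, species=prof.species
        )
        out[prof.species] = {rid.split("|")[1]: seq for rid, seq in recs}
    return out
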