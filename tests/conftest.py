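import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

import karyodelim as kd


@pytest.fixture(scope="session")
def reference_table():
    """Parsed packaged karyotype table: list of (SampleRecord, KaryotypeObservation)."""
    kary_path, _ = kd.reference_karyotype_fixture()
    return kd.read_karyotype_table(kary_path)


@pytest.fixture(scope="session")
def reference_localities():
    _, loc_path = kd.reference_karyotype_fixture()
    return kd.read_locality_table(loc_path)


@pytest.fixture(scope="session")
def taxon_observations(reference_table):
    """Observations grouped by prior taxon label."""
    groups = {}
    for rec, obs in reference_table:
        groups.setdefault(rec.taxon_label, []).append(obs)
    return groups


@pytest.fixture()
def tiny_alignment():
    return kd.Alignment(
        ["a1", "a2", "b1", "b2"],
        ["ACGTACGT", "ACGTACGT", "ACGAACGT", "ACGAACGT"],
    )
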