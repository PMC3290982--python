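import pytest

from expintensity import ApplicatorRecord, load_weight_table
from expintensity.synth import SimConfig, generate_cohort, generate_monitoring


@pytest.fixture(scope="session")
def v1():
    return load_weight_table("v1")


@pytest.fixture(scope="session")
def v2():
    return load_weight_table("v2")


def record(
    mix="did_not_mix",
    methods=("boom_on_tractor",),
    repair=False,
    ppe=(),
    rid="r1",
    days=None,
):
    return ApplicatorRecord(
        id=rid,
        mix_level=mix,
        methods=tuple(methods),
        repair=repair,
        ppe_items=frozenset(ppe),
        lifetime_days=days,
    )


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic monitoring data equal to the model mean exactly."""
    cohort = generate_cohort(SimConfig(seed=11))
    return generate_monitoring(cohort, gsd=1.0, seed=12)
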