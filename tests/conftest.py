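import pytest
from hypothesis import HealthCheck, settings

from clonetrace.synthetic import SimulationConfig, simulate_patient
from clonetrace.variant_io import MutationKey, MutationProfile, SomaticCall

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_NT = "ACGT"


def snv_key(i: int, chrom: str = "1") -> MutationKey:
    """Deterministic distinct SNV keys for toy profiles."""
    ref = _NT[i % 4]
    alt = _NT[(i + 1) % 4]
    return MutationKey(chrom, 1000 + i, ref, alt)


def make_profile(sample_id: str, indices, non_synonymous=True, **meta) -> MutationProfile:
    calls = tuple(
        SomaticCall(key=snv_key(i), depth=100, alt_reads=40, non_synonymous=non_synonymous)
        for i in indices
    )
    return MutationProfile(sample_id=sample_id, calls=calls, **meta)


@pytest.fixture(scope="session")
def clonal_patient():
    """Default-condition two-tumor clonal patient (trunk 150, private 50/50)."""
    return simulate_patient(SimulationConfig(n_tumors=2, relatedness=("clonal",), seed=7))


@pytest.fixture(scope="session")
def lu1_like_patient():
    """Clonal pair + independent tumor + benign sample, like the index patient."""
    return simulate_patient(
        SimulationConfig(
            n_tumors=3,
            relatedness=("clonal", "independent", "independent"),
            include_benign=True,
            seed=11,
        )
    )
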