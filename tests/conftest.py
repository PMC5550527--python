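import pytest
from hypothesis import settings

from satskew import synth

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def study():
    """One medium synthetic study shared by read-only tests."""
    return synth.simulate_study(seed=7)


@pytest.fixture(scope="session")
def small_study():
    cfg = synth.SynthConfig(
        n_candidate_males=12,
        n_females_per_group=6,
        n_offspring=12,
        birth_years=(2008,),
    )
    return synth.simulate_study(cfg, seed=11)
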