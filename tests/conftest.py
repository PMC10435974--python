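import numpy as np
import pytest
from hypothesis import settings

from nemafauna import CommunitySample, default_traits

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def traits():
    return default_traits()


@pytest.fixture(scope="session")
def trait_rows(traits):
    """Plain-tuple view of the fixture for literal-loop oracles."""
    return {
        r.genus: (r.trophic_group, r.cp_value, r.fresh_weight, r.predator)
        for r in traits
    }


def random_sample(rng: np.random.Generator, traits, min_genera=5) -> CommunitySample:
    """A random community over a random subset of the trait fixture."""
    genera = list(traits.genera)
    k = int(rng.integers(min_genera, len(genera) + 1))
    chosen = rng.choice(genera, size=k, replace=False)
    abund = {g: float(rng.gamma(1.5, 30.0)) for g in chosen}
    # sprinkle explicit zeros to exercise the zero-abundance path
    for g in rng.choice(genera, size=3, replace=False):
        abund.setdefault(g, 0.0)
    return CommunitySample(sample_id="rand", treatment="CK", abundance=abund)


@pytest.fixture
def make_sample(traits):
    def _make(**abundance):
        return CommunitySample(sample_id="s", treatment="CK", abundance=abundance)

    return _make
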