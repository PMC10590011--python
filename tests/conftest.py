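import pytest

from hotzones import SyntheticSpec, example_fixture, random_regions


@pytest.fixture(scope="session")
def example_regions():
    """The ten-region, three-TF worked-example dataset."""
    return example_fixture()


@pytest.fixture(scope="session")
def small_random_regions():
    """50 regions of 4 TFs on a 10 kb span — dense enough to overlap."""
    return random_regions(
        SyntheticSpec(n_tfs=4, n_regions=50, span=10_000,
                      length_range=(50, 400), seed=7)
    )
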