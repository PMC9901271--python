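import pytest

from ssram import load_paper_example
from ssram.example import expected as _expected_catalogue
from ssram.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def example():
    """The 12-animal worked example (inputs only)."""
    return load_paper_example()


@pytest.fixture(scope="session")
def expected():
    """Reference catalogue of known results for the worked example."""
    return _expected_catalogue()


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    return simulate(
        SimConfig(seed=11, n_founders=12, n_generations=3, progeny_per_mating=2,
                  n_markers=40, genotyped_fraction=0.3, phenotyped_fraction=0.6)
    )


def sim_dataset(seed, **kw):
    """Convenience factory for per-test simulated datasets."""
    defaults = dict(n_founders=10, n_generations=3, progeny_per_mating=2,
                    n_markers=40, genotyped_fraction=0.3, phenotyped_fraction=0.6)
    defaults.update(kw)
    return simulate(SimConfig(seed=seed, **defaults))
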