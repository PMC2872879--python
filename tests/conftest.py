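import numpy as np
import pytest

from motifrank.index import Region, build_index
from motifrank.search import MotifSearch, SearchConfig
from motifrank.synthetic import SyntheticSpec, synthesize_dataset

IUPAC = list("ACGTWSRYKMN")
# Weights favour plain bases so random motifs stay informative.
IUPAC_WEIGHTS = [0.15] * 4 + [0.06] * 6 + [0.04]


def random_regions(rng, n=30, length=200, prefix="r"):
    return [
        Region(f"{prefix}{i}", "".join(rng.choice(list("ACGT"), size=length)))
        for i in range(n)
    ]


def random_motif(rng, min_len=5, max_len=8):
    length = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(IUPAC, size=length, p=IUPAC_WEIGHTS))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted-motif dataset for search unit tests."""
    spec = SyntheticSpec(
        n_regions=150,
        region_length=150,
        motif="TGACTCA",
        planted_fraction=0.2,
        effect_size=3.0,
        noise_sd=1.0,
        seed=42,
    )
    return synthesize_dataset(spec)


@pytest.fixture(scope="session")
def small_engine(small_dataset):
    regions, _, _ = small_dataset
    cfg = SearchConfig(min_set_size=10, max_set_fraction=0.3)
    return MotifSearch(regions, cfg)


@pytest.fixture(scope="session")
def small_results(small_dataset, small_engine):
    _, ev, _ = small_dataset
    return small_engine.run(ev)
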