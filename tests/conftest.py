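import numpy as np
import pytest

from motifgat import PlantedMotifSpec, build_graph, generate_ppm, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-motif dataset (20 positives + 20 negatives, 60 bp)."""
    rng = np.random.default_rng(7)
    spec = PlantedMotifSpec(ppm=generate_ppm(6, 1.8, rng))
    records, truth = generate_synthetic(spec, n_pos=20, seq_len=60, lenk=5, rng_seed=7)
    return spec, records, truth


@pytest.fixture(scope="session")
def small_graph(small_planted):
    _, records, _ = small_planted
    return build_graph(records, lenk=5)


@pytest.fixture(scope="session")
def tiny_graph():
    """A deliberately tiny graph (4 short sequences) for scalar-oracle tests."""
    rng = np.random.default_rng(3)
    spec = PlantedMotifSpec(ppm=generate_ppm(4, 1.5, rng))
    records, _ = generate_synthetic(spec, n_pos=3, seq_len=14, lenk=3, rng_seed=3)
    return build_graph(records, lenk=3)
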