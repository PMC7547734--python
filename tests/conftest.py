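import numpy as np
import pytest

from disconnectomics import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_brain():
    return sd.make_toy_brain((16, 16, 16), 4, seed=1)


@pytest.fixture(scope="session")
def small_brain():
    return sd.make_toy_brain((8, 8, 8), 2, seed=7)


@pytest.fixture(scope="session")
def planted(toy_brain):
    """Planted structure + tractograms + clustered cohort + term matrix."""
    pairs = sd.default_connection_pairs(toy_brain)
    structure = sd.planted_bundle_structure(toy_brain, pairs[:4], n_terms=12, noise_sd=0.05, seed=0)
    tractograms = sd.make_toy_tractograms(toy_brain, pairs, 4, 20, 1.5, seed=2)
    cohort = sd.plant_lesion_cohort(toy_brain, structure, 60, "clustered", (8, 30), seed=3)
    terms = sd.make_toy_term_maps(structure, toy_brain.n_regions, seed=4)
    return {
        "pairs": pairs,
        "structure": structure,
        "tractograms": tractograms,
        "cohort": cohort,
        "terms": terms,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
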