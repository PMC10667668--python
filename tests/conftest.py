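import numpy as np
import pandas as pd
import pytest

from secretomics import SecretomeSimConfig, SpectralCountMatrix, generate_secretome_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic secretome (7 conditions, 33 planted secreted loci)."""
    return generate_secretome_dataset(SecretomeSimConfig(seed=0))


@pytest.fixture()
def small_matrix():
    """Hand-built matrix: 3 conditions x 2 fractions, 6 loci with the
    canonical evidence patterns (supernatant-only, both-fraction, single
    condition, cytosolic, absent)."""
    samples = pd.DataFrame(
        {
            "strain": ["WT"] * 6,
            "sugar": ["none", "none", "maltose", "maltose", "maltodextrin", "maltodextrin"],
            "fraction": ["supernatant", "cytosol"] * 3,
        },
        index=pd.Index(
            ["s_none", "c_none", "s_mal", "c_mal", "s_max", "c_max"],
            name="sample_id",
        ),
    )
    counts = pd.DataFrame(
        {
            # sup_none cyt_none sup_mal cyt_mal sup_max cyt_max
            "flagellin": [5, 0, 8, 0, 6, 0],  # sup-only, 3 conditions -> 1
            "amylopullulanase": [50, 5, 60, 5, 55, 5],  # both fractions, ratio wins -> 1
            "slayer": [0, 0, 0, 0, 20, 0],  # sup-only, single condition -> 0.5
            "lipoprotein": [10, 0, 12, 0, 0, 0],  # sup-only, 2 conditions -> 1
            "cytosolic": [1, 40, 0, 45, 0, 50],  # contamination -> 0
            "absent": [0, 0, 0, 0, 0, 0],  # never detected -> 0
        }
    ).T
    counts.columns = samples.index
    counts.index.name = "locus"
    return SpectralCountMatrix(counts=counts, samples=samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
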