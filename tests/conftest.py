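import numpy as np
import pandas as pd
import pytest

from plaquetx import (
    CountMatrix,
    SynthConfig,
    add_scaled_log2,
    aggregate,
    relative_abundance,
    simulate,
    size_factors,
)


@pytest.fixture(scope="session")
def small_config():
    """A fast twin cohort: full pair structure, reduced transcript load."""
    return SynthConfig(n_species=40, transcripts_per_species=5, seed=11)


@pytest.fixture(scope="session")
def sim(small_config):
    """(metadata, counts, truth) for the small cohort."""
    return simulate(small_config)


@pytest.fixture(scope="session")
def species_profile(sim):
    _, counts, _ = sim
    factors = size_factors(counts)
    prof = aggregate(counts, level="species")
    relative_abundance(prof)
    add_scaled_log2(prof, factors)
    return prof


def make_count_matrix(counts: np.ndarray, subjects=None, species=None) -> CountMatrix:
    """Hand-built CountMatrix with one transcript per species and stub roles."""
    counts = np.asarray(counts)
    n_t, n_s = counts.shape
    subjects = subjects or [f"S{j + 1}" for j in range(n_s)]
    species = species or [f"Genus{i + 1}_sp01" for i in range(n_t)]
    idx = pd.Index([f"t{i + 1}" for i in range(n_t)], name="transcript_id")
    ann = pd.DataFrame(
        {
            "species": species,
            "genus": [s.split("_")[0] for s in species],
            "role_category": "Protein translation",
            "subsystem": "Ribosome",
            "function": "ribosomal protein biogenesis",
        },
        index=idx,
    )
    mat = pd.DataFrame(counts, index=idx, columns=subjects)
    return CountMatrix(counts=mat, annotations=ann)
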