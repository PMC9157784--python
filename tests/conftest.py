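import numpy as np
import pandas as pd
import pytest

from aquasurvey import IncidenceMatrix, IncidenceCounts


@pytest.fixture
def species_table():
    return pd.DataFrame(
        {
            "code": ["elo", "myr", "cab", "val"],
            "name": ["waterweed", "milfoil", "fanwort", "eelgrass"],
            "origin": ["native", "non_native", "non_native", "native"],
            "growth_form": ["submerged", "submerged", "submerged", "submerged"],
        }
    )


@pytest.fixture
def unit_table():
    return pd.DataFrame(
        {
            "unit_id": ["A", "B", "C"],
            "x": [50.0, 150.0, 250.0],
            "y": [50.0, 50.0, 50.0],
            "zone": ["river", "river", "harbor"],
            "mean_depth": [1.0, 3.0, 6.0],
            "max_depth": [2.0, 4.0, 8.0],
        }
    )


def matrix_from_frequencies(freqs, m, species_meta=None, rng=None):
    """Incidence matrix with the given per-species frequencies over m units.

    Species j occupies a deterministic (or seeded-random) subset of s_j
    units, so tallies reproduce the requested marginals exactly.
    """
    freqs = list(freqs)
    s = len(freqs)
    codes = [f"sp{j:03d}" for j in range(s)]
    pres = np.zeros((m, s), dtype=bool)
    for j, f in enumerate(freqs):
        if rng is None:
            idx = [(j + k) % m for k in range(f)]
        else:
            idx = rng.choice(m, size=f, replace=False)
        pres[idx, j] = True
    presence = pd.DataFrame(
        pres, index=pd.Index([f"u{i:03d}" for i in range(m)], name="unit_id"),
        columns=codes,
    )
    if species_meta is None:
        species_meta = pd.DataFrame(
            {"name": codes, "origin": "native", "growth_form": "submerged"},
            index=pd.Index(codes, name="code"),
        )
    return IncidenceMatrix(presence, species_meta)


@pytest.fixture
def matrix_factory():
    return matrix_from_frequencies


@pytest.fixture
def random_matrix():
    def make(m=12, s=8, p=0.3, seed=0):
        rng = np.random.default_rng(seed)
        freqs = rng.binomial(m, p, size=s)
        return matrix_from_frequencies(freqs, m, rng=rng)

    return make


def counts_from_q(m, sobs, q1, q2, incidences=None):
    return IncidenceCounts.from_q(m, sobs, q1, q2, incidences=incidences)
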