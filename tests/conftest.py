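import numpy as np
import pandas as pd
import pytest

from mts.core_io import CommunitySurvey, SOIL_VARS


def make_survey(abundance: dict, meta: dict | None = None) -> CommunitySurvey:
    """Build a survey from {sample: row} dicts, filling default metadata."""
    ab = pd.DataFrame.from_dict(abundance, orient="index")
    ab = ab.div(ab.sum(axis=1), axis=0)
    samples = list(ab.index)
    base = {
        "site_id": [f"site{i}" for i in range(len(samples))],
        "system": ["OF"] * len(samples),
        "latitude": np.linspace(25, 40, len(samples)),
        "longitude": np.linspace(105, 120, len(samples)),
    }
    for var in SOIL_VARS:
        base[var] = np.linspace(5, 10, len(samples))
    frame = pd.DataFrame(base, index=samples)
    if meta:
        for key, values in meta.items():
            frame[key] = values
    return CommunitySurvey(ab, frame)


def random_sparse_survey(
    n_samples: int, n_taxa: int, seed: int, depth: int = 500
) -> CommunitySurvey:
    """Random sparse relative-abundance survey for oracle comparisons."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(n_taxa, 0.3), size=n_samples)
    counts = np.vstack([rng.multinomial(depth, row) for row in p])
    counts[counts.sum(axis=1) == 0, 0] = 1
    ab = {f"s{i}": counts[i] for i in range(n_samples)}
    return make_survey(ab)


@pytest.fixture
def paired_survey():
    """Six-sample survey with three resolvable OF/GH pairs."""
    rng = np.random.default_rng(42)
    abundance = {f"s{i}": rng.dirichlet(np.ones(8) * 2) for i in range(6)}
    return make_survey(
        abundance,
        meta={
            "site_id": ["a", "a", "b", "b", "c", "c"],
            "system": ["OF", "GH", "OF", "GH", "OF", "GH"],
        },
    )
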