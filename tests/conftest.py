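import numpy as np
import pytest

from clonalpop import (FilterConfig, GenotypeMatrix, SampleMeta, SiteMeta,
                       apply_filters, em_fit, simulate_cohort,
                       wild_garlic_preset)


def make_matrix(calls, sample_ids=None, loci=None, **sample_kw):
    """Build a GenotypeMatrix from a plain nested list of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    samples = [SampleMeta(sid, **sample_kw.get(sid, {})) for sid in sample_ids]
    if loci is None:
        sites = [SiteMeta(f"loc{j + 1}", 1, "A", "C") for j in range(m)]
    else:
        sites = [SiteMeta(lid, pos, "A", "C") for lid, pos in loci]
    return GenotypeMatrix(samples, sites, calls)


@pytest.fixture
def small_matrix():
    return make_matrix(
        [
            [0, 1, 2, 1, 0, -1],
            [1, 1, 0, 2, 0, 1],
            [2, 0, 0, 2, -1, 1],
            [0, 2, 1, 1, 0, 0],
        ]
    )


@pytest.fixture(scope="session")
def garlic_cohort():
    """Filtered wild-garlic preset cohort with truth tables (shared, ~10 s)."""
    matrix, truth = simulate_cohort(wild_garlic_preset(seed=1))
    matrix, _ = apply_filters(matrix, FilterConfig())
    return matrix, truth


@pytest.fixture(scope="session")
def garlic_fit_k3(garlic_cohort):
    """K=3 admixture fit of the shared cohort (expensive; fitted once)."""
    matrix, _ = garlic_cohort
    return em_fit(matrix, 3, n_starts=4, seed=1)
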