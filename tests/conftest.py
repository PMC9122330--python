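import warnings

import numpy as np
import pytest

from cgfdist import synthetic as syn

# mixed-model boundary warnings are routine on tiny synthetic worlds
warnings.filterwarnings("ignore", message=".*boundary of the parameter space.*")


@pytest.fixture(scope="session")
def small_hierarchy():
    return syn.make_hierarchy(2, 2, 3, seed=0)


@pytest.fixture(scope="session")
def small_truth(small_hierarchy):
    return syn.simulate_truth(
        small_hierarchy, range(1990, 2021), seed=1, age_groups=("6-11m", "12-23m")
    )


@pytest.fixture(scope="session")
def small_world(small_hierarchy, small_truth):
    """Hierarchy, truth, covariates and mixed survey sources."""
    covs = syn.simulate_covariates(small_truth, small_hierarchy, seed=2)
    rng = np.random.default_rng(3)
    sources = []
    for i, c in enumerate(small_hierarchy.countries):
        for y in range(1990, 2021):
            cells = [
                (c, y, a, s) for a in ("6-11m", "12-23m") for s in syn.SEXES
            ]
            if (y + i) % 4 == 0:
                sources.append(
                    syn.simulate_microdata(
                        small_truth, cells, 500, seed=int(rng.integers(2**31))
                    )
                )
            if (y + i) % 4 == 2:
                sources.append(
                    syn.simulate_tabulated(
                        small_truth, cells, 1500, seed=int(rng.integers(2**31))
                    )
                )
    return small_hierarchy, small_truth, covs, sources


@pytest.fixture(scope="session")
def end_to_end_result():
    """Full-pipeline truth recovery on the ten-country world (shared)."""
    from cgfdist import studies

    return studies.end_to_end_study(seed=1, n_draws=100)
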