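import numpy as np
import pytest

import maltopt as m
from maltopt.desirability import _evaluate


@pytest.fixture(scope="session")
def study():
    return m.builtin_study()


@pytest.fixture(scope="session")
def study_specs(study):
    return m.specs_from_table(study)


@pytest.fixture(scope="session")
def published_fitness(study, study_specs):
    """Vectorized overall-desirability fitness from the published surfaces."""

    def fitness(points):
        return _evaluate(m.PUBLISHED_MODELS, study_specs, np.atleast_2d(points))[2]

    return fitness


@pytest.fixture(scope="session")
def dense_grid_max(published_fitness):
    """Continuous-maximum oracle: exhaustive 0.01-coded-step search,
    chunked to keep memory flat."""
    ax = np.arange(-1.0, 1.0 + 1e-12, 0.01)
    yz = np.array(np.meshgrid(ax, ax, indexing="ij")).reshape(2, -1).T
    best = -np.inf
    for x in ax:
        pts = np.column_stack([np.full(len(yz), x), yz])
        best = max(best, float(published_fitness(pts).max()))
    return best
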