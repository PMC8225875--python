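import numpy as np
import pytest

import halfsib as h

# printed variance components of the two mock half-sib data sets
VC200 = dict(family=14170.0, family_x_year=2222.0, family_x_season=13406.0,
             family_x_location=38511.0, residual=221768.0)
VC1000 = dict(family=22345.0, family_x_year=4102.0, family_x_season=12942.0,
              family_x_location=58532.0, residual=159453.0)
MEAN200 = 3262.0
MEAN1000 = 3301.0


@pytest.fixture(scope="session")
def vc200():
    return h.VarianceComponents(**VC200)


@pytest.fixture(scope="session")
def vc1000():
    return h.VarianceComponents(**VC1000)


@pytest.fixture(scope="session")
def design200():
    return h.TrialDesign(n_locations=2, n_seasons=3, n_years=2, n_reps=3,
                         n_families=200)


@pytest.fixture(scope="session")
def design1000():
    return h.TrialDesign(n_locations=2, n_seasons=3, n_years=2, n_reps=3,
                         n_families=1000)


@pytest.fixture(scope="session")
def small_genome():
    """Reduced genome for fast unit tests: 3 linkage groups, 150 markers."""
    return h.make_genome(n_linkage_groups=3, n_markers=150, n_qtl=40,
                         target_additive_variance=400.0, seed=11)


@pytest.fixture(scope="session")
def small_founders(small_genome):
    return h.generate_founders(small_genome, 30, seed=12)
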