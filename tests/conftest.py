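import numpy as np
import pytest

from hccwashout import CohortSpec, EnhancementIndices, generate_cohort
from hccwashout import io as hio
from hccwashout.cohort_stats import ContingencyTable2x2

#: worked-example index vector from a CR lesion (forward-computable profile)
CR_EXAMPLE_INDICES = EnhancementIndices(cer=109.4, llc=56.3, wo_abs=46.5, wo_rel=24.3, dpar=123.2)

#: worked-example index vector from a residual-disease lesion
RESIDUAL_EXAMPLE_INDICES = EnhancementIndices(cer=123.4, llc=17.4, wo_abs=1.7, wo_rel=1.0, dpar=102.9)

#: CR x (DPAR >= 120) counts for the 129-lesion cohort
DPAR_TABLE = ContingencyTable2x2(a=41, b=21, c=23, d=44)

#: extreme strata: two favorable predictors vs none
EXTREME_TABLE = ContingencyTable2x2(a=26, b=7, c=11, d=31)


@pytest.fixture(scope="session")
def cr_example_indices():
    return CR_EXAMPLE_INDICES


@pytest.fixture(scope="session")
def residual_example_indices():
    return RESIDUAL_EXAMPLE_INDICES


@pytest.fixture(scope="session")
def exact_cohort():
    """The 129-lesion exact-counts synthetic cohort at the default seed."""
    return generate_cohort(CohortSpec())


@pytest.fixture(scope="session")
def exact_cohort_indexed(exact_cohort):
    return hio.add_indices(exact_cohort)


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same fresh stream
    return np.random.default_rng(20160101)
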