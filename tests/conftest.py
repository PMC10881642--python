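import logging

import numpy as np
import pytest

from fdgpattern import SyntheticCohortSpec, load_default_atlas, simulate_cohort

# component-matching chatter is expected in leave-one-in tests
logging.getLogger("fdgpattern.expression").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def atlas():
    return load_default_atlas()


@pytest.fixture(scope="session")
def small_cohort(atlas):
    """Down-scaled cohort (all six groups) for fast model/pipeline tests."""
    spec = SyntheticCohortSpec(
        seed=42,
        n_per_group={"HC": 14, "DLB_DATPOS": 26, "DLB_DATNEG": 8, "AD": 8, "PD": 8, "MSA": 8},
    )
    return simulate_cohort(spec, atlas)


@pytest.fixture(scope="session")
def default_cohort(atlas):
    """Reference-sized cohort (HC 23, DaT(+) 86, DaT(-) 22, AD 49, PD 33, MSA 19)."""
    return simulate_cohort(SyntheticCohortSpec(seed=0), atlas)


@pytest.fixture(scope="session")
def factor_cohort(atlas):
    """Training cohort drawn from a clean 4-factor covariance world.

    Each region loads on one of four factors (simple structure), so the
    varimax solution and component identity are sharply determined —
    the right setting for component-stability contracts.
    """
    rng = np.random.default_rng(7)
    B = 0.02 * rng.normal(0, 1, (77, 4))
    for i in range(77):
        B[i, i % 4] += 1.0 + 0.2 * rng.normal()
    cov = 0.004 * B @ B.T + np.eye(77) * 0.0008
    spec = SyntheticCohortSpec(
        seed=11,
        base_cov=cov,
        cov_boost={},
        n_per_group={"HC": 28, "DLB_DATPOS": 82, "DLB_DATNEG": 10, "AD": 0, "PD": 0, "MSA": 0},
    )
    return simulate_cohort(spec, atlas)
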