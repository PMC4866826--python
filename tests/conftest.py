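"""Shared fixtures and the independent brute-force oracle.

The oracle enumerates all 2^4 x 2^4 = 256 site-labeled microstates of the
tetramer directly (each Na+ site and each Gbg site independently empty or
occupied) and never touches the package's closed-form 25-macrostate
evaluation, so agreement between the two is a genuine cross-check.
"""

from itertools import product

import numpy as np
import pytest

from girkgate.model import GatingParams, REFERENCE_FIT


def microstate_partition_and_activity(
    params: GatingParams, na: float, m: float
) -> tuple[float, float]:
    """(Z, activity) by direct enumeration of 256 site-labeled microstates.

    Per microstate: a factor (na/Kdn) per occupied Na+ site, (m/Kdb) per
    occupied Gbg site, 1/n per occupied Na+-site pair, 1/b per occupied
    Gbg-site pair and 1/eta per occupied Na+-site/Gbg-site pair.  The
    activity of a microstate with occupancies (i, j) is 0 unless j = 4,
    else theta04 + i*(theta44-theta04)/4.
    """
    Z = 0.0
    num = 0.0
    for na_sites in product((0, 1), repeat=4):
        for gbg_sites in product((0, 1), repeat=4):
            i = sum(na_sites)
            j = sum(gbg_sites)
            w = (
                (na / params.kdn) ** i
                * (m / params.kdb) ** j
                * params.n_na ** (-(i * (i - 1) // 2))
                * params.b ** (-(j * (j - 1) // 2))
                * params.eta ** (-(i * j))
            )
            Z += w
            if j == 4:
                num += w * (params.theta04 + i * (params.theta44 - params.theta04) / 4)
    return Z, num / Z


@pytest.fixture(scope="session")
def ref_params() -> GatingParams:
    return REFERENCE_FIT


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
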