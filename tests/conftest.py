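import warnings

import numpy as np
import pytest

from dpgwas.tables import GenotypeTable, SmallCohortWarning


@pytest.fixture(autouse=True)
def _quiet_small_cohorts():
    """Tests build many tiny tables on purpose; silence the N<100 advisory."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallCohortWarning)
        yield


def random_genotype_tables(rng: np.random.Generator, n: int, N: int):
    """Rejection-sample n valid genotype tables with N individuals."""
    half = N // 2
    out = []
    while len(out) < n:
        probs = rng.dirichlet(np.ones(3))
        case = rng.multinomial(half, probs)
        ctrl = rng.multinomial(half, probs)
        m, nn = case[0] + ctrl[0], case[1] + ctrl[1]
        if m == 0 or nn == 0 or m + nn >= N:
            continue
        out.append(GenotypeTable(a=int(case[0]), b=int(case[1]),
                                 m=int(m), n=int(nn), N=N))
    return out
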