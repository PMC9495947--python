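import numpy as np
import pytest

from refugesim.genetics import GENOTYPES, SPECIES
from refugesim.payoffs import (
    INTRA_ONLY,
    INTRA_PLUS_INTER,
    PayoffEntry,
    PayoffMatrix,
    StrainKey,
)


def uniform_matrix(rho: float, crop: str = "cotton", mode: str = INTRA_PLUS_INTER) -> PayoffMatrix:
    """Payoff matrix with every entry equal: neutral competition."""
    entries = {}
    strains = [StrainKey(sp, g) for sp in SPECIES for g in GENOTYPES]
    for f in strains:
        for o in strains:
            if mode == INTRA_ONLY and f.species is not o.species:
                continue
            entries[(f, o)] = PayoffEntry(rho, "override")
    return PayoffMatrix(crop, mode, entries)


@pytest.fixture
def rng():
    return np.random.default_rng(20220915)
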