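import warnings

import numpy as np
import pytest

from reentrant_scope import synthetic as syn
from reentrant_scope.types import Contact, ContactMap


@pytest.fixture(autouse=True)
def _quiet_top_n_warnings():
    # select_top legitimately warns when a map holds fewer contacts than
    # requested; the synthetic maps frequently do and the tests assert on
    # behaviour, not on this warning.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="requested top")
        yield


@pytest.fixture(scope="session")
def deda():
    """Two inverted amphipathic + hairpin + TM units, moderate map noise."""
    return syn.build_protein(syn.deda_like_spec(seed=11))


@pytest.fixture(scope="session")
def bundle():
    """Irregular 4-TM bundle, noise-free map: the negative control."""
    return syn.build_protein(syn.tm_bundle_spec(seed=7))


@pytest.fixture(scope="session")
def two_domain():
    """Two helical domains joined by a linker centred on residue 60."""
    return syn.build_protein(syn.two_domain_spec(seed=5))


@pytest.fixture(scope="session")
def tandem():
    """Two identical 60-residue units in tandem, clean map."""
    return syn.build_protein(syn.tandem_repeat_spec(seed=3))


def random_contact_map(L: int, n: int, rng: np.random.Generator,
                       min_sep: int = 5) -> ContactMap:
    """Uniform random map: n distinct pairs at separation >= min_sep."""
    pairs = set()
    while len(pairs) < n:
        i = int(rng.integers(1, L - min_sep + 1))
        j = int(rng.integers(i + min_sep, L + 1))
        pairs.add((i, j))
    return ContactMap(
        L, [Contact(i, j, float(rng.uniform(0.0, 1.0))) for i, j in pairs]
    )
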