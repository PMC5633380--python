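import numpy as np
import pytest

from ecckit.core import Molecule, ReferenceGenome
from ecckit.simulate import _random_bases


@pytest.fixture
def rng():
    return np.random.default_rng(20170811)


@pytest.fixture
def random_genome(rng):
    """A 5-kb two-chromosome genome of random sequence."""
    return ReferenceGenome(
        {
            "chrI": _random_bases(rng, 3000, 0.4),
            "chrII": _random_bases(rng, 2000, 0.5),
        }
    )


def rotations_equal(a: Molecule, b: Molecule) -> bool:
    """Rotation-invariant circle equality (test helper only)."""
    return len(a) == len(b) and a.bases in b.bases + b.bases
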