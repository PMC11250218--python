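import numpy as np
import pytest

from burpmine import profilehmm as ph
from burpmine import synthdata as sd


def random_profile(rng: np.random.Generator, M: int,
                   concentration: float = 0.5) -> ph.ProfileHMM:
    """A random but valid profile HMM for property tests."""
    me = rng.dirichlet(np.ones(20) * concentration, size=M)
    ie = rng.dirichlet(np.ones(20), size=M)
    tr = np.zeros((M + 1, 7))
    for k in range(M + 1):
        tr[k, 0:3] = rng.dirichlet(np.ones(3))
        tr[k, 3:5] = rng.dirichlet(np.ones(2))
        tr[k, 5:7] = rng.dirichlet(np.ones(2))
    tr[M] = [1, 0, 0, 1, 0, 1, 0]
    return ph.ProfileHMM("random", me, ie, tr)


def conserved_profile(rng: np.random.Generator, M: int,
                      conservation: float = 0.6) -> ph.ProfileHMM:
    """A profile with a well-separated modal residue per column.

    Each match state emits a designated residue with probability
    ``conservation`` and the rest uniformly — the conservation level
    typical of recognition-sequence alignments, and high enough that
    modal identity is statistically recoverable from modest samples.
    """
    me = np.full((M, 20), (1.0 - conservation) / 19.0)
    modal = rng.integers(0, 20, size=M)
    me[np.arange(M), modal] = conservation
    ie = rng.dirichlet(np.ones(20), size=M)
    tr = np.zeros((M + 1, 7))
    for k in range(M + 1):
        tr[k, 0:3] = rng.dirichlet(np.ones(3))
        tr[k, 3:5] = rng.dirichlet(np.ones(2))
        tr[k, 5:7] = rng.dirichlet(np.ones(2))
    tr[M] = [1, 0, 0, 1, 0, 1, 0]
    return ph.ProfileHMM("conserved", me, ie, tr)


@pytest.fixture(scope="session")
def fixture_hmm():
    """Precursor profile trained on the fixture recognition alignment."""
    return sd.make_fixture_hmm(seed=0)


@pytest.fixture(scope="session")
def mining_bundle():
    """Shared small transcriptome: 5 split, 2 fused, 100 decoys x 2 asm."""
    return sd.make_transcriptome(5, 2, 100, [("Fixturea synthetica", 2)],
                                 seed=0)
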