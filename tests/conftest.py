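import numpy as np
import pytest

from gmycdelim import (
    AlignedSeq,
    Alignment,
    DistanceMatrix,
    distance_matrix,
    paper_like_fixture,
    upgma_tree,
)


@pytest.fixture(scope="session")
def fixture_data():
    """One study-like simulated data set, shared across tests."""
    return paper_like_fixture(seed=11)


@pytest.fixture(scope="session")
def fixture_tree(fixture_data):
    """Ingroup UPGMA tree of the shared fixture."""
    fx = fixture_data
    dm = distance_matrix(fx.alignment)
    keep = [t for t in dm.ids if fx.labels[t] != fx.outgroup]
    idx = [dm.ids.index(t) for t in keep]
    sub = DistanceMatrix(keep, fx_d(dm, idx))
    return upgma_tree(sub, height_separation=1.0 / (8 * fx.alignment.length))


def fx_d(dm, idx):
    return dm.d[np.ix_(idx, idx)]


def seqs(*pairs):
    """Helper: build an Alignment from (id, bases[, species]) tuples."""
    return Alignment(
        [
            AlignedSeq(id=p[0], bases=p[1], species=p[2] if len(p) > 2 else None)
            for p in pairs
        ]
    )


@pytest.fixture
def make_alignment():
    return seqs
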