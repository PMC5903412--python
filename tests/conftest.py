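import numpy as np
import pytest

from covnet import (SynthSpec, centroid_distances, make_parcellation,
                    simulate_cohort)
from covnet.netbuild import CovarianceNetwork


@pytest.fixture(scope="session")
def parc20():
    """Small mirrored parcellation: 10 regions per hemisphere."""
    return make_parcellation(10, rng_seed=11)


@pytest.fixture(scope="session")
def parc60():
    """60-region mirrored parcellation used by the null-model checks."""
    return make_parcellation(30, rng_seed=7)


@pytest.fixture(scope="session")
def dist60(parc60):
    return centroid_distances(parc60)


@pytest.fixture(scope="session")
def two_group_cohort(parc60):
    """Two groups with distinct decay lengths on the 60-region parcellation."""
    spec = SynthSpec(
        n_regions=60,
        n_per_group={"NT": 40, "ADHD": 40},
        decay_length={"NT": 100.0, "ADHD": 50.0},
        sites=("s1", "s2"),
        site_offsets={"s1": 0.05, "s2": -0.05},
        rng_seed=21,
    )
    return simulate_cohort(parc60, spec)


def net_from_adjacency(A, group="g", density=float("nan"), R=None):
    """Wrap a plain 0/1 adjacency matrix as a CovarianceNetwork."""
    A = np.asarray(A, dtype=bool)
    iu, ju = np.triu_indices(len(A), k=1)
    mask = A[iu, ju]
    r = (R[iu, ju][mask] if R is not None
         else np.zeros(mask.sum()))
    return CovarianceNetwork(group=group, density=density, A=A,
                             edges=np.column_stack([iu[mask], ju[mask]]),
                             edge_r=r)
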