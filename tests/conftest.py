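import numpy as np
import pytest

from rotamerbh.toys import cached_rotamer_chain, toy_library


@pytest.fixture(scope="session")
def chain4():
    """The benchmark rotamer chain: 4 residues, 3 wells, system seed 7."""
    return cached_rotamer_chain(4, 3, 7)


@pytest.fixture(scope="session")
def chain4_library(chain4):
    return toy_library(chain4)


@pytest.fixture(scope="session")
def chain2():
    """A small chain for cheap move/driver tests."""
    return cached_rotamer_chain(2, 3, 3)


@pytest.fixture(scope="session")
def chain2_library(chain2):
    return toy_library(chain2)


def brute_force_average_linkage(dist_matrix: np.ndarray, cutoff: float):
    """Independent naive average-linkage oracle.

    Clusters are leaf sets; the inter-cluster distance is recomputed from the
    original leaf distance matrix at every merge (no Lance-Williams update).
    Merging continues while the smallest average distance is below the
    cutoff; returns frozensets of leaves.
    """
    m = dist_matrix.shape[0]
    clusters = [frozenset([i]) for i in range(m)]
    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean(
                        [dist_matrix[i, j] for i in clusters[a] for j in clusters[b]]
                    )
                )
                if d < best_d - 1e-12:
                    best_d = d
                    best = (a, b)
        if best_d >= cutoff:
            break
        a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return set(clusters)


def labels_to_partition(labels):
    part = {}
    for leaf, lab in enumerate(labels):
        part.setdefault(lab, set()).add(leaf)
    return {frozenset(s) for s in part.values()}
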