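import numpy as np
import pandas as pd
import pytest

from nanodisp import corpus
from nanodisp.graph import MolecularGraph


@pytest.fixture(scope="session")
def records():
    return corpus.load_packaged_solvents()


@pytest.fixture(scope="session")
def matrix():
    return corpus.load_packaged_descriptor_matrix()


@pytest.fixture(scope="session")
def frame():
    """Descriptors + LogC + split, indexed by compound id."""
    return corpus.study_frame()


@pytest.fixture(scope="session")
def train_frame(frame):
    return frame[frame.split == "train"]


@pytest.fixture(scope="session")
def test_frame(frame):
    return frame[frame.split == "test"]


@pytest.fixture(scope="session")
def graphs(records):
    return {r.id: MolecularGraph.from_smiles(r.smiles) for r in records}


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the descriptor implementations
# ---------------------------------------------------------------------------


def count_closed_walks(adjacency: np.ndarray, k: int) -> int:
    """Exhaustive DFS enumeration of closed walks of length k."""
    n = adjacency.shape[0]
    total = 0

    def walk(start, current, remaining):
        nonlocal total
        if remaining == 0:
            if current == start:
                total += 1
            return
        for nxt in range(n):
            if adjacency[current, nxt]:
                walk(start, nxt, remaining - 1)

    for start in range(n):
        walk(start, start, k)
    return total


def enumerate_weighted_paths(graph: MolecularGraph, k: int) -> float:
    """Exhaustive simple-path enumeration with bond-order products.

    Counts ordered paths from every start and halves the total, a different
    counting strategy from the implementation's endpoint ordering.
    """
    total = 0.0

    def extend(path, weight):
        nonlocal total
        if len(path) == k + 1:
            total += weight
            return
        for nxt in graph.neighbors(path[-1]):
            if nxt not in path:
                extend(path + [int(nxt)], weight * graph.bond_order(path[-1], int(nxt)))

    for start in range(graph.n_atoms):
        extend([start], 1.0)
    return total / 2.0


def loo_refit_press(X: np.ndarray, y: np.ndarray) -> float:
    """PRESS by explicitly refitting with each observation left out."""
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        design = np.column_stack([X[keep], np.ones(n - 1)])
        beta, *_ = np.linalg.lstsq(design, y[keep], rcond=None)
        pred = np.concatenate([X[i], [1.0]]) @ beta
        press += (y[i] - pred) ** 2
    return press
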