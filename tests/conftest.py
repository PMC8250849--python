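import random

import dendropy
import numpy as np
import pytest

from astomecoev.reconcile import Tanglegram
from astomecoev.seqio import DistanceMatrix, MultipleAlignment


def tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def host_cherry():
    return tree("(a:1,b:1);")


@pytest.fixture
def host_three():
    return tree("((a:1,b:1):1,c:2);")


@pytest.fixture
def perfect_cherry_tanglegram(host_cherry):
    return Tanglegram(host=host_cherry, symbiont=tree("(x:1,y:1);"),
                      links={"x": {"a"}, "y": {"b"}})


@pytest.fixture
def perfect_three_tanglegram(host_three):
    return Tanglegram(host=host_three, symbiont=tree("((x:1,y:1):1,z:2);"),
                      links={"x": {"a"}, "y": {"b"}, "z": {"c"}})


def random_alignment(rng: random.Random, n_seqs: int, n_sites: int,
                     alphabet: str = "ACGT-N") -> MultipleAlignment:
    ids = [f"t{i}" for i in range(n_seqs)]
    rows = ["".join(rng.choice(alphabet) for _ in range(n_sites))
            for _ in range(n_seqs)]
    return MultipleAlignment(ids=ids, rows=rows)


def random_symmetric_distances(rng: np.random.Generator, labels,
                               scale: float = 1.0) -> DistanceMatrix:
    n = len(labels)
    d = rng.random((n, n)) * scale
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(labels), values=d)
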