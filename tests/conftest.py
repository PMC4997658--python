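"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's pruning/DP code paths: they
enumerate internal-node assignments (and ambiguous tip resolutions)
explicitly, so they are slow but unarguably correct on small trees.
"""

from itertools import product

import numpy as np
import pytest

from osteoasr.matrix_io import CharacterMatrix
from osteoasr.mk_likelihood import transition_matrix
from osteoasr.trees import Tree


@pytest.fixture
def rng():
    return np.random.default_rng(20160824)


def single_char_matrix(states: dict, k: int = 2) -> CharacterMatrix:
    """Matrix with one character; states maps taxon -> code/set/None."""
    taxa = sorted(states)
    rows = []
    for t in taxa:
        s = states[t]
        if s is None:
            rows.append([None])
        elif isinstance(s, int):
            rows.append([frozenset({s})])
        else:
            rows.append([frozenset(s)])
    return CharacterMatrix(
        taxa=taxa, states=rows, k=[k],
        character_labels=["c1"], partition_of=["p1"],
    )


def brute_likelihood(tree: Tree, states: dict, k: int, rates=None) -> float:
    """Exhaustive sum over internal assignments, tip resolutions and
    gamma categories (equal weights)."""
    rates = np.ones(1) if rates is None else np.asarray(rates)
    internals = [n for n in tree.postorder() if not n.is_tip]
    tips = tree.tips()
    tip_opts = []
    for t in tips:
        s = states[t.label]
        if s is None:
            tip_opts.append(list(range(k)))
        elif isinstance(s, int):
            tip_opts.append([s])
        else:
            tip_opts.append(sorted(s))
    total = 0.0
    for r in rates:
        P = {
            n: transition_matrix(k, n.length * r)
            for n in tree.postorder() if n.parent is not None
        }
        for assign in product(range(k), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            for tipstates in product(*tip_opts):
                a = dict(amap)
                a.update(dict(zip(tips, tipstates)))
                p = 1.0 / k
                for n in tree.postorder():
                    if n.parent is not None:
                        p *= P[n][a[n.parent], a[n]]
                total += p / len(rates)
    return total


def brute_marginal(tree: Tree, states: dict, k: int, node, rates=None) -> np.ndarray:
    """Exhaustive marginal posterior of the state at one internal node."""
    rates = np.ones(1) if rates is None else np.asarray(rates)
    internals = [n for n in tree.postorder() if not n.is_tip]
    tips = tree.tips()
    tip_opts = []
    for t in tips:
        s = states[t.label]
        if s is None:
            tip_opts.append(list(range(k)))
        elif isinstance(s, int):
            tip_opts.append([s])
        else:
            tip_opts.append(sorted(s))
    post = np.zeros(k)
    total = 0.0
    for r in rates:
        P = {
            n: transition_matrix(k, n.length * r)
            for n in tree.postorder() if n.parent is not None
        }
        for assign in product(range(k), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            for tipstates in product(*tip_opts):
                a = dict(amap)
                a.update(dict(zip(tips, tipstates)))
                p = 1.0 / k
                for n in tree.postorder():
                    if n.parent is not None:
                        p *= P[n][a[n.parent], a[n]]
                total += p / len(rates)
                post[a[node]] += p / len(rates)
    return post / total


def brute_parsimony_cost(tree: Tree, states: dict, costs, k: int,
                         root_state=None) -> float:
    """Minimum total transformation cost by exhaustive assignment."""
    internals = [n for n in tree.postorder() if not n.is_tip]
    tips = tree.tips()
    tip_opts = []
    for t in tips:
        s = states.get(t.label)
        if s is None:
            tip_opts.append(list(range(k)))
        elif isinstance(s, int):
            tip_opts.append([s])
        else:
            tip_opts.append(sorted(s))
    best = float("inf")
    for assign in product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        if root_state is not None and amap.get(tree.root, root_state) != root_state:
            continue
        for tipstates in product(*tip_opts):
            a = dict(amap)
            a.update(dict(zip(tips, tipstates)))
            c = 0.0
            for n in tree.postorder():
                if n.parent is not None:
                    c += costs[a[n.parent]][a[n]]
            best = min(best, c)
    return best


def random_tip_states(tree: Tree, k: int, rng, p_missing=0.15, p_set=0.15) -> dict:
    out = {}
    for lab in tree.tip_labels():
        u = rng.random()
        if u < p_missing:
            out[lab] = None
        elif u < p_missing + p_set and k >= 2:
            size = int(rng.integers(2, k + 1))
            out[lab] = frozenset(int(x) for x in rng.choice(k, size=size, replace=False))
        else:
            out[lab] = int(rng.integers(0, k))
    return out
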