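"""Shared fixtures and the brute-force parsimony oracle.

The oracle scores a character on a tree by exhaustive enumeration of all
internal-node state assignments (with per-leaf minimization over
polymorphic/missing state sets), independent of the package's dynamic
programming — it is deliberately slow and simple.
"""

import itertools

import numpy as np
import pytest

from sphaerexo import CharacterMatrix, PhyloTree, parse_newick, simulate_tree


def brute_force_steps(tree: PhyloTree, column: dict, ordered: bool) -> int:
    """Minimum steps over all internal assignments (exhaustive)."""
    post = tree.postorder()
    internals = [n for n in post if not n.is_leaf]
    states = set()
    for v in column.values():
        if v is None:
            continue
        states |= set(v) if isinstance(v, (set, frozenset)) else {v}
    k = max(states) + 1 if states else 1
    best = None
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        total = 0
        for n in post:
            if n.parent is None:
                continue
            pval = amap[n.parent]
            if n.is_leaf:
                cell = column[n.label]
                if cell is None:
                    cost = 0
                else:
                    cs = set(cell) if isinstance(cell, (set, frozenset)) else {cell}
                    cost = min(
                        (abs(s - pval) if ordered else int(s != pval)) for s in cs
                    )
            else:
                cost = abs(amap[n] - pval) if ordered else int(amap[n] != pval)
            total += cost
        if best is None or total < best:
            best = total
    return best


def random_column(tree: PhyloTree, rng: np.random.Generator, n_states: int = 3) -> dict:
    """Random character column with missing and polymorphic cells."""
    col = {}
    for name in tree.leaf_names():
        r = rng.random()
        if r < 0.1:
            col[name] = None
        elif r < 0.2:
            col[name] = frozenset(
                rng.choice(n_states, size=2, replace=False).tolist()
            )
        else:
            col[name] = int(rng.integers(n_states))
    return col


def balanced_newick(names):
    if len(names) == 1:
        return names[0]
    h = len(names) // 2
    return f"({balanced_newick(names[:h])},{balanced_newick(names[h:])})"


@pytest.fixture
def quartet():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def small_matrix():
    return CharacterMatrix(
        ["A", "B", "C", "D"],
        [[0, 0], [0, 0], [1, 1], [1, 0]],
    )


@pytest.fixture
def clean_matrix_and_tree():
    """Homoplasy-free matrix: one binary character per clade of the tree."""
    tree = simulate_tree(8, 42)
    names = sorted(tree.leaf_names())
    from sphaerexo import tree_splits

    splits = sorted(tree_splits(tree), key=sorted)
    cells = {t: [1 if t in s else 0 for s in splits] for t in names}
    matrix = CharacterMatrix(names, [cells[t] for t in names])
    return matrix, tree
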