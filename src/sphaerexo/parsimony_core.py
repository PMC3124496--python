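"""Trees, Newick I/O and maximum-parsimony machinery.

Parsimony scoring is implemented once, as a generalized (Sankoff) dynamic
program over small state spaces, which is exact on arbitrary trees —
including the hard polytomies that strict consensus trees carry — for both
unordered (Fitch) and ordered / linear-scale (Wagner) characters.  Missing
cells contribute the full state set; polymorphic cells contribute the
listed set (uncertainty semantics: any member state may be realized).

On top of the scorer sit the ensemble fit indices (CI, RI), the
most-parsimonious-reconstruction (MPR) state sets used for ancestral
character mapping, and bipartition-based strict consensus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import dendropy

from .matrix_io import CharacterMatrix

__all__ = [
    "TreeNode",
    "PhyloTree",
    "TreeScore",
    "OptimizationReport",
    "parse_newick",
    "write_newick",
    "fitch_steps",
    "wagner_steps",
    "steps_on_polytomous_tree",
    "tree_length",
    "consistency_index",
    "retention_index",
    "optimize_states",
    "strict_consensus",
    "tree_splits",
    "same_topology",
    "reroot_on_leaf",
    "robinson_foulds",
]

_INF = np.inf


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------


class TreeNode:
    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode | None" = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.label!r} deg={len(self.children)}>"


class PhyloTree:
    """Rooted-representation phylogenetic tree; polytomies permitted.

    ``rooted=False`` marks the root as an arbitrary anchoring (the tree is
    interpreted as unrooted for scoring and topological comparison, which
    are rooting-invariant anyway).
    """

    def __init__(self, root: TreeNode, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be labeled")

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
        return out

    def preorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def is_binary(self) -> bool:
        """True if every internal node is bifurcating (root may be
        trifurcating when the tree is unrooted)."""
        for node in self.internal_nodes():
            deg = len(node.children)
            if node is self.root:
                ok = deg == 2 or (not self.rooted and deg == 3)
            else:
                ok = deg == 2
            if not ok:
                return False
        return True

    def copy(self) -> "PhyloTree":
        def rec(n: TreeNode) -> TreeNode:
            m = TreeNode(n.label)
            for c in n.children:
                m.add(rec(c))
            return m

        return PhyloTree(rec(self.root), rooted=self.rooted)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_leaves={self.n_leaves} rooted={self.rooted}>"


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick string into a :class:`PhyloTree`."""
    if text.count("(") != text.count(")"):
        raise ValueError(
            f"unbalanced parentheses in Newick string "
            f"({text.count('(')} '(' vs {text.count(')')} ')')"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc

    def rec(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label.replace(" ", "_")
        elif dnode.label:
            label = dnode.label.replace(" ", "_")
        node = TreeNode(label)
        for dchild in dnode.child_nodes():
            node.add(rec(dchild))
        return node

    root = rec(dtree.seed_node)
    return PhyloTree(root, rooted=dtree.is_rooted if dtree.is_rooted else False)


def write_newick(tree: PhyloTree) -> str:
    """Serialize with canonical (min-leaf-label) child ordering."""

    def minleaf(n: TreeNode) -> str:
        while n.children:
            n = min(n.children, key=minleaf)
        return n.label

    def rec(n: TreeNode) -> str:
        if n.is_leaf:
            return n.label
        inner = ",".join(rec(c) for c in sorted(n.children, key=minleaf))
        lab = n.label or ""
        return f"({inner}){lab}"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# bipartitions, consensus, rerooting
# ---------------------------------------------------------------------------


def tree_splits(tree: PhyloTree) -> frozenset:
    """Non-trivial bipartitions of the (unrooted) tree.

    Each split is represented by the half not containing the reference
    leaf (the lexicographically smallest label), as a frozenset of names.
    """
    names = sorted(tree.leaf_names())
    ref = names[0]
    full = frozenset(names)
    splits = set()
    below: dict[TreeNode, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset({node.label})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
            side = below[node]
            if ref in side:
                side = full - side
            if 1 < len(side) < len(names) - 1:
                splits.add(side)
    return frozenset(splits)


def same_topology(a: PhyloTree, b: PhyloTree) -> bool:
    """Leaf-labeled isomorphism of the underlying unrooted topologies."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        return False
    return tree_splits(a) == tree_splits(b)


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted Robinson–Foulds distance (symmetric split difference)."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        raise ValueError("trees must share a leaf set")
    sa, sb = tree_splits(a), tree_splits(b)
    return len(sa ^ sb)


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the bipartitions present in every input."""
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    leafsets = {frozenset(t.leaf_names()) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("trees have mismatched leaf sets")
    common = set.intersection(*(set(tree_splits(t)) for t in trees))
    names = sorted(trees[0].leaf_names())
    return _tree_from_clades(names, common)


def _tree_from_clades(names: Sequence[str], clades: Iterable[frozenset]) -> PhyloTree:
    """Build an (unrooted-anchored) tree from a laminar family of clades,
    each a subset of ``names[1:]`` (the reference leaf ``names[0]`` lies
    outside every clade)."""
    ref = names[0]
    ordered = sorted(clades, key=len, reverse=True)
    root = TreeNode()
    node_of: dict[frozenset, TreeNode] = {}
    parent_clade: dict[frozenset, frozenset | None] = {}
    for cl in ordered:
        parent = None
        for cand in ordered:
            if len(cand) > len(cl) and cl < cand:
                if parent is None or len(cand) < len(parent):
                    parent = cand
        parent_clade[cl] = parent
    for cl in ordered:
        node_of[cl] = TreeNode()
    for cl in ordered:
        p = parent_clade[cl]
        (node_of[p] if p is not None else root).add(node_of[cl])
    for leaf in names:
        if leaf == ref:
            root.add(TreeNode(leaf))
            continue
        best = None
        for cl in ordered:
            if leaf in cl and (best is None or len(cl) < len(best)):
                best = cl
        (node_of[best] if best is not None else root).add(TreeNode(leaf))
    return PhyloTree(root, rooted=False)


def reroot_on_leaf(tree: PhyloTree, leaf: str) -> PhyloTree:
    """Reroot (for display) so the named leaf is the root's first child."""
    adj: dict[TreeNode, list[TreeNode]] = {}
    for node in tree.postorder():
        adj.setdefault(node, [])
        for c in node.children:
            adj[node].append(c)
            adj.setdefault(c, []).append(node)
    target = next((n for n in adj if n.is_leaf and n.label == leaf), None)
    if target is None:
        raise KeyError(f"leaf {leaf!r} not in tree")

    def build(node: TreeNode, came_from: TreeNode | None) -> TreeNode:
        fresh = TreeNode(node.label if node.is_leaf else None)
        for nb in adj[node]:
            if nb is not came_from:
                fresh.add(build(nb, node))
        return fresh

    anchor = adj[target][0]
    root = TreeNode()
    root.add(TreeNode(leaf))
    sub = build(anchor, target)
    if len(sub.children) == 1 and sub.label is None:  # suppress degree-2
        sub = sub.children[0]
    root.add(sub)
    return PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# generalized parsimony scoring (Sankoff DP, exact on any tree)
# ---------------------------------------------------------------------------


def _column_cells(char, leaf_names: Sequence[str]):
    """Normalize a character column (mapping taxon -> state/set/None)."""
    cells = []
    for name in leaf_names:
        try:
            v = char[name]
        except (KeyError, TypeError):
            raise KeyError(f"leaf {name!r} has no data in the character column")
        if v is None:
            cells.append(None)
        elif isinstance(v, (set, frozenset)):
            cells.append(frozenset(int(s) for s in v))
        else:
            cells.append(frozenset({int(v)}))
    return cells


def _cost_matrix(k: int, ordered: bool) -> np.ndarray:
    s = np.arange(k)
    if ordered:
        return np.abs(s[:, None] - s[None, :]).astype(float)
    return (s[:, None] != s[None, :]).astype(float)


def _sankoff_down(tree: PhyloTree, cells_by_char: list, ordered_flags: Sequence[bool]):
    """Down-pass DP.  Returns (postorder nodes, per-node cost arrays, k).

    cost arrays have shape (n_chars, k) where k = max state count over the
    scored characters; characters with fewer states are padded with +inf.
    """
    n_chars = len(cells_by_char)
    ks = [max((max(c) for c in col if c is not None), default=0) + 1 for col in cells_by_char]
    k = max(ks)
    W = np.stack(
        [
            _cost_matrix(k, ordered=ordered_flags[j])
            for j in range(n_chars)
        ]
    )  # (n_chars, k, k)
    post = tree.postorder()
    leaf_idx = {}
    li = 0
    for node in post:
        if node.is_leaf:
            leaf_idx[node] = li
            li += 1
    leaf_names = [n.label for n in post if n.is_leaf]
    cost: dict[TreeNode, np.ndarray] = {}
    for node in post:
        if node.is_leaf:
            arr = np.full((n_chars, k), _INF)
            i = leaf_idx[node]
            for j in range(n_chars):
                cell = cells_by_char[j][i]
                if cell is None:
                    arr[j, : ks[j]] = 0.0
                else:
                    for s in cell:
                        arr[j, s] = 0.0
            cost[node] = arr
        else:
            acc = np.zeros((n_chars, k))
            for c in node.children:
                acc += np.min(cost[c][:, None, :] + W, axis=2)
            # forbid padded states
            for j in range(n_chars):
                acc[j, ks[j]:] = _INF
            cost[node] = acc
    return post, cost, W, ks, leaf_names


def _score_columns(tree: PhyloTree, columns: list, ordered_flags: Sequence[bool]) -> np.ndarray:
    _, cost, _, _, _ = _sankoff_down(tree, columns, ordered_flags)
    root_cost = cost[tree.root]
    return np.min(root_cost, axis=1)


def _matrix_columns(matrix: CharacterMatrix, tree: PhyloTree):
    leaf_names = [n.label for n in tree.postorder() if n.is_leaf]
    missing = set(leaf_names) ^ set(matrix.taxon_names)
    if missing:
        raise ValueError(
            f"leaf set and matrix taxa differ: {sorted(missing)}"
        )
    rows = {t: matrix.row(t) for t in leaf_names}
    return [[rows[t][j] for t in leaf_names] for j in range(matrix.n_chars)]


def _require_binary(tree: PhyloTree, op: str) -> None:
    if not tree.is_binary():
        raise ValueError(
            f"{op} requires a binary tree; use steps_on_polytomous_tree for "
            "trees with polytomies"
        )


def fitch_steps(tree: PhyloTree, char: Mapping, ordered: bool = False) -> int:
    """Minimum number of changes for one unordered character on a binary tree.

    *char* maps leaf label -> state (int), state set, or None for missing.
    """
    _require_binary(tree, "fitch_steps")
    leaf_names = [n.label for n in tree.postorder() if n.is_leaf]
    cells = _column_cells(char, leaf_names)
    val = _score_columns(tree, [cells], [ordered])[0]
    return int(round(val))


def wagner_steps(tree: PhyloTree, char: Mapping, ordered: bool = True) -> int:
    """Minimum total |state transition| for an ordered character."""
    _require_binary(tree, "wagner_steps")
    leaf_names = [n.label for n in tree.postorder() if n.is_leaf]
    cells = _column_cells(char, leaf_names)
    val = _score_columns(tree, [cells], [ordered])[0]
    return int(round(val))


def steps_on_polytomous_tree(tree: PhyloTree, char: Mapping, ordered: bool = False) -> int:
    """Parsimony steps on an arbitrary tree, polytomies treated as hard.

    Equals :func:`fitch_steps` / :func:`wagner_steps` on binary trees.
    """
    leaf_names = [n.label for n in tree.postorder() if n.is_leaf]
    cells = _column_cells(char, leaf_names)
    val = _score_columns(tree, [cells], [ordered])[0]
    return int(round(val))


# ---------------------------------------------------------------------------
# tree length and ensemble indices
# ---------------------------------------------------------------------------


@dataclass
class TreeScore:
    """Per-character parsimony accounting for one tree.

    length = Σ weight_i · s_i over active characters, with s_i the observed
    steps, m_i the minimum possible on any tree, and g_i the maximum
    (star-tree) steps.
    """

    length: float
    per_char_steps: np.ndarray
    per_char_min: np.ndarray
    per_char_max: np.ndarray
    weights: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        s, m, g = self.per_char_steps, self.per_char_min, self.per_char_max
        if np.any(s < m - 1e-9) or np.any(s > g + 1e-9):
            raise AssertionError("m_i <= s_i <= g_i violated")


def _min_steps(cells, ordered: bool) -> int:
    scored = [c for c in cells if c is not None]
    if not scored:
        return 0
    if ordered:
        hi = max(min(c) for c in scored)
        lo = min(max(c) for c in scored)
        return max(0, hi - lo)
    # smallest set of states hitting every cell, minus one
    universe = sorted(set().union(*scored))
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            cs = set(combo)
            if all(cs & c for c in scored):
                return size - 1
    return len(universe) - 1  # pragma: no cover


def _max_steps(cells, ordered: bool) -> int:
    """Steps on the star tree (worst binary-tree score equals it)."""
    scored = [c for c in cells if c is not None]
    if not scored:
        return 0
    top = max(max(c) for c in scored)
    best = None
    for center in range(top + 1):
        if ordered:
            tot = sum(min(abs(x - center) for x in c) for c in scored)
        else:
            tot = sum(1 for c in scored if center not in c)
        best = tot if best is None else min(best, tot)
    return int(best)


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> TreeScore:
    """Score all active characters of *matrix* on *tree* (hard polytomies)."""
    columns = _matrix_columns(matrix, tree)
    ordered_flags = [cm.ordered for cm in matrix.char_meta]
    steps = _score_columns(tree, columns, ordered_flags)
    mins = np.array(
        [_min_steps(col, cm.ordered) for col, cm in zip(columns, matrix.char_meta)],
        dtype=float,
    )
    maxs = np.array(
        [_max_steps(col, cm.ordered) for col, cm in zip(columns, matrix.char_meta)],
        dtype=float,
    )
    weights = np.array([cm.weight for cm in matrix.char_meta])
    active = np.array([cm.active for cm in matrix.char_meta], dtype=bool)
    length = float(np.sum(weights[active] * steps[active]))
    return TreeScore(length, steps, mins, maxs, weights, active)


def consistency_index(score: TreeScore, restrict: Iterable[int] | None = None) -> float:
    """CI = Σm_i / Σs_i over the (optionally restricted) active characters.

    Pass the parsimony-informative index set to reproduce the
    'excluding uninformative characters' variant.
    """
    mask = score.active.copy()
    if restrict is not None:
        keep = np.zeros_like(mask)
        keep[list(restrict)] = True
        mask &= keep
    w = score.weights[mask]
    s = float(np.sum(w * score.per_char_steps[mask]))
    m = float(np.sum(w * score.per_char_min[mask]))
    if s == 0:
        return 1.0
    return m / s


def retention_index(score: TreeScore) -> float:
    """RI = (Σg − Σs) / (Σg − Σm), excluding characters with g_i = m_i."""
    mask = score.active & (score.per_char_max > score.per_char_min)
    if not np.any(mask):
        raise ValueError("retention index undefined: no character with g > m")
    w = score.weights[mask]
    s = float(np.sum(w * score.per_char_steps[mask]))
    m = float(np.sum(w * score.per_char_min[mask]))
    g = float(np.sum(w * score.per_char_max[mask]))
    return (g - s) / (g - m)


# ---------------------------------------------------------------------------
# ancestral-state optimization (MPR sets)
# ---------------------------------------------------------------------------


@dataclass
class OptimizationReport:
    """Per-node, per-character most-parsimonious state sets.

    ``states[name][j]`` is the union of states node *name* takes across all
    most-parsimonious reconstructions of character *j*; the entry is flagged
    ambiguous iff more than one state appears.  Leaf entries are the observed
    cells (or the full state set when missing).
    """

    node_names: list[str]
    states: dict[str, list[frozenset]]

    def is_ambiguous(self, node: str, char: int) -> bool:
        return len(self.states[node][char]) > 1

    def state_of(self, node: str, char: int) -> frozenset:
        return self.states[node][char]


def _ensure_node_names(tree: PhyloTree) -> None:
    """Label unnamed internal nodes N1, N2, ... in preorder."""
    used = {n.label for n in tree.postorder() if n.label}
    counter = 1
    for node in tree.preorder():
        if node.label is None:
            while f"N{counter}" in used:
                counter += 1
            node.label = f"N{counter}"
            used.add(node.label)


def optimize_states(tree: PhyloTree, matrix: CharacterMatrix) -> OptimizationReport:
    """MPR state sets for every node and character, via down + up passes.

    The reported set for a node is the union over *all* most-parsimonious
    reconstructions; |set| = 1 marks an unambiguous optimization.
    """
    _require_binary(tree, "optimize_states")
    work = tree
    _ensure_node_names(work)
    columns = _matrix_columns(matrix, work)
    ordered_flags = [cm.ordered for cm in matrix.char_meta]
    post, down, W, ks, _ = _sankoff_down(work, columns, ordered_flags)
    n_chars = len(columns)
    k = W.shape[1]
    total = np.min(down[work.root], axis=1)  # (n_chars,)

    up: dict[TreeNode, np.ndarray] = {work.root: np.zeros((n_chars, k))}
    for node in work.preorder():
        if node.is_leaf:
            continue
        # contribution of each child to this node's cost, per parent state
        contribs = {
            c: np.min(down[c][:, None, :] + W, axis=2) for c in node.children
        }
        total_contrib = sum(contribs.values())
        for c in node.children:
            others = total_contrib - contribs[c]
            base = up[node] + others  # (n_chars, k) cost at parent state t
            up[c] = np.min(base[:, :, None] + W, axis=1)

    leaf_order = {n: i for i, n in enumerate(n for n in post if n.is_leaf)}
    states: dict[str, list[frozenset]] = {}
    for node in post:
        full = down[node] + up[node]
        sets = []
        for j in range(n_chars):
            if node.is_leaf:
                cell = columns[j][leaf_order[node]]
                sets.append(
                    frozenset(range(ks[j])) if cell is None else frozenset(cell)
                )
            else:
                mpr = np.nonzero(full[j] <= total[j] + 1e-9)[0]
                sets.append(frozenset(int(s) for s in mpr))
        states[node.label] = sets
    return OptimizationReport([n.label for n in post], states)
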