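"""Maximum-parsimony tree search and clade-support statistics.

The search stack operates on a light unrooted-binary representation
(integer adjacency lists; leaves ``0..n-1`` indexing matrix taxa) and a
vectorized per-matrix encoding.  Tree-bisection-reconnection (TBR)
neighborhoods are scored exactly but cheaply through the two-subtree join
identity: reconnecting component ``A`` (attached along edge *a*) to
component ``B`` (along edge *b*) yields a tree of length

    len(A) + len(B) + join_cost(S_a, S_b)

where ``S_a`` is the parsimony state set (Fitch mask, or Farris interval
for ordered characters) of ``A`` rooted on edge *a*, and the join cost is
one step per character whose sets are incompatible across the new branch.
Both quantities come from a single down/up pass per component, so a full
TBR neighborhood costs O(edges² · characters) vectorized numpy work
instead of one tree traversal per rearrangement.

Strategies: seeded random-addition starts + TBR hill climbing with a
bounded pool of equally parsimonious trees per replicate (the
"traditional search" of morphological practice); exhaustive enumeration
over all (2n−5)!! unrooted binary topologies, which also yields the full
tree-length distribution; and branch-and-bound as an exact fallback for
intermediate taxon counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .matrix_io import CharacterMatrix
from .parsimony_core import PhyloTree, TreeNode, strict_consensus, tree_splits

__all__ = [
    "SearchConfig",
    "SearchResult",
    "double_factorial_topologies",
    "random_addition_tree",
    "tbr_search",
    "exhaustive_search",
    "branch_and_bound_search",
    "search",
    "bootstrap_support",
    "jackknife_support",
    "bremer_support",
]

_EXHAUSTIVE_MAX_TAXA = 12


def double_factorial_topologies(n_leaves: int) -> int:
    """(2n−5)!! — the number of unrooted binary topologies on n leaves."""
    if n_leaves < 3:
        return 1
    out = 1
    for k in range(4, n_leaves + 1):
        out *= 2 * k - 5
    return out


# ---------------------------------------------------------------------------
# configuration / results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchConfig:
    """Replicated-search settings; identical config + matrix → identical
    result set."""

    n_replicates: int = 100
    trees_saved_per_rep: int = 10
    seed: int = 1
    strategy: str = "tbr_heuristic"  # | exhaustive | branch_and_bound

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.trees_saved_per_rep < 1:
            raise ValueError("trees_saved_per_rep must be >= 1")


@dataclass
class SearchResult:
    best_length: float
    mpt_set: list[PhyloTree]
    length_distribution: np.ndarray | None = None
    n_rearrangements: int = 0

    @property
    def n_mpts(self) -> int:
        return len(self.mpt_set)


# ---------------------------------------------------------------------------
# matrix encoding for fast scoring
# ---------------------------------------------------------------------------


class _Encoding:
    """Per-matrix arrays: Fitch bitmasks for unordered characters and
    Farris intervals for ordered ones (active characters only)."""

    def __init__(self, matrix: CharacterMatrix):
        self.n_taxa = matrix.n_taxa
        u_cols, o_cols = [], []
        for j, cm in enumerate(matrix.char_meta):
            if not cm.active:
                continue
            (o_cols if cm.ordered else u_cols).append(j)
        ks = [matrix.max_state(j) + 1 for j in range(matrix.n_chars)]
        nU, nO = len(u_cols), len(o_cols)
        self.umask = np.zeros((self.n_taxa, nU), dtype=np.uint32)
        self.uw = np.array([matrix.char_meta[j].weight for j in u_cols])
        for cj, j in enumerate(u_cols):
            full = (1 << ks[j]) - 1
            for i in range(self.n_taxa):
                cell = matrix.cells[i][j]
                if cell is None:
                    self.umask[i, cj] = full
                else:
                    m = 0
                    for s in cell:
                        m |= 1 << s
                    self.umask[i, cj] = m
        self.olo = np.zeros((self.n_taxa, nO), dtype=np.int64)
        self.ohi = np.zeros((self.n_taxa, nO), dtype=np.int64)
        self.ow = np.array([matrix.char_meta[j].weight for j in o_cols])
        for cj, j in enumerate(o_cols):
            for i in range(self.n_taxa):
                cell = matrix.cells[i][j]
                if cell is None:
                    self.olo[i, cj], self.ohi[i, cj] = 0, ks[j] - 1
                else:
                    self.olo[i, cj], self.ohi[i, cj] = min(cell), max(cell)
        self.nU, self.nO = nU, nO

    def leaf_profile(self, taxon: int):
        return self.umask[taxon], self.olo[taxon], self.ohi[taxon]


def _combine_masks(a: np.ndarray, b: np.ndarray):
    inter = a & b
    empty = inter == 0
    return np.where(empty, a | b, inter), empty


def _combine_intervals(alo, ahi, blo, bhi):
    lo = np.maximum(alo, blo)
    hi = np.minimum(ahi, bhi)
    gap = np.maximum(lo - hi, 0)
    # disjoint intervals collapse to the between-interval
    glo = np.minimum(ahi, bhi)
    ghi = np.maximum(alo, blo)
    bad = lo > hi
    return np.where(bad, glo, lo), np.where(bad, ghi, hi), gap


class _Profiles:
    """Directed-pass summary of one unrooted component: per-edge join
    profiles plus the component's own parsimony length."""

    __slots__ = ("edges", "masks", "los", "his", "length")

    def __init__(self, edges, masks, los, his, length):
        self.edges = edges
        self.masks = masks
        self.los = los
        self.his = his
        self.length = length


def _leaf_profiles(enc: _Encoding, taxon: int) -> _Profiles:
    m, lo, hi = enc.leaf_profile(taxon)
    return _Profiles(
        [None], m[None, :].copy(), lo[None, :].copy(), hi[None, :].copy(), 0.0
    )


def _component_profiles(adj: Mapping[int, list], enc: _Encoding, start: int) -> _Profiles:
    """Down/up passes over the component containing *start* (a leaf)."""
    nodes = list(adj)
    if len(nodes) == 1:
        return _leaf_profiles(enc, start)
    root = start  # a leaf; orient everything toward it
    parent: dict[int, int] = {root: -1}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                order.append(v)
                stack.append(v)
    dmask: dict[int, np.ndarray] = {}
    dlo: dict[int, np.ndarray] = {}
    dhi: dict[int, np.ndarray] = {}
    length = 0.0
    for u in reversed(order):
        kids = [] if u == root else [v for v in adj[u] if v != parent[u]]
        if not kids:
            m, lo, hi = enc.leaf_profile(u)
            dmask[u], dlo[u], dhi[u] = m, lo, hi
        else:
            m, lo, hi = dmask[kids[0]], dlo[kids[0]], dhi[kids[0]]
            for v in kids[1:]:
                m, empty = _combine_masks(m, dmask[v])
                if enc.nU:
                    length += float(enc.uw @ empty)
                lo, hi, gap = _combine_intervals(lo, hi, dlo[v], dhi[v])
                if enc.nO:
                    length += float(enc.ow @ gap)
            dmask[u], dlo[u], dhi[u] = m, lo, hi
    # root is a leaf: account for its pendant edge
    child = [v for v in adj[root] if v != parent[root]][0]
    m, empty = _combine_masks(dmask[root], dmask[child])
    if enc.nU:
        length += float(enc.uw @ empty)
    _, _, gap = _combine_intervals(dlo[root], dhi[root], dlo[child], dhi[child])
    if enc.nO:
        length += float(enc.ow @ gap)
    # up pass: umask[u] = profile of the tree minus subtree(u)
    umask: dict[int, np.ndarray] = {child: dmask[root]}
    ulo: dict[int, np.ndarray] = {child: dlo[root]}
    uhi: dict[int, np.ndarray] = {child: dhi[root]}
    for u in order:
        if u == root or u not in umask:
            continue
        kids = [v for v in adj[u] if v != parent[u]]
        for v in kids:
            m, lo, hi = umask[u], ulo[u], uhi[u]
            for w in kids:
                if w is v:
                    continue
                m, _ = _combine_masks(m, dmask[w])
                lo, hi, _ = _combine_intervals(lo, hi, dlo[w], dhi[w])
            umask[v], ulo[v], uhi[v] = m, lo, hi
    edges = []
    masks, los, his = [], [], []
    for u in order:
        if u == root:
            continue
        p = parent[u]
        m, _ = _combine_masks(dmask[u], umask[u])
        lo, hi, _ = _combine_intervals(dlo[u], dhi[u], ulo[u], uhi[u])
        edges.append((u, p))
        masks.append(m)
        los.append(lo)
        his.append(hi)
    return _Profiles(
        edges, np.stack(masks), np.stack(los), np.stack(his), length
    )


def _join_costs(pa: _Profiles, pb: _Profiles, enc: _Encoding) -> np.ndarray:
    """(len(A-edges), len(B-edges)) matrix of junction costs."""
    cost = np.zeros((pa.masks.shape[0], pb.masks.shape[0]))
    if enc.nU:
        empty = (pa.masks[:, None, :] & pb.masks[None, :, :]) == 0
        cost += empty @ enc.uw
    if enc.nO:
        gap = np.maximum(
            np.maximum(pa.los[:, None, :], pb.los[None, :, :])
            - np.minimum(pa.his[:, None, :], pb.his[None, :, :]),
            0,
        )
        cost += gap @ enc.ow
    return cost


# ---------------------------------------------------------------------------
# unrooted adjacency utilities
# ---------------------------------------------------------------------------


def _three_taxon_adj() -> dict[int, list]:
    # leaves 0,1,2 around a central node; ids >= n_taxa are internal
    return {0: [-1], 1: [-1], 2: [-1], -1: [0, 1, 2]}


def _adj_edges(adj: Mapping[int, list]) -> list[tuple]:
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _insert_leaf(adj: dict[int, list], edge: tuple, leaf: int, new_node: int) -> dict[int, list]:
    u, v = edge
    out = {k: list(vs) for k, vs in adj.items()}
    out[u][out[u].index(v)] = new_node
    out[v][out[v].index(u)] = new_node
    out[new_node] = [u, v, leaf]
    out[leaf] = [new_node]
    return out


def _adj_splits(adj: Mapping[int, list], n_taxa: int) -> frozenset:
    """Canonical nontrivial-split bitmask set (side without leaf 0)."""
    full = (1 << n_taxa) - 1
    start = 0
    parent = {start: None}
    order = [start]
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                order.append(v)
                stack.append(v)
    below: dict[int, int] = {}
    splits = set()
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            below[u] = 1 << u if 0 <= u < n_taxa else 0
        else:
            below[u] = 0
            for v in kids:
                below[u] |= below[v]
        mask = below[u]
        if mask & 1:
            mask ^= full
        nb = mask.bit_count()
        if 1 < nb < n_taxa - 1:
            splits.add(mask)
    return frozenset(splits)


def _adj_to_phylo(adj: Mapping[int, list], taxon_names: Sequence[str]) -> PhyloTree:
    """Anchor the unrooted tree at the internal node next to leaf 0."""
    if len(adj) == 1:  # pragma: no cover - degenerate
        return PhyloTree(TreeNode(taxon_names[0]), rooted=False)
    start = adj[0][0]

    def build(u: int, came: int | None) -> TreeNode:
        if 0 <= u < len(taxon_names) and len(adj[u]) == 1:
            return TreeNode(taxon_names[u])
        node = TreeNode()
        for v in adj[u]:
            if v != came:
                node.add(build(v, u))
        return node

    return PhyloTree(build(start, None), rooted=False)


def _phylo_to_adj(tree: PhyloTree, taxon_names: Sequence[str]) -> dict[int, list]:
    index = {t: i for i, t in enumerate(taxon_names)}
    nxt = [len(taxon_names)]
    adj: dict[int, list] = {}

    def add_edge(a: int, b: int) -> None:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def visit(node: TreeNode) -> int:
        if node.is_leaf:
            return index[node.label]
        me = nxt[0]
        nxt[0] += 1
        adj.setdefault(me, [])
        for c in node.children:
            add_edge(me, visit(c))
        return me

    root_id = visit(tree.root)
    # suppress a degree-2 anchoring root
    if len(adj[root_id]) == 2:
        a, b = adj[root_id]
        adj[a][adj[a].index(root_id)] = b
        adj[b][adj[b].index(root_id)] = a
        del adj[root_id]
    return adj


# ---------------------------------------------------------------------------
# random (greedy Wagner) addition
# ---------------------------------------------------------------------------


def _random_addition(enc: _Encoding, rng: np.random.Generator, order=None):
    n = enc.n_taxa
    if order is None:
        order = rng.permutation(n)
    order = list(order)
    adj: dict[int, list] = {order[0]: [-1], order[1]: [-1], order[2]: [-1], -1: order[:3]}
    # relabel internal ids upward from n
    adj = {(n if k == -1 else k): [(n if x == -1 else x) for x in v] for k, v in adj.items()}
    next_id = n + 1
    length = 0.0
    for leaf in order[3:]:
        prof = _component_profiles(adj, enc, _any_leaf(adj, n))
        lp = _leaf_profiles(enc, leaf)
        costs = _join_costs(prof, lp, enc)[:, 0]
        best = np.min(costs)
        cand = np.nonzero(costs <= best + 1e-9)[0]
        pick = int(cand[rng.integers(len(cand))]) if len(cand) > 1 else int(cand[0])
        adj = _insert_leaf(adj, prof.edges[pick], leaf, next_id)
        next_id += 1
        length = prof.length + float(best)
    return adj, length


def _any_leaf(adj: Mapping[int, list], n_taxa: int) -> int:
    for u in adj:
        if 0 <= u < n_taxa:
            return u
    raise AssertionError("component without a leaf")


def random_addition_tree(matrix: CharacterMatrix, seed: int) -> PhyloTree:
    """Greedy stepwise-addition tree in a seeded random taxon order."""
    if matrix.n_taxa < 3:
        raise ValueError("random addition requires at least 3 taxa")
    enc = _Encoding(matrix)
    rng = np.random.default_rng(seed)
    adj, _ = _random_addition(enc, rng)
    return _adj_to_phylo(adj, matrix.taxon_names)


# ---------------------------------------------------------------------------
# TBR neighborhood
# ---------------------------------------------------------------------------


def _bisect(adj: Mapping[int, list], edge: tuple, n_taxa: int):
    """Split on *edge*; return (component adjacencies, suppressed ids)."""
    u, v = edge

    def side(a: int, b: int) -> dict[int, list]:
        comp = {a: [x for x in adj[a] if x != b]}
        stack = [a]
        while stack:
            x = stack.pop()
            for y in comp[x]:
                if y not in comp:
                    comp[y] = list(adj[y])
                    stack.append(y)
        # suppress the degree-2 cut node
        if len(comp[a]) == 2:
            p, q = comp[a]
            comp[p][comp[p].index(a)] = q
            comp[q][comp[q].index(a)] = p
            del comp[a]
        return comp

    return side(u, v), side(v, u)


def _tbr_neighbor(adjA, edgeA, adjB, edgeB, leafA, leafB, jidA, jidB):
    """Reconnect components along the chosen edges; fresh junction ids."""
    out = {k: list(v) for k, v in adjA.items()}
    for k, v in adjB.items():
        out[k] = list(v)

    def attach(edge, jid):
        if edge is None:  # single-leaf component
            return None
        a, b = edge
        out[a][out[a].index(b)] = jid
        out[b][out[b].index(a)] = jid
        out[jid] = [a, b]
        return jid

    ja = attach(edgeA, jidA)
    jb = attach(edgeB, jidB)
    pa = ja if ja is not None else leafA
    pb = jb if jb is not None else leafB
    out.setdefault(pa, []).append(pb)
    out.setdefault(pb, []).append(pa)
    return out


def _scan_tbr(adj, enc, n_taxa):
    """Evaluate the full TBR neighborhood.

    Returns (best_length, list of (length, builder) for the best moves,
    and a callable-producing structure for equal-length moves).
    """
    edges = _adj_edges(adj)
    max_id = max(adj)
    results = []  # (length, adjA, edgeA, adjB, edgeB, leafA, leafB)
    for edge in edges:
        compA, compB = _bisect(adj, edge, n_taxa)
        leafA = _any_leaf(compA, n_taxa)
        leafB = _any_leaf(compB, n_taxa)
        profA = (
            _leaf_profiles(enc, leafA)
            if len(compA) == 1
            else _component_profiles(compA, enc, leafA)
        )
        profB = (
            _leaf_profiles(enc, leafB)
            if len(compB) == 1
            else _component_profiles(compB, enc, leafB)
        )
        cost = _join_costs(profA, profB, enc) + (profA.length + profB.length)
        results.append((cost, compA, profA.edges, compB, profB.edges, leafA, leafB))
    best = min(float(c.min()) for c, *_ in results)
    return best, results, max_id


def _moves_at_length(results, target, max_id, eps=1e-9):
    for cost, compA, edgesA, compB, edgesB, leafA, leafB in results:
        ia, ib = np.nonzero(cost <= target + eps)
        for a, b in zip(ia, ib):
            yield _tbr_neighbor(
                compA, edgesA[a], compB, edgesB[b], leafA, leafB, max_id + 1, max_id + 2
            )


def tbr_search(matrix: CharacterMatrix, config: SearchConfig) -> SearchResult:
    """Replicated random-addition + TBR hill-climbing search.

    Per replicate the climb accepts the best improving rearrangement until
    none exists, then pools up to ``trees_saved_per_rep`` equally
    parsimonious trees reachable through equal-length rearrangements.
    Replicate pools are merged, deduplicated under leaf-labeled
    isomorphism, and filtered to the globally best length.
    """
    if matrix.n_taxa < 4:
        raise ValueError("tbr_search requires at least 4 taxa")
    enc = _Encoding(matrix)
    n = matrix.n_taxa
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.n_replicates)
    global_best = np.inf
    pool: dict[frozenset, dict] = {}
    n_rearr = 0
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(rep_seeds[rep])
        adj, length = _random_addition(enc, rng)
        # hill climb
        while True:
            best, results, max_id = _scan_tbr(adj, enc, n)
            n_rearr += sum(c.size for c, *_ in results)
            if best < length - 1e-9:
                adj = next(_moves_at_length(results, best, max_id))
                length = best
            else:
                break
        # plateau exploration: collect equal-length trees (bounded)
        rep_pool: dict[frozenset, dict] = {_adj_splits(adj, n): adj}
        frontier = [adj]
        while frontier and len(rep_pool) < config.trees_saved_per_rep:
            cur = frontier.pop()
            best, results, max_id = _scan_tbr(cur, enc, n)
            n_rearr += sum(c.size for c, *_ in results)
            if best < length - 1e-9:  # plateau walk found an improvement
                adj, length = next(_moves_at_length(results, best, max_id)), best
                rep_pool = {_adj_splits(adj, n): adj}
                frontier = [adj]
                continue
            for nb in _moves_at_length(results, length, max_id):
                if len(rep_pool) >= config.trees_saved_per_rep:
                    break
                key = _adj_splits(nb, n)
                if key not in rep_pool:
                    rep_pool[key] = nb
                    frontier.append(nb)
        if length < global_best - 1e-9:
            global_best = length
            pool = {}
        if abs(length - global_best) <= 1e-9:
            for key, a in rep_pool.items():
                pool.setdefault(key, a)
    trees = [_adj_to_phylo(a, matrix.taxon_names) for a in pool.values()]
    return SearchResult(
        float(global_best), trees, length_distribution=None, n_rearrangements=n_rearr
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration and branch and bound
# ---------------------------------------------------------------------------


def _enumerate_lengths(
    enc: _Encoding,
    n: int,
    keep: Callable[[float], bool],
    prune_at: Callable[[], float] | None,
    on_complete: Callable[[dict, float], None],
    lengths_out: list | None,
):
    """Shared recursion: taxa inserted in index order, lengths incremental.

    ``keep`` gates tree construction at the final level (complete-topology
    lengths are always recorded in *lengths_out* when given); ``prune_at``
    bounds the recursion for branch and bound.
    """

    def rec(adj: dict[int, list], next_taxon: int, next_id: int):
        prof = _component_profiles(adj, enc, 0)
        lp = _leaf_profiles(enc, next_taxon)
        costs = _join_costs(prof, lp, enc)[:, 0] + prof.length
        if next_taxon == n - 1:
            if lengths_out is not None:
                lengths_out.append(costs.copy())
            for e, clen in zip(prof.edges, costs):
                if keep(float(clen)):
                    on_complete(_insert_leaf(adj, e, next_taxon, next_id), float(clen))
            return
        bound = prune_at() if prune_at is not None else np.inf
        for e, clen in zip(prof.edges, costs):
            if clen <= bound + 1e-9:
                rec(_insert_leaf(adj, e, next_taxon, next_id), next_taxon + 1, next_id + 1)

    base = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    if n == 3:
        prof = _component_profiles(base, enc, 0)
        on_complete(base, prof.length)
        if lengths_out is not None:
            lengths_out.append(np.array([prof.length]))
        return
    rec(base, 3, n + 1)


def exhaustive_search(matrix: CharacterMatrix) -> SearchResult:
    """Enumerate every unrooted binary topology; exact MPT set plus the
    full tree-length distribution (input to the g1 signal test)."""
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("exhaustive search requires at least 3 taxa")
    if n > _EXHAUSTIVE_MAX_TAXA:
        raise ValueError(
            f"exhaustive search is limited to {_EXHAUSTIVE_MAX_TAXA} taxa "
            f"(got {n}); use tbr_search or branch_and_bound_search"
        )
    enc = _Encoding(matrix)
    lengths: list[np.ndarray] = []
    best = [np.inf]
    kept: list[tuple[dict, float]] = []

    def on_complete(adj: dict, length: float) -> None:
        if length < best[0] - 1e-9:
            best[0] = length
            kept[:] = [(adj, length)]
        elif abs(length - best[0]) <= 1e-9:
            kept.append((adj, length))

    _enumerate_lengths(
        enc, n, lambda l: l <= best[0] + 1e-9, None, on_complete, lengths
    )
    dist = np.concatenate(lengths)
    expected = double_factorial_topologies(n)
    assert dist.size == expected, (dist.size, expected)
    seen: dict[frozenset, dict] = {}
    mpts = []
    for adj, length in kept:
        if abs(length - best[0]) <= 1e-9:
            key = _adj_splits(adj, n)
            if key not in seen:
                seen[key] = adj
                mpts.append(_adj_to_phylo(adj, matrix.taxon_names))
    return SearchResult(float(best[0]), mpts, length_distribution=dist)


def branch_and_bound_search(
    matrix: CharacterMatrix, upper_bound: float | None = None, slack: float = 0.0
) -> SearchResult:
    """Exact search by depth-first enumeration with length pruning.

    Partial-tree length never decreases as taxa are added, so subtrees
    exceeding the running best (+ *slack*) are skipped.  With ``slack > 0``
    every topology within ``best + slack`` is returned (used for Bremer
    support).  The initial bound comes from one greedy addition tree.
    """
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("branch and bound requires at least 3 taxa")
    enc = _Encoding(matrix)
    if upper_bound is None:
        _, upper_bound = _random_addition(enc, np.random.default_rng(0), order=np.arange(n))
    state = {"best": float(upper_bound)}
    kept: list[tuple[dict, float]] = []

    def on_complete(adj: dict, length: float) -> None:
        if length < state["best"] - 1e-9:
            state["best"] = length
        kept.append((adj, length))

    _enumerate_lengths(
        enc,
        n,
        lambda l: l <= state["best"] + slack + 1e-9,
        lambda: state["best"] + slack,
        on_complete,
        None,
    )
    best = min(l for _, l in kept)
    seen: dict[frozenset, tuple[dict, float]] = {}
    for adj, length in kept:
        if length <= best + slack + 1e-9:
            key = _adj_splits(adj, n)
            if key not in seen or length < seen[key][1]:
                seen[key] = (adj, length)
    mpts = [
        _adj_to_phylo(adj, matrix.taxon_names)
        for adj, length in seen.values()
        if abs(length - best) <= 1e-9
    ]
    result = SearchResult(float(best), mpts)
    result.suboptimal_pool = [  # type: ignore[attr-defined]
        (_adj_to_phylo(adj, matrix.taxon_names), length)
        for adj, length in seen.values()
    ]
    return result


def search(matrix: CharacterMatrix, config: SearchConfig) -> SearchResult:
    """Dispatch on ``config.strategy``."""
    if config.strategy == "tbr_heuristic":
        return tbr_search(matrix, config)
    if config.strategy == "exhaustive":
        return exhaustive_search(matrix)
    if config.strategy == "branch_and_bound":
        return branch_and_bound_search(matrix)
    raise ValueError(f"unknown strategy {config.strategy!r}")


# ---------------------------------------------------------------------------
# clade support
# ---------------------------------------------------------------------------


def _named_splits(tree: PhyloTree) -> frozenset:
    return tree_splits(tree)


def _replicate_search(matrix: CharacterMatrix, seed: int, saved: int) -> SearchResult:
    cfg = SearchConfig(n_replicates=1, trees_saved_per_rep=saved, seed=seed)
    return tbr_search(matrix, cfg)


def bootstrap_support(matrix: CharacterMatrix, config: SearchConfig) -> dict:
    """Bipartition → % of character-resampled replicates whose strict
    consensus (of that replicate's MPT set) contains it."""
    rng = np.random.default_rng(config.seed)
    counts: dict[frozenset, int] = {}
    for rep in range(config.n_replicates):
        idx = rng.integers(matrix.n_chars, size=matrix.n_chars)
        sub = matrix.with_characters(list(idx))
        res = _replicate_search(sub, int(rng.integers(2**31 - 1)), config.trees_saved_per_rep)
        cons = strict_consensus(res.mpt_set)
        for split in _named_splits(cons):
            counts[split] = counts.get(split, 0) + 1
    return {s: 100.0 * c / config.n_replicates for s, c in counts.items()}


def jackknife_support(matrix: CharacterMatrix, config: SearchConfig, n_deleted: int) -> dict:
    """As bootstrap, but each replicate deletes exactly *n_deleted*
    characters without replacement."""
    if not 0 < n_deleted < matrix.n_chars:
        raise ValueError("n_deleted must satisfy 0 < n_deleted < n_chars")
    rng = np.random.default_rng(config.seed)
    counts: dict[frozenset, int] = {}
    for rep in range(config.n_replicates):
        idx = rng.permutation(matrix.n_chars)[: matrix.n_chars - n_deleted]
        sub = matrix.with_characters(sorted(int(i) for i in idx))
        res = _replicate_search(sub, int(rng.integers(2**31 - 1)), config.trees_saved_per_rep)
        cons = strict_consensus(res.mpt_set)
        for split in _named_splits(cons):
            counts[split] = counts.get(split, 0) + 1
    return {s: 100.0 * c / config.n_replicates for s, c in counts.items()}


def bremer_support(
    matrix: CharacterMatrix,
    mpt_set: Sequence[PhyloTree],
    max_extra: int = 5,
    config: SearchConfig | None = None,
) -> dict:
    """Decay index per consensus bipartition: the smallest k ≤ max_extra
    such that some tree of length best+k lacks the bipartition; values
    surviving the window are reported as max_extra + 1 (read: > max_extra).

    Suboptimal trees come from branch-and-bound enumeration for small
    matrices and from a TBR sweep retaining near-optimal trees otherwise.
    """
    if not mpt_set:
        raise ValueError("empty MPT set")
    consensus = strict_consensus(list(mpt_set))
    targets = _named_splits(consensus)
    if not targets:
        return {}
    if matrix.n_taxa <= 11:
        res = branch_and_bound_search(matrix, slack=float(max_extra))
        pool = res.suboptimal_pool  # type: ignore[attr-defined]
        best = res.best_length
    else:
        cfg = config or SearchConfig(n_replicates=20, trees_saved_per_rep=50, seed=7)
        res = tbr_search(matrix, cfg)
        best = res.best_length
        pool = [(t, best) for t in res.mpt_set]
        # widen: climb again accepting anything within the window
        enc = _Encoding(matrix)
        n = matrix.n_taxa
        seen = {}
        frontier = [(_phylo_to_adj(t, matrix.taxon_names)) for t in res.mpt_set]
        budget = 4000
        while frontier and budget > 0:
            cur = frontier.pop()
            b, results, max_id = _scan_tbr(cur, enc, n)
            for nb in _moves_at_length(results, best + max_extra, max_id):
                key = _adj_splits(nb, n)
                if key not in seen:
                    prof = _component_profiles(nb, enc, 0)
                    seen[key] = (nb, prof.length)
                    budget -= 1
                    if budget <= 0:
                        break
        pool = pool + [
            (_adj_to_phylo(a, matrix.taxon_names), l) for a, l in seen.values()
        ]
    out: dict[frozenset, int] = {}
    for split in targets:
        k = max_extra + 1
        for tree, length in pool:
            if split not in tree_splits(tree):
                k = min(k, int(round(length - best)))
        out[split] = max(k, 1) if k <= max_extra else max_extra + 1
    return out
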