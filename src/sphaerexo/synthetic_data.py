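"""Ground-truth simulators: matrices, trees and biogeographic scenarios.

Every stage of the pipeline is testable without downloads: discrete
characters evolve on a known tree under a symmetric Mk-style change
process, and clade histories unfold over an area set with *scripted*
vicariance (range-contraction) and geodispersal (range-expansion) events
whose truth log can be compared with what LBPA recovers.  All generators
are pure functions of their seed.

The demo scenario mirrors the study conditions of the empirical system
this package was built around: 31 trilobite taxa scored for 39 characters
with at most three states, distributed over 7 Ordovician–Silurian
paleogeographic areas rooted on an all-zero hypothetical ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix_io import (
    AREA_CODES,
    AreaAssignment,
    CharacterMatrix,
    CharMeta,
    read_area_assignment,
    read_matrix,
)
from .lbpa import BiogeoMatrix
from .parsimony_core import PhyloTree, TreeNode, _ensure_node_names

__all__ = [
    "SimScenario",
    "BiogeoEvent",
    "BiogeoScenario",
    "BiogeoSim",
    "simulate_tree",
    "simulate_matrix",
    "simulate_biogeography",
    "random_matrix",
    "demo_scenario",
    "load_paper_fixtures",
]


# ---------------------------------------------------------------------------
# character evolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimScenario:
    """Mk-style simulation settings: *change_rate* is the expected number
    of state changes per character per branch."""

    true_tree: PhyloTree
    n_chars: int
    n_states: int = 3
    change_rate: float = 0.1
    seed: int = 0


def simulate_tree(n_taxa: int, seed: int, prefix: str = "T") -> PhyloTree:
    """Uniform random unrooted binary labeled topology.

    Built by inserting each successive leaf on a uniformly chosen edge,
    which makes every (2n−5)!! topology equally likely.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    names = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    # adjacency on ints: leaves 0..n-1, internals n..
    adj: dict[int, list] = {0: [n_taxa], 1: [n_taxa], 2: [n_taxa], n_taxa: [0, 1, 2]}
    next_id = n_taxa + 1
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        adj[u][adj[u].index(v)] = next_id
        adj[v][adj[v].index(u)] = next_id
        adj[next_id] = [u, v, leaf]
        adj[leaf] = [next_id]
        next_id += 1

    def build(node: int, came: int | None) -> TreeNode:
        if node < n_taxa:
            return TreeNode(names[node])
        out = TreeNode()
        for nb in adj[node]:
            if nb != came:
                out.add(build(nb, node))
        return out

    return PhyloTree(build(n_taxa, None), rooted=False)


def simulate_matrix(scenario: SimScenario) -> CharacterMatrix:
    """Evolve characters independently down the true tree.

    Per branch the number of changes is Poisson(change_rate); each change
    jumps to a uniformly chosen *different* state.  Rate 0 yields an
    all-constant matrix.
    """
    rng = np.random.default_rng(scenario.seed)
    k = scenario.n_states
    tree = scenario.true_tree
    n_chars = scenario.n_chars
    states: dict[TreeNode, np.ndarray] = {
        tree.root: rng.integers(k, size=n_chars)
    }
    rows: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            parent_states = states[node.parent].copy()
            n_changes = rng.poisson(scenario.change_rate, size=n_chars)
            for j in np.nonzero(n_changes)[0]:
                s = parent_states[j]
                for _ in range(n_changes[j]):
                    s = (s + 1 + rng.integers(k - 1)) % k
                parent_states[j] = s
            states[node] = parent_states
        if node.is_leaf:
            rows[node.label] = states[node]
    names = tree.leaf_names()
    cells = [[int(s) for s in rows[t]] for t in names]
    return CharacterMatrix(names, cells, [CharMeta() for _ in range(n_chars)])


def random_matrix(
    n_taxa: int,
    n_chars: int,
    n_states: int = 3,
    seed: int = 0,
    missing_rate: float = 0.0,
    ordered: bool = False,
) -> CharacterMatrix:
    """I.i.d. uniform random matrix (no tree signal), for stress tests."""
    rng = np.random.default_rng(seed)
    names = [f"T{i + 1}" for i in range(n_taxa)]
    cells = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_chars):
            if missing_rate and rng.random() < missing_rate:
                row.append(None)
            else:
                row.append(int(rng.integers(n_states)))
        cells.append(row)
    meta = [CharMeta(ordered=ordered) for _ in range(n_chars)]
    return CharacterMatrix(names, cells, meta)


# ---------------------------------------------------------------------------
# biogeographic scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiogeoEvent:
    """A scripted range event on the branch *above* the named node.

    vicariance: the lineage's range contracts to ``areas`` (which must be
    a non-empty proper subset of the inherited range); geodispersal: the
    range expands by ``areas``.
    """

    branch: str
    kind: str  # "vicariance" | "geodispersal"
    areas: frozenset

    def __post_init__(self) -> None:
        if self.kind not in ("vicariance", "geodispersal"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class BiogeoScenario:
    taxon_count: int
    root_areas: frozenset
    events: tuple
    area_names: tuple
    seed: int = 0
    #: explicit taxon tree (internal nodes will be named); when None a
    #: uniform random topology is simulated from the seed
    tree: PhyloTree | None = None


@dataclass
class BiogeoSim:
    tree: PhyloTree  # taxon tree with named internal nodes
    assignment: AreaAssignment
    event_log: list


def simulate_biogeography(scenario: BiogeoScenario) -> BiogeoSim:
    """Taxon phylogeny whose lineages inherit area sets, contracted at
    scripted vicariance events and expanded at scripted geodispersal
    events; returns leaf distributions plus the truth log."""
    tree = (
        scenario.tree
        if scenario.tree is not None
        else simulate_tree(scenario.taxon_count, scenario.seed)
    )
    tree = tree.copy()
    tree.rooted = True
    _ensure_node_names(tree)
    labels = {n.label for n in tree.postorder()}
    for ev in scenario.events:
        if ev.branch not in labels:
            raise ValueError(f"event references missing branch {ev.branch!r}")
    events_at: dict[str, list] = {}
    for ev in scenario.events:
        events_at.setdefault(ev.branch, []).append(ev)
    dist: dict[str, frozenset] = {}
    log = []
    for node in tree.preorder():
        inherited = (
            scenario.root_areas
            if node.parent is None
            else dist[node.parent.label]
        )
        current = inherited
        for ev in events_at.get(node.label, []):
            if ev.kind == "vicariance":
                new = current & ev.areas
                if not new or new == current:
                    raise ValueError(
                        f"vicariance on {ev.branch!r} must contract "
                        f"{sorted(current)} to a non-empty proper subset"
                    )
                current = new
            else:
                current = current | ev.areas
            log.append((node.label, ev.kind, frozenset(current)))
        dist[node.label] = current
    occurrences = {n.label: dist[n.label] for n in tree.leaves()}
    assignment = AreaAssignment(tuple(scenario.area_names), occurrences)
    return BiogeoSim(tree, assignment, log)


# ---------------------------------------------------------------------------
# study-scale demo scenario
# ---------------------------------------------------------------------------


def demo_scenario(seed: int = 1):
    """Paper-scale synthetic stand-in: 31 taxa × 39 three-state characters
    on one true tree, with a scripted 7-area history on the same tree.

    The change rate (0.05 expected changes per character per branch, ~3
    expected changes per character tree-wide) is chosen to produce the
    substantial-but-not-saturating homoplasy typical of morphological
    matrices of this size.  Returns (matrix, assignment, sim, scenario).
    """
    n_taxa, n_chars = 31, 39
    tree = simulate_tree(n_taxa, seed)
    tree = tree.copy()
    tree.rooted = True
    _ensure_node_names(tree)
    scenario = SimScenario(
        true_tree=tree, n_chars=n_chars, n_states=3, change_rate=0.05, seed=seed
    )
    matrix = simulate_matrix(scenario)

    areas = tuple(AREA_CODES[i] for i in sorted(AREA_CODES))
    rng = np.random.default_rng(seed + 1)
    internals = [n.label for n in tree.internal_nodes() if n.parent is not None]
    rng.shuffle(internals)
    # scripted history: a deep two-way vicariant split, later expansions,
    # and shallow contractions — both signals present, as in real systems
    a = list(areas)
    events = []
    picks = internals[:6]
    kinds = ["vicariance", "vicariance", "geodispersal", "geodispersal",
             "vicariance", "geodispersal"]
    # walk the tree to keep scripted events consistent with inheritance
    dist_now: dict[str, frozenset] = {}
    planned: dict[str, tuple] = {}
    order = {lbl: i for i, lbl in enumerate(n.label for n in tree.preorder())}
    picks.sort(key=order.get)
    for lbl, kind in zip(picks, kinds):
        planned[lbl] = kind
    for node in tree.preorder():
        inherited = (
            frozenset(a[:5]) if node.parent is None else dist_now[node.parent.label]
        )
        current = inherited
        if node.label in planned:
            kind = planned[node.label]
            if kind == "vicariance" and len(current) > 1:
                keep = rng.choice(sorted(current), size=max(1, len(current) // 2),
                                  replace=False)
                events.append(BiogeoEvent(node.label, "vicariance",
                                          frozenset(keep.tolist())))
                current = frozenset(keep.tolist())
            elif kind == "geodispersal":
                absent = sorted(set(a) - current)
                if absent:
                    gained = frozenset({absent[int(rng.integers(len(absent)))]})
                    events.append(BiogeoEvent(node.label, "geodispersal", gained))
                    current = current | gained
        dist_now[node.label] = current
    bscenario = BiogeoScenario(
        taxon_count=n_taxa,
        root_areas=frozenset(a[:5]),
        events=tuple(events),
        area_names=areas,
        seed=seed,
    )
    sim = simulate_biogeography(bscenario)
    return matrix, sim.assignment, sim, scenario


# ---------------------------------------------------------------------------
# empirical fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "s1": "table_s1.csv",
    "s2": "table_s2.csv",
    "s3": "table_s3.csv",
    "areas": "fig5_areas.csv",
}


def load_paper_fixtures(fixture_dir: str | Path = "data") -> dict:
    """Load the transcribed empirical fixtures from *fixture_dir*.

    Expects ``table_s1.csv`` (31 taxa × 39 characters), ``table_s2.csv``
    (geodispersal) and ``table_s3.csv`` (vicariance; both 7 areas + the
    all-zero ANCESTOR row) and ``fig5_areas.csv`` (taxon,area1;area2).
    The source supplementary tables are distributed as DOC files and must
    be transcribed by hand; see ``data/TRANSCRIPTION.md``.  Missing files
    raise ``FileNotFoundError`` naming the checklist.
    """
    fixture_dir = Path(fixture_dir)
    missing = [
        f for f in _FIXTURE_FILES.values() if not (fixture_dir / f).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"empirical fixtures not found in {fixture_dir}/: {missing}. "
            "These must be transcribed from the study's supplementary DOC "
            "tables; see data/TRANSCRIPTION.md for the checklist."
        )
    s1 = read_matrix(fixture_dir / _FIXTURE_FILES["s1"], dialect="csv")
    if (s1.n_taxa, s1.n_chars) != (31, 39):
        raise ValueError(
            f"table_s1.csv must be 31 taxa x 39 characters, got "
            f"{s1.n_taxa} x {s1.n_chars}"
        )
    s2 = BiogeoMatrix.from_csv(fixture_dir / _FIXTURE_FILES["s2"], "geodispersal")
    s3 = BiogeoMatrix.from_csv(fixture_dir / _FIXTURE_FILES["s3"], "vicariance")
    for bm in (s2, s3):
        if len(bm.areas) != 7:
            raise ValueError(f"{bm.kind} matrix must have 7 area rows + outgroup")
    areas = read_area_assignment(fixture_dir / _FIXTURE_FILES["areas"])
    if len(areas.area_names) != 7:
        raise ValueError("area assignment must cover exactly 7 areas")
    return {"s1": s1, "s2": s2, "s3": s3, "areas": areas}
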