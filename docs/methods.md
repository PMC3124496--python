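# Methods

This note documents the models and procedures the package implements,
the parameters that matter and why their defaults are what they are, the
numerical choices hiding inside the algorithms, and what the synthetic
validation scenario does and does not demonstrate.

## Parsimony scoring

All character scoring is one engine: a generalized (Sankoff) dynamic
program over per-character state spaces, with unit costs for unordered
(Fitch) characters and |i−j| costs for ordered (Wagner) characters on a
linear scale. The DP is exact on arbitrary trees, so strict-consensus
trees with polytomies are scored directly as *hard* polytomies (minimum
over center states with all children attached) — the binary-only
entry points `fitch_steps`/`wagner_steps` refuse polytomies explicitly,
and `steps_on_polytomous_tree` accepts anything.

Cell semantics: `?` is full ambiguity (the character may take any
observed state at that leaf); a polymorphic cell `{a,b}` is treated as
uncertainty over the listed states (the reconstruction may choose
either at zero cost). This is the convention the standard desktop
programs use by default; it matters only for the handful of dimorphic
codings a morphological matrix typically carries.

Per-character bounds, used by the ensemble indices:

- minimum mᵢ: for unordered characters, the smallest number of states
  that can cover every cell minus one (computed exactly over the ≤2¹⁰
  subsets of observed states — with polymorphism this is a hitting-set
  problem, not simply "observed states − 1"); for ordered characters,
  max(0, max-of-cell-minima − min-of-cell-maxima).
- maximum gᵢ: the star-tree score, minimized over the center state.

CI is reported over a caller-chosen character subset so that the
conventional "excluding uninformative characters" variant is the
natural call (`consistency_index(score, informative_characters(m))`);
RI excludes characters with gᵢ = mᵢ from its sums and is undefined (an
error) when no character remains.

Ancestral states (`optimize_states`) are most-parsimonious-
reconstruction sets: a state belongs to a node's set iff some MPR
assigns it, computed from the DP's down-pass plus an outside ("up")
pass; |set| = 1 flags an unambiguous optimization. Sets are computed on
one designated tree, not pooled across the MPT set.

## Search

**TBR hill climbing.** Each replicate starts from a greedy random-
addition tree (seeded taxon order, ties broken by the replicate's RNG)
and repeatedly takes the best tree-bisection-reconnection move until
none improves, then pools up to `trees_saved_per_rep` equally
parsimonious trees reachable through equal-length moves. Replicate
pools are merged, deduplicated by bipartition sets, and filtered to the
global best length.

The neighborhood is evaluated through an exact join identity rather
than per-neighbor traversals: bisecting on an edge leaves two
components A and B whose unrooted lengths are rooting-invariant, and
reconnecting along edges a ∈ A, b ∈ B yields a tree of length
len(A) + len(B) + Σᵢ join(Sᵢ(a), Sᵢ(b)), where S(a) is the
component's root state set (Fitch mask, or Farris interval for ordered
characters) when rooted on a, and the join cost is one step per
character with incompatible sets (interval gap for ordered). One
down/up pass per component prices the entire reconnection grid as a
single vectorized operation. The identity — and therefore the whole
search stack — is checked against brute-force enumeration in the test
suite. One caveat: the interval representation treats a non-contiguous
polymorphic cell in an *ordered* character as its hull; the Sankoff
engine (used for all reported tree lengths) handles such cells exactly,
and none of the intended matrices contains one.

**Exhaustive enumeration** inserts taxa in index order, pricing each
insertion with the same identity, and visits all (2n−5)!! unrooted
binary topologies; it returns the exact MPT set plus the full
tree-length distribution. The guard is 12 taxa; at 11–12 the
enumeration is combinatorially legal but impractically slow, and every
consumer in this package uses ≤ 9. **Branch and bound** prunes the same
recursion with the running best (+ slack, when collecting near-optimal
trees for Bremer support), seeded by one greedy addition tree; partial
lengths only grow as taxa are added, so pruning is safe.

**Support.** Bootstrap resamples characters with replacement to the
original count; jackknife deletes a caller-specified number without
replacement; both count a bipartition per replicate iff it appears in
the strict consensus of that replicate's MPT set. Bremer support is the
smallest extra length k at which some near-optimal tree lacks the
bipartition, from branch-and-bound enumeration within best+k on small
matrices and a TBR pool otherwise; values surviving the window are
reported as max_extra + 1.

Defaults: 100 replicates, 10 trees saved per replicate, one master seed
with per-replicate streams spawned from it. The desk-scale replicate
count (the published workflow used 10,000 in compiled software) is a
deliberate choice: on matrices of this size the best length stabilizes
within tens of replicates, and the reproduction pipeline asserts
lengths, not tree counts.

## LBPA

The area cladogram is the taxon consensus with leaves carrying area
sets; polytomies are retained (the empirical consensus contains a large
one). Ancestral areas come from a modified Fitch pass: down-pass takes
the children's intersection when non-empty, otherwise the areas shared
by ≥ 2 children, otherwise the union; the up-pass keeps the root's
down-pass set and unions every other node's down-pass set with
(parent's final set ∩ union of its children's down-pass sets). The pass
is deterministic and total: every internal node ends non-empty.

Matrix coding, per node/terminal x with range D and parent range P
(P = D at the root), per area a: 0 if a ∉ D; in the vicariance matrix 2
if D ⊊ P (every retained area of a contracted range is marked) else 1;
in the geodispersal matrix 2 if a ∈ D∖P (the lineage expanded into a)
else 1. Consequences used as test invariants: the root column never
contains a 2; both matrices share the same 0/non-0 pattern; a strictly
nested (contraction-only) history has no 2 in the geodispersal matrix.
Terminals contribute columns alongside internal nodes (classic BPA
convention). The exact event semantics of the published coding are
specified in the method's primary literature rather than recoverable
from the study itself; the rule above is this package's concrete,
documented choice, and the transcription checklist (`data/`) is written
so that a transcribed supplementary matrix can be compared
column-for-column against regenerated output.

Both matrices are analyzed by exhaustive ordered parsimony over rows =
areas + an all-zero hypothetical ancestor, which forces rooting; MPTs
and consensus are reported rooted on that ancestor.

**g1.** The skewness of the exhaustive tree-length distribution, by
default the adjusted Fisher–Pearson estimator
g₁ = [n/((n−1)(n−2))]·Σ((Lᵢ−L̄)/s)³ with s the (n−1)-denominator
standard deviation (equivalently `scipy.stats.skew(…, bias=False)`);
the plain moment estimator m₃/m₂^{3/2} is available because published
values do not always say which variant their software used.
Significance is assessed, when requested, by a seeded Monte-Carlo null:
each replicate shuffles every character column independently across the
area rows (preserving per-character state frequencies, destroying
congruence) and recomputes g₁ exhaustively; the reported level is the
strongest of {0.01, 0.05} with p = (1 + #{g₁ⁿᵘˡˡ ≤ g₁ᵒᵇˢ})/(1 + n_null).
A Monte-Carlo null was chosen over the classical printed critical-value
table because the table's entries could not be verified against an
authoritative source at build time; embedding unverifiable constants
under a citation seemed worse than computing the null. At the default
99 replicates the finest attainable level is exactly 0.01.
Distributions with fewer than 3 lengths or zero variance (too few
areas, eventless histories) yield g₁ = NaN rather than an error in the
end-to-end pipeline.

## Synthetic data

`simulate_tree` draws uniform unrooted binary topologies by sequential
random edge insertion. `simulate_matrix` evolves each character
independently down the tree: Poisson(change_rate) changes per branch,
each jumping to a uniformly chosen different state — a symmetric
Mk-style process with no rate heterogeneity across branches or
characters, no correlation between characters, and no missing data.
`simulate_biogeography` gives every lineage its inherited area set,
applying scripted vicariance (contraction to a stated proper subset)
and geodispersal (expansion) events on named branches, and emits the
leaf occurrences plus the truth log.

The study-scale demo (`demo_scenario`) mirrors the empirical
conditions: 31 taxa × 39 characters with ≤ 3 states, 7 areas, an
ancestor-rooted area analysis over all 10,395 topologies. Its change
rate, 0.05 expected changes per character per branch (≈ 3 per character
across the ~59-branch tree), was chosen to produce substantial but
unsaturated homoplasy — consistency indices around 0.4–0.6, the regime
morphological matrices of this size actually occupy. The area script
mixes deep vicariance with later expansions so both matrices carry
signal.

What passing synthetic tests shows: the scoring, search, coding and
test statistics are mutually consistent and exact where exactness is
claimed, and the pipeline separates scripted contraction histories from
expansion histories. What it does not show: anything about real
morphological evolution — correlated characters, ontogenetic or
preservational missingness, taxon-sampling artifacts, or soft
polytomies — nor the published numerical results themselves, which
require the transcribed supplementary fixtures (`data/TRANSCRIPTION.md`).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the demo scenario with
20 TBR replicates (the library default is 100) and skip the Monte-Carlo
g₁ null by default; exhaustive analyses are exact at these sizes, so
replicate count affects only the heuristic search, whose best length is
stable across seeds at this scale. Every stochastic component — taxon
addition order, TBR tie-breaking, resampling, simulation, the g₁ null —
derives from a single integer seed, and identical seeds produce
byte-identical outputs.

## Known limitations

- No branch lengths, likelihood, Bayesian inference, or implied
  weighting; characters are equal-weighted by default (a weight field
  exists for generality).
- TBR is a local search: on adversarial matrices a replicate can stall
  on a local optimum; replicates are the mitigation, as in practice.
- The MPT *count* depends on zero-length-branch collapsing conventions
  that differ between programs; counts are reported informationally and
  never asserted against published counts.
- Exhaustive enumeration beyond 10 taxa, while permitted up to 12, is
  slow in pure Python; use branch and bound there.
- Jackknife/bootstrap support on very small or barely informative
  matrices is noisy by nature; replicate counts are the caller's
  responsibility.
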