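"""Maximum-parsimony inference on binary breakpoint characters.

Trees are rooted by an explicit all-absent ``normal`` pseudo-tip standing
for the unaltered ancestor. Characters are presence/absence; NA is a
wildcard {0,1}. Branch lengths are Fitch change counts, with ambiguity
resolved by the standard parent-preferred traceback (for binary
characters ACCTRAN and DELTRAN coincide under a fixed root state, so the
``resolve`` knob only documents intent).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np

from ._tree import Node, Phylogeny
from .markers import NA, CharacterMatrix
from .profiles_io import ValidationError

NORMAL_TIP = "normal"

_EXHAUSTIVE_LIMIT = 9  # (2n-3)!! rooted topologies; 9 samples = 2,027,025

# character state sets as 2-bit masks: {0} -> 1, {1} -> 2, {0,1} -> 3
_SET0, _SET1, _BOTH = np.uint8(1), np.uint8(2), np.uint8(3)


def _tip_sets(matrix: CharacterMatrix) -> dict[str, np.ndarray]:
    sets = {}
    for sid, row in zip(matrix.sample_ids, matrix.values):
        s = np.where(row == NA, _BOTH, np.where(row == 1, _SET1, _SET0))
        sets[sid] = s.astype(np.uint8)
    sets[NORMAL_TIP] = np.full(len(matrix.marker_ids), _SET0, dtype=np.uint8)
    return sets


def _combine(children_sets: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Fold Fitch set union/intersection over children; return (set, changes)."""
    acc = children_sets[0]
    changes = np.zeros(acc.shape, dtype=np.int64)
    for child in children_sets[1:]:
        inter = acc & child
        union = acc | child
        empty = inter == 0
        acc = np.where(empty, union, inter)
        changes += empty
    return acc, changes


def fitch_score(tree: Phylogeny, matrix: CharacterMatrix) -> int:
    """Minimum total state changes over all characters (Fitch bottom-up)."""
    sets = _tip_sets(matrix)
    known = set(matrix.sample_ids) | {NORMAL_TIP}
    total = np.zeros(len(matrix.marker_ids), dtype=np.int64)
    node_sets: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in known:
                raise ValidationError(f"tip {node.label!r} absent from matrix")
            node_sets[node] = sets[node.label]
        else:
            acc, changes = _combine([node_sets[c] for c in node.children])
            node_sets[node] = acc
            total += changes
    return int(total.sum())


# ---------------------------------------------------------------------------
# tuple-tree machinery for search (leaf = taxon index, internal = 2-tuple)
# ---------------------------------------------------------------------------


def _score_tuple(tree, tips: np.ndarray) -> int:
    """Fitch score of a tuple tree rooted by an implicit all-0 normal tip."""

    def down(t):
        if isinstance(t, int):
            return tips[t], 0
        (ls, lc), (rs, rc) = down(t[0]), down(t[1])
        inter = ls & rs
        empty = inter == 0
        acc = np.where(empty, ls | rs, inter)
        return acc, lc + rc + int(empty.sum())

    root_set, changes = down(tree)
    return changes + int((root_set & _SET0 == 0).sum())


def _insertions(tree, leaf) -> Iterable:
    yield (tree, leaf)
    if isinstance(tree, tuple):
        for sub in _insertions(tree[0], leaf):
            yield (sub, tree[1])
        for sub in _insertions(tree[1], leaf):
            yield (tree[0], sub)


def _all_topologies(n: int) -> Iterable:
    def grow(tree, k):
        if k == n:
            yield tree
            return
        for t in _insertions(tree, k):
            yield from grow(t, k + 1)

    if n == 1:
        yield 0
        return
    yield from grow((0, 1), 2)


def _nni_neighbors(tree) -> Iterable:
    """All trees one nearest-neighbor interchange away."""

    def neighbors(t):
        if not isinstance(t, tuple):
            return
        a, b = t
        if isinstance(a, tuple):
            x, y = a
            yield ((x, b), y)
            yield ((y, b), x)
        if isinstance(b, tuple):
            x, y = b
            yield (x, (y, a))
            yield (y, (x, a))
        for sub in neighbors(a):
            yield (sub, b)
        for sub in neighbors(b):
            yield (a, sub)

    yield from neighbors(tree)


def _canonical(tree, labels: Sequence[str]):
    """Canonical (newick string, min-label) pair for topology dedup/ordering."""

    def walk(t):
        if isinstance(t, int):
            return labels[t], labels[t]
        (na, ma), (nb, mb) = walk(t[0]), walk(t[1])
        if (ma, na) > (mb, nb):
            na, nb = nb, na
            ma, mb = mb, ma
        return f"({na},{nb})", min(ma, mb)

    return walk(tree)[0]


def _tuple_to_phylogeny(tree, labels: Sequence[str]) -> Phylogeny:
    root = Node()
    root.add_child(Node(NORMAL_TIP))

    def build(t) -> Node:
        if isinstance(t, int):
            return Node(labels[t])
        node = Node()
        node.add_child(build(t[0]))
        node.add_child(build(t[1]))
        return node

    root.add_child(build(tree))
    return Phylogeny(root)


def search_parsimony(matrix: CharacterMatrix, mode: str = "heuristic",
                     n_restarts: int = 20, seed: int = 0
                     ) -> tuple[Phylogeny, list[Phylogeny], int]:
    """Minimum-Fitch-score tree rooted on the normal pseudo-tip.

    Returns ``(best_tree, co_optimal_trees, score)``. ``exhaustive``
    enumerates every rooted topology (allowed up to 9 samples);
    ``heuristic`` runs random stepwise addition plus NNI hill climbing per
    restart. Ties are broken by lexicographically smallest Newick string.
    """
    n = len(matrix.sample_ids)
    if n < 3:
        raise ValidationError("search_parsimony needs at least 3 samples")
    labels = list(matrix.sample_ids)
    tipsets = _tip_sets(matrix)
    tips = np.stack([tipsets[s] for s in labels])

    best: dict[str, tuple] = {}
    best_score = None

    def consider(tree):
        nonlocal best_score
        score = _score_tuple(tree, tips)
        if best_score is None or score < best_score:
            best_score = score
            best.clear()
        if score == best_score:
            best[_canonical(tree, labels)] = tree

    if mode == "exhaustive":
        if n > _EXHAUSTIVE_LIMIT:
            raise ValidationError(
                f"exhaustive search limited to {_EXHAUSTIVE_LIMIT} samples (got {n})"
            )
        for tree in _all_topologies(n):
            consider(tree)
    elif mode == "heuristic":
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            order = list(rng.permutation(n))
            tree = (int(order[0]), int(order[1]))
            for k in order[2:]:
                tree = min(
                    _insertions(tree, int(k)),
                    key=lambda t: (_score_tuple(t, tips), _canonical(t, labels)),
                )
            # NNI hill climbing to a local optimum
            score = _score_tuple(tree, tips)
            improved = True
            while improved:
                improved = False
                for cand in _nni_neighbors(tree):
                    s = _score_tuple(cand, tips)
                    if s < score:
                        tree, score, improved = cand, s, True
                        break
            consider(tree)
            for cand in _nni_neighbors(tree):  # co-optimal NNI neighbors
                if _score_tuple(cand, tips) == best_score:
                    consider(cand)
    else:
        raise ValidationError(f"unknown search mode {mode!r}")

    ordered = sorted(best)
    co_optimal = [_tuple_to_phylogeny(best[key], labels) for key in ordered]
    winner = co_optimal[0].copy()
    assign_branch_lengths(winner, matrix)
    return winner, co_optimal, int(best_score)


# ---------------------------------------------------------------------------
# branch lengths and distances
# ---------------------------------------------------------------------------


def assign_branch_lengths(tree: Phylogeny, matrix: CharacterMatrix,
                          resolve: str = "acctran") -> Phylogeny:
    """Per-branch Fitch change counts; totals are conserved.

    The traceback takes the parent state whenever the node's Fitch set
    allows it (the unique most-parsimonious refinement for binary
    characters once the root prefers the ancestral absent state), so
    ``resolve`` currently has no observable effect; both spellings are
    accepted.
    """
    if resolve not in ("acctran", "deltran"):
        raise ValidationError(f"unknown resolution {resolve!r}")
    sets = _tip_sets(matrix)
    node_sets: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in sets:
                raise ValidationError(f"tip {node.label!r} absent from matrix")
            node_sets[node] = sets[node.label]
        else:
            node_sets[node], _ = _combine([node_sets[c] for c in node.children])

    states: dict[Node, np.ndarray] = {}
    root_set = node_sets[tree.root]
    states[tree.root] = np.where(root_set & _SET0 != 0, 0, 1).astype(np.int8)
    tree.root.length = tree.root.length or 0.0
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = states[node.parent]
        own = node_sets[node]
        parent_bit = np.where(parent_state == 0, _SET0, _SET1)
        keeps = (own & parent_bit) != 0
        state = np.where(keeps, parent_state, 1 - parent_state).astype(np.int8)
        states[node] = state
        node.length = float((state != parent_state).sum())
    return tree


def patristic_distance(tree: Phylogeny, sample1: str, sample2: str) -> float:
    """Sum of branch lengths along the path between two tips."""
    a, b = tree.find(sample1), tree.find(sample2)
    if a is b:
        return 0.0
    ancestors = {}
    node, dist = a, 0.0
    while node is not None:
        ancestors[id(node)] = dist
        dist += node.length or 0.0
        node = node.parent
    node, dist = b, 0.0
    while node is not None:
        if id(node) in ancestors:
            return dist + ancestors[id(node)]
        dist += node.length or 0.0
        node = node.parent
    raise ValidationError("tips do not share a root")  # pragma: no cover


def distance_from_normal(tree: Phylogeny, sample: str) -> float:
    """Change count separating a sample from the unaltered ancestral state."""
    try:
        return patristic_distance(tree, sample, NORMAL_TIP)
    except KeyError:
        node, dist = tree.find(sample), 0.0
        while node.parent is not None:
            dist += node.length or 0.0
            node = node.parent
        return dist


def diversity(tree: Phylogeny, group: Sequence[str]) -> float:
    """Mean pairwise patristic distance over a group of tips."""
    group = list(group)
    if len(group) < 2:
        raise ValidationError("diversity needs at least 2 samples")
    dists = [patristic_distance(tree, a, b) for a, b in itertools.combinations(group, 2)]
    return float(np.mean(dists))


def build_distance_table(tree: Phylogeny, metas=None):
    """All pairwise tip distances (normal excluded) with grouping covariates."""
    import pandas as pd

    meta_by_id = {m.sample_id: m for m in metas} if metas else {}
    tips = [t for t in tree.tip_labels() if t != NORMAL_TIP]
    rows = []
    for a, b in itertools.combinations(tips, 2):
        d = patristic_distance(tree, a, b)
        ma, mb = meta_by_id.get(a), meta_by_id.get(b)
        same_biopsy = same_tp = None
        physical = None
        if ma and mb:
            same_biopsy = ma.biopsy_id == mb.biopsy_id
            same_tp = ma.time_point == mb.time_point
            if same_biopsy and ma.baguette_section and mb.baguette_section:
                physical = abs(ma.baguette_section - mb.baguette_section)
        rows.append((a, b, d, same_biopsy, same_tp, physical))
    return pd.DataFrame(
        rows,
        columns=["sample1", "sample2", "evolutionary_distance",
                 "same_biopsy", "same_time_point", "physical_distance"],
    )
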