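"""Maximum-parsimony clone trees from binary event matrices.

Subclones (rows of the event matrix) are taxa; events (columns) are binary
characters; a normal, all-zero outgroup roots the tree. Small problems are
solved exactly by branch-and-bound over rooted topologies; larger ones by
stepwise addition with nearest-neighbor-interchange hill climbing under a
fixed seed. Scoring is unordered binary Fitch parsimony. After the search the
optimal character states are backtraced onto the nodes, events are mapped to
the edges where their state changes, and zero-length edges are collapsed so
that a subclone whose genotype equals an internal reconstruction sits at that
internal node (ancestral subclone). Edge lengths are event counts; the stem
is the edge from the normal root to the tumor MRCA.

Ties between equally parsimonious trees are broken deterministically by
(a) fewer internal nodes after collapsing, then (b) lexicographic order of
the sorted leaf partitions.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import InvalidInputError

NORMAL = "normal"
EXHAUSTIVE_LIMIT = 9


@dataclass
class SampleDetection:
    sample_id: str
    site: str
    sample_class: str  # primary | lymph_node | distant | relapse
    fraction: float


@dataclass
class CloneNode:
    name: str
    parent: Optional[str]
    events: tuple  # events changing state on the edge into this node
    genotype: frozenset  # events present in this clone
    children: list = field(default_factory=list)
    subclones: tuple = ()  # subclone ids sitting at this node
    detections: list = field(default_factory=list)  # list[SampleDetection]


class CloneTree:
    """Rooted clone tree: normal root -> stem -> subclones."""

    def __init__(self):
        self.nodes: dict[str, CloneNode] = {}
        self.root = NORMAL

    def add_node(self, node: CloneNode):
        self.nodes[node.name] = node
        if node.parent is not None:
            self.nodes[node.parent].children.append(node.name)

    # -- topology queries ---------------------------------------------------
    def parent(self, name: str) -> Optional[str]:
        return self.nodes[name].parent

    def ancestors(self, name: str) -> list[str]:
        """Strict ancestors, nearest first."""
        out = []
        p = self.nodes[name].parent
        while p is not None:
            out.append(p)
            p = self.nodes[p].parent
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` is a strict ancestor of ``b``."""
        return a in self.ancestors(b)

    def is_ancestor_or_self(self, a: str, b: str) -> bool:
        return a == b or self.is_ancestor(a, b)

    def mrca(self, names: Iterable[str]) -> str:
        names = list(names)
        if not names:
            raise InvalidInputError("mrca of an empty set")
        paths = [[n] + self.ancestors(n) for n in names]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common ancestor = first common node on any root-ward path
        for node in paths[0]:
            if node in common:
                return node
        raise InvalidInputError("nodes share no ancestor")  # pragma: no cover

    def edge_length(self, name: str) -> int:
        return len(self.nodes[name].events)

    def path_length(self, ancestor: str, descendant: str) -> int:
        """Total events on the path from ``ancestor`` down to ``descendant``."""
        if ancestor == descendant:
            return 0
        length = 0
        n = descendant
        while n != ancestor:
            length += self.edge_length(n)
            n = self.nodes[n].parent
            if n is None:
                raise InvalidInputError(f"{ancestor} is not an ancestor of {descendant}")
        return length

    @property
    def stem_node(self) -> Optional[str]:
        kids = self.nodes[self.root].children
        return kids[0] if len(kids) == 1 else None

    @property
    def stem_length(self) -> int:
        kids = self.nodes[self.root].children
        return self.edge_length(kids[0]) if len(kids) == 1 else 0

    def subclone_node(self, subclone_id: str) -> str:
        for name, node in self.nodes.items():
            if subclone_id in node.subclones:
                return name
        raise InvalidInputError(f"subclone {subclone_id} not in tree")

    # -- serialization ------------------------------------------------------
    def newick(self) -> str:
        def fmt(name):
            node = self.nodes[name]
            label = "+".join(node.subclones) if node.subclones else name
            if node.children:
                inner = ",".join(fmt(c) for c in sorted(node.children))
                return f"({inner}){label}:{len(node.events)}"
            return f"{label}:{len(node.events)}"

        return fmt(self.root) + ";"

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick(), schema="newick")

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.nodes):
            node = self.nodes[name]
            if node.parent is None:
                continue
            rows.append({
                "parent": node.parent,
                "child": name,
                "n_events": len(node.events),
                "event_ids": ",".join(node.events),
                "subclones": ",".join(node.subclones),
            })
        return pd.DataFrame(rows, columns=["parent", "child", "n_events", "event_ids", "subclones"])

    def fitch_score_total(self) -> int:
        return sum(len(self.nodes[n].events) for n in self.nodes if self.nodes[n].parent is not None)


# ---------------------------------------------------------------------------
# Fitch scoring on nested-tuple topologies (bitmask over characters)
# ---------------------------------------------------------------------------

def _leaf_masks(matrix: pd.DataFrame) -> tuple[dict, int]:
    n_chars = matrix.shape[1]
    full = (1 << n_chars) - 1
    masks = {}
    for taxon, row in matrix.iterrows():
        b = 0
        for c, v in enumerate(row.values):
            if v:
                b |= 1 << c
        masks[taxon] = (full & ~b, b)  # (contains-0 mask, contains-1 mask)
    masks[NORMAL] = (full, 0)
    return masks, full


def _fitch_sets(tree, masks, full):
    """Return (A, B, score): per-character state-set bitmasks and change count."""
    if not isinstance(tree, tuple):
        a, b = masks[tree]
        return a, b, 0
    a1, b1, s1 = _fitch_sets(tree[0], masks, full)
    a2, b2, s2 = _fitch_sets(tree[1], masks, full)
    ia, ib = a1 & a2, b1 & b2
    empty = full & ~(ia | ib)
    a = ia | (empty & (a1 | a2))
    b = ib | (empty & (b1 | b2))
    return a, b, s1 + s2 + empty.bit_count()


def _score_rooted(tree, masks, full) -> int:
    """Fitch score with the normal outgroup forcing state 0 at the root."""
    a, b, s = _fitch_sets(tree, masks, full)
    return s + (full & ~a).bit_count()  # characters whose root set lacks 0


def fitch_score(tree_topology, matrix: pd.DataFrame) -> int:
    """Fitch small-parsimony count of a topology over the event matrix.

    ``tree_topology`` is a nested tuple of subclone ids (matrix row labels);
    the normal all-zero outgroup is attached at the root implicitly (it may
    also appear explicitly as the string ``"normal"``).
    """
    leaves = set(_tuple_leaves(tree_topology)) - {NORMAL}
    rows = set(matrix.index)
    if leaves != rows:
        raise InvalidInputError(f"topology leaves {sorted(leaves)} != matrix rows {sorted(rows)}")
    masks, full = _leaf_masks(matrix)
    return _score_rooted(_strip_normal(tree_topology), masks, full)


def _tuple_leaves(t):
    if isinstance(t, tuple):
        for sub in t:
            yield from _tuple_leaves(sub)
    else:
        yield t


def _strip_normal(t):
    if not isinstance(t, tuple):
        return t
    parts = [p for p in t if p != NORMAL]
    if len(parts) == 1:
        return _strip_normal(parts[0])
    return tuple(_strip_normal(p) for p in parts)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _insertions(tree, leaf):
    """All trees obtained by attaching ``leaf`` on an edge of ``tree`` (or above the root)."""
    yield (tree, leaf)
    if isinstance(tree, tuple):
        for sub in _insertions(tree[0], leaf):
            yield (sub, tree[1])
        for sub in _insertions(tree[1], leaf):
            yield (tree[0], sub)


def enumerate_topologies(leaves: list):
    """All rooted binary topologies over the leaves (the normal root edge is implicit)."""
    if not leaves:
        return
    if len(leaves) == 1:
        yield leaves[0]
        return
    for t in enumerate_topologies(leaves[:-1]):
        yield from _insertions(t, leaves[-1])


def _branch_and_bound(leaves, masks, full, best=None):
    """Exact minimum score and one witness via DFS with score pruning."""
    best_score = best if best is not None else float("inf")
    best_tree = None

    def rec(tree, remaining):
        nonlocal best_score, best_tree
        score = _score_rooted(tree, masks, full)
        if score >= best_score and remaining:
            return
        if not remaining:
            if score < best_score:
                best_score, best_tree = score, tree
            return
        nxt, rest = remaining[0], remaining[1:]
        for t in _insertions(tree, nxt):
            rec(t, rest)

    if len(leaves) == 1:
        return _score_rooted(leaves[0], masks, full), leaves[0]
    rec((leaves[0], leaves[1]), leaves[2:])
    return best_score, best_tree


def _collect_optimal(leaves, masks, full, target, cap=20000):
    """All topologies reaching the target score (pruned DFS, capped)."""
    out = []

    def rec(tree, remaining):
        if len(out) >= cap:
            return
        if _score_rooted(tree, masks, full) > target:
            return
        if not remaining:
            if _score_rooted(tree, masks, full) == target:
                out.append(tree)
            return
        for t in _insertions(tree, remaining[0]):
            rec(t, remaining[1:])

    if len(leaves) == 1:
        return [leaves[0]]
    rec((leaves[0], leaves[1]), leaves[2:])
    return out


def _nni_moves(tree):
    """Nearest-neighbor interchanges on internal edges of a rooted tuple tree."""
    if not isinstance(tree, tuple):
        return
    l, r = tree
    if isinstance(l, tuple):
        yield ((l[0], r), l[1])
        yield ((l[1], r), l[0])
        for m in _nni_moves(l):
            yield (m, r)
    if isinstance(r, tuple):
        yield (r[0], (l, r[1]))
        yield (r[1], (l, r[0]))
        for m in _nni_moves(r):
            yield (l, m)


def _heuristic_search(leaves, masks, full, seed: int):
    rng = random.Random(seed)
    order = list(leaves)
    rng.shuffle(order)
    tree = (order[0], order[1]) if len(order) > 1 else order[0]
    for leaf in order[2:]:
        tree = min(_insertions(tree, leaf), key=lambda t: (_score_rooted(t, masks, full), repr(t)))
    best = _score_rooted(tree, masks, full)
    improved = True
    while improved:
        improved = False
        for cand in _nni_moves(tree):
            s = _score_rooted(cand, masks, full)
            if s < best:
                tree, best, improved = cand, s, True
                break
    return best, tree


def max_parsimony_tree(
    matrix: pd.DataFrame,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
    seed: int = 0,
) -> CloneTree:
    """Minimum-Fitch-score rooted clone tree over the event matrix rows.

    Exact (branch-and-bound over all rooted topologies) up to
    ``exhaustive_limit`` subclones, heuristic (seeded stepwise addition +
    NNI hill climbing) beyond. Deterministic for a fixed seed.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InvalidInputError("empty event matrix")
    taxa = sorted(matrix.index)
    masks, full = _leaf_masks(matrix)

    if len(taxa) <= exhaustive_limit:
        best, _ = _branch_and_bound(taxa, masks, full)
        candidates = _collect_optimal(taxa, masks, full, best)
    else:
        best, tree = _heuristic_search(taxa, masks, full, seed)
        candidates = [tree]

    scored = [(_tiebreak_key(t, matrix), t) for t in candidates]
    scored.sort(key=lambda x: x[0])
    return build_clone_tree(scored[0][1], matrix)


def _tiebreak_key(tree, matrix):
    ct = build_clone_tree(tree, matrix)
    n_internal = sum(1 for n in ct.nodes.values() if not n.subclones and n.name != NORMAL)
    clades = []
    for name, node in ct.nodes.items():
        if name == NORMAL:
            continue
        below = _subclones_below(ct, name)
        clades.append(tuple(sorted(below)))
    return (n_internal, tuple(sorted(clades)))


def _subclones_below(ct: CloneTree, name: str) -> list:
    out = list(ct.nodes[name].subclones)
    for c in ct.nodes[name].children:
        out.extend(_subclones_below(ct, c))
    return out


# ---------------------------------------------------------------------------
# backtrace and CloneTree construction
# ---------------------------------------------------------------------------

def build_clone_tree(tree_topology, matrix: pd.DataFrame) -> CloneTree:
    """Backtrace Fitch states onto a topology and collapse zero-length edges."""
    events = list(matrix.columns)
    masks, full = _leaf_masks(matrix)
    topo = _strip_normal(tree_topology)

    # bottom-up state sets
    sets: dict[int, tuple] = {}
    children: dict[int, list] = {}
    labels: dict[int, Optional[str]] = {}
    counter = itertools.count()

    def up(t):
        nid = next(counter)
        if isinstance(t, tuple):
            l, r = up(t[0]), up(t[1])
            children[nid] = [l, r]
            labels[nid] = None
            a1, b1 = sets[l][:2]
            a2, b2 = sets[r][:2]
            ia, ib = a1 & a2, b1 & b2
            empty = full & ~(ia | ib)
            sets[nid] = (ia | (empty & (a1 | a2)), ib | (empty & (b1 | b2)))
        else:
            children[nid] = []
            labels[nid] = t
            sets[nid] = masks[t]
        return nid

    top = up(topo)

    # top-down assignment; root (normal side) is all-zero, prefer the parent
    # state, else prefer presence (gains over losses)
    state: dict[int, int] = {}

    def down(nid, parent_state):
        a, b = sets[nid][:2]
        s = 0
        for c in range(len(events)):
            bit = 1 << c
            p = (parent_state >> c) & 1
            has0, has1 = bool(a & bit), bool(b & bit)
            if p == 0 and has0:
                v = 0
            elif p == 1 and has1:
                v = 1
            elif has1:
                v = 1
            else:
                v = 0
            s |= v << c
        state[nid] = s
        for ch in children[nid]:
            down(ch, s)

    down(top, 0)

    # build the raw rooted tree: normal -> top -> ...
    ct = CloneTree()
    ct.add_node(CloneNode(NORMAL, None, (), frozenset()))
    name_counter = itertools.count(1)

    def genotype(nid):
        return frozenset(events[c] for c in range(len(events)) if (state[nid] >> c) & 1)

    def changed(nid, parent_state):
        diff = state[nid] ^ parent_state
        return tuple(events[c] for c in range(len(events)) if (diff >> c) & 1)

    def build(nid, parent_name, parent_state):
        gt = genotype(nid)
        ev = changed(nid, parent_state)
        label = labels[nid]
        parent_node = ct.nodes[parent_name]
        if not ev and parent_name != NORMAL:
            # zero-length edge: collapse into the parent node
            if label is not None:
                parent_node.subclones = tuple(sorted(set(parent_node.subclones) | {label}))
            for ch in children[nid]:
                build(ch, parent_name, state[nid])
            return
        if label is not None:
            name = label
            subs = (label,)
        else:
            name = f"node{next(name_counter)}"
            subs = ()
        node = CloneNode(name, parent_name, ev, gt, subclones=subs)
        ct.add_node(node)
        for ch in children[nid]:
            build(ch, name, state[nid])

    build(top, NORMAL, 0)
    _suppress_unary(ct)
    return ct


def _suppress_unary(ct: CloneTree) -> None:
    """Merge internal nodes that have one child and host no subclone."""
    changed = True
    while changed:
        changed = False
        for name in list(ct.nodes):
            node = ct.nodes.get(name)
            if node is None or name == NORMAL:
                continue
            if not node.subclones and len(node.children) == 1:
                child = ct.nodes[node.children[0]]
                child.events = tuple(node.events) + tuple(child.events)
                child.parent = node.parent
                parent = ct.nodes[node.parent]
                parent.children[parent.children.index(name)] = child.name
                del ct.nodes[name]
                changed = True
                break


def annotate_tree(
    tree: CloneTree,
    metadata: dict,
    fractions: pd.DataFrame,
    detection_threshold: float = 0.05,
) -> CloneTree:
    """Attach per-sample detections (sample, site, class, fraction) to nodes.

    ``metadata`` maps sample_id -> (site, sample_class); ``fractions`` is the
    subclone x sample fraction table from deconvolution. A subclone is
    detected in a sample when its fraction reaches the threshold.
    """
    for sid in fractions.columns:
        if sid not in metadata:
            raise InvalidInputError(f"sample {sid} missing from metadata")
    for subclone_id, row in fractions.iterrows():
        try:
            node_name = tree.subclone_node(subclone_id)
        except InvalidInputError:
            continue
        node = tree.nodes[node_name]
        for sid, frac in row.items():
            if frac >= detection_threshold:
                site, cls = metadata[sid]
                node.detections.append(SampleDetection(sid, site, cls, float(frac)))
    return tree
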