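"""Maximum-parsimony clone trees: Fitch scoring, exact search, annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonespread import annotate_tree, fitch_score, max_parsimony_tree
from clonespread.errors import InvalidInputError


# --- independent small-parsimony oracle (set-based, enumerative) -----------

def _oracle_topologies(leaves):
    if len(leaves) == 1:
        yield leaves[0]
        return
    for sub in _oracle_topologies(leaves[:-1]):
        yield from _oracle_insert(sub, leaves[-1])


def _oracle_insert(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        for left in _oracle_insert(tree[0], leaf):
            yield (left, tree[1])
        for right in _oracle_insert(tree[1], leaf):
            yield (tree[0], right)


def _oracle_fitch(tree, states):
    """Bottom-up Fitch with python sets; returns (per-char sets, changes)."""
    if not isinstance(tree, tuple):
        return [{v} for v in states[tree]], 0
    ls, lc = _oracle_fitch(tree[0], states)
    rs, rc = _oracle_fitch(tree[1], states)
    out, changes = [], lc + rc
    for a, b in zip(ls, rs):
        inter = a & b
        if inter:
            out.append(inter)
        else:
            out.append(a | b)
            changes += 1
    return out, changes


def _oracle_min_score(matrix):
    states = {t: list(matrix.loc[t]) for t in matrix.index}
    best = None
    for topo in _oracle_topologies(list(matrix.index)):
        sets, changes = _oracle_fitch(topo, states)
        changes += sum(1 for s in sets if 0 not in s)  # normal root is all-zero
        best = changes if best is None else min(best, changes)
    return best


def _matrix(rows):
    events = sorted({e for evs in rows.values() for e in evs})
    return pd.DataFrame({e: [1 if e in rows[r] else 0 for r in rows] for e in events},
                        index=list(rows))


class TestFitchScore:
    def test_nested_chain(self):
        m = _matrix({"s1": set(), "s2": {"A"}, "s3": {"A", "B"}})
        assert fitch_score(("s1", ("s2", "s3")), m) == 2

    def test_single_subclone_stem_only(self):
        m = _matrix({"s1": {"A", "B", "C"}})
        assert fitch_score("s1", m) == 3

    def test_shared_event_joins_below_stem(self):
        m = _matrix({"s1": {"A", "B"}, "s2": {"A", "C"}})
        assert fitch_score(("s1", "s2"), m) == 3

    def test_leaf_mismatch_rejected(self):
        m = _matrix({"s1": {"A"}, "s2": {"B"}})
        with pytest.raises(InvalidInputError):
            fitch_score(("s1", "s3"), m)


class TestMaxParsimony:
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sub = int(rng.integers(3, 7))
        n_ev = int(rng.integers(4, 11))
        mat = pd.DataFrame(rng.integers(0, 2, size=(n_sub, n_ev)),
                           index=[f"s{i}" for i in range(n_sub)],
                           columns=[f"e{j}" for j in range(n_ev)])
        mat = mat.loc[:, mat.sum(axis=0) > 0]
        mat = mat[~mat.duplicated()]
        if mat.shape[1] == 0 or mat.shape[0] < 2:
            return
        tree = max_parsimony_tree(mat)
        assert tree.fitch_score_total() == _oracle_min_score(mat)

    def test_perfect_phylogeny_one_edge_per_event(self):
        m = _matrix({
            "s1": {"t1"},
            "s2": {"t1", "a1"},
            "s3": {"t1", "a1", "a2"},
            "s4": {"t1", "b1"},
        })
        tree = max_parsimony_tree(m)
        assert tree.fitch_score_total() == 4
        placed = [e for name in tree.nodes for e in tree.nodes[name].events]
        assert sorted(placed) == ["a1", "a2", "b1", "t1"]

    def test_stem_only_tree(self):
        m = _matrix({"s1": {"A", "B", "C"}})
        tree = max_parsimony_tree(m)
        assert tree.stem_length == 3
        assert tree.subclone_node("s1") is not None

    def test_duplicate_row_does_not_change_score(self):
        m = _matrix({"s1": {"A"}, "s2": {"A", "B"}, "s3": {"B", "C"}})
        base = max_parsimony_tree(m).fitch_score_total()
        m2 = pd.concat([m, m.loc[["s3"]].rename(index={"s3": "s3b"})])
        assert max_parsimony_tree(m2).fitch_score_total() == base

    def test_deterministic_newick(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.integers(0, 2, size=(5, 8)),
                           index=[f"s{i}" for i in range(5)],
                           columns=[f"e{j}" for j in range(8)])
        mat = mat.loc[:, mat.sum(axis=0) > 0]
        mat = mat[~mat.duplicated()]
        assert max_parsimony_tree(mat, seed=3).newick() == max_parsimony_tree(mat, seed=3).newick()

    def test_heuristic_mode_reaches_exact_optimum_on_clean_matrix(self):
        rows = {"s0": {"t"}}
        for i in range(1, 11):
            rows[f"s{i}"] = {"t", f"a{i}"}
        m = _matrix(rows)
        tree = max_parsimony_tree(m, exhaustive_limit=5, seed=1)
        assert tree.fitch_score_total() == 11

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            max_parsimony_tree(pd.DataFrame())

    def test_newick_parses_with_dendropy(self):
        m = _matrix({"s1": {"A"}, "s2": {"A", "B"}})
        t = max_parsimony_tree(m).to_dendropy()
        assert len(t.nodes()) >= 3  # normal root plus both subclone nodes


class TestAnnotateTree:
    def test_detections_attached_and_unknown_sample_rejected(self):
        m = _matrix({"s1": {"A"}, "s2": {"A", "B"}})
        tree = max_parsimony_tree(m)
        fractions = pd.DataFrame({"P1": [0.6, 0.4], "N1": [0.0, 0.9]},
                                 index=["s1", "s2"])
        meta = {"P1": ("P", "primary"), "N1": ("N", "lymph_node")}
        annotate_tree(tree, meta, fractions)
        node = tree.nodes[tree.subclone_node("s2")]
        assert {d.site for d in node.detections} == {"P", "N"}
        with pytest.raises(InvalidInputError):
            annotate_tree(tree, {"P1": ("P", "primary")}, fractions)

    def test_below_threshold_not_detected(self):
        m = _matrix({"s1": {"A"}, "s2": {"A", "B"}})
        tree = max_parsimony_tree(m)
        fractions = pd.DataFrame({"P1": [0.6, 0.04]}, index=["s1", "s2"])
        annotate_tree(tree, {"P1": ("P", "primary")}, fractions)
        assert tree.nodes[tree.subclone_node("s2")].detections == []
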