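"""Spread-mode classification, IGD, and cohort statistics."""

import pytest

from clonespread import (classify_patient, classify_phyletic, classify_timing,
                         cohort_grid, cohort_tests, detect_intermetastatic,
                         igd, primary_mrca, seeding_lineages)
from clonespread.errors import InvalidInputError, QualityWarning
from clonespread.tree import NORMAL, CloneNode, CloneTree, SampleDetection


def build_tree(edges, detections=None):
    """CloneTree from (parent, child, n_events) plus {node: [(sample, site, class, frac)]}."""
    t = CloneTree()
    t.add_node(CloneNode(NORMAL, None, (), frozenset()))
    counter = [0]

    def evs(n):
        out = tuple(f"ev{counter[0] + i}" for i in range(n))
        counter[0] += n
        return out

    for parent, child, n in edges:
        t.add_node(CloneNode(child, parent, evs(n), frozenset(), subclones=(child,)))
    for node, dets in (detections or {}).items():
        for sid, site, cls, frac in dets:
            t.nodes[node].detections.append(SampleDetection(sid, site, cls, frac))
    return t


@pytest.fixture
def earlier_tree():
    """Stem -> (primary trunk with two subclones, one metastatic lineage)."""
    return build_tree(
        [(NORMAL, "stem", 4), ("stem", "trunk", 2), ("trunk", "p2", 2),
         ("stem", "met", 3)],
        {
            "trunk": [("P1", "P", "primary", 0.6)],
            "p2": [("P1", "P", "primary", 0.4)],
            "met": [("M1a", "M1", "distant", 1.0)],
        },
    )


@pytest.fixture
def later_tree():
    """Metastasis descends from a primary-detected subclone below the MRCA."""
    return build_tree(
        [(NORMAL, "stem", 4), ("stem", "p1", 2), ("p1", "met", 2)],
        {
            "stem": [("P1", "P", "primary", 0.3)],
            "p1": [("P1", "P", "primary", 0.5)],
            "met": [("N1a", "N1", "lymph_node", 1.0)],
        },
    )


class TestIgd:
    def test_no_divergence_is_zero(self):
        t = build_tree([(NORMAL, "stem", 5), ("stem", "a", 2)])
        assert igd(t, ["stem"]) == 0.0

    def test_worked_example(self):
        t = build_tree([(NORMAL, "stem", 4), ("stem", "x", 0),
                        ("x", "a", 2), ("x", "b", 2)])
        assert igd(t, ["a", "b"]) == pytest.approx(1 / 3)

    def test_zero_stem_maximal_diversity(self):
        t = build_tree([(NORMAL, "a", 1), (NORMAL, "b", 1)])
        assert igd(t, ["a", "b"]) == 1.0

    def test_zero_stem_zero_divergence_flagged(self):
        t = build_tree([(NORMAL, "a", 1), (NORMAL, "b", 1)])
        with pytest.warns(QualityWarning):
            assert igd(t, ["a"]) == 0.0

    def test_empty_subset_rejected(self):
        t = build_tree([(NORMAL, "stem", 2)])
        with pytest.raises(InvalidInputError):
            igd(t, [])

    def test_decreasing_in_stem_length(self):
        short = build_tree([(NORMAL, "stem", 2), ("stem", "a", 2), ("stem", "b", 2)])
        long = build_tree([(NORMAL, "stem", 8), ("stem", "a", 2), ("stem", "b", 2)])
        assert igd(short, ["a", "b"]) > igd(long, ["a", "b"])


class TestPrimaryMrca:
    def test_chain(self, later_tree):
        assert primary_mrca(later_tree) == "stem"

    def test_two_branches_join(self, earlier_tree):
        assert primary_mrca(earlier_tree) == "trunk"

    def test_single_primary_subclone_is_itself(self):
        t = build_tree([(NORMAL, "stem", 3), ("stem", "a", 1)],
                       {"a": [("P1", "P", "primary", 0.9)]})
        assert primary_mrca(t) == "a"

    def test_no_primary_samples_rejected(self):
        t = build_tree([(NORMAL, "stem", 3)],
                       {"stem": [("M1a", "M1", "distant", 1.0)]})
        with pytest.raises(InvalidInputError):
            primary_mrca(t)


class TestTiming:
    def test_stem_attachment_above_mrca_is_earlier(self, earlier_tree):
        assert classify_timing(earlier_tree, "M1") == "earlier"

    def test_descent_from_primary_subclone_is_later(self, later_tree):
        assert classify_timing(later_tree, "N1") == "later"

    def test_mixed_lineages_are_both(self):
        t = build_tree(
            [(NORMAL, "stem", 3), ("stem", "trunk", 2), ("trunk", "p2", 1),
             ("stem", "met1", 2), ("p2", "met2", 2)],
            {
                "trunk": [("P1", "P", "primary", 0.5)],
                "p2": [("P1", "P", "primary", 0.4)],
                "met1": [("M1a", "M1", "distant", 0.5)],
                "met2": [("M1a", "M1", "distant", 0.5)],
            },
        )
        assert classify_timing(t, "M1") == "both"

    def test_attachment_exactly_at_mrca_is_later(self):
        t = build_tree(
            [(NORMAL, "stem", 3), ("stem", "met", 2)],
            {"stem": [("P1", "P", "primary", 1.0)],
             "met": [("M1a", "M1", "distant", 1.0)]},
        )
        assert classify_timing(t, "M1") == "later"


class TestClonalityAndPhyletic:
    def test_ancestral_pair_is_one_lineage(self):
        t = build_tree(
            [(NORMAL, "stem", 3), ("stem", "m1", 2), ("m1", "m2", 1)],
            {"m1": [("M1a", "M1", "distant", 0.5)],
             "m2": [("M1a", "M1", "distant", 0.4)]},
        )
        assert seeding_lineages(t, "M1") == ["m1"]

    def test_disjoint_pair_is_polyclonal(self):
        t = build_tree(
            [(NORMAL, "stem", 3), ("stem", "m1", 2), ("stem", "m2", 1)],
            {"m1": [("M1a", "M1", "distant", 0.5)],
             "m2": [("M1a", "M1", "distant", 0.4)]},
        )
        assert seeding_lineages(t, "M1") == ["m1", "m2"]
        assert classify_phyletic(t, ["M1"]) == "polyphyletic"

    def test_single_metastasis_is_monophyletic(self, earlier_tree):
        assert classify_phyletic(earlier_tree, ["M1"]) == "monophyletic"

    def test_stepwise_sites_on_one_branch_are_monophyletic(self):
        t = build_tree(
            [(NORMAL, "stem", 3), ("stem", "m1", 2), ("m1", "m2", 2)],
            {"m1": [("M1a", "M1", "distant", 1.0)],
             "m2": [("M2a", "M2", "lymph_node", 1.0)]},
        )
        assert classify_phyletic(t, ["M1", "M2"]) == "monophyletic"


class TestIntermetastatic:
    def test_directed_edge_via_private_ancestor(self):
        t = build_tree(
            [(NORMAL, "stem", 3), ("stem", "lung", 2), ("lung", "brain", 2)],
            {"lung": [("L1", "lung", "distant", 1.0)],
             "brain": [("B1", "brain", "distant", 1.0)]},
        )
        edges = detect_intermetastatic(t, ["lung", "brain"])
        assert edges == [("lung", "brain", ("lung",), True)]

    def test_shared_subclone_without_private_ancestor_is_unresolved(self):
        t = build_tree(
            [(NORMAL, "stem", 3), ("stem", "m", 2)],
            {"m": [("A1", "A", "distant", 1.0), ("B1", "B", "distant", 1.0)]},
        )
        edges = detect_intermetastatic(t, ["A", "B"])
        assert {(a, b, r) for a, b, _, r in edges} == {("A", "B", False), ("B", "A", False)}

    def test_primary_shared_ancestors_give_no_edge(self):
        t = build_tree(
            [(NORMAL, "stem", 3), ("stem", "m1", 2), ("stem", "m2", 2)],
            {
                "stem": [("P1", "P", "primary", 1.0)],
                "m1": [("A1", "A", "distant", 1.0)],
                "m2": [("B1", "B", "distant", 1.0)],
            },
        )
        assert detect_intermetastatic(t, ["A", "B"]) == []

    def test_single_site_not_evaluable(self, earlier_tree):
        with pytest.raises(InvalidInputError):
            detect_intermetastatic(earlier_tree, ["M1"])


class TestReports:
    def test_classify_patient_flags(self, earlier_tree):
        rep = classify_patient(earlier_tree, patient_id="X")
        assert rep.has_earlier is True
        assert rep.has_polyclonal is False
        assert rep.phyletic == "monophyletic"
        assert rep.has_intermetastatic is None  # single metastatic site
        assert "class:primary" in rep.igd

    def test_grid_states(self, earlier_tree, later_tree):
        reports = [classify_patient(earlier_tree, "A"), classify_patient(later_tree, "B")]
        grid = cohort_grid(reports)
        assert grid.loc["earlier", "A"] == "present"
        assert grid.loc["earlier", "B"] == "absent"
        assert grid.loc["intermetastatic", "A"] == "not_evaluable"

    def test_report_roundtrips_to_dict(self, earlier_tree):
        d = classify_patient(earlier_tree, "X").to_dict()
        assert d["patient_id"] == "X"
        assert d["sites"]["M1"]["timing"] == "earlier"


class TestCohortTests:
    def test_identical_groups_not_significant(self):
        rep = cohort_tests({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        mw = rep["mann_whitney"]["a_vs_b"]
        assert mw["evaluable"] and not mw["significant"]

    def test_paired_zero_differences(self):
        rep = cohort_tests({}, paired=("x", "y", [0.3, 0.5, 0.7], [0.3, 0.5, 0.7]))
        assert rep["paired_t"] == {"evaluable": True, "t": 0.0, "p": 1.0,
                                   "significant": False, "labels": ["x", "y"]}

    def test_exact_u_statistic_and_pvalue(self):
        rep = cohort_tests({"a": [1, 2, 3], "b": [4, 5, 6]})
        mw = rep["mann_whitney"]["a_vs_b"]
        assert mw["U"] == 0.0
        assert mw["p"] == pytest.approx(0.1)  # exact two-sided rank enumeration

    def test_undersized_group_not_evaluable(self):
        rep = cohort_tests({"a": [1], "b": [2, 3]})
        assert rep["mann_whitney"]["a_vs_b"] == {"evaluable": False}
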