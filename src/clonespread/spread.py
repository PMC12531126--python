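"""Metastatic spread-mode classification and genomic diversity.

Given an annotated clone tree (per-node sample/site detections), classifies a
patient's pattern of metastatic dissemination:

* **timing** — a seeding lineage is *earlier* when it diverged from the
  primary-tumor lineage strictly above the most recent common ancestor (MRCA)
  of the subclones detected in the primary tumor, *later* otherwise (a
  lineage attaching exactly at the primary MRCA counts as later);
* **clonality** per metastatic site — *monoclonal* when a single lineage
  seeds the site, *polyclonal* when two or more independent lineages do;
* **phyletic pattern** patient-wide — *monophyletic* when every seeding
  lineage attaches along a single root-to-leaf branch path, *polyphyletic*
  otherwise;
* **intermetastatic spread** — an edge A -> B when a subclone detected at
  metastatic site A but never in the primary has itself or a descendant
  detected at site B; direction requires a source-private ancestor, otherwise
  the link is reported unresolved in both orientations.

The index of genomic diversity (IGD) of a set of subclones is
sum(d_i) / (sum(d_i) + l*N) where d_i is the event-count distance from the
set's closest common node to subclone i, l is the stem length and N the
number of subclones; it is 0 for a clonally homogeneous site and grows toward
1 as within-site divergence outweighs the truncal stem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .errors import InvalidInputError, QualityWarning
from .tree import CloneTree

METASTATIC_CLASSES = ("lymph_node", "distant", "relapse")


@dataclass
class SiteCall:
    site: str
    timing: str  # earlier | later | both
    n_seeding_lineages: int
    clonality: str  # monoclonal | polyclonal
    lineage_roots: list = field(default_factory=list)


@dataclass
class SpreadReport:
    patient_id: str
    sites: dict = field(default_factory=dict)  # site -> SiteCall
    phyletic: Optional[str] = None  # monophyletic | polyphyletic
    intermetastatic_edges: list = field(default_factory=list)  # (src, dst, mediators, resolved)
    intermetastatic_evaluable: bool = True
    timing_evaluable: bool = True
    igd: dict = field(default_factory=dict)  # label -> IGD value
    flags: list = field(default_factory=list)

    @property
    def has_earlier(self) -> Optional[bool]:
        if not self.timing_evaluable or not self.sites:
            return None
        return any(c.timing in ("earlier", "both") for c in self.sites.values())

    @property
    def has_polyclonal(self) -> Optional[bool]:
        if not self.sites:
            return None
        return any(c.clonality == "polyclonal" for c in self.sites.values())

    @property
    def has_intermetastatic(self) -> Optional[bool]:
        if not self.intermetastatic_evaluable:
            return None
        return bool(self.intermetastatic_edges)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "sites": {
                s: {
                    "timing": c.timing,
                    "n_seeding_lineages": c.n_seeding_lineages,
                    "clonality": c.clonality,
                    "lineage_roots": c.lineage_roots,
                }
                for s, c in self.sites.items()
            },
            "phyletic": self.phyletic,
            "intermetastatic_edges": [
                {"source": a, "target": b, "mediators": list(m), "resolved": r}
                for a, b, m, r in self.intermetastatic_edges
            ],
            "intermetastatic_evaluable": self.intermetastatic_evaluable,
            "timing_evaluable": self.timing_evaluable,
            "igd": self.igd,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# detection helpers
# ---------------------------------------------------------------------------

def detected_nodes(tree: CloneTree, site: Optional[str] = None,
                   sample_class: Optional[str] = None) -> list[str]:
    """Nodes with a detection matching the site and/or sample class."""
    out = []
    for name, node in tree.nodes.items():
        for det in node.detections:
            if site is not None and det.site != site:
                continue
            if sample_class is not None and det.sample_class != sample_class:
                continue
            out.append(name)
            break
    return sorted(out)


def metastatic_sites(tree: CloneTree, count_relapse: bool = True) -> list[str]:
    """Distinct non-primary anatomical sites with at least one detected subclone."""
    sites = {}
    for node in tree.nodes.values():
        for det in node.detections:
            if det.sample_class == "primary":
                continue
            if det.sample_class == "relapse" and not count_relapse:
                continue
            sites[det.site] = True
    primary_sites = {det.site for node in tree.nodes.values() for det in node.detections
                     if det.sample_class == "primary"}
    return sorted(s for s in sites if s not in primary_sites)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def igd(tree: CloneTree, subclone_nodes: Iterable[str]) -> float:
    """Index of genomic diversity of a set of subclone nodes."""
    nodes = sorted(set(subclone_nodes))
    if not nodes:
        raise InvalidInputError("igd requires a nonempty subclone set")
    common = tree.mrca(nodes)
    dists = [tree.path_length(common, n) for n in nodes]
    total_d = sum(dists)
    l = tree.stem_length
    n = len(nodes)
    if total_d == 0:
        if l == 0:
            warnings.warn("IGD undefined: zero stem and zero divergence; returning 0",
                          QualityWarning, stacklevel=2)
        return 0.0
    return total_d / (total_d + l * n)


def primary_mrca(tree: CloneTree) -> str:
    """Deepest node ancestral to every subclone detected in a primary sample."""
    prim = detected_nodes(tree, sample_class="primary")
    if not prim:
        raise InvalidInputError("no subclone detected in any primary sample")
    return tree.mrca(prim)


def seeding_lineages(tree: CloneTree, site: str) -> list[str]:
    """Roots of the maximal site-detected subtrees (independent seeding lineages)."""
    at_site = detected_nodes(tree, site=site)
    if not at_site:
        return []
    site_set = set(at_site)
    return sorted(u for u in at_site
                  if not any(a in site_set for a in tree.ancestors(u)))


def _divergence_node(tree: CloneTree, lineage_root: str, primary_set: set) -> Optional[str]:
    """Deepest ancestor-or-self of the lineage root that leads to a primary subclone."""
    for node in [lineage_root] + tree.ancestors(lineage_root):
        if any(tree.is_ancestor_or_self(node, p) for p in primary_set):
            return node
    return None


def classify_timing(tree: CloneTree, site: str) -> str:
    """earlier / later / both for the seeding of one metastatic site.

    A lineage is earlier iff its divergence from the primary-detected lineage
    set is a strict ancestor of the primary MRCA (divergence exactly at the
    MRCA counts as later).
    """
    mrca_p = primary_mrca(tree)
    primary_set = set(detected_nodes(tree, sample_class="primary"))
    labels = set()
    for root in seeding_lineages(tree, site):
        div = _divergence_node(tree, root, primary_set)
        if div is not None and tree.is_ancestor(div, mrca_p):
            labels.add("earlier")
        else:
            labels.add("later")
    if labels == {"earlier", "later"}:
        return "both"
    return labels.pop() if labels else "later"


def classify_phyletic(tree: CloneTree, sites: Iterable[str]) -> str:
    """monophyletic iff all seeding-lineage attachments lie on one branch path."""
    roots = []
    for site in sites:
        roots.extend(seeding_lineages(tree, site))
    roots = sorted(set(roots))
    if len(roots) <= 1:
        return "monophyletic"
    for i, a in enumerate(roots):
        for b in roots[i + 1:]:
            if not (tree.is_ancestor_or_self(a, b) or tree.is_ancestor_or_self(b, a)):
                return "polyphyletic"
    return "monophyletic"


def detect_intermetastatic(tree: CloneTree, sites: Iterable[str]) -> list[tuple]:
    """Edges of spread between metastatic sites.

    Returns tuples ``(source, target, mediator_nodes, resolved)``. A directed,
    resolved edge requires a source-private non-primary subclone with a strict
    descendant at the target; a subclone shared by both sites without such a
    private ancestor yields an unresolved edge in both orientations.
    """
    sites = sorted(set(sites))
    if len(sites) < 2:
        raise InvalidInputError("intermetastatic spread needs >= 2 distinct metastatic sites")
    primary_set = set(detected_nodes(tree, sample_class="primary"))
    at = {s: set(detected_nodes(tree, site=s)) for s in sites}

    edges = []
    unresolved_pairs = set()
    for a in sites:
        for b in sites:
            if a == b:
                continue
            mediators = []
            for c in sorted(at[a] - primary_set - at[b]):
                if any(tree.is_ancestor(c, d) for d in at[b]):
                    mediators.append(c)
            if mediators:
                edges.append((a, b, tuple(mediators), True))
            else:
                shared = sorted((at[a] & at[b]) - primary_set)
                if shared and a < b:
                    unresolved_pairs.add((a, b, tuple(shared)))
    directed = {(a, b) for a, b, _, _ in edges}
    for a, b, shared in sorted(unresolved_pairs):
        if (a, b) not in directed and (b, a) not in directed:
            edges.append((a, b, shared, False))
            edges.append((b, a, shared, False))
    return sorted(edges)


# ---------------------------------------------------------------------------
# per-patient report
# ---------------------------------------------------------------------------

def classify_patient(tree: CloneTree, patient_id: str = "",
                     count_relapse: bool = True) -> SpreadReport:
    """Full spread-mode classification of one patient from an annotated tree."""
    report = SpreadReport(patient_id=patient_id)
    mets = metastatic_sites(tree, count_relapse=count_relapse)
    try:
        primary_mrca(tree)
        timing_ok = True
    except InvalidInputError:
        timing_ok = False
        report.timing_evaluable = False
        report.flags.append("no primary sample; timing not evaluable")

    for site in mets:
        lineages = seeding_lineages(tree, site)
        if not lineages:
            continue
        timing = classify_timing(tree, site) if timing_ok else "not_evaluable"
        report.sites[site] = SiteCall(
            site=site,
            timing=timing,
            n_seeding_lineages=len(lineages),
            clonality="polyclonal" if len(lineages) >= 2 else "monoclonal",
            lineage_roots=lineages,
        )

    report.phyletic = classify_phyletic(tree, mets) if mets else None

    if len(mets) >= 2:
        report.intermetastatic_edges = detect_intermetastatic(tree, mets)
        report.intermetastatic_evaluable = True
    else:
        report.intermetastatic_evaluable = False

    # IGD per anatomical site and per sample class
    for site in sorted({d.site for n in tree.nodes.values() for d in n.detections}):
        nodes = detected_nodes(tree, site=site)
        if nodes:
            report.igd[f"site:{site}"] = igd(tree, nodes)
    for cls in ("primary",) + METASTATIC_CLASSES:
        nodes = detected_nodes(tree, sample_class=cls)
        if nodes:
            report.igd[f"class:{cls}"] = igd(tree, nodes)
    return report


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def cohort_tests(groups: dict, paired: Optional[tuple] = None) -> dict:
    """Cohort-level significance tests.

    ``groups`` maps label -> list of values; every unordered pair of groups
    is compared with a two-sided Mann-Whitney U test. ``paired`` may be a
    tuple (label_a, label_b, values_a, values_b) of matched per-patient
    values, compared with a paired t test. Significance is p < 0.05.
    """
    report = {"mann_whitney": {}, "paired_t": None}
    labels = sorted(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa, xb = list(groups[a]), list(groups[b])
            if len(xa) < 2 or len(xb) < 2:
                report["mann_whitney"][f"{a}_vs_{b}"] = {"evaluable": False}
                continue
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            report["mann_whitney"][f"{a}_vs_{b}"] = {
                "evaluable": True,
                "U": float(res.statistic),
                "p": float(res.pvalue),
                "significant": bool(res.pvalue < 0.05),
            }
    if paired is not None:
        la, lb, xa, xb = paired
        if len(xa) != len(xb) or len(xa) < 2:
            report["paired_t"] = {"evaluable": False}
        else:
            diffs = np.asarray(xa, dtype=float) - np.asarray(xb, dtype=float)
            if np.allclose(diffs, 0):
                report["paired_t"] = {"evaluable": True, "t": 0.0, "p": 1.0,
                                      "significant": False, "labels": [la, lb]}
            else:
                res = stats.ttest_rel(xa, xb)
                report["paired_t"] = {
                    "evaluable": True,
                    "t": float(res.statistic),
                    "p": float(res.pvalue),
                    "significant": bool(res.pvalue < 0.05),
                    "labels": [la, lb],
                }
    return report


def cohort_grid(reports: Iterable[SpreadReport]) -> "pd.DataFrame":
    """Presence/absence/not-evaluable grid: spread modes x patients."""
    import pandas as pd

    def cell(value):
        if value is None:
            return "not_evaluable"
        return "present" if value else "absent"

    cols = {}
    for r in reports:
        poly = None if r.phyletic is None else (r.phyletic == "polyphyletic")
        cols[r.patient_id] = {
            "earlier": cell(r.has_earlier),
            "polyclonal": cell(r.has_polyclonal),
            "polyphyletic": cell(poly),
            "intermetastatic": cell(r.has_intermetastatic),
        }
    return pd.DataFrame(cols)
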