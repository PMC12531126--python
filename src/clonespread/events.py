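"""Patient-level event merging and subclonal deconvolution.

Alterations quantified per sample are merged into patient-level *events*
(same-kind copy-number footprints with high reciprocal overlap across
samples; point mutations by exact locus). Events are then grouped into
clusters that share a clone-fraction profile across samples, and the clusters
are arranged into a nesting forest of subclones using pigeonhole constraints
on the mutated clone fractions:

* two clusters whose fractions sum to more than 1 (+ tolerance) in any sample
  must overlap, and under the infinite-sites view overlap means nesting;
* a cluster can only nest inside a cluster whose fraction is at least as
  large (within tolerance) in every sample;
* clusters whose profiles agree within tolerance in every sample, with
  co-occurrence evidence (forced overlap somewhere, or joint presence in at
  least two samples), are the same subclone;
* remaining nested-versus-disjoint ambiguities default to disjoint and are
  flagged.

The output is the set of subclones (cumulative event sets along each nesting
chain) with per-sample fractions, and the binary subclone-by-event incidence
matrix used for phylogenetic reconstruction.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import AmbiguityError, DeconvolutionConflictError, InvalidInputError
from .genome import CANONICAL_CHROMS
from .segments import SegmentCall

#: An event below this MCF in a sample is treated as absent there.
DETECTION_THRESHOLD = 0.05
#: Default clone-fraction tolerance for clustering and nesting decisions.
MCF_TOLERANCE = 0.1
#: Default reciprocal-overlap threshold for merging copy-number footprints.
RECIPROCAL_OVERLAP = 0.9

_CHROM_ORDER = {c: i for i, c in enumerate(CANONICAL_CHROMS)}


@dataclass
class EventRecord:
    """One patient-level event with its per-sample clone fractions."""

    event_id: str
    kind: str  # gain | loss | cnni | snv
    chrom: str
    start: int
    end: int
    mcf: dict = field(default_factory=dict)  # sample_id -> MCF (0 when absent)
    clonal: dict = field(default_factory=dict)  # sample_id -> bool
    sd: dict = field(default_factory=dict)  # sample_id -> measurement SD of the MCF
    present: dict = field(default_factory=dict)  # sample_id -> curated presence (a row exists)

    def sort_key(self):
        return (_CHROM_ORDER.get(self.chrom, 99), self.start, self.end, self.kind, self.event_id)


@dataclass
class EventTable:
    patient_id: str
    events: list  # list[EventRecord]
    samples: list  # sample ids, stable order

    def mcf_frame(self) -> pd.DataFrame:
        """events x samples MCF matrix (0 = absent)."""
        data = {e.event_id: [e.mcf.get(s, 0.0) for s in self.samples] for e in self.events}
        return pd.DataFrame(data, index=self.samples).T


@dataclass
class Subclone:
    subclone_id: str
    events: frozenset
    fractions: dict = field(default_factory=dict)  # sample_id -> fraction of tumor cells
    ambiguous: bool = False


@dataclass
class EventMatrix:
    """Binary subclone x event incidence with per-sample subclone fractions."""

    matrix: pd.DataFrame  # rows subclone ids, columns event ids, values 0/1
    fractions: pd.DataFrame  # rows subclone ids, columns sample ids
    conflicts: list = field(default_factory=list)

    def __post_init__(self):
        if self.matrix.duplicated().any():
            raise InvalidInputError("event matrix has duplicate subclone rows")
        if ((self.matrix.sum(axis=0) == 0).any()):
            raise InvalidInputError("event matrix has an all-zero event column")


# ---------------------------------------------------------------------------
# event merging
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: SegmentCall, b: SegmentCall) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.size, inter / b.size)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_events(
    segments: Iterable[SegmentCall],
    reciprocal_overlap: float = RECIPROCAL_OVERLAP,
    detection_threshold: float = DETECTION_THRESHOLD,
    mcf_sd: Optional[dict] = None,
) -> EventTable:
    """Merge per-sample alterations of one patient into patient-level events.

    Copy-number alterations of the same kind merge when their footprints
    reciprocally overlap at least ``reciprocal_overlap``; SNVs merge by exact
    locus (chrom, pos, ref, alt — carried in ``gene``/``hgvs``). The merged
    footprint is the bounding interval of the member rows. ``mcf_sd`` may map
    (sample_id, kind) -> measurement SD to propagate onto the events.
    """
    segs = [s for s in segments if s.mcf is not None]
    if not segs:
        raise InvalidInputError("no quantified segments supplied")
    patients = {s.patient_id for s in segs}
    if len(patients) != 1:
        raise InvalidInputError(f"segments span multiple patients: {sorted(patients)}")
    patient_id = segs[0].patient_id
    samples = sorted({s.sample_id for s in segs})

    segs = sorted(segs, key=lambda s: (_CHROM_ORDER.get(s.chrom, 99), s.start, s.end, s.alteration_type, s.sample_id))
    uf = _UnionFind(len(segs))
    for i, a in enumerate(segs):
        for j in range(i + 1, len(segs)):
            b = segs[j]
            if b.chrom != a.chrom or b.start > a.end:
                break
            if a.alteration_type != b.alteration_type or a.alteration_type == "snv":
                continue
            if _reciprocal_overlap(a, b) >= reciprocal_overlap:
                uf.union(i, j)
    # SNVs: exact locus key
    snv_key: dict[tuple, int] = {}
    for i, s in enumerate(segs):
        if s.alteration_type == "snv":
            key = (s.chrom, s.start, s.hgvs or "")
            if key in snv_key:
                uf.union(snv_key[key], i)
            else:
                snv_key[key] = i

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(segs)):
        groups[uf.find(i)].append(i)

    events: list[EventRecord] = []
    for root in sorted(groups):
        members = [segs[i] for i in groups[root]]
        kinds = {m.alteration_type for m in members}
        if len(kinds) != 1:  # cannot happen via the merge rules above; guard anyway
            raise AmbiguityError(f"conflicting kinds in merged event: {[m.alteration_type for m in members]}")
        kind = kinds.pop()
        chrom = members[0].chrom
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        ev = EventRecord(event_id="", kind=kind, chrom=chrom, start=start, end=end)
        per_sample: dict[str, list[SegmentCall]] = defaultdict(list)
        for m in members:
            per_sample[m.sample_id].append(m)
        for sid, rows in per_sample.items():
            vals = [r.mcf for r in rows]
            if max(vals) - min(vals) > 1e-6:
                raise AmbiguityError(
                    f"sample {sid} contributes conflicting MCFs {vals} to one event "
                    f"({kind} {chrom}:{start}-{end})"
                )
            ev.mcf[sid] = vals[0]
            ev.present[sid] = True
            ev.clonal[sid] = bool(rows[0].is_clonal)
            if rows[0].mcf_sd is not None:
                ev.sd[sid] = 0.0 if ev.clonal[sid] else rows[0].mcf_sd
            elif mcf_sd:
                ev.sd[sid] = mcf_sd.get((sid, kind), mcf_sd.get(kind, 0.0))
        if any(v >= detection_threshold for v in ev.mcf.values()):
            events.append(ev)

    events.sort(key=EventRecord.sort_key)
    seen = defaultdict(int)
    for ev in events:
        base = f"{ev.kind}_{ev.chrom}_{ev.start}"
        seen[base] += 1
        ev.event_id = base if seen[base] == 1 else f"{base}_{seen[base]}"
    return EventTable(patient_id=patient_id, events=events, samples=samples)


# ---------------------------------------------------------------------------
# single-sample deconvolution
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    events: list  # event ids
    fractions: dict  # sample -> cluster fraction
    children: list = field(default_factory=list)
    parent: object = None
    ambiguous: bool = False

    def frac(self, s):
        return self.fractions.get(s, 0.0)


def deconvolve_sample(
    events: EventTable,
    sample_id: str,
    mcf_tolerance: float = MCF_TOLERANCE,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> list[Subclone]:
    """Infer subclones in one sample from event MCFs.

    Events are clustered by MCF; clusters are nested by the pigeonhole
    principle (two clusters summing above 1 + tolerance must be nested; a
    clonal cluster hosts everything). Ambiguous disjoint-versus-nested pairs
    default to disjoint with a flag. Returns subclones with cumulative event
    sets; fractions sum to <= 1 (+ tolerance).
    """
    tol = mcf_tolerance
    present = [(e, e.mcf.get(sample_id, 0.0)) for e in events.events]
    present = [(e, m) for e, m in present if m >= detection_threshold]
    if not present:
        return []

    clonal = [e for e, m in present if e.clonal.get(sample_id, False) or m >= 1.0 - 1e-9]
    clonal_ids = {id(e) for e in clonal}
    rest = [(e, m) for e, m in present if id(e) not in clonal_ids]

    # cluster the non-clonal events: same cluster iff close AND forced to co-occur
    uf = _UnionFind(len(rest))
    for i, (ei, mi) in enumerate(rest):
        for j in range(i + 1, len(rest)):
            ej, mj = rest[j]
            if abs(mi - mj) <= tol and mi + mj > 1.0 + tol:
                uf.union(i, j)
    cl_members: dict[int, list[int]] = defaultdict(list)
    for i in range(len(rest)):
        cl_members[uf.find(i)].append(i)
    clusters = []
    for root in sorted(cl_members):
        idx = cl_members[root]
        evs = sorted((rest[i][0] for i in idx), key=EventRecord.sort_key)
        f = float(np.mean([rest[i][1] for i in idx]))
        clusters.append(_Node(events=[e.event_id for e in evs], fractions={sample_id: f}))

    root = _Node(events=[], fractions={sample_id: 1.0})
    if clonal:
        root.events = [e.event_id for e in sorted(clonal, key=EventRecord.sort_key)]
    # place clusters from largest fraction down
    clusters.sort(key=lambda c: (-c.frac(sample_id), c.events[0]))
    for c in clusters:
        _place_single(c, root, sample_id, tol)

    return _forest_to_subclones(root, [sample_id], detection_threshold,
                                include_root=bool(clonal))


def _place_single(c: _Node, parent: _Node, s: str, tol: float) -> None:
    siblings = parent.children
    hosts = [n for n in siblings if n.frac(s) + tol >= c.frac(s)]
    forced = [n for n in hosts if n.frac(s) + c.frac(s) > 1.0 + tol]
    level_total = sum(n.frac(s) for n in siblings) + c.frac(s)
    capacity = parent.frac(s)
    if forced:
        host = max(forced, key=lambda n: (n.frac(s), n.events and n.events[0]))
        if len(forced) > 1:
            c.ambiguous = True
        _place_single(c, host, s, tol)
        return
    if level_total > capacity + tol:
        if not hosts:
            raise DeconvolutionConflictError(
                f"clusters total {level_total:.3f} exceed capacity {capacity:.3f} in sample {s} "
                "and no nesting is possible",
                clusters=[(n.events, n.frac(s)) for n in siblings] + [(c.events, c.frac(s))],
            )
        host = max(hosts, key=lambda n: (n.frac(s), n.events and n.events[0]))
        c.ambiguous = len(hosts) > 1
        _place_single(c, host, s, tol)
        return
    if hosts:
        c.ambiguous = True  # nested reading also possible; default disjoint
    c.parent = parent
    siblings.append(c)


def _forest_to_subclones(root: _Node, samples: list, detection_threshold: float,
                         include_root: bool = True) -> list[Subclone]:
    """Subclones (cumulative event sets) with per-sample clone fractions.

    A node's fraction is its cluster fraction minus its children's; residual
    fractions within the propagated measurement noise are zeroed (they are
    noise, not a detection), and a sample whose fractions total above 1 is
    rescaled onto the simplex (clone fractions cannot exceed the tumor)."""
    nodes, cum_sets = [], {}

    def visit(node, inherited):
        cum = inherited | set(node.events)
        cum_sets[id(node)] = cum
        nodes.append(node)
        for ch in sorted(node.children, key=lambda n: (n.events and n.events[0]) or ""):
            visit(ch, cum)

    visit(root, set())

    phi = {id(n): {} for n in nodes}
    for s in samples:
        for n in nodes:
            f = n.frac(s) - sum(ch.frac(s) for ch in n.children)
            sd_phi = math.sqrt(_node_sd(n, s) ** 2
                               + sum(_node_sd(ch, s) ** 2 for ch in n.children))
            if f < max(1e-9, 2.5 * sd_phi):
                f = 0.0
            phi[id(n)][s] = max(0.0, f)
        total = sum(phi[id(n)][s] for n in nodes if n is not root or include_root)
        if total > 1.0:
            for n in nodes:
                phi[id(n)][s] /= total

    out = []
    for node in nodes:
        if node is root and not include_root:
            continue
        out.append(Subclone("", frozenset(cum_sets[id(node)]), phi[id(node)], node.ambiguous))
    out = [sc for sc in out if sc.events and max(sc.fractions.values(), default=0.0) >= detection_threshold]
    for i, sc in enumerate(sorted(out, key=lambda sc: (len(sc.events), sorted(sc.events)))):
        sc.subclone_id = f"SC{i + 1}"
    return sorted(out, key=lambda sc: sc.subclone_id)


# ---------------------------------------------------------------------------
# multi-sample reconciliation
# ---------------------------------------------------------------------------

#: Merge thresholds for the normalized squared profile distance: the mean
#: over co-present samples and the single worst sample both must pass.
CLUSTER_D_MEAN_MAX = 2.0
CLUSTER_D_SAMPLE_MAX = 7.0
#: After trimming one noisy outlier sample, a re-absorbed edge fragment must
#: match its parent nearly exactly.
ABSORB_D_MEAN_MAX = 1.2
ABSORB_D_SAMPLE_MAX = 5.0
#: An SNV cluster may be absent where a partner cluster is below this MCF
#: (the tumor-VAF floor makes low-fraction SNV absence uninformative).
SNV_PRESENCE_LIMIT = 0.25


class _Cluster:
    """A group of events sharing a cross-sample MCF profile."""

    def __init__(self, events_, samples):
        self.members = list(events_)  # list[EventRecord]
        self.samples = samples
        self.refresh()

    def refresh(self):
        self.f, self.var, self._present = {}, {}, {}
        def pres(e, s):
            return e.present.get(s, e.mcf.get(s, 0.0) > 0)

        for s in self.samples:
            vals = [e.mcf.get(s, 0.0) for e in self.members if pres(e, s)]
            if vals:
                self.f[s] = float(np.mean(vals))
                sds = [e.sd.get(s, 0.0) for e in self.members if pres(e, s)]
                mean_sq = float(np.mean([v ** 2 for v in sds]))
                # averaging shrinks independent noise but not the shared
                # purity-calibration error; keep a floor for the latter
                self.var[s] = mean_sq / len(vals) + 0.25 * mean_sq
                self._present[s] = True
            else:
                self.f[s] = 0.0
                self.var[s] = 0.0
                self._present[s] = False
        self.all_snv = all(e.kind == "snv" for e in self.members)

    def present(self, s):
        return self._present[s]


def _cluster_distance(g: _Cluster, h: _Cluster, tol: float) -> float:
    """Normalized squared profile difference over co-present samples.

    Returns inf when the (curated) presence patterns are inconsistent, when
    co-occurrence evidence is lacking, or when any single sample separates
    the profiles decisively; otherwise the mean normalized squared
    difference, which must also pass its own threshold to allow a merge.
    """
    copresent, terms = [], []
    vfloor = (tol / 2.0) ** 2
    for s in g.samples:
        pg, ph = g.present(s), h.present(s)
        if pg and ph:
            copresent.append(s)
            d = g.f[s] - h.f[s]
            terms.append(d * d / (g.var[s] + h.var[s] + 2 * vfloor))
        elif pg != ph:
            absent, present_side = (h, g) if pg else (g, h)
            if not (absent.all_snv and present_side.f[s] <= SNV_PRESENCE_LIMIT):
                return math.inf
    if not copresent:
        return math.inf
    forced = any(g.f[s] + h.f[s] > 1.0 + tol for s in copresent)
    if not forced and len(copresent) < 2:
        return math.inf  # ambiguous co-occurrence: default disjoint
    if max(terms) > CLUSTER_D_SAMPLE_MAX:
        return math.inf
    return float(np.mean(terms))


def _cluster_events(evs, samples, tol) -> list[_Cluster]:
    """Agglomerative profile clustering with cluster-mean updates."""
    clusters = [_Cluster([e], samples) for e in evs]
    while len(clusters) > 1:
        best, bi, bj = math.inf, -1, -1
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = _cluster_distance(clusters[i], clusters[j], tol)
                if d < best:
                    best, bi, bj = d, i, j
        if best > CLUSTER_D_MEAN_MAX:
            break
        merged = _Cluster(clusters[bi].members + clusters[bj].members, samples)
        clusters = [c for k, c in enumerate(clusters) if k not in (bi, bj)] + [merged]
    return clusters


def _node_sd(n, s):
    return getattr(n, "sd", {}).get(s, 0.0)


def _node_present(n, s):
    return getattr(n, "present", {}).get(s, n.frac(s) > 0)


def _eff_tol(g, h, s, tol):
    eff = max(tol, 2.0 * math.sqrt(_node_sd(g, s) ** 2 + _node_sd(h, s) ** 2))
    return min(eff, 0.35)


def _dominates(g, h, samples, tol):
    """g could be ancestral to h: present (and at least as frequent) wherever
    h is present. Presence is curated, hence strict; an all-SNV ancestor may
    escape detection at low clone fractions."""
    for s in samples:
        if not _node_present(h, s):
            continue
        if not _node_present(g, s):
            if getattr(g, "all_snv", False) and h.frac(s) <= SNV_PRESENCE_LIMIT:
                continue
            return False
        if g.frac(s) < h.frac(s) - _eff_tol(g, h, s, tol):
            return False
    return True


def _forced_overlap(g, h, samples, tol):
    """Pigeonhole: fractions summing above 1 force the clusters to overlap.

    Under measurement noise the sum of two genuinely disjoint clusters
    (which is at most 1) can drift over the threshold, so a noisy sum only
    forces nesting when one side is pinned clonal or both are precise."""
    for s in samples:
        sd_pair = math.sqrt(_node_sd(g, s) ** 2 + _node_sd(h, s) ** 2)
        if g.frac(s) + h.frac(s) <= 1.0 + max(tol, 2.5 * sd_pair):
            continue
        pinned = any(n.frac(s) >= 1.0 - 1e-9 and _node_sd(n, s) <= 1e-9 for n in (g, h))
        if pinned or sd_pair <= 0.05:
            return True
    return False


def deconvolve_patient(
    events: EventTable,
    mcf_tolerance: float = MCF_TOLERANCE,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> tuple[list[Subclone], EventMatrix]:
    """Joint deconvolution over all samples of a patient.

    Uses the full cross-sample MCF profile of every event: events sharing a
    profile (with co-occurrence evidence) form one cluster; clusters nest
    where the profiles dominate and the pigeonhole rule forces overlap.
    Presence/absence of an event in a sample is treated as reliable (it is
    curated upstream), while values carry the propagated measurement SD.
    Returns the subclones and the binary event matrix.
    """
    tol = mcf_tolerance
    evs = events.events
    samples = events.samples
    if not evs:
        raise InvalidInputError("empty event table")

    clusters = _cluster_events(evs, samples, tol)
    groups: list[_Node] = []
    for c in sorted(clusters, key=lambda c: min(e.sort_key() for e in c.members)):
        g_events = sorted(c.members, key=EventRecord.sort_key)
        node = _Node(events=[e.event_id for e in g_events], fractions=dict(c.f))
        # within-cluster scatter floors the uncertainty: a cluster whose
        # members disagree at a sample is not precisely located there
        node.sd = {}
        for s in samples:
            vals = [e.mcf.get(s, 0.0) for e in c.members
                    if e.present.get(s, e.mcf.get(s, 0.0) > 0)]
            scatter = float(np.std(vals)) if len(vals) > 1 else 0.0
            node.sd[s] = max(math.sqrt(c.var[s]), scatter)
        node.present = dict(c._present)
        node.all_snv = c.all_snv
        groups.append(node)

    conflicts: list[str] = []

    def dominates(g, h):
        return _dominates(g, h, samples, tol)

    def forced_overlap(g, h):
        return _forced_overlap(g, h, samples, tol)

    root = _Node(events=[], fractions={s: 1.0 for s in samples})
    root.sd = {s: 0.0 for s in samples}
    order = sorted(groups, key=lambda g: (-sum(g.frac(s) for s in samples), g.events[0]))
    placed: list[_Node] = []

    def depth(node):
        d = 0
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    for h in order:
        anc = [g for g in placed if dominates(g, h)]
        forced = [g for g in anc if forced_overlap(g, h)]
        # contradictory forcing (overlap forced, but neither profile dominates)
        # is reported and otherwise ignored: presence patterns outrank noisy sums
        for g in placed:
            if g not in anc and forced_overlap(g, h) and not dominates(h, g):
                conflicts.append(
                    f"forced overlap without dominance between {g.events[0]} and {h.events[0]}"
                )
        if forced:
            host = max(forced, key=lambda g: (depth(g), sum(g.frac(s) for s in samples), g.events[0]))
            h.ambiguous = len({id(g) for g in forced if depth(g) == depth(host)}) > 1
        else:
            host = root
            h.ambiguous = bool(anc)  # nested reading possible; default disjoint
        h.parent = host
        host.children.append(h)
        placed.append(h)

    _repair_capacity(root, samples, tol, conflicts)
    _absorb_fragments(root, samples, tol, conflicts)
    _rehang(root, samples, tol)
    _absorb_fragments(root, samples, tol, conflicts)

    subclones = _forest_to_subclones(root, samples, detection_threshold, include_root=False)
    if not subclones:
        raise DeconvolutionConflictError("no subclone reached the detection threshold")
    matrix = _build_matrix(subclones, events, samples)
    matrix.conflicts = conflicts
    return subclones, matrix


def _repair_capacity(node: _Node, samples: list, tol: float, conflicts: list, _depth=0) -> None:
    """Push children down when a level's fractions exceed the parent capacity."""
    if _depth > 50:
        raise DeconvolutionConflictError("nesting repair did not converge")
    for s in samples:
        while True:
            total = sum(ch.frac(s) for ch in node.children)
            slack = max(2 * tol, 2.5 * math.sqrt(sum(_node_sd(ch, s) ** 2
                                                     for ch in node.children)))
            if total <= node.frac(s) + slack or len(node.children) < 2:
                break
            moved = False
            kids = sorted(node.children, key=lambda c: (sum(c.frac(x) for x in samples), c.events[0]))
            for small in kids:
                hosts = [c for c in node.children if c is not small
                         and _dominates(c, small, samples, tol)
                         and _forced_overlap(c, small, samples, tol)]
                if hosts:
                    host = max(hosts, key=lambda c: (sum(c.frac(x) for x in samples), c.events[0]))
                    conflicts.append(
                        f"capacity overflow in sample {s}: nested {small.events[0]} under {host.events[0]}")
                    node.children.remove(small)
                    small.parent = host
                    host.children.append(small)
                    moved = True
                    break
            if not moved:
                conflicts.append(
                    f"capacity overflow in sample {s} left unresolved "
                    f"(total {total:.3f} > {node.frac(s):.3f})"
                )
                break
    for ch in node.children:
        _repair_capacity(ch, samples, tol, conflicts, _depth + 1)


def _rehang(root: _Node, samples: list, tol: float) -> None:
    """Move each node under the deepest node that dominates it with forced
    overlap; placement order can otherwise strand a cluster higher up."""
    def walk(n):
        yield n
        for c in list(n.children):
            yield from walk(c)

    def depth(n):
        d = 0
        while n.parent is not None:
            d += 1
            n = n.parent
        return d

    for _ in range(10):
        moved = False
        nodes = [n for n in walk(root) if n is not root]
        for h in nodes:
            in_subtree = set(id(x) for x in walk(h))
            cands = [g for g in nodes
                     if id(g) not in in_subtree and g is not h.parent
                     and _dominates(g, h, samples, tol) and _forced_overlap(g, h, samples, tol)]
            if not cands:
                continue
            best = max(cands, key=lambda g: (depth(g), sum(g.frac(s) for s in samples), g.events[0]))
            if depth(best) > depth(h.parent):
                h.parent.children.remove(h)
                h.parent = best
                best.children.append(h)
                moved = True
        if not moved:
            break


def _absorb_fragments(root: _Node, samples: list, tol: float, conflicts: list) -> None:
    """Merge a child into its parent when both are fragments of one edge.

    A measurement outlier in a single sample can split an edge's events into
    two clusters that end up parent and child. A child whose curated presence
    pattern equals the parent's and whose values agree in every sample —
    allowing one discordant sample when its measurement noise is substantial
    — is re-absorbed. The root (whole tumor) never absorbs."""
    vfloor = (tol / 2.0) ** 2
    changed = True
    while changed:
        changed = False
        stack = list(root.children)
        parents = {id(ch): root for ch in root.children}
        order = []
        while stack:
            node = stack.pop()
            order.append(node)
            for ch in node.children:
                parents[id(ch)] = node
                stack.append(ch)
        candidates = []
        for child in order:
            parent = parents[id(child)]
            if parent is not root:
                candidates.append((parent, child, False))
            for sib in parents[id(child)].children:
                if sib is not child:
                    candidates.append((sib, child, True))
        for parent, child, is_sibling in candidates:
            if any(_node_present(parent, s) != _node_present(child, s) for s in samples):
                continue
            terms = []
            for s in samples:
                if not _node_present(child, s):
                    continue
                d = parent.frac(s) - child.frac(s)
                v = _node_sd(parent, s) ** 2 + _node_sd(child, s) ** 2
                pin_trim = (
                    (parent.frac(s) >= 1.0 - 1e-9 and _node_sd(parent, s) <= 1e-9
                     and _node_sd(child, s) > 0.05)
                    or (child.frac(s) >= 1.0 - 1e-9 and _node_sd(child, s) <= 1e-9
                        and _node_sd(parent, s) > 0.05)
                )
                terms.append((d * d / (v + 2 * vfloor), math.sqrt(v), pin_trim))
            if not terms:
                continue
            zs = sorted(terms, key=lambda t: -t[0])
            if len(zs) >= 2:
                # one outlier sample may be discounted: for a chain merge any
                # noisy sample, for a sibling merge only a sample where one
                # side is pinned clonal and the other is noisy (a genuinely
                # distinct sibling is never contradicted by a pinned partner)
                if (not is_sibling and zs[0][1] > 0.05) or (is_sibling and zs[0][2]):
                    zs = zs[1:]
            if not zs or max(z for z, _, _ in zs) > ABSORB_D_SAMPLE_MAX:
                continue
            if float(np.mean([z for z, _, _ in zs])) > ABSORB_D_MEAN_MAX:
                continue
            # merge: weighted profile, union of events, children move across
            target = parent
            wp, wc = max(1, len(target.events)), max(1, len(child.events))
            for s in samples:
                if _node_present(child, s):
                    delta = abs(target.frac(s) - child.frac(s))
                    target.fractions[s] = (wp * target.frac(s) + wc * child.frac(s)) / (wp + wc)
                    model = math.sqrt((wp * _node_sd(target, s) ** 2
                                       + wc * _node_sd(child, s) ** 2) / (wp + wc))
                    scatter = delta * math.sqrt(wp * wc) / (wp + wc)
                    target.sd[s] = max(model, scatter)
            target.events = sorted(set(target.events) | set(child.events))
            parents[id(child)].children.remove(child)
            for gc in child.children:
                gc.parent = target
                target.children.append(gc)
            conflicts.append(f"absorbed edge fragment {child.events[0]} into {target.events[0]}")
            changed = True
            break


def _build_matrix(subclones: list, events: EventTable, samples: list) -> EventMatrix:
    ev_ids = [e.event_id for e in sorted(events.events, key=EventRecord.sort_key)]
    used = set().union(*(sc.events for sc in subclones))
    ev_ids = [e for e in ev_ids if e in used]
    rows = {sc.subclone_id: [1 if e in sc.events else 0 for e in ev_ids] for sc in subclones}
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=ev_ids)
    fractions = pd.DataFrame(
        {s: [sc.fractions.get(s, 0.0) for sc in subclones] for s in samples},
        index=[sc.subclone_id for sc in subclones],
    )
    return EventMatrix(matrix=matrix, fractions=fractions)


def reconcile_across_samples(
    fragments_by_sample: dict,
    patient_id: str = "",
    mcf_tolerance: float = MCF_TOLERANCE,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> tuple[list[Subclone], EventMatrix]:
    """Unify per-sample subclone fragments into patient-level subclones.

    Rebuilds each event's cross-sample MCF profile from the fragments (the
    MCF of an event is the summed fraction of fragments carrying it) and runs
    the joint deconvolution, so that nesting seen in one sample is imposed on
    samples where the same events were ambiguous.
    """
    samples = sorted(fragments_by_sample)
    if not samples:
        raise InvalidInputError("no fragments supplied")
    mcf: dict[str, dict[str, float]] = defaultdict(lambda: defaultdict(float))
    for sid, frags in fragments_by_sample.items():
        for frag in frags:
            for ev in frag.events:
                mcf[ev][sid] += frag.fractions.get(sid, 0.0)
    events = [
        EventRecord(event_id=ev, kind="snv" if ev.startswith("snv") else ev.split("_")[0],
                    chrom=ev.split("_")[1] if "_" in ev else "chr1",
                    start=int(ev.split("_")[2]) if len(ev.split("_")) > 2 and ev.split("_")[2].isdigit() else 0,
                    end=0, mcf={s: min(1.0, v) for s, v in sm.items()})
        for ev, sm in sorted(mcf.items())
    ]
    table = EventTable(patient_id=patient_id, events=events, samples=samples)
    return deconvolve_patient(table, mcf_tolerance, detection_threshold)
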