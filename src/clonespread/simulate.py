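"""Synthetic multiregional cohorts with known ground truth.

The generator forward-models the whole measurement chain the pipeline
inverts: it grows a random subclone tree (normal root, truncal stem, then
branching subclones), assigns copy-number and point-mutation events to
edges, colonizes anatomical sites according to requested spread modes
(earlier seeding above the primary MRCA, polyclonal seeding of one site by
several lineages, intermetastatic chains with site-private clones, ...),
draws per-sample clone mixtures and tumor cell fractions, and emits noisy
raw measurements:

* log2R = log2((Np + MSF·(Nt−Np))/Np) + Normal(0, sd)
* mBAF of the allelic mixture + Normal(0, sd), folded into [0.5, 1]
* per-caller VAF ~ Binomial(depth, expected allele fraction)/depth

Sampling emulates multiregion pathology: each clone carried by a site is the
regionally dominant clone of one sample from that site (fraction ~0.6), with
a few minor clones per sample at fractions >= 0.12. Presence of an
alteration in a sample is curated (a segment row is emitted only where the
alteration is truly present), matching review-verified absence calls;
measurement noise perturbs values, not presence.

Ground-truth spread labels are obtained by running the spread classifier on
the noise-free truth tree and detections, so labels are consistent with the
tree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genome import AUTOSOMES, HG38_CHROM_LENGTHS
from .segments import SegmentCall
from .spread import SpreadReport, classify_patient
from .tree import CloneNode, CloneTree, NORMAL, SampleDetection
from .variants import VariantCall

_BASES = "ACGT"
_CNA_KINDS = ("gain", "loss", "cnni")
_CNA_PROBS = (0.45, 0.35, 0.2)
_MET_CLASSES = ("lymph_node", "distant")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort."""

    seed: int = 0
    n_patients: int = 17
    n_primary_subclones: tuple = (2, 4)  # internal subclones below the primary root
    events_per_branch: tuple = (2, 4)
    stem_events: tuple = (5, 10)
    cna_fraction: float = 0.7  # fraction of branch events that are CNAs (TDS patients)
    p_tds: float = 0.5  # fraction of patients with targeted sequencing (SNVs)
    p_earlier: float = 0.6
    p_polyclonal: float = 0.45
    p_polyphyletic: float = 0.45
    p_intermetastatic: float = 0.8
    p_relapse: float = 0.15
    tcf_range: tuple = (0.5, 0.9)
    depth: Optional[int] = 1000  # None = noiseless infinite depth
    log2r_sd: float = 0.1
    baf_sd: float = 0.01
    caller_dropout: float = 0.2
    n_artifacts: int = 3
    min_clone_fraction: float = 0.12
    featured_fraction: float = 0.6
    detection_threshold: float = 0.05
    n_bed_regions: int = 150

    def __post_init__(self):
        for p in (self.cna_fraction, self.p_tds, self.p_earlier, self.p_polyclonal,
                  self.p_polyphyletic, self.p_intermetastatic, self.p_relapse,
                  self.caller_dropout):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if self.depth is not None and self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        for rng_pair in (self.n_primary_subclones, self.events_per_branch,
                         self.stem_events, self.tcf_range):
            if len(rng_pair) != 2 or rng_pair[1] < rng_pair[0]:
                raise ConfigurationError(f"empty range {rng_pair}")

    @property
    def noise_free(self) -> bool:
        return self.log2r_sd == 0 and self.baf_sd == 0 and self.depth is None


@dataclass
class GroundTruth:
    tree: CloneTree  # annotated truth tree over extant clones
    clone_fractions: pd.DataFrame  # clones x samples
    event_mcf: pd.DataFrame  # events x samples
    clone_events: dict  # clone -> frozenset of event ids
    event_aliases: dict  # simulator event id -> pipeline-style genomic event id
    purities: dict  # sample -> TCF
    report: SpreadReport  # classifier output on the truth
    labels: dict  # patient-level flags derived from the report


@dataclass
class PatientBundle:
    patient_id: str
    segments: list  # list[SegmentCall] with raw measurements only
    variants: list  # list[VariantCall]
    metadata: dict  # sample_id -> (site, sample_class)
    truth: GroundTruth


@dataclass
class CohortBundle:
    config: SimulationConfig
    patients: list  # list[PatientBundle]
    bed: list  # (chrom, start0, end0) targeted regions
    truth_grid: pd.DataFrame  # spread modes x patients, from ground truth


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def make_bed(rng: np.random.Generator, n_regions: int) -> list:
    """A synthetic targeted panel: gene-sized regions across the autosomes."""
    bed = []
    for _ in range(n_regions):
        chrom = AUTOSOMES[rng.integers(len(AUTOSOMES))]
        size = int(rng.integers(10_000, 40_000))
        start = int(rng.integers(1_000_000, HG38_CHROM_LENGTHS[chrom] - size - 1_000_000))
        bed.append((chrom, start, start + size))
    return sorted(bed)


def _overlaps(a, b) -> bool:
    return a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]


class _Patient:
    """Working state while one patient is being generated."""

    def __init__(self, patient_id, rng, config, bed):
        self.pid = patient_id
        self.rng = rng
        self.cfg = config
        self.bed = bed
        self.parent = {}  # clone -> parent clone (root child of NORMAL)
        self.edge_events = {}  # clone -> list of event ids on the edge into it
        self.events = {}  # event_id -> dict(kind, chrom, start, end, nt, na, nb)
        self.extant = []  # clones that exist as cell populations
        self.site_clones = {}  # site -> ordered list of extant clones
        self.site_class = {}  # site -> sample class
        self.used_regions = []
        self.n_events = 0
        self.has_tds = rng.random() < config.p_tds

    # -- tree building ------------------------------------------------------
    def new_clone(self, parent, prefix="C"):
        name = f"{prefix}{len(self.parent) + 1}"
        self.parent[name] = parent
        self.edge_events[name] = []
        return name

    def genotype(self, clone) -> frozenset:
        out = set()
        c = clone
        while c != NORMAL:
            out.update(self.edge_events[c])
            c = self.parent[c]
        return frozenset(out)

    def is_anc(self, a, b) -> bool:
        c = self.parent.get(b)
        while c is not None and c != NORMAL:
            if c == a:
                return True
            c = self.parent.get(c)
        return False

    # -- events ---------------------------------------------------------------
    def _cna_footprint(self):
        for _ in range(200):
            chrom = AUTOSOMES[self.rng.integers(len(AUTOSOMES))]
            size = int(self.rng.integers(1_000_000, 30_000_000))
            limit = HG38_CHROM_LENGTHS[chrom] - size - 1
            if limit < 2:
                continue
            start = int(self.rng.integers(1, limit))
            region = (chrom, start, start + size - 1)
            clash = any(_overlaps(region, r) for r in self.used_regions)
            clash = clash or any(_overlaps(region, (b[0], b[1] + 1, b[2])) for b in self.bed)
            if not clash:
                self.used_regions.append(region)
                return region
        raise ConfigurationError("could not place a CNA footprint without overlap")

    def add_events(self, clone, n):
        for _ in range(n):
            self.n_events += 1
            eid = f"E{self.n_events}"
            is_cna = (not self.has_tds) or self.rng.random() < self.cfg.cna_fraction
            if is_cna:
                kind = self.rng.choice(_CNA_KINDS, p=_CNA_PROBS)
                chrom, start, end = self._cna_footprint()
                nt, na, nb = {"gain": (3, 1, 2), "loss": (1, 0, 1), "cnni": (2, 0, 2)}[kind]
                self.events[eid] = dict(kind=str(kind), chrom=chrom, start=start, end=end,
                                        nt=nt, na=na, nb=nb)
            else:
                chrom, b0, b1 = self.bed[self.rng.integers(len(self.bed))]
                pos = int(self.rng.integers(b0 + 1, b1))
                ref = _BASES[self.rng.integers(4)]
                alt = _BASES[(int(_BASES.index(ref)) + 1 + self.rng.integers(3)) % 4]
                self.events[eid] = dict(kind="snv", chrom=chrom, start=pos, end=pos,
                                        ref=ref, alt=alt)
            self.edge_events[clone].append(eid)


def _draw_flags(rng, cfg):
    e = rng.random() < cfg.p_earlier
    pc = rng.random() < cfg.p_polyclonal
    pp = pc or (rng.random() < cfg.p_polyphyletic)
    im = rng.random() < cfg.p_intermetastatic
    return e, pc, pp, im


def _n_met_sites(rng, e, pc, pp, im):
    base = 1 + int(rng.random() < 0.5)
    if im and pp and not pc:
        return 3
    if im or (pp and not pc):
        return max(base, 2)
    if e and not pp:
        return 1
    return base


def simulate_patient(config: SimulationConfig, seed: int, patient_id: str = "SIM1") -> PatientBundle:
    """One patient: ground-truth tree, spread pattern, samples, raw measurements."""
    rng = np.random.default_rng(seed)
    bed = make_bed(rng, config.n_bed_regions)
    return _simulate_patient_inner(config, rng, patient_id, bed)


def _simulate_patient_inner(config, rng, patient_id, bed) -> PatientBundle:
    cfg = config
    pt = _Patient(patient_id, rng, cfg, bed)

    earlier, polyclonal, polyphyletic, intermet = _draw_flags(rng, cfg)
    n_met = _n_met_sites(rng, earlier, polyclonal, polyphyletic, intermet)

    # --- topology -----------------------------------------------------------
    c1 = pt.new_clone(NORMAL)  # tumor MRCA (stem below it)
    pt.add_events(c1, int(rng.integers(cfg.stem_events[0], cfg.stem_events[1] + 1)))
    if earlier:
        primary_root = pt.new_clone(c1)
        pt.add_events(primary_root, _n_branch(rng, cfg))
    else:
        primary_root = c1
    primary_clones = [primary_root]
    for _ in range(int(rng.integers(cfg.n_primary_subclones[0], cfg.n_primary_subclones[1] + 1))):
        parent = primary_clones[int(rng.integers(len(primary_clones)))]
        clone = pt.new_clone(parent)
        pt.add_events(clone, _n_branch(rng, cfg))
        primary_clones.append(clone)
    pt.extant.extend(primary_clones)

    def new_lineage_clone(attach):
        clone = pt.new_clone(attach, prefix="L")
        pt.add_events(clone, _n_branch(rng, cfg))
        pt.extant.append(clone)
        return clone

    met_sites = [f"M{i + 1}" for i in range(n_met)]
    for s in met_sites:
        pt.site_class[s] = _MET_CLASSES[int(rng.integers(2))]
        pt.site_clones[s] = []
    pt.site_class["P"] = "primary"
    pt.site_clones["P"] = list(primary_clones)

    attach1 = c1 if earlier else primary_clones[int(rng.integers(len(primary_clones)))]
    r1 = new_lineage_clone(attach1)
    pt.site_clones["M1"].append(r1)

    if intermet:
        r1c = new_lineage_clone(r1)
        pt.site_clones["M2"].append(r1c)
    elif rng.random() < 0.5:
        r1b = new_lineage_clone(r1)  # within-site depth; still monoclonal
        pt.site_clones["M1"].append(r1b)

    if polyclonal:
        attach2 = primary_clones[int(rng.integers(len(primary_clones)))]
        r2 = new_lineage_clone(attach2)
        pt.site_clones["M1"].append(r2)

    if polyphyletic and not polyclonal:
        other_site = "M3" if intermet else "M2"
        attach3 = primary_clones[int(rng.integers(len(primary_clones)))]
        r3 = new_lineage_clone(attach3)
        pt.site_clones[other_site].append(r3)

    if not intermet and not (polyphyletic and not polyclonal) and n_met >= 2:
        # second site seeded by primary-detected clones, comparable with L1:
        # no intermetastatic link, no extra branch
        seed_clone = attach1 if attach1 in primary_clones else primary_root
        pt.site_clones["M2"].append(seed_clone)

    if n_met >= 2 and intermet and polyclonal and polyphyletic and n_met == 2:
        pass  # M1 polyclonal already covers polyphyly

    # optional relapse sampling at the primary site (anatomically identical,
    # so it does not add a metastatic site)
    relapse = rng.random() < cfg.p_relapse
    if relapse:
        pt.site_class["P_relapse"] = "relapse"
        pt.site_clones["P_relapse"] = [primary_clones[int(rng.integers(len(primary_clones)))]]

    # --- samples and clone mixtures ------------------------------------------
    samples = []  # (sample_id, site, class, featured clone)
    metadata = {}
    for site in ["P"] + met_sites + (["P_relapse"] if relapse else []):
        clones = pt.site_clones.get(site, [])
        anatomical_site = "P" if site == "P_relapse" else site
        for i, featured in enumerate(clones):
            sid = f"{patient_id}_{site}s{i + 1}"
            samples.append((sid, anatomical_site, pt.site_class[site], featured))
            metadata[sid] = (anatomical_site, pt.site_class[site])

    clone_order = sorted(pt.extant)
    phi = pd.DataFrame(0.0, index=clone_order, columns=[s[0] for s in samples])
    for sid, site_label, cls, featured in samples:
        site_key = next(k for k in pt.site_clones
                        if (("P" if k == "P_relapse" else k) == site_label)
                        and pt.site_class[k] == cls)
        pool = [c for c in pt.site_clones[site_key] if c != featured]
        k = min(len(pool), int(rng.integers(0, 3)))
        others = list(rng.choice(pool, size=k, replace=False)) if k else []
        if not others:
            phi.loc[featured, sid] = 1.0
        else:
            f_feat = cfg.featured_fraction + rng.uniform(-0.02, 0.02)
            rest = 1.0 - f_feat
            if len(others) == 1:
                shares = [rest]
            else:
                x = rng.uniform(cfg.min_clone_fraction + 0.01, rest - cfg.min_clone_fraction - 0.01)
                shares = [x, rest - x]
            phi.loc[featured, sid] = f_feat
            for c, sh in zip(others, shares):
                phi.loc[c, sid] = sh

    # --- true event MCFs ------------------------------------------------------
    genotypes = {c: pt.genotype(c) for c in clone_order}
    event_ids = sorted(pt.events, key=lambda e: int(e[1:]))
    mcf = pd.DataFrame(0.0, index=event_ids, columns=phi.columns)
    for eid in event_ids:
        carriers = [c for c in clone_order if eid in genotypes[c]]
        if carriers:
            mcf.loc[eid] = phi.loc[carriers].sum(axis=0)

    purities = {sid: float(rng.uniform(*cfg.tcf_range)) for sid in phi.columns}

    # --- emit measurements -----------------------------------------------------
    segments, variants = [], []
    for eid in event_ids:
        ev = pt.events[eid]
        for sid in phi.columns:
            m = float(mcf.loc[eid, sid])
            if m < cfg.detection_threshold:
                continue
            tcf = purities[sid]
            msf = m * tcf
            if ev["kind"] in ("gain", "loss"):
                nt, np_ = ev["nt"], 2
                log2r = np.log2((np_ + msf * (nt - np_)) / np_)
                if cfg.log2r_sd > 0:
                    log2r += rng.normal(0.0, cfg.log2r_sd)
                segments.append(SegmentCall(
                    patient_id=patient_id, sample_id=sid, chrom=ev["chrom"],
                    start=ev["start"], end=ev["end"], alteration_type=ev["kind"],
                    n_alleles_total=nt, n_a=ev["na"], n_b=ev["nb"], background_ploidy=2,
                    log2r=float(log2r), marker_count=max(30, (ev["end"] - ev["start"]) // 5000),
                ))
            elif ev["kind"] == "cnni":
                mbaf = (1.0 + msf) / 2.0
                if cfg.baf_sd > 0:
                    mbaf += rng.normal(0.0, cfg.baf_sd)
                mbaf = min(1.0, max(0.5, mbaf))
                segments.append(SegmentCall(
                    patient_id=patient_id, sample_id=sid, chrom=ev["chrom"],
                    start=ev["start"], end=ev["end"], alteration_type="cnni",
                    n_alleles_total=2, n_a=0, n_b=2, background_ploidy=2,
                    mbaf=float(mbaf), marker_count=max(30, (ev["end"] - ev["start"]) // 5000),
                ))
            else:  # snv
                true_vaf = m * tcf / 2.0
                callers = ["mutect2", "strelka2"]
                for extra in ("varscan2", "manta"):
                    if rng.random() > cfg.caller_dropout:
                        callers.append(extra)
                for caller in callers:
                    if cfg.depth is None:
                        vaf_obs, dp = true_vaf, 10_000
                    else:
                        dp = cfg.depth
                        vaf_obs = rng.binomial(dp, true_vaf) / dp
                    variants.append(VariantCall(
                        patient_id=patient_id, sample_id=sid, chrom=ev["chrom"],
                        pos=ev["start"], ref=ev["ref"], alt=ev["alt"], caller=caller,
                        vaf_tumor=float(vaf_obs), vaf_normal=0.0,
                        dp_tumor=dp, dp_normal=dp, mapq=60.0,
                        annotation=f"gene_{ev['chrom']}_{ev['start']}",
                    ))

    # sequencing artifacts: removed by the consensus / quality filters
    if pt.has_tds:
        some_sample = phi.columns[0]
        for _ in range(cfg.n_artifacts):
            chrom, b0, b1 = bed[int(rng.integers(len(bed)))]
            pos = int(rng.integers(b0 + 1, b1))
            kind = rng.random()
            if kind < 0.5:  # single sample, single caller
                variants.append(VariantCall(
                    patient_id=patient_id, sample_id=some_sample, chrom=chrom, pos=pos,
                    ref="A", alt="T", caller="varscan2", vaf_tumor=0.15, vaf_normal=0.0,
                    dp_tumor=cfg.depth or 10_000, dp_normal=cfg.depth or 10_000, mapq=60.0,
                ))
            else:  # below the tumor-VAF floor
                for caller in ("mutect2", "strelka2"):
                    variants.append(VariantCall(
                        patient_id=patient_id, sample_id=some_sample, chrom=chrom, pos=pos,
                        ref="G", alt="C", caller=caller, vaf_tumor=0.03, vaf_normal=0.0,
                        dp_tumor=cfg.depth or 10_000, dp_normal=cfg.depth or 10_000, mapq=60.0,
                    ))

    truth = _build_truth(pt, phi, mcf, genotypes, purities, metadata, cfg)
    return PatientBundle(patient_id=patient_id, segments=segments, variants=variants,
                         metadata=metadata, truth=truth)


def _n_branch(rng, cfg):
    return int(rng.integers(cfg.events_per_branch[0], cfg.events_per_branch[1] + 1))


def _build_truth(pt, phi, mcf, genotypes, purities, metadata, cfg) -> GroundTruth:
    tree = CloneTree()
    tree.add_node(CloneNode(NORMAL, None, (), frozenset()))
    # topological order: parents before children
    order, pending = [], sorted(pt.parent)
    placed = {NORMAL}
    while pending:
        for c in list(pending):
            if pt.parent[c] in placed:
                order.append(c)
                placed.add(c)
                pending.remove(c)
    for clone in order:
        tree.add_node(CloneNode(
            clone, pt.parent[clone], tuple(pt.edge_events[clone]),
            genotypes.get(clone, pt.genotype(clone)),
            subclones=(clone,) if clone in pt.extant else (),
        ))
    for clone in pt.extant:
        node = tree.nodes[clone]
        for sid in phi.columns:
            f = float(phi.loc[clone, sid])
            if f >= cfg.detection_threshold:
                site, cls = metadata[sid]
                node.detections.append(SampleDetection(sid, site, cls, f))
    report = classify_patient(tree, patient_id=pt.pid)
    labels = {
        "earlier": report.has_earlier,
        "polyclonal": report.has_polyclonal,
        "polyphyletic": None if report.phyletic is None else report.phyletic == "polyphyletic",
        "intermetastatic": report.has_intermetastatic,
    }
    aliases = {eid: f"{ev['kind']}_{ev['chrom']}_{ev['start']}"
               for eid, ev in pt.events.items()}
    return GroundTruth(tree=tree, clone_fractions=phi, event_mcf=mcf,
                       clone_events={c: genotypes[c] for c in pt.extant},
                       event_aliases=aliases,
                       purities=purities, report=report, labels=labels)


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Independent patients with per-patient seeds derived from the master seed.

    The per-patient seed depends on the patient number, not its position, so
    permuting the patient order reproduces identical per-patient outputs. The
    targeted panel (BED) is shared by the cohort.
    """
    if config.n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    bed_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    bed = make_bed(bed_rng, config.n_bed_regions)
    patients = []
    for i in range(1, config.n_patients + 1):
        child = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(child)
        patients.append(_simulate_patient_inner(config, rng, f"SIM{i:02d}", bed))

    def cell(v):
        return "not_evaluable" if v is None else ("present" if v else "absent")

    grid = pd.DataFrame({
        p.patient_id: {k: cell(v) for k, v in p.truth.labels.items()}
        for p in patients
    })
    return CohortBundle(config=config, patients=patients, bed=bed, truth_grid=grid)
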