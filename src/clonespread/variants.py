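"""Multi-caller, multi-sample somatic variant filtering and MCF from VAF.

The filter reproduces a conservative FFPE targeted-deep-sequencing scheme:
calls must pass the caller's internal filters and population-database /
panel-of-normals removal upstream (boolean columns on input), then

* excluded per call: tumor VAF < 0.05, normal VAF > 0.05, tumor or normal
  depth < 20, mapping quality < 50;
* kept per locus: called in >= 2 samples by >= 2 distinct callers in total,
  or, when seen in a single sample, by >= 2 callers in that sample; and the
  locus must fall inside the targeted (BED) regions.

VAF is converted to the mutated clone fraction with a copy-number- and
purity-aware model: for a variant at a locus where a fraction f1 of tumor
cells carries a CNA with total copy number CN1 (the rest at CN2, normal cells
diploid),

    MCF = VAF · (CN1·TCF·f1 + CN2·(TCF − TCF·f1) + 2·(1 − TCF)) / (M·TCF)

with M the number of mutated alleles per cell. M defaults to 1 and is raised
to 2 when the resulting MCF exceeds 1.1; values still above 1 are clamped
with a QC flag. Without a CNA this reduces to the textbook diploid
MCF = 2·VAF/TCF.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .errors import ConfigurationError, InvalidInputError

CALLERS = ("mutect2", "strelka2", "varscan2", "manta")

VAF_TUMOR_MIN = 0.05
VAF_NORMAL_MAX = 0.05
DP_MIN = 20
MAPQ_MIN = 50.0
MCF_ESCALATION_THRESHOLD = 1.1


@dataclass
class VariantCall:
    """One caller's record of one variant in one tumor/normal pair."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    caller: str
    vaf_tumor: float
    vaf_normal: float
    dp_tumor: int
    dp_normal: int
    mapq: float = 60.0
    passed_internal: bool = True
    in_pon: bool = False
    in_popdb: bool = False
    annotation: str = ""

    def __post_init__(self):
        if not (0.0 <= self.vaf_tumor <= 1.0 and 0.0 <= self.vaf_normal <= 1.0):
            raise InvalidInputError(f"VAF out of [0,1] at {self.chrom}:{self.pos}")
        if self.dp_tumor < 0 or self.dp_normal < 0:
            raise InvalidInputError(f"negative depth at {self.chrom}:{self.pos}")

    @property
    def locus_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilteredVariant:
    """A consensus-kept locus with per-sample VAF/depth and clone fractions."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    samples: frozenset
    callers: frozenset
    vaf: dict = field(default_factory=dict)  # sample_id -> depth-weighted mean tumor VAF
    dp: dict = field(default_factory=dict)  # sample_id -> total tumor depth
    mcf: dict = field(default_factory=dict)  # sample_id -> mutated clone fraction
    m_alleles: dict = field(default_factory=dict)  # sample_id -> M used (1 or 2)
    qc_flags: list = field(default_factory=list)
    annotation: str = ""

    @property
    def locus_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def exclude_low_quality(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Drop calls failing the per-call VAF/depth/mapping-quality thresholds.

    Only calls that passed caller-internal filters and were absent from the
    population databases / panel of normals are eligible.
    """
    kept = []
    for c in calls:
        if not c.passed_internal or c.in_pon or c.in_popdb:
            continue
        if c.vaf_tumor < VAF_TUMOR_MIN:
            continue
        if c.vaf_normal > VAF_NORMAL_MAX:
            continue
        if c.dp_tumor < DP_MIN or c.dp_normal < DP_MIN:
            continue
        if c.mapq < MAPQ_MIN:
            continue
        kept.append(c)
    return kept


def build_bed_index(intervals: Iterable[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    """Interval trees per chromosome from 0-based half-open BED rows."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end in intervals:
        if end > start:
            trees[chrom].addi(start, end)
    return dict(trees)


def in_bed(bed: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    """Whether a 1-based position falls inside the half-open BED intervals."""
    tree = bed.get(chrom)
    return bool(tree is not None and tree.overlaps(pos - 1))


def consensus_keep(
    calls: Iterable[VariantCall],
    bed: Optional[dict[str, IntervalTree]],
) -> list[FilteredVariant]:
    """Apply the multi-sample/multi-caller consensus rule per locus.

    A locus is kept iff it lies inside the BED intervals and either
    (a) it was detected in >= 2 samples and by >= 2 distinct callers in total,
    or (b) it was detected in exactly 1 sample by >= 2 callers.
    Per-sample VAF is the depth-weighted mean over agreeing callers.
    """
    if bed is None:
        raise ConfigurationError("a BED file of targeted regions is required for consensus filtering")
    by_locus: dict[tuple, list[VariantCall]] = defaultdict(list)
    for c in calls:
        by_locus[(c.patient_id,) + c.locus_key].append(c)

    kept: list[FilteredVariant] = []
    for key in sorted(by_locus, key=lambda k: (k[0], k[1], k[2], k[3], k[4])):
        group = by_locus[key]
        patient, chrom, pos, ref, alt = key
        samples = {c.sample_id for c in group}
        callers = {c.caller for c in group}
        if not in_bed(bed, chrom, pos):
            continue
        if not ((len(samples) >= 2 and len(callers) >= 2) or (len(samples) == 1 and len(callers) >= 2)):
            continue
        fv = FilteredVariant(
            patient_id=patient, chrom=chrom, pos=pos, ref=ref, alt=alt,
            samples=frozenset(samples), callers=frozenset(callers),
            annotation=next((c.annotation for c in group if c.annotation), ""),
        )
        per_sample: dict[str, list[VariantCall]] = defaultdict(list)
        for c in group:
            per_sample[c.sample_id].append(c)
        for sid, cs in per_sample.items():
            total_dp = sum(c.dp_tumor for c in cs)
            if total_dp > 0:
                fv.vaf[sid] = sum(c.vaf_tumor * c.dp_tumor for c in cs) / total_dp
            else:
                fv.vaf[sid] = sum(c.vaf_tumor for c in cs) / len(cs)
            fv.dp[sid] = total_dp
        kept.append(fv)
    return kept


def mcf_from_vaf(
    vaf: float,
    cn1: int = 2,
    f1: float = 0.0,
    cn2: int = 2,
    f2: Optional[float] = None,
    tcf: float = 1.0,
    m: int = 1,
) -> tuple[float, int]:
    """Mutated clone fraction from a VAF with copy-number/purity correction.

    ``f2`` defaults to ``f1`` (the CNA-bearing tumor fraction), making the
    bracketed term the mean copy number at the locus across tumor and normal
    cells. Returns ``(mcf, m_used)``; ``m`` escalates from 1 to 2 when the raw
    MCF exceeds 1.1, and the final value is clamped into [0, 1].
    """
    if not (0.0 < tcf <= 1.0):
        raise InvalidInputError(f"tcf must be in (0, 1], got {tcf}")
    if m not in (1, 2):
        raise InvalidInputError(f"m must be 1 or 2, got {m}")
    if cn1 < 0 or cn2 < 0:
        raise InvalidInputError("copy numbers must be nonnegative")
    if f2 is None:
        f2 = f1
    locus_cn = cn1 * tcf * f1 + cn2 * (tcf - tcf * f2) + 2.0 * (1.0 - tcf)
    raw = vaf * locus_cn / (m * tcf)
    m_used = m
    if raw > MCF_ESCALATION_THRESHOLD and m == 1:
        m_used = 2
        raw = vaf * locus_cn / (m_used * tcf)
    return min(1.0, max(0.0, raw)), m_used


def fill_mcf(
    variants: list[FilteredVariant],
    purities: dict[str, float],
    cna_lookup=None,
    clonal_intervals: Optional[dict] = None,
) -> list[FilteredVariant]:
    """Fill per-sample MCFs on consensus-kept variants.

    ``purities`` maps sample_id -> TCF. ``cna_lookup(sample_id, chrom, pos)``
    may return ``(cn1, f1)`` for a CNA overlapping the locus in that sample
    (``None`` for a diploid locus). ``clonal_intervals`` may map sample_id ->
    (low, high), the sample's clonal interval in MCF space: a raw MCF inside
    it is pinned to 1 (clonal) before the M-escalation rule is considered, so
    purity jitter does not masquerade as a two-allele variant.
    """
    for fv in variants:
        for sid, vaf in fv.vaf.items():
            tcf = purities.get(sid)
            if tcf is None:
                raise InvalidInputError(f"no purity for sample {sid}")
            cn1, f1 = 2, 0.0
            if cna_lookup is not None:
                hit = cna_lookup(sid, fv.chrom, fv.pos)
                if hit is not None:
                    cn1, f1 = hit
            locus_cn = cn1 * tcf * f1 + 2 * (tcf - tcf * f1) + 2 * (1 - tcf)
            raw = vaf * locus_cn / tcf  # M = 1
            interval = (clonal_intervals or {}).get(sid)
            if interval is not None and interval[0] <= raw <= interval[1]:
                fv.mcf[sid] = 1.0
                fv.m_alleles[sid] = 1
                continue
            mcf, m_used = mcf_from_vaf(vaf, cn1=cn1, f1=f1, cn2=2, tcf=tcf)
            raw_at_m = raw / m_used
            if raw_at_m > MCF_ESCALATION_THRESHOLD:
                fv.qc_flags.append(f"{sid}: raw MCF {raw_at_m:.3f} > 1.1 at M=2; clamped")
            fv.mcf[sid] = mcf
            fv.m_alleles[sid] = m_used
    return variants
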