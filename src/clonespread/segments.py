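"""Clone-fraction quantification from SNP-array segment calls.

Converts per-segment raw measurements (log2 intensity ratio, mirrored B-allele
frequency) into the mutated sample fraction (MSF, the proportion of *all* cells
in a sample carrying an alteration), estimates sample purity (tumor cell
fraction, TCF) from the clearly clonal alterations, and normalizes MSF to the
mutated clone fraction (MCF = MSF/TCF, the proportion of tumor cells carrying
the alteration). Alterations whose MCF falls inside the clonal interval
(TCF ± 2·SD_MSF)/TCF are called clonal and pinned to MCF = 1.

Model
-----
A sample is a two-population mixture: a fraction MSF of cells carries the
altered copy state (Nt total copies; allelic composition NA/NB for imbalances)
and the remainder sits at the background ploidy Np. For a copy-number change
the mean copy number is Np + MSF·(Nt − Np), observed as
log2R = log2(mean/Np), which inverts to

    MSF = Np·(2^log2R − 1) / (Nt − Np).

Copy-number-neutral imbalances (CNNI) leave log2R flat; the mirrored BAF of the
mixture inverts instead to

    MSF = (Np/2 − Np·mBAF) / (mBAF·(NA + NB − Np) − NB + Np/2),

which for a diploid background (Np = 2) is the familiar
(1 − 2·mBAF)/(mBAF·(NA+NB−2) − NB + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientAnchorsError, InvalidInputError, DegenerateCompositionError, QualityWarning

#: Raw MSF values outside this range trigger a QualityWarning before clamping.
MSF_QC_RANGE = (-0.02, 1.05)

#: Minimum retained CNA size (bp) and marker count.
MIN_CNA_SIZE = 30_000
MIN_MARKER_COUNT = 30

ALTERATION_TYPES = ("gain", "loss", "cnni", "snv")


@dataclass
class SegmentCall:
    """One genetic alteration in one sample.

    Coordinates are 1-based inclusive (hg38). ``n_alleles_total`` is the copy
    number carried by altered cells, ``background_ploidy`` the copy number of
    non-altered cells at the locus (2 for diploid, 4 after whole-genome
    doubling — supplied by the caller, never inferred here).
    """

    patient_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    alteration_type: str
    n_alleles_total: Optional[int] = None
    n_a: Optional[int] = None
    n_b: Optional[int] = None
    background_ploidy: int = 2
    log2r: Optional[float] = None
    mbaf: Optional[float] = None
    msf: Optional[float] = None
    mcf: Optional[float] = None
    is_clonal: Optional[bool] = None
    marker_count: Optional[int] = None
    gene: Optional[str] = None
    hgvs: Optional[str] = None
    mcf_sd: Optional[float] = None  # propagated measurement SD of the MCF

    def __post_init__(self):
        if self.alteration_type not in ALTERATION_TYPES:
            raise InvalidInputError(
                f"unknown alteration_type {self.alteration_type!r}; expected one of {ALTERATION_TYPES}"
            )
        if self.end < self.start:
            raise InvalidInputError(f"end < start for segment {self.chrom}:{self.start}-{self.end}")
        if self.alteration_type == "cnni":
            if self.n_a is None or self.n_b is None:
                raise InvalidInputError("cnni segments require an allelic composition (n_a, n_b)")
            if self.n_a + self.n_b != self.background_ploidy:
                raise InvalidInputError(
                    f"cnni requires n_a + n_b == background_ploidy, got {self.n_a}+{self.n_b} != {self.background_ploidy}"
                )
            if self.n_b <= self.n_a:
                raise InvalidInputError("cnni requires n_b > n_a")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def passes_cna_filters(self) -> bool:
        """Size >= 30 kbp and marker count >= 30 (SNVs always pass)."""
        if self.alteration_type == "snv":
            return True
        ok_size = self.size >= MIN_CNA_SIZE
        ok_markers = self.marker_count is None or self.marker_count >= MIN_MARKER_COUNT
        return ok_size and ok_markers


@dataclass
class SamplePurity:
    """Per-sample tumor cell fraction and the clonal interval in MCF space."""

    sample_id: str
    tcf: float
    sd_msf: float
    clonal_low: float
    clonal_high: float
    n_clonal_anchors: int

    def __post_init__(self):
        if not (0.0 < self.tcf <= 1.0):
            raise InvalidInputError(f"tcf must be in (0, 1], got {self.tcf}")
        if self.sd_msf < 0:
            raise InvalidInputError("sd_msf must be nonnegative")


def msf_from_log2r(log2r: float, np_: int, nt: int) -> float:
    """Mutated sample fraction of a copy-number change from its log2 ratio.

    Parameters
    ----------
    log2r : observed log2 intensity ratio of the segment.
    np_ : background ploidy the ratio was normalized against (>= 1).
    nt : total copy number of the altered cells; must differ from ``np_``.

    Returns the mixture fraction clamped into [0, 1]. Raw values outside
    [-0.02, 1.05] additionally emit a :class:`QualityWarning` (FFPE noise).
    """
    if np_ < 1:
        raise InvalidInputError(f"background ploidy must be >= 1, got {np_}")
    if nt == np_:
        raise InvalidInputError(
            "nt == np_ is copy-number neutral; use msf_from_mbaf for CNNI segments"
        )
    raw = np_ * (2.0 ** log2r - 1.0) / (nt - np_)
    _qc_check(raw)
    return min(1.0, max(0.0, raw))


def msf_from_mbaf(mbaf: float, n_a: int, n_b: int, np_: Optional[int] = None) -> float:
    """Mutated sample fraction of an allelic imbalance from its mirrored BAF.

    ``np_`` is the background ploidy; by default it is ``n_a + n_b`` (the
    copy-neutral case). With ``np_=2`` this is exactly the diploid-background
    inversion (1 − 2·mBAF)/(mBAF·(NA+NB−2) − NB + 1), valid for any altered
    composition.
    """
    if n_b <= n_a:
        raise InvalidInputError(f"requires n_b > n_a, got n_a={n_a}, n_b={n_b}")
    if not (0.5 <= mbaf <= 1.0 + 1e-9):
        raise InvalidInputError(f"mbaf must be in [0.5, 1], got {mbaf}")
    if np_ is None:
        np_ = n_a + n_b
    denom = mbaf * (n_a + n_b - np_) - n_b + np_ / 2.0
    if abs(denom) < 1e-12:
        raise DegenerateCompositionError(
            f"allelic composition ({n_a},{n_b}) on background ploidy {np_} is degenerate at mbaf={mbaf}"
        )
    raw = (np_ / 2.0 - np_ * mbaf) / denom
    _qc_check(raw)
    return min(1.0, max(0.0, raw))


def _qc_check(raw: float) -> None:
    lo, hi = MSF_QC_RANGE
    if raw < lo or raw > hi:
        warnings.warn(
            f"raw MSF {raw:.4f} outside plausible range [{lo}, {hi}]; clamped",
            QualityWarning,
            stacklevel=3,
        )


def estimate_tcf(clonal_msfs: Sequence[float], sample_id: str = "") -> SamplePurity:
    """Tumor cell fraction as the mean MSF of the clearly clonal alterations.

    The clonal interval, in MCF space, is ((TCF − 2·SD_MSF)/TCF,
    (TCF + 2·SD_MSF)/TCF) where SD_MSF is the sample standard deviation of the
    anchor MSFs (0 for a single anchor).
    """
    vals = list(clonal_msfs)
    if not vals:
        raise InsufficientAnchorsError(
            "no clonal anchor segments; designate anchors or supply the TCF directly"
        )
    for v in vals:
        if not (0.0 < v <= 1.0):
            raise InvalidInputError(f"clonal anchor MSF must be in (0, 1], got {v}")
    tcf = mean(vals)
    sd = stdev(vals) if len(vals) > 1 else 0.0
    return SamplePurity(
        sample_id=sample_id,
        tcf=tcf,
        sd_msf=sd,
        clonal_low=(tcf - 2.0 * sd) / tcf,
        clonal_high=(tcf + 2.0 * sd) / tcf,
        n_clonal_anchors=len(vals),
    )


def mcf_normalize(msf: float, purity: SamplePurity) -> tuple[float, bool]:
    """MCF = MSF/TCF; clonal iff the raw MCF falls inside the clonal interval.

    Clonal alterations are pinned to MCF = 1; subclonal MCFs are capped at 1.
    """
    if purity.tcf <= 0:
        raise InvalidInputError("purity.tcf must be positive")
    raw = msf / purity.tcf
    if purity.clonal_low <= raw <= purity.clonal_high:
        return 1.0, True
    return min(raw, 1.0), False


def _raw_msf(seg: SegmentCall) -> float:
    if seg.alteration_type == "cnni":
        if seg.mbaf is None:
            raise InvalidInputError(f"cnni segment {seg.chrom}:{seg.start} lacks an mBAF")
        return msf_from_mbaf(seg.mbaf, seg.n_a, seg.n_b, np_=seg.background_ploidy)
    if seg.log2r is None:
        raise InvalidInputError(f"segment {seg.chrom}:{seg.start} lacks a log2R")
    return msf_from_log2r(seg.log2r, seg.background_ploidy, seg.n_alleles_total)


def select_anchors(raw_msfs: Sequence[float], gap: float = 0.1,
                   msf_sd: float = 0.0) -> list[int]:
    """Indices of the 'clearly clonal' cluster: the highest-MSF cluster.

    Sorts the raw MSFs, splits at gaps larger than ``gap`` and keeps the top
    cluster; the cluster is then widened to every segment within 2 standard
    deviations of its mean (mirroring how clearly clonal alterations are read
    off an allele-specific copy-number plot). ``msf_sd`` is the assumed
    per-segment measurement SD and acts as a floor on both the gap and the
    widening, so a noisy outlier cannot strand the cluster.
    """
    if not raw_msfs:
        return []
    vals = np.asarray(raw_msfs, dtype=float)
    n = len(vals)
    if n <= 3:
        order = sorted(range(n), key=lambda i: -vals[i])
        cluster = [order[0]]
        for i in order[1:]:
            if vals[cluster[-1]] - vals[i] <= max(gap, 2.0 * msf_sd):
                cluster.append(i)
            else:
                break
        return sorted(cluster)
    # kernel-density mode seeking: the clonal alterations form the rightmost
    # substantial mode (no MSF level can exceed the clonal one)
    bw = max(msf_sd, 0.02)
    grid = np.linspace(0.0, 1.05, 250)
    dens = np.exp(-0.5 * ((grid[:, None] - vals[None, :]) / bw) ** 2).sum(axis=1)
    min_mass = max(2.0, 0.08 * n)
    mode = None
    for k in range(len(grid) - 1, -1, -1):
        left = dens[k - 1] if k > 0 else -1.0
        right = dens[k + 1] if k < len(grid) - 1 else -1.0
        if dens[k] >= left and dens[k] >= right:
            support = int(np.sum(np.abs(vals - grid[k]) <= 1.5 * bw))
            if support >= min_mass:
                mode = grid[k]
                break
    if mode is None:
        mode = float(vals.max())
    window = 2.0 * bw
    return sorted(i for i in range(n) if abs(vals[i] - mode) <= window + 1e-12)


def quantify_sample(
    segments: list[SegmentCall],
    anchors: Optional[Sequence[int]] = None,
    tcf_override: Optional[float] = None,
    anchor_gap: float = 0.1,
    msf_sd: float = 0.0,
) -> tuple[list[SegmentCall], SamplePurity]:
    """Fill MSF/MCF/clonality on every segment of one sample.

    Routes each segment to the log2R or mBAF inversion by alteration type,
    estimates the purity from anchor segments (by index; default: the
    highest-MSF cluster), then normalizes every segment. ``tcf_override``
    bypasses anchor-based purity estimation (sd_msf = 0).
    """
    if not segments:
        raise InvalidInputError("no segments supplied")
    sample_ids = {s.sample_id for s in segments}
    if len(sample_ids) != 1:
        raise InvalidInputError(f"segments span multiple samples: {sorted(sample_ids)}")
    sample_id = segments[0].sample_id

    quantifiable = [s for s in segments if s.alteration_type != "snv"]
    raw = {id(s): _raw_msf(s) for s in quantifiable}

    if tcf_override is not None:
        if not (0.0 < tcf_override <= 1.0):
            raise InvalidInputError(f"tcf override must be in (0, 1], got {tcf_override}")
        purity = SamplePurity(sample_id, tcf_override, 0.0, 1.0, 1.0, 0)
    else:
        if anchors is None:
            raws = [raw[id(s)] for s in quantifiable]
            anchor_idx = select_anchors(raws, gap=anchor_gap, msf_sd=msf_sd)
            anchor_vals = [raws[i] for i in anchor_idx if 0.0 < raws[i] <= 1.0]
        else:
            anchor_vals = [raw[id(quantifiable[i])] for i in anchors]
        purity = estimate_tcf(anchor_vals, sample_id=sample_id)
        if purity.sd_msf < msf_sd:  # the assay cannot be more precise than its noise floor
            sd = msf_sd
            purity = SamplePurity(sample_id, purity.tcf, sd,
                                  (purity.tcf - 2 * sd) / purity.tcf,
                                  (purity.tcf + 2 * sd) / purity.tcf,
                                  purity.n_clonal_anchors)

    for seg in quantifiable:
        seg.msf = raw[id(seg)]
        seg.mcf, seg.is_clonal = mcf_normalize(seg.msf, purity)
    return segments, purity
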