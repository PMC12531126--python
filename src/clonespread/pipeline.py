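"""End-to-end orchestration: quantify -> filter -> deconvolve -> tree -> classify.

Per patient the pipeline fills MSF/MCF on the segment table, estimates
per-sample purity, filters and converts targeted-sequencing variants, merges
alterations into patient-level events, deconvolves subclones, reconstructs
the maximum-parsimony clone tree and classifies the spread modes. Per-patient
failures are isolated: the patient is flagged not-evaluable and the run
continues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as csio
from .errors import ClonespreadError, ConfigurationError
from .events import (DETECTION_THRESHOLD, MCF_TOLERANCE, RECIPROCAL_OVERLAP,
                     EventMatrix, EventTable, deconvolve_patient, merge_events)
from .segments import SegmentCall
from .spread import SpreadReport, classify_patient, cohort_grid, cohort_tests
from .tree import CloneTree, EXHAUSTIVE_LIMIT, annotate_tree, max_parsimony_tree
from .variants import (FilteredVariant, build_bed_index, consensus_keep,
                       exclude_low_quality, fill_mcf)

LN2 = math.log(2.0)


@dataclass
class PipelineConfig:
    """Thresholds and measurement assumptions for one run."""

    detection_threshold: float = DETECTION_THRESHOLD
    mcf_tolerance: float = MCF_TOLERANCE
    reciprocal_overlap: float = RECIPROCAL_OVERLAP
    anchor_gap: float = 0.1
    log2r_sd: float = 0.0  # assumed log2R measurement SD (0 = noiseless assay)
    baf_sd: float = 0.0
    exhaustive_limit: int = EXHAUSTIVE_LIMIT
    seed: int = 0
    count_relapse: bool = True
    tcf_overrides: dict = field(default_factory=dict)  # sample_id -> TCF

    def __post_init__(self):
        for name in ("detection_threshold", "mcf_tolerance", "reciprocal_overlap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PatientResult:
    patient_id: str
    segments: list = field(default_factory=list)
    purities: dict = field(default_factory=dict)  # sample -> SamplePurity
    filtered_variants: list = field(default_factory=list)
    event_table: Optional[EventTable] = None
    subclones: list = field(default_factory=list)
    matrix: Optional[EventMatrix] = None
    tree: Optional[CloneTree] = None
    report: Optional[SpreadReport] = None
    error: Optional[str] = None


def quantify_patient(segments: list, config: PipelineConfig) -> tuple[list, dict]:
    """Quantify every sample of one patient; returns (segments, purities).

    Purity is anchored on the truncal alterations — the ones whose footprint
    recurs in every sample of the patient (presence calls are curated, so
    this set is reliable): their MSF level in a sample is the tumor cell
    fraction. Samples fall back to the per-sample highest-mode estimate when
    fewer than three truncal alterations exist.
    """
    from .events import merge_events as _merge
    from .segments import _raw_msf, SamplePurity, select_anchors

    by_sample: dict[str, list[SegmentCall]] = {}
    for s in segments:
        if s.alteration_type == "snv" or not s.passes_cna_filters():
            continue
        by_sample.setdefault(s.sample_id, []).append(s)
    if not by_sample:
        raise ConfigurationError("no quantifiable segments")
    samples = sorted(by_sample)

    for sid in samples:
        for seg in by_sample[sid]:
            seg.msf = _raw_msf(seg)
            seg.mcf = seg.msf  # provisional: lets the footprint merge run on MSF
            seg.mcf_sd = _msf_noise(seg, config)
    all_segs = [s for sid in samples for s in by_sample[sid]]
    table = _merge(all_segs, reciprocal_overlap=config.reciprocal_overlap,
                   detection_threshold=0.0)
    truncal = [ev for ev in table.events
               if all(ev.present.get(s, False) for s in samples)]

    purities = {}
    for sid in samples:
        override = config.tcf_overrides.get(sid)
        if override is not None:
            purities[sid] = SamplePurity(sid, override, 0.0, 1.0, 1.0, 0)
            continue
        if len(truncal) >= 3:
            vals = [ev.mcf[sid] for ev in truncal]
            bws = [max(ev.sd.get(sid, 0.0), 0.02) for ev in truncal]
        else:
            vals = [seg.msf for seg in by_sample[sid]]
            bws = [max(seg.mcf_sd or 0.0, 0.02) for seg in by_sample[sid]]
        anchor_vals = _top_mode_values(vals, bws)
        mu = float(np.mean(anchor_vals))
        scatter = float(np.std(anchor_vals, ddof=1)) if len(anchor_vals) > 1 else 0.0
        sd = max(scatter, 2.0 * LN2 * config.log2r_sd)
        mu = min(max(mu, 1e-6), 1.0)
        purities[sid] = SamplePurity(sid, mu, sd, (mu - 2 * sd) / mu, (mu + 2 * sd) / mu,
                                     len(anchor_vals))

    from .segments import mcf_normalize

    out = []
    for sid in samples:
        purity = purities[sid]
        for seg in by_sample[sid]:
            seg.mcf, seg.is_clonal = mcf_normalize(seg.msf, purity)
            seg.mcf_sd = _segment_mcf_sd(seg, purity.tcf, config)
            out.append(seg)
    return out, purities


def _msf_noise(seg: SegmentCall, config: PipelineConfig) -> float:
    """Assumed measurement SD of one segment's MSF."""
    if seg.alteration_type in ("gain", "loss") and seg.log2r is not None:
        return abs(seg.background_ploidy * (2.0 ** seg.log2r) * LN2
                   / (seg.n_alleles_total - seg.background_ploidy)) * config.log2r_sd
    if seg.alteration_type == "cnni":
        return (seg.background_ploidy / abs(seg.n_b - seg.background_ploidy / 2.0)) * config.baf_sd
    return 0.0


def _top_mode_values(vals: list, bws: list) -> list:
    """Values belonging to the rightmost substantial density mode.

    Per-point bandwidths let precise measurement kinds (BAF-based) sharpen
    the mode even when noisy ones (log2R-based) smear it.
    """
    if len(vals) == 1:
        return list(vals)
    v = np.asarray(vals, dtype=float)
    b = np.asarray(bws, dtype=float)
    grid = np.linspace(0.0, 1.05, 264)
    dens = (np.exp(-0.5 * ((grid[:, None] - v[None, :]) / b[None, :]) ** 2) / b[None, :]).sum(axis=1)
    for k in range(len(grid) - 1, -1, -1):
        left = dens[k - 1] if k > 0 else -1.0
        right = dens[k + 1] if k < len(grid) - 1 else -1.0
        if dens[k] >= left and dens[k] >= right:
            inside = np.abs(v - grid[k]) <= 2.0 * b
            if int(inside.sum()) >= 2:
                return list(v[inside])
    return [float(v.max())]


def _segment_mcf_sd(seg: SegmentCall, tcf: float, config: PipelineConfig) -> float:
    """Propagate the assumed assay noise onto the MCF of one segment."""
    if seg.alteration_type in ("gain", "loss") and seg.log2r is not None:
        slope = abs(seg.background_ploidy * (2.0 ** seg.log2r) * LN2
                    / (seg.n_alleles_total - seg.background_ploidy))
        return slope * config.log2r_sd / tcf
    if seg.alteration_type == "cnni":
        slope = seg.background_ploidy / abs(seg.n_b - seg.background_ploidy / 2.0)
        return slope * config.baf_sd / tcf
    return 0.0


def process_variants(
    variants: list,
    bed_regions: list,
    purities: dict,
    quantified_segments: list,
    config: PipelineConfig,
) -> tuple[list, list]:
    """Filter calls, convert VAF to MCF, and emit type=snv segment rows."""
    if not variants:
        return [], []
    if not bed_regions:
        raise ConfigurationError("variant calls supplied without a BED file")
    bed = build_bed_index(bed_regions)
    calls = exclude_low_quality(variants)
    kept = consensus_keep(calls, bed)

    cna_by_sample: dict[str, list[SegmentCall]] = {}
    for seg in quantified_segments:
        if seg.alteration_type in ("gain", "loss", "cnni"):
            cna_by_sample.setdefault(seg.sample_id, []).append(seg)

    def cna_lookup(sid, chrom, pos):
        for seg in cna_by_sample.get(sid, []):
            if seg.chrom == chrom and seg.start <= pos <= seg.end:
                return seg.n_alleles_total, seg.mcf or 0.0
        return None

    tcfs = {sid: p.tcf for sid, p in purities.items()}
    intervals = {sid: (p.clonal_low, p.clonal_high) for sid, p in purities.items()}
    fill_mcf(kept, tcfs, cna_lookup=cna_lookup, clonal_intervals=intervals)

    snv_segments = csio.filtered_variants_to_segments(kept)
    for seg in snv_segments:
        fv = next(v for v in kept if v.chrom == seg.chrom and v.pos == seg.start
                  and seg.sample_id in v.mcf)
        vaf = fv.vaf[seg.sample_id]
        dp = max(1, fv.dp[seg.sample_id])
        tcf = tcfs.get(seg.sample_id, 1.0)
        seg.mcf_sd = 2.0 * math.sqrt(max(vaf * (1 - vaf), 1.0 / dp) / dp) / tcf
    return kept, snv_segments


def analyze_patient(
    patient_id: str,
    segments: list,
    variants: Optional[list] = None,
    bed_regions: Optional[list] = None,
    metadata: Optional[dict] = None,
    config: Optional[PipelineConfig] = None,
) -> PatientResult:
    """Run the full per-patient analysis; failures are captured, not raised."""
    config = config or PipelineConfig()
    result = PatientResult(patient_id=patient_id)
    try:
        quantified, purities = quantify_patient(segments, config)
        result.segments, result.purities = quantified, purities

        snv_rows: list = []
        if variants:
            kept, snv_rows = process_variants(variants, bed_regions or [], purities,
                                              quantified, config)
            result.filtered_variants = kept

        table = merge_events(quantified + snv_rows,
                             reciprocal_overlap=config.reciprocal_overlap,
                             detection_threshold=config.detection_threshold)
        result.event_table = table

        subclones, matrix = deconvolve_patient(
            table, mcf_tolerance=config.mcf_tolerance,
            detection_threshold=config.detection_threshold)
        result.subclones, result.matrix = subclones, matrix

        tree = max_parsimony_tree(matrix.matrix, exhaustive_limit=config.exhaustive_limit,
                                  seed=config.seed)
        if metadata:
            annotate_tree(tree, metadata, matrix.fractions,
                          detection_threshold=config.detection_threshold)
        result.tree = tree
        if metadata:
            result.report = classify_patient(tree, patient_id=patient_id,
                                             count_relapse=config.count_relapse)
    except ClonespreadError as exc:
        result.error = f"{type(exc).__name__}: {exc}"
    return result


def analyze_cohort(patients: list, config: Optional[PipelineConfig] = None) -> dict:
    """Analyze a list of per-patient input dicts.

    Each input dict needs keys patient_id, segments; optional variants,
    bed_regions, metadata. Returns {"results": [...], "grid": DataFrame,
    "igd": DataFrame, "stats": dict}.
    """
    config = config or PipelineConfig()
    results = [
        analyze_patient(p["patient_id"], p["segments"], p.get("variants"),
                        p.get("bed_regions"), p.get("metadata"), config)
        for p in patients
    ]
    reports = [r.report for r in results if r.report is not None]
    grid = cohort_grid(reports) if reports else pd.DataFrame()

    igd_rows = []
    for r in results:
        if r.report is None:
            continue
        for key, val in r.report.igd.items():
            scope, name = key.split(":", 1)
            igd_rows.append({"patient": r.patient_id, "scope": scope,
                             "label": name, "igd": val})
    igd_table = pd.DataFrame(igd_rows, columns=["patient", "scope", "label", "igd"])

    stats = _cohort_statistics(results, igd_table)
    return {"results": results, "grid": grid, "igd": igd_table, "stats": stats}


def _cohort_statistics(results: list, igd_table: pd.DataFrame) -> dict:
    """CNA burden by sample class (Mann-Whitney) and paired IGD tests."""
    burden: dict[str, list] = {}
    for r in results:
        if r.error:
            continue
        meta = {}
        if r.report is not None and r.tree is not None:
            for node in r.tree.nodes.values():
                for det in node.detections:
                    meta[det.sample_id] = det.sample_class
        counts: dict[str, int] = {}
        for seg in r.segments:
            if seg.alteration_type == "snv":
                continue
            counts[seg.sample_id] = counts.get(seg.sample_id, 0) + 1
        for sid, n in counts.items():
            cls = meta.get(sid)
            if cls:
                burden.setdefault(cls, []).append(n)

    paired = None
    if not igd_table.empty:
        cls_igd = igd_table[igd_table.scope == "class"]
        prim = cls_igd[cls_igd.label == "primary"].set_index("patient")["igd"]
        dist = cls_igd[cls_igd.label == "distant"].set_index("patient")["igd"]
        common = sorted(set(prim.index) & set(dist.index))
        if len(common) >= 2:
            paired = ("igd_primary", "igd_distant",
                      [float(prim[p]) for p in common], [float(dist[p]) for p in common])

    if len(burden) >= 2 or paired is not None:
        return cohort_tests(burden if len(burden) >= 2 else {"a": [], "b": []}, paired=paired)
    return {"mann_whitney": {}, "paired_t": None}


# ---------------------------------------------------------------------------
# file-based run
# ---------------------------------------------------------------------------

def run_pipeline(
    segments_path,
    metadata_path,
    outdir,
    variants_path=None,
    bed_path=None,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """File-in, file-out run over a cohort segment table.

    Writes, per patient: quantified segment file, filtered-variant table,
    event matrix + subclone fractions, Newick tree + edge table, spread
    report JSON; and cohort-level grid/IGD/statistics TSV/JSON plus a run
    log recording every threshold.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    segments = csio.read_segments(segments_path)
    meta_df = csio.read_metadata(metadata_path)
    metadata = csio.metadata_to_dict(meta_df)
    variants = csio.read_variants(variants_path) if variants_path else []
    bed_regions = csio.read_bed(bed_path) if bed_path else []
    if variants and not bed_regions:
        raise ConfigurationError("variants supplied without a BED file")

    by_patient: dict[str, dict] = {}
    for seg in segments:
        by_patient.setdefault(seg.patient_id, {"segments": [], "variants": []})["segments"].append(seg)
    for v in variants:
        by_patient.setdefault(v.patient_id, {"segments": [], "variants": []})["variants"].append(v)

    inputs = [
        {"patient_id": pid, "segments": d["segments"], "variants": d["variants"],
         "bed_regions": bed_regions,
         "metadata": {sid: m for sid, m in metadata.items()
                      if sid in {s.sample_id for s in d["segments"]}}}
        for pid, d in sorted(by_patient.items())
    ]
    out = analyze_cohort(inputs, config)

    for r in out["results"]:
        pdir = outdir / r.patient_id
        pdir.mkdir(exist_ok=True)
        if r.error:
            (pdir / "ERROR.txt").write_text(r.error + "\n")
            continue
        csio.write_segments(r.segments, pdir / "segments_quantified.tsv")
        if r.matrix is not None:
            csio.write_matrix(r.matrix.matrix, pdir / "event_matrix.tsv")
            csio.write_matrix(r.matrix.fractions, pdir / "subclone_fractions.tsv")
        if r.tree is not None:
            (pdir / "tree.nwk").write_text(r.tree.newick() + "\n")
            r.tree.edge_table().to_csv(pdir / "tree_edges.tsv", sep="\t", index=False)
        if r.report is not None:
            csio.write_report(r.report, pdir / "spread_report.json")

    if not out["grid"].empty:
        out["grid"].to_csv(outdir / "spread_grid.tsv", sep="\t", index_label="mode")
    out["igd"].to_csv(outdir / "igd_table.tsv", sep="\t", index=False)
    with open(outdir / "statistics.json", "w") as fh:
        json.dump(out["stats"], fh, indent=2, sort_keys=True)

    log = {
        "seed": config.seed,
        "detection_threshold": config.detection_threshold,
        "mcf_tolerance": config.mcf_tolerance,
        "reciprocal_overlap": config.reciprocal_overlap,
        "anchor_gap": config.anchor_gap,
        "log2r_sd": config.log2r_sd,
        "baf_sd": config.baf_sd,
        "exhaustive_limit": config.exhaustive_limit,
        "count_relapse": config.count_relapse,
        "n_patients": len(out["results"]),
        "errors": {r.patient_id: r.error for r in out["results"] if r.error},
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
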