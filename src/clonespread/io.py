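"""Readers and writers for the pipeline's tab-delimited formats.

* segment files: one row per alteration per sample, mirroring the cohort
  segment-table layout (patient, sample, chrom, start, end, type, Nt, NA, NB,
  Np, log2R, mBAF, MSF, MCF, clonal, gene, hgvs); missing numeric cells "NA"
* variant tables: flat per-caller TSV, or VCF v4.2 via cyvcf2
* BED (0-based half-open) target regions
* sample metadata (patient, sample, site, sample_class, timepoint)
* event matrices / subclone fraction tables as TSV
"""

from __future__ import annotations

import json
import math
from typing import Iterable, Optional

import pandas as pd

from .errors import DataError
from .segments import SegmentCall
from .variants import FilteredVariant, VariantCall

SEGMENT_COLUMNS = [
    "patient", "sample", "chrom", "start", "end", "type",
    "Nt", "NA", "NB", "Np", "log2R", "mBAF", "MSF", "MCF", "clonal",
    "gene", "hgvs",
]

VARIANT_COLUMNS = [
    "patient", "sample", "caller", "chrom", "pos", "ref", "alt",
    "vaf_t", "vaf_n", "dp_t", "dp_n", "mapq",
    "passed_internal", "in_pon", "in_popdb", "annotation",
]

METADATA_COLUMNS = ["patient", "sample", "site", "sample_class", "timepoint"]


def _na(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _opt(v, cast):
    if v in ("NA", "", None) or (isinstance(v, float) and math.isnan(v)):
        return None
    return cast(v)


# ---------------------------------------------------------------------------
# segment files
# ---------------------------------------------------------------------------

def segments_to_frame(segments: Iterable[SegmentCall]) -> pd.DataFrame:
    rows = []
    for s in segments:
        rows.append({
            "patient": s.patient_id, "sample": s.sample_id, "chrom": s.chrom,
            "start": s.start, "end": s.end, "type": s.alteration_type,
            "Nt": _na(s.n_alleles_total), "NA": _na(s.n_a), "NB": _na(s.n_b),
            "Np": s.background_ploidy, "log2R": _na(s.log2r), "mBAF": _na(s.mbaf),
            "MSF": _na(s.msf), "MCF": _na(s.mcf), "clonal": _na(s.is_clonal),
            "gene": _na(s.gene), "hgvs": _na(s.hgvs),
        })
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segments(segments: Iterable[SegmentCall], path) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[SegmentCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"segment file {path} lacks columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(SegmentCall(
                patient_id=row["patient"], sample_id=row["sample"], chrom=row["chrom"],
                start=int(row["start"]), end=int(row["end"]), alteration_type=row["type"],
                n_alleles_total=_opt(row["Nt"], int), n_a=_opt(row["NA"], int),
                n_b=_opt(row["NB"], int), background_ploidy=int(row["Np"]),
                log2r=_opt(row["log2R"], float), mbaf=_opt(row["mBAF"], float),
                msf=_opt(row["MSF"], float), mcf=_opt(row["MCF"], float),
                is_clonal=None if row["clonal"] == "NA" else bool(int(row["clonal"])),
                gene=_opt(row["gene"], str), hgvs=_opt(row["hgvs"], str),
            ))
        except (ValueError, KeyError) as exc:
            raise DataError(f"segment file {path}, row {i + 2}: {exc}") from exc
    return out


def filtered_variants_to_segments(variants: Iterable[FilteredVariant]) -> list[SegmentCall]:
    """Represent consensus-kept SNVs as type=snv segment rows (one per sample)."""
    out = []
    for fv in variants:
        for sid in sorted(fv.mcf):
            out.append(SegmentCall(
                patient_id=fv.patient_id, sample_id=sid, chrom=fv.chrom,
                start=fv.pos, end=fv.pos, alteration_type="snv",
                mcf=fv.mcf[sid], msf=None,
                is_clonal=fv.mcf[sid] >= 1.0 - 1e-9,
                gene=fv.annotation or None, hgvs=f"{fv.ref}>{fv.alt}",
            ))
    return out


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def variants_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "patient": c.patient_id, "sample": c.sample_id, "caller": c.caller,
            "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "vaf_t": f"{c.vaf_tumor:.6g}", "vaf_n": f"{c.vaf_normal:.6g}",
            "dp_t": c.dp_tumor, "dp_n": c.dp_normal, "mapq": f"{c.mapq:.6g}",
            "passed_internal": int(c.passed_internal), "in_pon": int(c.in_pon),
            "in_popdb": int(c.in_popdb), "annotation": c.annotation or "NA",
        })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variants(calls: Iterable[VariantCall], path) -> None:
    variants_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_variants(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"variant table {path} lacks columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(VariantCall(
                patient_id=row["patient"], sample_id=row["sample"], caller=row["caller"],
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                vaf_tumor=float(row["vaf_t"]), vaf_normal=float(row["vaf_n"]),
                dp_tumor=int(row["dp_t"]), dp_normal=int(row["dp_n"]),
                mapq=float(row["mapq"]),
                passed_internal=bool(int(row["passed_internal"])),
                in_pon=bool(int(row["in_pon"])), in_popdb=bool(int(row["in_popdb"])),
                annotation="" if row["annotation"] == "NA" else row["annotation"],
            ))
        except (ValueError, KeyError) as exc:
            raise DataError(f"variant table {path}, row {i + 2}: {exc}") from exc
    return out


def read_vcf(path, patient_id: str, sample_id: str, caller: str,
             tumor_sample: str = "TUMOR", normal_sample: str = "NORMAL") -> list[VariantCall]:
    """Read a two-sample (tumor/normal) VCF v4.2 produced by one caller.

    Uses the per-sample AF and DP FORMAT fields and the FILTER column
    (PASS/. -> passed_internal).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    try:
        ti, ni = names.index(tumor_sample), names.index(normal_sample)
    except ValueError as exc:
        raise DataError(f"{path}: expected samples {tumor_sample}/{normal_sample}, found {names}") from exc
    out = []
    for rec in vcf:
        af = rec.format("AF")
        dp = rec.format("DP")
        if af is None or dp is None:
            raise DataError(f"{path}: records need AF and DP FORMAT fields")
        mq = rec.INFO.get("MQ", 60.0)
        for alt in rec.ALT:
            out.append(VariantCall(
                patient_id=patient_id, sample_id=sample_id, caller=caller,
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                vaf_tumor=float(af[ti][0]), vaf_normal=float(af[ni][0]),
                dp_tumor=int(dp[ti][0]), dp_normal=int(dp[ni][0]), mapq=float(mq),
                passed_internal=rec.FILTER is None,
            ))
    return out


# ---------------------------------------------------------------------------
# BED / metadata / matrices / reports
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}, line {i + 1}: BED needs >= 3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(regions: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"metadata {path} lacks columns {sorted(missing)}")
    return df


def write_metadata(metadata: dict, patient_id: str, path) -> None:
    rows = [{"patient": patient_id, "sample": sid, "site": site,
             "sample_class": cls, "timepoint": "diagnosis" if cls != "relapse" else "relapse"}
            for sid, (site, cls) in sorted(metadata.items())]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def metadata_to_dict(df: pd.DataFrame) -> dict:
    return {row["sample"]: (row["site"], row["sample_class"]) for _, row in df.iterrows()}


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="subclone")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subclone")


def write_report(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
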