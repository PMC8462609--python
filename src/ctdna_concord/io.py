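"""Readers and writers for the formats the pipeline touches.

VCF dialect
-----------
Somatic calls are exchanged as single-sample VCF 4.2 with a flat INFO
schema rather than nested VeP/SnpEff annotation strings:

==========  =======  ==========================================
INFO key    Number   meaning
==========  =======  ==========================================
POP_AF      A        general-population allele frequency
IMPACT      A        HIGH / MODERATE / LOW / MODIFIER
CADD        A        CADD Phred-scaled deleteriousness score
SAF         A        alt-supporting reads, forward strand
SAR         A        alt-supporting reads, reverse strand
VAF         A        variant (mutant) allele fraction
GENE        A        HGNC-style gene symbol
CSQ_CLASS   A        consequence class (missense, nonsense, ...)
==========  =======  ==========================================

All eight keys must be declared in the header (schema error otherwise);
a record may omit any of them, which maps to the ``None`` sentinel on the
variant. Adapters for real VeP/SnpEff output can populate the same keys.

Other formats: clinical and fragment tables are tab-separated with
documented headers; panels are written as BED4 (0-based half-open, gene
symbol in column 4). VCF positions are 1-based; the 1-based/0-based
conversion lives in the BED writer only.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .data_model import (
    FragmentProfile,
    PanelSpec,
    PatientRecord,
    SomaticVariant,
    ValidationError,
    infer_variant_type,
)

MANDATORY_INFO_KEYS = ("POP_AF", "IMPACT", "CADD", "SAF", "SAR", "VAF", "GENE", "CSQ_CLASS")

CLINICAL_COLUMNS = [
    "sample_id", "age", "sex", "t_stage", "n_stage", "m_stage",
    "survival_days", "event", "cea", "ca19_9", "ca72_4",
    "msi_status", "tmb", "group",
]


class VcfParseError(ValueError):
    """The VCF could not be parsed; the message names the offending line."""


class SchemaError(ValueError):
    """The VCF header does not declare a mandatory INFO key."""


def _info_scalar(rec: "pysam.VariantRecord", key: str, alt_index: int):
    """Per-ALT INFO value or None when the record omits the key."""
    if key not in rec.info:
        return None
    val = rec.info[key]
    if isinstance(val, tuple):
        val = val[alt_index] if alt_index < len(val) else None
    if val is None or (isinstance(val, str) and val in (".", "")):
        return None
    return val


def read_somatic_vcf(path: str | os.PathLike, compartment: str) -> list[SomaticVariant]:
    """Read a single-sample somatic VCF into SomaticVariant objects.

    Multi-allelic records are split into one variant per ALT allele.
    Missing annotations become ``None`` sentinels (never zero), so the
    filter cascade can reject them with an explicit reason.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    for key in MANDATORY_INFO_KEYS:
        if key not in vcf.header.info:
            raise SchemaError(f"VCF {path} header missing mandatory INFO key {key}")
    sample_id = list(vcf.header.samples)[0] if len(vcf.header.samples) else path.stem
    variants: list[SomaticVariant] = []
    try:
        for rec in vcf:
            for i, alt in enumerate(rec.alts or ()):
                pop_af = _info_scalar(rec, "POP_AF", i)
                cadd = _info_scalar(rec, "CADD", i)
                saf = _info_scalar(rec, "SAF", i)
                sar = _info_scalar(rec, "SAR", i)
                vaf = _info_scalar(rec, "VAF", i)
                variants.append(SomaticVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=_info_scalar(rec, "GENE", i),
                    consequence_class=_info_scalar(rec, "CSQ_CLASS", i),
                    variant_type=infer_variant_type(rec.ref, alt),
                    population_af=None if pop_af is None else float(pop_af),
                    impact=_info_scalar(rec, "IMPACT", i),
                    cadd_phred=None if cadd is None else float(cadd),
                    fwd_support=None if saf is None else int(saf),
                    rev_support=None if sar is None else int(sar),
                    vaf=None if vaf is None else float(vaf),
                    sample_id=sample_id,
                    compartment=compartment,
                ))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"malformed record in {path}: {exc}") from exc
    finally:
        vcf.close()
    return variants


def _fmt(val, ndigits: int | None = None) -> str:
    if val is None:
        return "."
    if ndigits is not None and isinstance(val, float):
        return f"{val:.{ndigits}g}"
    return str(val)


def write_somatic_vcf(variants: Sequence[SomaticVariant], path: str | os.PathLike,
                      sample_id: Optional[str] = None) -> None:
    """Write variants (one subject, one compartment) as uncompressed VCF 4.2."""
    path = Path(path)
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else path.stem
    contigs = sorted({v.chrom for v in variants})
    header = pysam.VariantHeader()
    for c in contigs:
        header.contigs.add(c, length=250_000_000)
    header.info.add("POP_AF", "A", "Float", "General-population allele frequency")
    header.info.add("IMPACT", "A", "String", "Predicted impact class")
    header.info.add("CADD", "A", "Float", "CADD Phred-scaled score")
    header.info.add("SAF", "A", "Integer", "Alt-supporting reads, forward strand")
    header.info.add("SAR", "A", "Integer", "Alt-supporting reads, reverse strand")
    header.info.add("VAF", "A", "Float", "Variant allele fraction")
    header.info.add("GENE", "A", "String", "Gene symbol")
    header.info.add("CSQ_CLASS", "A", "String", "Consequence class")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_id)
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with open(path, "w") as fh:
        fh.write(str(header))
        for v in ordered:
            info_parts = []
            for key, val in (("POP_AF", v.population_af), ("IMPACT", v.impact),
                             ("CADD", v.cadd_phred), ("SAF", v.fwd_support),
                             ("SAR", v.rev_support), ("VAF", v.vaf),
                             ("GENE", v.gene), ("CSQ_CLASS", v.consequence_class)):
                if val is not None:
                    info_parts.append(f"{key}={_fmt(val, 9)}")
            info = ";".join(info_parts) if info_parts else "."
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t0/1\n")


def read_clinical_table(path: str | os.PathLike) -> list[PatientRecord]:
    """Read the tab-separated clinical table into PatientRecord objects.

    Raises ValidationError listing any stage/vocabulary values outside the
    closed vocabularies.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    records = []
    errors = []
    for _, row in df.iterrows():
        try:
            records.append(PatientRecord(
                sample_id=row["sample_id"],
                age=float(row["age"]),
                sex=str(row["sex"]),
                t_stage=str(row["t_stage"]),
                n_stage=str(row["n_stage"]),
                m_stage=str(row["m_stage"]),
                survival_days=float(row["survival_days"]),
                event=bool(int(row["event"])),
                cea=float(row["cea"]),
                ca19_9=float(row["ca19_9"]),
                ca72_4=float(row["ca72_4"]),
                msi_status=str(row["msi_status"]),
                tmb=float(row["tmb"]),
                group=str(row["group"]),
            ))
        except ValidationError as exc:
            errors.append(f"{row['sample_id']}: {exc}")
    if errors:
        raise ValidationError("invalid clinical rows: " + "; ".join(errors))
    return records


def write_clinical_table(records: Iterable[PatientRecord], path: str | os.PathLike) -> None:
    rows = [{
        "sample_id": r.sample_id, "age": r.age, "sex": r.sex,
        "t_stage": r.t_stage, "n_stage": r.n_stage, "m_stage": r.m_stage,
        "survival_days": r.survival_days, "event": int(r.event),
        "cea": r.cea, "ca19_9": r.ca19_9, "ca72_4": r.ca72_4,
        "msi_status": r.msi_status, "tmb": r.tmb, "group": r.group,
    } for r in records]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fragment_profile(path: str | os.PathLike) -> FragmentProfile:
    """Read a two-column size/concentration table.

    Leading ``#`` comment lines may carry ``sample_id=`` and
    ``analysis_range=lo,hi`` metadata; otherwise the file stem names the
    sample and the range defaults to [100, 1000] bp.
    """
    path = Path(path)
    sample_id = path.stem
    analysis_range = (100.0, 1000.0)
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("sample_id="):
                sample_id = body.split("=", 1)[1]
            elif body.startswith("analysis_range="):
                lo, hi = body.split("=", 1)[1].split(",")
                analysis_range = (float(lo), float(hi))
    df = pd.read_csv(path, sep="\t", skiprows=header_lines)
    if not {"size_bp", "conc_pg_per_ml_bp"} <= set(df.columns):
        raise ValidationError(
            f"fragment table {path} must have columns size_bp, conc_pg_per_ml_bp")
    return FragmentProfile(
        sample_id=sample_id,
        sizes=df["size_bp"].to_numpy(dtype=float),
        concentrations=df["conc_pg_per_ml_bp"].to_numpy(dtype=float),
        analysis_range=analysis_range,
    )


def write_fragment_profile(profile: FragmentProfile, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id={profile.sample_id}\n")
        lo, hi = profile.analysis_range
        fh.write(f"# analysis_range={lo:g},{hi:g}\n")
        fh.write("size_bp\tconc_pg_per_ml_bp\n")
        for s, c in zip(profile.sizes, profile.concentrations):
            fh.write(f"{s:g}\t{c:.10g}\n")


def write_panel_bed(panel: PanelSpec, path: str | os.PathLike) -> None:
    """Emit the panel as BED4 (0-based half-open), gene symbol in column 4."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene\n")
        for chrom, start, end in panel.intervals:
            gene = _gene_for_interval(panel, chrom, start, end)
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


def _gene_for_interval(panel: PanelSpec, chrom: str, start: int, end: int) -> str:
    for gene, variants in panel.provenance.items():
        for v in variants:
            if v.chrom == chrom and start < v.pos <= end:  # BED half-open vs 1-based pos
                return gene
    return "."


def read_panel_bed(path: str | os.PathLike) -> PanelSpec:
    genes: list[str] = []
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, gene = line.rstrip("\n").split("\t")[:4]
            intervals.append((chrom, int(start), int(end)))
            if gene != "." and gene not in genes:
                genes.append(gene)
    return PanelSpec(genes=genes, intervals=intervals)
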