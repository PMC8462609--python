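"""Tissue-plasma variant matching and mutational-spectrum summaries.

Matching is exact on normalized (chrom, pos, ref, alt) keys: plasma
sequencing here is tumor-informed (the panel was designed from the same
patients' tissue calls), so a plasma variant either is or is not the
tissue variant — no fuzzy windows. Spectrum summaries follow the
conventions of cohort mutational-landscape tools: six pyrimidine-
normalized substitution classes, per-sample counts, recurrence-ranked
top genes and a gene x sample oncomatrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .data_model import ConcordanceResult, SomaticVariant, VariantKey

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class SpectrumSummary:
    class_counts: dict[str, int]
    type_counts: dict[str, int]
    substitution_counts: dict[str, int]
    per_sample_counts: dict[str, int]
    mean_per_sample: float
    top_genes: list[tuple[str, int, float]]  # (gene, n mutated samples, fraction of variants)
    oncomatrix: pd.DataFrame = field(default_factory=pd.DataFrame)


def match_variants(tissue: Sequence[SomaticVariant],
                   plasma: Sequence[SomaticVariant]) -> ConcordanceResult:
    """Partition one patient's tissue and plasma calls into tissue-only,
    plasma-only and shared sets on normalized keys; VAF pairs are kept
    for shared keys (tumor-fraction / MAF analyses downstream)."""
    sids = {v.sample_id for v in tissue} | {v.sample_id for v in plasma}
    if len(sids) > 1:
        raise ValueError(f"mixed sample_ids in one comparison: {sorted(sids)}")
    sample_id = sids.pop() if sids else ""
    t_by_key = {v.key: v for v in tissue}
    p_by_key = {v.key: v for v in plasma}
    shared = set(t_by_key) & set(p_by_key)
    return ConcordanceResult(
        sample_id=sample_id,
        tissue_only_keys=set(t_by_key) - shared,
        plasma_only_keys=set(p_by_key) - shared,
        shared_keys=shared,
        shared_vaf_pairs={k: (t_by_key[k].vaf, p_by_key[k].vaf) for k in shared},
    )


@dataclass
class CohortConcordance:
    """Cohort-level detection fractions, always carried with their
    numerator/denominator (no bare percentages)."""

    n_tissue_positive: int
    n_plasma_positive: int          # >=1 plasma alteration of any kind
    n_shared_positive: int          # >=1 tissue-matching plasma alteration
    plasma_positive_fraction: Optional[float]
    shared_positive_fraction: Optional[float]
    mean_plasma_per_positive: Optional[float]
    mean_shared_per_positive: Optional[float]


def cohort_concordance(results: Sequence[ConcordanceResult],
                       tissue_positive_ids: Sequence[str]) -> CohortConcordance:
    """Detection fractions among tissue-alteration-positive patients.

    Fractions are None sentinels when ``tissue_positive_ids`` is empty.
    """
    positive = set(tissue_positive_ids)
    by_id = {r.sample_id: r for r in results}
    plasma_pos = [sid for sid in positive if sid in by_id and by_id[sid].n_plasma > 0]
    shared_pos = [sid for sid in positive if sid in by_id and by_id[sid].n_shared > 0]
    n_tp = len(positive)
    plasma_counts = [by_id[sid].n_plasma for sid in plasma_pos]
    shared_counts = [by_id[sid].n_shared for sid in shared_pos]
    return CohortConcordance(
        n_tissue_positive=n_tp,
        n_plasma_positive=len(plasma_pos),
        n_shared_positive=len(shared_pos),
        plasma_positive_fraction=len(plasma_pos) / n_tp if n_tp else None,
        shared_positive_fraction=len(shared_pos) / n_tp if n_tp else None,
        mean_plasma_per_positive=(sum(plasma_counts) / len(plasma_counts)
                                  if plasma_counts else None),
        mean_shared_per_positive=(sum(shared_counts) / len(shared_counts)
                                  if shared_counts else None),
    )


def _pyrimidine_class(ref: str, alt: str) -> Optional[str]:
    if ref in "GA":
        ref, alt = _COMPLEMENT.get(ref, "?"), _COMPLEMENT.get(alt, "?")
    cls = f"{ref}>{alt}"
    return cls if cls in SUBSTITUTION_CLASSES else None


def summarize_spectra(variants: Sequence[SomaticVariant]) -> SpectrumSummary:
    """Cohort mutational-spectrum summary.

    SNP substitutions are normalized to the pyrimidine reference (a G>A
    call counts as C>T). Top genes are ranked by number of mutated
    samples, then total variant count, then symbol.
    """
    class_counts: dict[str, int] = {}
    type_counts: dict[str, int] = {"SNP": 0, "INS": 0, "DEL": 0}
    sub_counts: dict[str, int] = {c: 0 for c in SUBSTITUTION_CLASSES}
    per_sample: dict[str, int] = {}
    gene_samples: dict[str, set[str]] = {}
    gene_totals: dict[str, int] = {}
    cells: dict[tuple[str, str], str] = {}
    for v in variants:
        cc = v.consequence_class or "other"
        class_counts[cc] = class_counts.get(cc, 0) + 1
        type_counts[v.variant_type] = type_counts.get(v.variant_type, 0) + 1
        if v.variant_type == "SNP":
            sub = _pyrimidine_class(v.ref, v.alt)
            if sub:
                sub_counts[sub] += 1
        per_sample[v.sample_id] = per_sample.get(v.sample_id, 0) + 1
        if v.gene:
            gene_samples.setdefault(v.gene, set()).add(v.sample_id)
            gene_totals[v.gene] = gene_totals.get(v.gene, 0) + 1
            cell = (v.gene, v.sample_id)
            cells[cell] = "multi_hit" if cell in cells else cc
    total = len(variants)
    ranked = sorted(gene_totals, key=lambda g: (-len(gene_samples[g]), -gene_totals[g], g))
    top_genes = [(g, len(gene_samples[g]), gene_totals[g] / total if total else 0.0)
                 for g in ranked]
    if cells:
        onc = pd.DataFrame("", index=ranked, columns=sorted(per_sample))
        for (g, sid), cls in cells.items():
            onc.loc[g, sid] = cls
    else:
        onc = pd.DataFrame()
    return SpectrumSummary(
        class_counts=class_counts,
        type_counts=type_counts,
        substitution_counts=sub_counts,
        per_sample_counts=dict(sorted(per_sample.items())),
        mean_per_sample=(total / len(per_sample) if per_sample else 0.0),
        top_genes=top_genes,
        oncomatrix=onc,
    )
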