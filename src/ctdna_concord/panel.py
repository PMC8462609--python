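"""Five-criterion somatic-variant filter cascade and capture-panel design.

Tissue somatic calls are retained only when ALL of the following hold:

(i)   population allele frequency < 1% (strict),
(ii)  protein-coding non-synonymous consequence with HIGH predicted impact,
(iii) CADD Phred score > 30 (strict),
(iv)  the variant key is NOT carried by 100% of cohort tissue samples,
(v)   >= 2 alt-supporting reads on each strand (inclusive).

A variant missing any annotation a criterion needs fails with the explicit
reason ``missing_annotation`` — unknowns never pass silently. The retained
variants then seed a recurrence-ranked gene panel truncated to
``max_genes`` (38 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .data_model import PanelSpec, SomaticVariant, VariantKey

# consequence classes counted as protein-coding non-synonymous; configurable
# because annotation vocabularies differ between annotators
CODING_NONSYNONYMOUS = frozenset({
    "missense", "nonsense", "frameshift-ins", "frameshift-del",
    "splice-site", "in-frame-indel",
})

POP_AF_MAX = 0.01
CADD_MIN = 30.0
STRAND_MIN = 2


@dataclass
class FilterDecision:
    key: VariantKey
    passed: bool
    failed_criteria: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failed_criteria) == 0)


@dataclass
class CohortFilterSummary:
    n_samples: int
    n_positive: int  # samples retaining >= 1 variant
    per_sample_retained: dict[str, int]
    mean_retained_among_positive: float

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_samples if self.n_samples else float("nan")


def passes_filters(v: SomaticVariant, cohort_presence_fraction: float, *,
                   pop_af_max: float = POP_AF_MAX,
                   cadd_min: float = CADD_MIN,
                   strand_min: int = STRAND_MIN,
                   coding_classes: frozenset[str] = CODING_NONSYNONYMOUS,
                   ) -> FilterDecision:
    """Evaluate the five filter criteria on one variant.

    ``cohort_presence_fraction`` is the fraction of cohort tissue samples
    carrying this variant's normalized key. Returns a decision, never an
    exception: each failed criterion is listed, and criteria that cannot
    be evaluated because the annotation is absent contribute a single
    ``missing_annotation`` reason.
    """
    failed: list[str] = []
    missing = False

    if v.population_af is None:
        missing = True
    elif not v.population_af < pop_af_max:
        failed.append("pop_af")

    if v.consequence_class is None or v.impact is None:
        missing = True
    elif not (v.consequence_class in coding_classes and v.impact == "HIGH"):
        failed.append("impact")

    if v.cadd_phred is None:
        missing = True
    elif not v.cadd_phred > cadd_min:
        failed.append("cadd")

    if not cohort_presence_fraction < 1.0:
        failed.append("ubiquity")

    if v.fwd_support is None or v.rev_support is None:
        missing = True
    elif not (v.fwd_support >= strand_min and v.rev_support >= strand_min):
        failed.append("strand_support")

    if missing:
        failed.append("missing_annotation")
    return FilterDecision(key=v.key, passed=not failed, failed_criteria=failed)


def cohort_presence(tissue_by_sample: Mapping[str, Sequence[SomaticVariant]]
                    ) -> dict[VariantKey, float]:
    """Fraction of tissue samples carrying each normalized variant key."""
    n = len(tissue_by_sample)
    counts: dict[VariantKey, int] = {}
    for variants in tissue_by_sample.values():
        for key in {v.key for v in variants}:
            counts[key] = counts.get(key, 0) + 1
    return {k: c / n for k, c in counts.items()} if n else {}


def filter_cohort(tissue_by_sample: Mapping[str, Sequence[SomaticVariant]], **thresholds
                  ) -> tuple[dict[str, list[SomaticVariant]], CohortFilterSummary,
                             dict[str, list[FilterDecision]]]:
    """Apply the cascade across a tissue cohort.

    Cohort presence fractions are computed on normalized keys over all
    samples BEFORE any per-variant decision, so the ubiquity criterion
    sees the unfiltered cohort. Returns (retained variants per sample,
    cohort summary, all per-variant decisions).
    """
    presence = cohort_presence(tissue_by_sample)
    retained: dict[str, list[SomaticVariant]] = {}
    decisions: dict[str, list[FilterDecision]] = {}
    for sid in sorted(tissue_by_sample):
        keep: list[SomaticVariant] = []
        decs: list[FilterDecision] = []
        for v in tissue_by_sample[sid]:
            if v.compartment != "tissue":
                raise ValueError(f"filter_cohort expects tissue variants, got "
                                 f"{v.compartment} for {sid}")
            d = passes_filters(v, presence.get(v.key, 0.0), **thresholds)
            decs.append(d)
            if d.passed:
                keep.append(v)
        retained[sid] = keep
        decisions[sid] = decs
    per_sample = {sid: len(vs) for sid, vs in retained.items()}
    positives = [c for c in per_sample.values() if c > 0]
    summary = CohortFilterSummary(
        n_samples=len(tissue_by_sample),
        n_positive=len(positives),
        per_sample_retained=per_sample,
        mean_retained_among_positive=(sum(positives) / len(positives)
                                      if positives else float("nan")),
    )
    return retained, summary, decisions


def _merge_intervals(intervals: Sequence[tuple[str, int, int]]
                     ) -> list[tuple[str, int, int]]:
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], end)))
        else:
            merged.append((chrom, start, end))
    return merged


def build_panel(retained_by_sample: Mapping[str, Sequence[SomaticVariant]],
                gene_intervals: Mapping[str, Sequence[tuple[str, int, int]]],
                max_genes: int = 38) -> PanelSpec:
    """Construct the capture panel from filtered tissue variants.

    Genes are ranked by (number of mutated samples, total variant count,
    then lexicographic symbol as a deterministic tie-break) and truncated
    to ``max_genes``; per-gene intervals are merged. A retained gene
    absent from ``gene_intervals`` is an error naming the gene.
    """
    sample_hits: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    provenance: dict[str, list[SomaticVariant]] = {}
    for sid, variants in retained_by_sample.items():
        for v in variants:
            if v.gene is None:
                continue
            sample_hits.setdefault(v.gene, set()).add(sid)
            totals[v.gene] = totals.get(v.gene, 0) + 1
            provenance.setdefault(v.gene, []).append(v)
    ranked = sorted(totals, key=lambda g: (-len(sample_hits[g]), -totals[g], g))
    genes = ranked[:max_genes]
    intervals: list[tuple[str, int, int]] = []
    for g in genes:
        if g not in gene_intervals:
            raise KeyError(f"gene {g} missing from gene_intervals")
        intervals.extend(gene_intervals[g])
    return PanelSpec(
        genes=genes,
        intervals=_merge_intervals(intervals),
        provenance={g: provenance[g] for g in genes},
    )
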