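"""Shared domain types for the tumor-informed liquid-biopsy pipeline.

The pipeline tracks somatic variants called in tumor tissue into plasma
cell-free DNA (cfDNA). These dataclasses are the common currency between
the simulator, the variant filter cascade, the tissue/plasma concordance
analysis and the statistical layer.

Missing annotations are represented by ``None`` sentinels and are never
coerced to zero: downstream filters reject them explicitly with a
``missing_annotation`` reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

CONSEQUENCE_CLASSES = frozenset({
    "missense", "nonsense", "frameshift-ins", "frameshift-del",
    "splice-site", "in-frame-indel", "synonymous", "other",
})
VARIANT_TYPES = frozenset({"SNP", "INS", "DEL"})
IMPACTS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})
COMPARTMENTS = frozenset({"tissue", "plasma"})
T_STAGES = frozenset({"T1", "T2", "T3", "T4", "unknown"})
N_STAGES = frozenset({"N0", "N1", "N2", "N3", "unknown"})
M_STAGES = frozenset({"M0", "M1", "unknown"})
MSI_STATUSES = frozenset({"MSS", "MSI-high", "unknown"})
SEXES = frozenset({"male", "female"})
GROUPS = frozenset({"case", "control"})


class ValidationError(ValueError):
    """An input violates a documented invariant or closed vocabulary."""


def infer_variant_type(ref: str, alt: str) -> str:
    """Classify an allele pair as SNP, INS or DEL from allele lengths."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(alt) > len(ref):
        return "INS"
    if len(alt) < len(ref):
        return "DEL"
    return "SNP" if len(ref) == 1 else "DEL"  # MNVs are rare; treat same-length >1 as DEL-like block


class VariantKey(NamedTuple):
    """Canonical (chrom, pos, ref, alt) identity used for all matching."""

    chrom: str
    pos: int
    ref: str
    alt: str


def normalize_variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Canonicalize a variant to its minimal left-shifted representation.

    Alleles are uppercased; shared trailing bases are trimmed, then shared
    leading bases are trimmed with the position shifted right accordingly.
    SNPs are unchanged. Key equality is the matching relation used by the
    whole pipeline (tissue-plasma concordance, cohort presence counting).
    """
    ref = ref.upper()
    alt = alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref = ref[:-1]
        alt = alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


@dataclass
class SomaticVariant:
    """One annotated somatic call in one compartment of one subject.

    ``population_af``, ``impact``, ``cadd_phred``, ``fwd_support``,
    ``rev_support``, ``vaf`` and ``consequence_class`` may be ``None`` when
    the source VCF record lacks the annotation.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str]
    consequence_class: Optional[str]
    variant_type: str
    population_af: Optional[float]
    impact: Optional[str]
    cadd_phred: Optional[float]
    fwd_support: Optional[int]
    rev_support: Optional[int]
    vaf: Optional[float]
    sample_id: str
    compartment: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.variant_type not in VARIANT_TYPES:
            raise ValidationError(f"unknown variant_type {self.variant_type!r}")
        if self.variant_type == "SNP" and not (len(self.ref) == 1 and len(self.alt) == 1):
            raise ValidationError(
                f"variant_type SNP inconsistent with alleles {self.ref}>{self.alt}")
        if self.consequence_class is not None and self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValidationError(f"unknown consequence_class {self.consequence_class!r}")
        if self.impact is not None and self.impact not in IMPACTS:
            raise ValidationError(f"unknown impact {self.impact!r}")
        for name in ("population_af", "vaf"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValidationError(f"{name} outside [0,1]: {val}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"cadd_phred negative: {self.cadd_phred}")
        for name in ("fwd_support", "rev_support"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValidationError(f"{name} negative: {val}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")

    @property
    def key(self) -> VariantKey:
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PatientRecord:
    """Clinical covariates, serum markers, staging and outcome for one subject."""

    sample_id: str
    age: float
    sex: str
    t_stage: str
    n_stage: str
    m_stage: str
    survival_days: float
    event: bool
    cea: float
    ca19_9: float
    ca72_4: float
    msi_status: str
    tmb: float
    group: str

    def __post_init__(self) -> None:
        if self.survival_days < 0:
            raise ValidationError(f"survival_days negative: {self.survival_days}")
        checks = [
            ("sex", self.sex, SEXES),
            ("t_stage", self.t_stage, T_STAGES),
            ("n_stage", self.n_stage, N_STAGES),
            ("m_stage", self.m_stage, M_STAGES),
            ("msi_status", self.msi_status, MSI_STATUSES),
            ("group", self.group, GROUPS),
        ]
        bad = [f"{name}={val!r}" for name, val, vocab in checks if val not in vocab]
        if bad:
            raise ValidationError("values outside closed vocabulary: " + ", ".join(bad))


@dataclass
class FragmentProfile:
    """cfDNA fragment size -> concentration curve for one plasma sample.

    Emulates capillary-electrophoresis output: ``concentrations[i]`` is the
    concentration density (pg/mL per bp) at fragment length ``sizes[i]``.
    """

    sample_id: str
    sizes: np.ndarray
    concentrations: np.ndarray
    analysis_range: tuple[float, float] = (100.0, 1000.0)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.sizes.shape != self.concentrations.shape:
            raise ValidationError("sizes and concentrations must have equal length")
        if self.sizes.size and np.any(np.diff(self.sizes) <= 0):
            raise ValidationError("sizes must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be non-negative")
        lo, hi = self.analysis_range
        if not lo < hi:
            raise ValidationError(f"invalid analysis_range {self.analysis_range}")


@dataclass
class PanelSpec:
    """A designed capture panel: gene list plus genomic target intervals.

    Intervals are 0-based half-open, merged per chromosome. ``provenance``
    maps each panel gene to the filtered tissue variants that put it on
    the panel.
    """

    genes: list[str]
    intervals: list[tuple[str, int, int]]
    provenance: dict[str, list[SomaticVariant]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("panel genes must be unique")


@dataclass
class ConcordanceResult:
    """Per-patient partition of tissue and plasma variant keys."""

    sample_id: str
    tissue_only_keys: set[VariantKey]
    plasma_only_keys: set[VariantKey]
    shared_keys: set[VariantKey]
    shared_vaf_pairs: dict[VariantKey, tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict)

    @property
    def n_tissue_only(self) -> int:
        return len(self.tissue_only_keys)

    @property
    def n_plasma_only(self) -> int:
        return len(self.plasma_only_keys)

    @property
    def n_shared(self) -> int:
        return len(self.shared_keys)

    @property
    def n_plasma(self) -> int:
        return self.n_plasma_only + self.n_shared

    @property
    def n_tissue(self) -> int:
        return self.n_tissue_only + self.n_shared


def variants_by_sample(variants: Sequence[SomaticVariant]) -> dict[str, list[SomaticVariant]]:
    """Group a flat variant list by sample_id (sorted keys for determinism)."""
    out: dict[str, list[SomaticVariant]] = {}
    for v in variants:
        out.setdefault(v.sample_id, []).append(v)
    return {sid: out[sid] for sid in sorted(out)}
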