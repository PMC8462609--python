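"""Synthetic cohort generator for the tumor-informed liquid-biopsy pipeline.

No patient-level data are published for the study design this pipeline
implements, so every downstream stage is exercised on a fully synthetic
cohort whose defaults encode the study conditions: 29 gastric-cancer
cases and 20 controls; 23/29 cases carrying filter-passing tissue
alterations; ~8.4 retained tissue variants per positive sample (range
1-23, negative-binomial); stage-dependent ctDNA shedding (10% of T1-T2,
55.6% of T3-T4 cases have >=1 tissue variant detectable in plasma);
log-normal cfDNA yields with arithmetic group means 87.59 (case) and
2.01 (control) ng/mL; tri-modal nucleosomal fragment-size profiles with
the mononucleosomal mode near 170 bp (shifted down in cases); and
survival times whose hazard increases with the number of
tissue-matching plasma variants, giving expected Kaplan-Meier medians of
803 / 469 / 315 / 44 days across the 0 / 1-2 / 3-6 / >6 strata.

The same seed always yields byte-identical output: every subject gets an
independent RNG stream keyed by (seed, subject index), so results do not
depend on iteration order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    FragmentProfile,
    PatientRecord,
    SomaticVariant,
    infer_variant_type,
)
from .io import (
    write_clinical_table,
    write_fragment_profile,
    write_somatic_vcf,
)

# Synthetic gene model: gastric-cancer-associated symbols with invented
# coordinates (one coding block per gene; 0-based half-open).
GENE_INTERVALS: dict[str, list[tuple[str, int, int]]] = {
    gene: [(chrom, start, start + length)]
    for gene, (chrom, start, length) in {
        "TP53": ("chr17", 7_570_000, 20_000), "ARID1A": ("chr1", 27_020_000, 90_000),
        "CDH1": ("chr16", 68_770_000, 100_000), "PIK3CA": ("chr3", 178_860_000, 90_000),
        "KRAS": ("chr12", 25_360_000, 46_000), "ERBB2": ("chr17", 37_840_000, 40_000),
        "RHOA": ("chr3", 49_390_000, 53_000), "SMAD4": ("chr18", 48_550_000, 55_000),
        "APC": ("chr5", 112_040_000, 110_000), "CTNNB1": ("chr3", 41_240_000, 41_000),
        "MUC6": ("chr11", 1_010_000, 24_000), "RNF43": ("chr17", 56_430_000, 64_000),
        "KMT2C": ("chr7", 151_830_000, 230_000), "KMT2D": ("chr12", 49_410_000, 40_000),
        "FAT4": ("chr4", 126_230_000, 170_000), "LRP1B": ("chr2", 140_990_000, 1_900_000),
        "PTEN": ("chr10", 89_620_000, 105_000), "ATM": ("chr11", 108_090_000, 146_000),
        "BRCA2": ("chr13", 32_880_000, 84_000), "NOTCH1": ("chr9", 139_390_000, 51_000),
        "FBXW7": ("chr4", 153_240_000, 210_000), "MSH6": ("chr2", 48_010_000, 24_000),
        "TGFBR2": ("chr3", 30_640_000, 87_000), "CCDC178": ("chr18", 30_790_000, 480_000),
        "GNAS": ("chr20", 57_410_000, 71_000), "EGFR": ("chr7", 55_080_000, 190_000),
        "MET": ("chr7", 116_310_000, 125_000), "FGFR2": ("chr10", 123_230_000, 120_000),
        "MYC": ("chr8", 128_740_000, 7_000), "CDKN2A": ("chr9", 21_960_000, 27_000),
        "STK11": ("chr19", 1_200_000, 23_000), "NF1": ("chr17", 29_420_000, 287_000),
        "RB1": ("chr13", 48_870_000, 180_000), "AKT1": ("chr14", 105_230_000, 26_000),
        "SMARCA4": ("chr19", 11_090_000, 101_000), "BCOR": ("chrX", 39_910_000, 126_000),
        "PREX2": ("chr8", 68_860_000, 280_000), "SPTA1": ("chr1", 158_580_000, 76_000),
        "PCLO": ("chr7", 82_380_000, 410_000), "CSMD3": ("chr8", 113_230_000, 1_200_000),
        "DNAH5": ("chr5", 13_690_000, 79_000), "OBSCN": ("chr1", 228_390_000, 170_000),
        "TTN": ("chr2", 179_390_000, 280_000), "RYR2": ("chr1", 237_200_000, 790_000),
        "ZFHX4": ("chr8", 77_590_000, 180_000),
    }.items()
}
GENE_POOL = sorted(GENE_INTERVALS)

_BASES = "ACGT"
_CODING_CLASSES = ("missense", "nonsense", "frameshift-ins", "frameshift-del",
                   "splice-site", "in-frame-indel")
# class weights: missense dominates real tumor spectra
_CLASS_PROBS = (0.62, 0.12, 0.08, 0.08, 0.06, 0.04)

EXOME_SIZE_MB = 40.0  # assayed coding region for the TMB denominator


@dataclass
class SimParams:
    """Generator parameters; defaults encode the study conditions."""

    n_cases: int = 29
    n_controls: int = 20
    seed: int = 0
    # tissue alterations
    tissue_positive_prob: float = 23 / 29
    tissue_count_mean: float = 8.4
    tissue_count_dispersion: float = 3.0   # NB size; overdispersed to span 1-23
    tissue_count_range: tuple[int, int] = (1, 23)
    extra_failing_mean: float = 3.0        # filter-failing calls per tissue sample
    vaf_alpha: float = 1.2
    vaf_beta: float = 4.0
    vaf_range: tuple[float, float] = (0.028, 0.871)
    # plasma detection
    shed_prob_t12: float = 0.10
    shed_prob_t34: float = 0.556
    per_variant_detection_prob: float = 0.65
    m1_detection_boost: float = 1.4   # higher tumor burden with distant metastasis
    plasma_private_mean: float = 2.0
    plasma_vaf_attenuation: float = 0.5
    plasma_vaf_jitter_sd: float = 0.3
    # cfDNA yield and fragmentation
    yield_case_mean: float = 87.59         # ng/mL, arithmetic mean
    yield_control_mean: float = 2.01
    yield_log_sd: float = 0.8
    case_peaks: tuple[tuple[float, float, float], ...] = (
        (160.0, 22.0, 0.62), (345.0, 40.0, 0.22), (515.0, 55.0, 0.16))
    control_peaks: tuple[tuple[float, float, float], ...] = (
        (170.0, 25.0, 0.60), (350.0, 45.0, 0.25), (520.0, 60.0, 0.15))
    profile_noise_sd: float = 0.02         # relative, multiplicative; 0 = noiseless
    size_step_bp: float = 1.0
    analysis_range: tuple[float, float] = (100.0, 1000.0)
    # survival: Weibull PH on matching-count strata; log-HR increments
    # chosen so expected medians are 803/469/315/44 days at shape 1
    weibull_shape: float = 1.0
    median_no_ctdna_days: float = 803.0
    survival_log_hr: dict = field(default_factory=lambda: {
        "0": 0.0,
        "1-2": math.log(803 / 469),
        "3-6": math.log(803 / 315),
        ">6": math.log(803 / 44),
    })
    censor_window_days: tuple[float, float] = (180.0, 2200.0)
    # serum markers; CEA linked to yield through a Gaussian copula
    marker_spearman_cea_yield: float = 0.6
    cea_case_mean: float = 12.0
    cea_control_mean: float = 2.5
    cea_log_sd: float = 0.9
    ca19_9_mean: float = 25.0
    ca72_4_mean: float = 5.0
    msi_high_prob: float = 0.2
    # fixture mode: guarantee one variant failing only each filter criterion
    ensure_filter_edge_cases: bool = False

    def __post_init__(self) -> None:
        probs = [self.tissue_positive_prob, self.shed_prob_t12, self.shed_prob_t34,
                 self.per_variant_detection_prob, self.msi_high_prob]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")


@dataclass
class Cohort:
    params: SimParams
    clinical: list[PatientRecord]
    tissue: dict[str, list[SomaticVariant]]    # raw tissue calls, pre-filter
    plasma: dict[str, list[SomaticVariant]]
    profiles: dict[str, FragmentProfile]
    matching_counts: dict[str, int]            # programmed tissue-matching plasma counts
    tissue_passing: dict[str, list[SomaticVariant]]  # generator ground truth
    manifest: Optional[pd.DataFrame] = None


def _subject_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _draw_vaf(params: SimParams, rng: np.random.Generator) -> float:
    lo, hi = params.vaf_range
    return float(np.clip(rng.beta(params.vaf_alpha, params.vaf_beta), lo, hi))


def _random_snv(gene: str, rng: np.random.Generator) -> tuple[str, int, str, str, str]:
    chrom, start, end = GENE_INTERVALS[gene][0]
    pos = int(rng.integers(start + 1, end + 1))  # VCF 1-based within the block
    cls = str(rng.choice(_CODING_CLASSES, p=_CLASS_PROBS))
    ref = _BASES[rng.integers(4)]
    if cls == "frameshift-ins":
        alt = ref + "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 3))))
    elif cls == "frameshift-del":
        ref = ref + "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 3))))
        alt = ref[0]
    else:
        alt = _BASES[(int(_BASES.index(ref)) + int(rng.integers(1, 4))) % 4]
    return chrom, pos, ref, alt, cls


def _passing_variant(sample_id: str, rng: np.random.Generator,
                     params: SimParams, gene: Optional[str] = None) -> SomaticVariant:
    if gene is None:
        gene = str(rng.choice(GENE_POOL))
    chrom, pos, ref, alt, cls = _random_snv(gene, rng)
    return SomaticVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence_class=cls, variant_type=infer_variant_type(ref, alt),
        population_af=float(rng.uniform(0.0, 0.009)),
        impact="HIGH",
        cadd_phred=float(rng.uniform(30.5, 45.0)),
        fwd_support=int(2 + rng.poisson(20)),
        rev_support=int(2 + rng.poisson(20)),
        vaf=_draw_vaf(params, rng),
        sample_id=sample_id, compartment="tissue",
    )


_FAIL_MODES = ("pop_af", "impact", "cadd", "strand_support", "missing_annotation")


def _failing_variant(sample_id: str, mode: str, rng: np.random.Generator,
                     params: SimParams) -> SomaticVariant:
    """A tissue call failing exactly one filter criterion (``mode``)."""
    v = _passing_variant(sample_id, rng, params)
    if mode == "pop_af":
        v.population_af = float(rng.uniform(0.011, 0.3))
    elif mode == "impact":
        if rng.random() < 0.5:
            v.consequence_class = "synonymous"
        else:
            v.impact = str(rng.choice(["MODERATE", "LOW", "MODIFIER"]))
    elif mode == "cadd":
        v.cadd_phred = float(rng.uniform(0.0, 30.0))
    elif mode == "strand_support":
        if rng.random() < 0.5:
            v.fwd_support = int(rng.integers(0, 2))
        else:
            v.rev_support = int(rng.integers(0, 2))
    elif mode == "missing_annotation":
        v.cadd_phred = None
    else:
        raise ValueError(f"unknown failure mode {mode}")
    return v


def ubiquitous_variant(sample_id: str) -> SomaticVariant:
    """The fixed-key variant planted in EVERY tissue sample; it carries
    otherwise-passing annotations, so it fails only the ubiquity
    criterion (present in 100% of samples)."""
    return SomaticVariant(
        chrom="chr17", pos=7_577_120, ref="G", alt="A", gene="TP53",
        consequence_class="missense", variant_type="SNP",
        population_af=0.001, impact="HIGH", cadd_phred=35.0,
        fwd_support=10, rev_support=10, vaf=0.2,
        sample_id=sample_id, compartment="tissue",
    )


def _truncated_nb_count(params: SimParams, rng: np.random.Generator) -> int:
    mean, r = params.tissue_count_mean, params.tissue_count_dispersion
    p = r / (r + mean)
    lo, hi = params.tissue_count_range
    for _ in range(1000):
        k = int(rng.negative_binomial(r, p))
        if lo <= k <= hi:
            return k
    return int(np.clip(k, lo, hi))


def simulate_tissue_variants(sample_id: str, tissue_positive: bool,
                             params: SimParams, rng: np.random.Generator
                             ) -> tuple[list[SomaticVariant], list[SomaticVariant]]:
    """Draw one case's tissue calls: (filter-passing, filter-failing).

    Positive samples receive a truncated negative-binomial number of
    passing variants; every sample additionally receives a Poisson number
    of calls that each fail exactly one randomly chosen criterion,
    mimicking the raw-caller background the cascade removes.
    """
    passing: list[SomaticVariant] = []
    if tissue_positive:
        n = _truncated_nb_count(params, rng)
        genes = rng.choice(GENE_POOL, size=min(n, len(GENE_POOL)), replace=False)
        for i in range(n):
            gene = str(genes[i % len(genes)])
            passing.append(_passing_variant(sample_id, rng, params, gene=gene))
    failing = [
        _failing_variant(sample_id, str(rng.choice(_FAIL_MODES)), rng, params)
        for _ in range(int(rng.poisson(params.extra_failing_mean)))
    ]
    return passing, failing


def _shed_prob(t_stage: str, params: SimParams) -> float:
    return params.shed_prob_t12 if t_stage in ("T1", "T2") else params.shed_prob_t34


def simulate_plasma_variants(t_stage: str, tissue_passing: list[SomaticVariant],
                             params: SimParams, rng: np.random.Generator,
                             m_stage: str = "M0"
                             ) -> tuple[list[SomaticVariant], int]:
    """Draw one case's plasma calls; returns (variants, n tissue-matching).

    With probability shed_prob(stage) the tumor sheds: each passing
    tissue variant is then detected in plasma independently with
    ``per_variant_detection_prob`` (conditioned on >=1 detection when the
    detection probability is positive). Plasma VAFs are the tissue VAFs
    attenuated in expectation by ``plasma_vaf_attenuation``. Independent
    plasma-private variants (clonal hematopoiesis, tumor regions missed
    by the biopsy) are added at a Poisson rate regardless of shedding.
    """
    plasma: list[SomaticVariant] = []
    matched = 0
    sheds = bool(tissue_passing) and rng.random() < _shed_prob(t_stage, params)
    detect_p = params.per_variant_detection_prob
    if m_stage == "M1":  # metastatic burden raises per-variant detectability,
        detect_p = min(1.0, detect_p * params.m1_detection_boost)  # not shed prob
    if sheds and detect_p > 0:
        detect = rng.random(len(tissue_passing)) < detect_p
        if not detect.any():
            # condition on >=1 detection: shedding means detectable ctDNA
            best = int(np.argmax([v.vaf or 0.0 for v in tissue_passing]))
            detect[best] = True
        for v, hit in zip(tissue_passing, detect):
            if not hit:
                continue
            jitter = rng.lognormal(-params.plasma_vaf_jitter_sd**2 / 2,
                                   params.plasma_vaf_jitter_sd)
            vaf = min(0.999, (v.vaf or 0.05) * params.plasma_vaf_attenuation * jitter)
            plasma.append(SomaticVariant(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, gene=v.gene,
                consequence_class=v.consequence_class, variant_type=v.variant_type,
                population_af=v.population_af, impact=v.impact,
                cadd_phred=v.cadd_phred,
                fwd_support=int(2 + rng.poisson(8)), rev_support=int(2 + rng.poisson(8)),
                vaf=float(max(vaf, 1e-4)),
                sample_id=v.sample_id, compartment="plasma",
            ))
            matched += 1
    sid = tissue_passing[0].sample_id if tissue_passing else ""
    n_private = int(rng.poisson(params.plasma_private_mean))
    for _ in range(n_private):
        v = _passing_variant(sid, rng, params)
        v.compartment = "plasma"
        v.vaf = float(np.clip(rng.beta(1.1, 20.0), 1e-4, 0.2))
        plasma.append(v)
    return plasma, matched


def simulate_survival(matching_count: int, params: SimParams,
                      rng: np.random.Generator) -> tuple[float, bool]:
    """Weibull proportional-hazards survival draw with uniform censoring.

    The linear predictor is the log-HR of the subject's matching-count
    stratum; at the default shape the expected KM medians across strata
    are 803 / 469 / 315 / 44 days.
    """
    from .stats import bin_matching_count

    eta = params.survival_log_hr[bin_matching_count(matching_count)]
    k = params.weibull_shape
    lam = params.median_no_ctdna_days / math.log(2) ** (1 / k)
    t = lam * (-math.log(rng.random()) * math.exp(-eta)) ** (1 / k)
    lo, hi = params.censor_window_days
    c = rng.uniform(lo, hi)
    return (min(t, c), t <= c)


def simulate_fragment_profile(group: str, params: SimParams,
                              rng: np.random.Generator,
                              sample_id: str = "",
                              yield_ng: Optional[float] = None) -> FragmentProfile:
    """Tri-modal nucleosomal size profile whose integral over the
    analysis range equals the subject's drawn yield exactly."""
    from scipy.stats import norm

    peaks = params.case_peaks if group == "case" else params.control_peaks
    mean = params.yield_case_mean if group == "case" else params.yield_control_mean
    if yield_ng is None:
        mu = math.log(mean) - params.yield_log_sd**2 / 2
        yield_ng = float(rng.lognormal(mu, params.yield_log_sd))
    lo, hi = params.analysis_range
    sizes = np.arange(lo, hi + params.size_step_bp / 2, params.size_step_bp)
    curve = np.zeros_like(sizes)
    for mode, width, frac in peaks:
        curve += frac * norm.pdf(sizes, loc=mode, scale=width)
    if params.profile_noise_sd > 0:
        curve *= np.maximum(0.0, 1.0 + rng.normal(0.0, params.profile_noise_sd,
                                                  size=curve.size))
    integral = np.trapezoid(curve, sizes)
    curve *= (yield_ng * 1000.0) / integral  # ng -> pg; exact mass conservation
    return FragmentProfile(sample_id=sample_id, sizes=sizes, concentrations=curve,
                           analysis_range=params.analysis_range)


def _correlated_normals(rng: np.random.Generator, rho_spearman: float
                        ) -> tuple[float, float]:
    # Gaussian copula: Pearson rho giving the requested Spearman rho
    rho_g = 2.0 * math.sin(math.pi * rho_spearman / 6.0)
    z1 = rng.standard_normal()
    z2 = rho_g * z1 + math.sqrt(1 - rho_g**2) * rng.standard_normal()
    return z1, z2


def _simulate_subject(idx: int, group: str, params: SimParams) -> dict:
    stream = idx if group == "case" else 1_000_000 + idx
    rng = _subject_rng(params.seed, stream)
    sid = f"GC{idx + 1:03d}" if group == "case" else f"CT{idx + 1:03d}"
    age = float(np.clip(rng.normal(65 if group == "case" else 55, 10), 30, 92))
    sex = "male" if rng.random() < 0.5 else "female"
    if group == "case":
        t_stage = str(rng.choice(["T1", "T2", "T3", "T4"], p=[0.15, 0.21, 0.43, 0.21]))
        n_stage = str(rng.choice(["N0", "N1", "N2", "N3"], p=[0.35, 0.3, 0.2, 0.15]))
        # metastasis more likely in advanced T; marginal P(M1) ~ 0.41
        p_m1 = 0.5 if t_stage in ("T3", "T4") else 0.25
        m_stage = "M1" if rng.random() < p_m1 else "M0"
        msi = "MSI-high" if rng.random() < params.msi_high_prob else "MSS"
    else:
        t_stage = n_stage = m_stage = "unknown"
        msi = "unknown"

    tissue: list[SomaticVariant] = []
    passing: list[SomaticVariant] = []
    plasma: list[SomaticVariant] = []
    matched = 0
    if group == "case":
        tissue_positive = rng.random() < params.tissue_positive_prob
        passing, failing = simulate_tissue_variants(sid, tissue_positive, params, rng)
        tissue = passing + failing
        plasma, matched = simulate_plasma_variants(t_stage, passing, params, rng,
                                                   m_stage=m_stage)
        for v in plasma:
            v.sample_id = sid

    z_yield, z_cea = _correlated_normals(rng, params.marker_spearman_cea_yield)
    mean_yield = params.yield_case_mean if group == "case" else params.yield_control_mean
    mu_y = math.log(mean_yield) - params.yield_log_sd**2 / 2
    yield_ng = float(math.exp(mu_y + params.yield_log_sd * z_yield))
    profile = simulate_fragment_profile(group, params, rng, sample_id=sid,
                                        yield_ng=yield_ng)
    cea_mean = params.cea_case_mean if group == "case" else params.cea_control_mean
    mu_c = math.log(cea_mean) - params.cea_log_sd**2 / 2
    cea = float(math.exp(mu_c + params.cea_log_sd * z_cea))
    ca19_9 = float(rng.lognormal(math.log(params.ca19_9_mean) - 0.32, 0.8))
    ca72_4 = float(rng.lognormal(math.log(params.ca72_4_mean) - 0.32, 0.8))

    if group == "case":
        survival_days, event = simulate_survival(matched, params, rng)
    else:
        survival_days, event = float(rng.uniform(300, 1500)), False
    tmb_val = len(tissue) / EXOME_SIZE_MB if group == "case" else 0.0

    record = PatientRecord(
        sample_id=sid, age=age, sex=sex, t_stage=t_stage, n_stage=n_stage,
        m_stage=m_stage, survival_days=survival_days, event=event,
        cea=cea, ca19_9=ca19_9, ca72_4=ca72_4, msi_status=msi,
        tmb=tmb_val, group=group,
    )
    return {"record": record, "tissue": tissue, "passing": passing,
            "plasma": plasma, "profile": profile, "matched": matched}


def simulate_cohort(params: SimParams,
                    out_dir: Optional[str | Path] = None) -> Cohort:
    """Generate the full synthetic cohort; optionally write it to disk.

    On-disk layout: ``clinical.tsv``, ``fragments/<sid>.tsv``,
    ``vcf/<sid>.tissue.vcf`` (cases only), ``vcf/<sid>.plasma.vcf``
    (cases only) and ``manifest.tsv`` with a sha256 checksum per file.
    """
    subjects = [_simulate_subject(i, "case", params) for i in range(params.n_cases)]
    subjects += [_simulate_subject(i, "control", params) for i in range(params.n_controls)]

    if params.ensure_filter_edge_cases and subjects and subjects[0]["tissue"] is not None:
        rng = _subject_rng(params.seed, 9_999_999)
        first = subjects[0]
        sid = first["record"].sample_id
        for mode in _FAIL_MODES:
            first["tissue"].append(_failing_variant(sid, mode, rng, params))
        for s in subjects:
            if s["record"].group == "case":
                s["tissue"].append(ubiquitous_variant(s["record"].sample_id))

    cohort = Cohort(
        params=params,
        clinical=[s["record"] for s in subjects],
        tissue={s["record"].sample_id: s["tissue"] for s in subjects
                if s["record"].group == "case"},
        plasma={s["record"].sample_id: s["plasma"] for s in subjects
                if s["record"].group == "case"},
        profiles={s["record"].sample_id: s["profile"] for s in subjects},
        matching_counts={s["record"].sample_id: s["matched"] for s in subjects
                         if s["record"].group == "case"},
        tissue_passing={s["record"].sample_id: s["passing"] for s in subjects
                        if s["record"].group == "case"},
    )
    if out_dir is not None:
        cohort.manifest = _write_cohort(cohort, Path(out_dir))
    return cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_cohort(cohort: Cohort, out_dir: Path) -> pd.DataFrame:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "fragments").mkdir(exist_ok=True)
    (out_dir / "vcf").mkdir(exist_ok=True)
    files: list[tuple[str, int]] = []

    clin_path = out_dir / "clinical.tsv"
    write_clinical_table(cohort.clinical, clin_path)
    files.append(("clinical.tsv", len(cohort.clinical)))
    for sid in sorted(cohort.profiles):
        rel = f"fragments/{sid}.tsv"
        write_fragment_profile(cohort.profiles[sid], out_dir / rel)
        files.append((rel, int(cohort.profiles[sid].sizes.size)))
    for sid in sorted(cohort.tissue):
        rel = f"vcf/{sid}.tissue.vcf"
        write_somatic_vcf(cohort.tissue[sid], out_dir / rel, sample_id=sid)
        files.append((rel, len(cohort.tissue[sid])))
    for sid in sorted(cohort.plasma):
        rel = f"vcf/{sid}.plasma.vcf"
        write_somatic_vcf(cohort.plasma[sid], out_dir / rel, sample_id=sid)
        files.append((rel, len(cohort.plasma[sid])))

    manifest = pd.DataFrame(
        [{"path": rel, "sha256": _sha256(out_dir / rel), "n_rows": n}
         for rel, n in files])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Deterministic fixture with prescribed detection counts
# ---------------------------------------------------------------------------

def make_concordance_fixture(n_cases: int = 29, n_tissue_positive: int = 23,
                             n_plasma_positive: int = 21, n_shared_positive: int = 11,
                             seed: int = 0
                             ) -> tuple[dict[str, list[SomaticVariant]],
                                        dict[str, list[SomaticVariant]]]:
    """Engineer a cohort with exact tissue/plasma detection counts.

    Returns (tissue calls by sample, plasma calls by sample) for
    ``n_cases`` patients of whom exactly ``n_tissue_positive`` carry
    filter-passing tissue variants, ``n_plasma_positive`` of those have
    >=1 plasma alteration of any kind, and ``n_shared_positive`` have
    >=1 tissue-matching plasma alteration. Exercises the filter cascade
    and concordance end to end with known denominators.
    """
    if not n_shared_positive <= n_plasma_positive <= n_tissue_positive <= n_cases:
        raise ValueError("counts must be nested: shared <= plasma <= tissue <= cases")
    params = SimParams(seed=seed)
    rng = _subject_rng(seed, 777)
    tissue: dict[str, list[SomaticVariant]] = {}
    plasma: dict[str, list[SomaticVariant]] = {}
    for i in range(n_cases):
        sid = f"FX{i + 1:03d}"
        if i < n_tissue_positive:
            n_vars = 1 + int(rng.poisson(params.tissue_count_mean - 1))
            tis = [_passing_variant(sid, rng, params) for _ in range(min(n_vars, 23))]
        else:
            # tissue-negative: only filter-failing calls
            tis = [_failing_variant(sid, "cadd", rng, params)]
        tissue[sid] = tis
        pla: list[SomaticVariant] = []
        if i < n_shared_positive:
            shared_src = tis[0]
            shared = _passing_variant(sid, rng, params)
            shared.chrom, shared.pos = shared_src.chrom, shared_src.pos
            shared.ref, shared.alt = shared_src.ref, shared_src.alt
            shared.gene = shared_src.gene
            shared.variant_type = shared_src.variant_type
            shared.compartment = "plasma"
            shared.vaf = (shared_src.vaf or 0.1) * 0.5
            pla.append(shared)
        if i < n_plasma_positive:
            private = _passing_variant(sid, rng, params)
            private.compartment = "plasma"
            private.vaf = 0.03
            pla.append(private)
        plasma[sid] = pla
    return tissue, plasma
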