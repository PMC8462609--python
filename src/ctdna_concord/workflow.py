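"""End-to-end orchestration: simulate -> filter/design panel -> match
tissue and plasma -> quantify cfDNA -> association statistics, with a
machine-readable results bundle and a checksummed run manifest.

Every stage is a pure function of (inputs, config, seed); re-running
with the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import concordance as conc
from . import panel as panel_mod
from . import quant, stats
from .sim import GENE_INTERVALS, Cohort, SimParams, simulate_cohort


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def params_from_config(config: dict[str, Any]) -> SimParams:
    sim_cfg = dict(config.get("sim", {}))
    fields = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(sim_cfg) - fields
    if unknown:
        raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
    return SimParams(**sim_cfg)


def _config_hash(config: dict[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: Optional[dict[str, Any]] = None,
            out_dir: Optional[str | Path] = None) -> dict[str, Any]:
    """Run the whole pipeline on a simulated cohort.

    Returns a results dictionary with per-stage outputs: filter summary,
    panel, concordance fractions, yield quantification, group tests,
    survival strata and M0/M1 discrimination. When ``out_dir`` is given,
    the cohort files, ``results.json`` and ``run_manifest.tsv`` are
    written there.
    """
    config = config or {}
    params = params_from_config(config)
    out_dir = Path(out_dir) if out_dir is not None else None

    try:
        cohort = simulate_cohort(params, out_dir / "cohort" if out_dir else None)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError(f"simulate: {exc}") from exc

    try:
        retained, summary, _decisions = panel_mod.filter_cohort(cohort.tissue)
        max_genes = int(config.get("panel", {}).get("max_genes", 38))
        positives = {sid for sid, vs in retained.items() if vs}
        panel = (panel_mod.build_panel(retained, GENE_INTERVALS, max_genes=max_genes)
                 if positives else None)
    except Exception as exc:
        raise StageError(f"design-panel: {exc}") from exc

    try:
        results_by_sid = [conc.match_variants(retained[sid], cohort.plasma.get(sid, []))
                          for sid in sorted(retained)]
        cohort_conc = conc.cohort_concordance(results_by_sid, sorted(positives))
        spectra = conc.summarize_spectra(
            [v for sid in sorted(retained) for v in retained[sid]])
    except Exception as exc:
        raise StageError(f"concord: {exc}") from exc

    try:
        yields = {sid: quant.total_yield(p) for sid, p in cohort.profiles.items()}
        case_ids = [r.sample_id for r in cohort.clinical if r.group == "case"]
        control_ids = [r.sample_id for r in cohort.clinical if r.group == "control"]
        case_yields = [yields[sid] for sid in case_ids]
        control_yields = [yields[sid] for sid in control_ids]
        fc = quant.fold_change(float(np.mean(case_yields)), float(np.mean(control_yields)))
        decomp = {sid: quant.nucleosomal_decomposition(p)
                  for sid, p in cohort.profiles.items()}
    except Exception as exc:
        raise StageError(f"quantify: {exc}") from exc

    try:
        assoc = _associate(cohort, results_by_sid, positives, yields,
                           case_ids, control_ids)
    except Exception as exc:
        raise StageError(f"associate: {exc}") from exc

    report: dict[str, Any] = {
        "seed": params.seed,
        "config_hash": _config_hash(config),
        "n_cases": params.n_cases,
        "n_controls": params.n_controls,
        "filter_summary": {
            "n_samples": summary.n_samples,
            "n_positive": summary.n_positive,
            "positive_fraction": summary.positive_fraction,
            "mean_retained_among_positive": summary.mean_retained_among_positive,
        },
        "panel_genes": panel.genes if panel else [],
        "concordance": {
            "n_tissue_positive": cohort_conc.n_tissue_positive,
            "n_plasma_positive": cohort_conc.n_plasma_positive,
            "n_shared_positive": cohort_conc.n_shared_positive,
            "plasma_positive_fraction": cohort_conc.plasma_positive_fraction,
            "shared_positive_fraction": cohort_conc.shared_positive_fraction,
        },
        "spectra": {
            "class_counts": spectra.class_counts,
            "type_counts": spectra.type_counts,
            "substitution_counts": spectra.substitution_counts,
            "mean_per_sample": spectra.mean_per_sample,
        },
        "quant": {
            "case_mean_yield_ng_ml": float(np.mean(case_yields)),
            "control_mean_yield_ng_ml": float(np.mean(control_yields)),
            "fold_change": fc,
            "mean_mono_yield_case_pg_ml": float(np.mean(
                [decomp[sid].regions["mono"].yield_pg_per_ml for sid in case_ids])),
            "mean_mono_yield_control_pg_ml": float(np.mean(
                [decomp[sid].regions["mono"].yield_pg_per_ml for sid in control_ids])),
        },
        "associations": assoc,
    }

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "results.json").write_text(
            json.dumps(report, indent=2, default=_json_default))
        _write_run_manifest(out_dir, cohort)
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(f"not JSON serializable: {type(o)}")


def _associate(cohort: Cohort, results_by_sid, positives, yields,
               case_ids, control_ids) -> dict[str, Any]:
    clinical = {r.sample_id: r for r in cohort.clinical}
    case_yields = [yields[sid] for sid in case_ids]
    control_yields = [yields[sid] for sid in control_ids]
    mw = stats.mann_whitney_from_samples(control_yields, case_yields)

    shared_by_sid = {r.sample_id: r.n_shared for r in results_by_sid}
    # stage x ctDNA-detection 2x2 among tissue-positive, staged cases
    rows = []
    for sid in sorted(positives):
        rec = clinical[sid]
        if rec.t_stage == "unknown":
            continue
        rows.append((rec.t_stage in ("T3", "T4"), shared_by_sid.get(sid, 0) > 0))
    tbl = np.zeros((2, 2), dtype=int)
    for advanced, detected in rows:
        tbl[0 if not advanced else 1, 0 if detected else 1] += 1
    try:
        chi2_stat, chi2_p = stats.pearson_chi2_2x2(tbl)
    except ValueError:
        chi2_stat, chi2_p = float("nan"), float("nan")

    case_records = [clinical[sid] for sid in case_ids]
    strata = stats.survival_by_strata(
        [r.survival_days for r in case_records],
        [r.event for r in case_records],
        [shared_by_sid.get(r.sample_id, 0) for r in case_records],
    )

    # within-case correlation: pooling groups would conflate the case/control
    # mean shift with the programmed within-subject marker link
    rho, rho_p = stats.spearman([yields[sid] for sid in case_ids],
                                [clinical[sid].cea for sid in case_ids])

    # M0/M1 discrimination from the two analytes: matching-variant count
    # and presence of any plasma alteration
    m_known = [r for r in case_records if r.m_stage in ("M0", "M1")]
    features = pd.DataFrame({
        "n_matching": [shared_by_sid.get(r.sample_id, 0) for r in m_known],
        "any_plasma_alteration": [
            float(len(cohort.plasma.get(r.sample_id, [])) > 0) for r in m_known],
    })
    labels = [r.m_stage == "M1" for r in m_known]
    disc_auc = None
    if any(labels) and not all(labels):
        rng = np.random.default_rng([cohort.params.seed, 424242])
        disc = stats.discriminate(features, labels, rng=rng)
        disc_auc = disc.auc

    return {
        "yield_mw_u": mw.u_statistic,
        "yield_mw_p": mw.p_two_sided,
        "yield_mw_method": mw.method,
        "stage_detection_table": tbl.tolist(),
        "stage_detection_chi2": chi2_stat,
        "stage_detection_chi2_p": chi2_p,
        "km_medians_by_stratum": strata.medians,
        "logrank_p": strata.logrank_p,
        "spearman_yield_cea": rho,
        "spearman_yield_cea_p": rho_p,
        "m0_m1_auc": disc_auc,
    }


def _write_run_manifest(out_dir: Path, cohort: Cohort) -> None:
    rows = []
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.tsv":
            h = hashlib.sha256(path.read_bytes()).hexdigest()
            rows.append({"path": str(path.relative_to(out_dir)), "sha256": h})
    pd.DataFrame(rows).to_csv(out_dir / "run_manifest.tsv", sep="\t", index=False)
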