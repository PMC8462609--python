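"""Synthetic-cohort generator: determinism, programmed laws and limit cases."""

import math

import numpy as np
import pytest

from ctdna_concord import panel as panel_mod
from ctdna_concord import stats
from ctdna_concord.quant import total_yield
from ctdna_concord.sim import (
    SimParams,
    make_concordance_fixture,
    simulate_cohort,
    simulate_fragment_profile,
    simulate_survival,
)

N_BATCH = 200  # Monte-Carlo batch size for the law-recovery checks


@pytest.fixture(scope="module")
def cohort_batch():
    """One pass of many simulated cohorts, shared across the recovery tests."""
    out = []
    for seed in range(N_BATCH):
        c = simulate_cohort(SimParams(seed=seed))
        clinical = {r.sample_id: r for r in c.clinical}
        positives = [sid for sid, vs in c.tissue_passing.items() if vs]
        yields = {sid: total_yield(p) for sid, p in c.profiles.items()}
        out.append({
            "n_positive": len(positives),
            "shed": [(clinical[sid].t_stage, c.matching_counts[sid] > 0)
                     for sid in positives],
            "case_yield": np.mean([yields[r.sample_id] for r in c.clinical
                                   if r.group == "case"]),
            "control_yield": np.mean([yields[r.sample_id] for r in c.clinical
                                      if r.group == "control"]),
            "spearman_yield_cea": stats.spearman(
                [yields[r.sample_id] for r in c.clinical if r.group == "case"],
                [r.cea for r in c.clinical if r.group == "case"])[0],
        })
    return out


class TestDeterminism:
    def test_same_seed_byte_identical_manifests(self, tmp_path):
        m1 = simulate_cohort(SimParams(seed=1), tmp_path / "a").manifest
        m2 = simulate_cohort(SimParams(seed=1), tmp_path / "b").manifest
        assert list(m1["sha256"]) == list(m2["sha256"])
        assert list(m1["path"]) == list(m2["path"])

    def test_different_seeds_differ(self, tmp_path):
        m1 = simulate_cohort(SimParams(seed=1), tmp_path / "a").manifest
        m2 = simulate_cohort(SimParams(seed=2), tmp_path / "b").manifest
        assert list(m1["sha256"]) != list(m2["sha256"])

    def test_cohort_composition(self):
        c = simulate_cohort(SimParams(seed=0))
        assert len(c.clinical) == 49
        groups = [r.group for r in c.clinical]
        assert groups.count("case") == 29 and groups.count("control") == 20
        assert set(c.tissue) == {r.sample_id for r in c.clinical if r.group == "case"}
        assert set(c.plasma) == set(c.tissue)
        assert set(c.profiles) == {r.sample_id for r in c.clinical}

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimParams(tissue_positive_prob=1.5)


class TestProgrammedLaws:
    def test_tissue_positive_count_matches_binomial(self, cohort_batch):
        # positives ~ Binomial(29, 23/29): batch mean within 3 SE of 23
        mean_pos = np.mean([b["n_positive"] for b in cohort_batch])
        p = 23 / 29
        se = math.sqrt(29 * p * (1 - p) / len(cohort_batch))
        assert abs(mean_pos - 23) < 3 * se

    @pytest.mark.parametrize("stages, target", [
        (("T3", "T4"), 0.556),
        (("T1", "T2"), 0.10),
    ])
    def test_stagewise_shedding_fraction(self, cohort_batch, stages, target):
        flags = [shed for b in cohort_batch for (t, shed) in b["shed"]
                 if t in stages]
        frac = np.mean(flags)
        se = math.sqrt(target * (1 - target) / len(flags))
        assert abs(frac - target) < 3 * se

    def test_yield_fold_change_recovered(self, cohort_batch):
        fcs = [b["case_yield"] / b["control_yield"] for b in cohort_batch]
        assert abs(np.mean(fcs) - 43.6) / 43.6 < 0.10

    def test_marker_yield_spearman_link(self, cohort_batch):
        rhos = [b["spearman_yield_cea"] for b in cohort_batch]
        assert abs(np.mean(rhos) - 0.6) < 0.1

    def test_survival_medians_monotone_across_strata(self):
        params = SimParams(seed=0)
        rng = np.random.default_rng(0)
        medians = {}
        for label, k in (("0", 0), ("1-2", 2), ("3-6", 5), (">6", 9)):
            draws = [simulate_survival(k, params, rng) for _ in range(500)]
            t, e = zip(*draws)
            medians[label] = stats.km_estimator(t, e).median
        assert medians[">6"] < medians["3-6"] < medians["1-2"] < medians["0"]


class TestFragmentProfiles:
    def test_mass_conservation_zero_noise(self):
        params = SimParams(seed=0, profile_noise_sd=0.0)
        rng = np.random.default_rng(0)
        prof = simulate_fragment_profile("control", params, rng, yield_ng=3.7)
        assert total_yield(prof) == pytest.approx(3.7, rel=1e-6)

    def test_case_mono_mode_shifted_below_control(self):
        from ctdna_concord.quant import nucleosomal_decomposition
        params = SimParams(seed=0, profile_noise_sd=0.0)
        rng = np.random.default_rng(0)
        case = simulate_fragment_profile("case", params, rng, yield_ng=50.0)
        ctrl = simulate_fragment_profile("control", params, rng, yield_ng=2.0)
        mode = {g: nucleosomal_decomposition(p).regions["mono"].modal_size_bp
                for g, p in (("case", case), ("control", ctrl))}
        assert mode["case"] < mode["control"]

    def test_single_peak_mode_round_trips_through_decomposition(self):
        from ctdna_concord.quant import nucleosomal_decomposition
        params = SimParams(seed=0, profile_noise_sd=0.0,
                           control_peaks=((173.0, 20.0, 1.0),))
        rng = np.random.default_rng(0)
        prof = simulate_fragment_profile("control", params, rng, yield_ng=5.0)
        d = nucleosomal_decomposition(prof)
        assert abs(d.regions["mono"].modal_size_bp - 173.0) <= params.size_step_bp


class TestPlasmaLimitCases:
    def test_full_detection_reproduces_tissue_keys(self):
        params = SimParams(seed=4, per_variant_detection_prob=1.0,
                           plasma_private_mean=0.0,
                           shed_prob_t12=1.0, shed_prob_t34=1.0)
        c = simulate_cohort(params)
        for sid, passing in c.tissue_passing.items():
            if passing:
                assert {v.key for v in c.plasma[sid]} == {v.key for v in passing}

    def test_zero_detection_zero_private_gives_empty_plasma(self):
        params = SimParams(seed=4, per_variant_detection_prob=0.0,
                           plasma_private_mean=0.0)
        c = simulate_cohort(params)
        assert all(len(v) == 0 for v in c.plasma.values())

    def test_plasma_vaf_attenuated_in_expectation(self):
        params = SimParams(seed=5, per_variant_detection_prob=1.0,
                           plasma_private_mean=0.0,
                           shed_prob_t12=1.0, shed_prob_t34=1.0)
        ratios = []
        for seed in range(30):
            params.seed = seed
            c = simulate_cohort(params)
            for sid, passing in c.tissue_passing.items():
                t_by_key = {v.key: v.vaf for v in passing}
                for pv in c.plasma[sid]:
                    ratios.append(pv.vaf / t_by_key[pv.key])
        assert abs(np.mean(ratios) - params.plasma_vaf_attenuation) < 0.05


class TestFilterEdgeCoverage:
    def test_every_criterion_has_a_sole_failure_witness(self):
        c = simulate_cohort(SimParams(seed=2, ensure_filter_edge_cases=True))
        _, _, decisions = panel_mod.filter_cohort(c.tissue)
        sole_failures = {tuple(d.failed_criteria) for decs in decisions.values()
                         for d in decs if len(d.failed_criteria) == 1}
        for crit in ("pop_af", "impact", "cadd", "ubiquity", "strand_support",
                     "missing_annotation"):
            assert (crit,) in sole_failures, f"no variant fails only {crit}"


class TestConcordanceFixture:
    def test_counts_engineered_exactly(self):
        from ctdna_concord.concordance import cohort_concordance, match_variants
        tissue, plasma = make_concordance_fixture()
        retained, summary, _ = panel_mod.filter_cohort(tissue)
        assert summary.n_positive == 23 and summary.n_samples == 29
        results = [match_variants(retained[sid], plasma[sid])
                   for sid in sorted(retained)]
        cc = cohort_concordance(results, [s for s, v in retained.items() if v])
        assert cc.n_plasma_positive == 21 and cc.n_shared_positive == 11

    def test_invalid_nesting_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            make_concordance_fixture(n_plasma_positive=25, n_tissue_positive=23)
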