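"""Generator contracts: determinism, component structure, cohort design, ground truth."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import retscreen as rs
from retscreen.synthetic import _lognormal_factor, gamma_kernel, generative_components


class TestSimulateWaveform:
    def test_same_seed_gives_identical_samples(self, default_params, acq):
        w1 = rs.simulate_waveform(default_params, acq=acq, seed=5)
        w2 = rs.simulate_waveform(default_params, acq=acq, seed=5)
        np.testing.assert_array_equal(w1.samples_uV, w2.samples_uV)

    def test_different_seed_differs(self, default_params, acq):
        w1 = rs.simulate_waveform(default_params, acq=acq, seed=5)
        w2 = rs.simulate_waveform(default_params, acq=acq, seed=6)
        assert not np.array_equal(w1.samples_uV, w2.samples_uV)

    def test_single_component_case_is_pure_p3_after_bandpass(self, acq):
        params = replace(
            rs.WaveformModelParams(), noise_sd_uV=0.0, p2_amp_uV=0.0, op_atoms=(), drift_amp_uV=0.0
        )
        w = rs.simulate_waveform(params, acq=acq, seed=0)
        expected = acq.bandpass(rs.p3_model_trace(params.p3, acq.time_grid(), 2.07))
        np.testing.assert_allclose(w.samples_uV, expected, atol=1e-9)

    def test_prestimulus_contains_only_noise_and_drift(self, acq):
        params = replace(rs.WaveformModelParams(), noise_sd_uV=0.0, drift_amp_uV=0.0)
        w = rs.simulate_waveform(params, acq=acq, seed=0)
        pre = w.samples_uV[w.time_s < 0]
        assert np.max(np.abs(pre)) < 1e-9

    def test_early_sample_negative_on_a_wave_leading_edge(self, noiseless_params, acq):
        # Oracle: the generative sum itself, evaluated just after the delay.
        t_probe = noiseless_params.p3.t_delay_s + 0.002
        comps = generative_components(noiseless_params, np.array([t_probe]))
        assert sum(v[0] for v in comps.values()) < 0.0
        w = rs.simulate_waveform(noiseless_params, acq=acq, seed=0)
        idx = np.argmin(np.abs(w.time_s - t_probe))
        assert w.samples_uV[idx] < 0.0

    def test_nonfinite_parameter_rejected_with_field_name(self):
        with pytest.raises(ValueError, match="noise_sd_uV"):
            rs.WaveformModelParams(noise_sd_uV=float("nan"))
        with pytest.raises(ValueError, match="op_atoms"):
            rs.WaveformModelParams(op_atoms=((0.02, float("inf"), 10.0, 0.004),))

    def test_op_frequency_outside_band_rejected(self):
        with pytest.raises(ValueError, match="60-200"):
            rs.WaveformModelParams(op_atoms=((0.02, 40.0, 10.0, 0.004),))


def test_gamma_kernel_unit_peak_at_expected_time():
    t = np.linspace(0, 0.4, 40001)
    g = gamma_kernel(t, 0.018, 6)
    assert np.max(g) == pytest.approx(1.0, abs=1e-6)
    assert t[np.argmax(g)] == pytest.approx(5 * 0.018, abs=1e-4)
    assert np.all(g[t <= 0] == 0)


class TestSimulateCohort:
    def test_row_count_matches_design(self):
        design = rs.CohortDesign(n_per_group={g: 12 for g in rs.GROUPS}, seed=0)
        truth = rs.simulate_cohort_amplitudes(design)
        assert len(truth) == 4 * 12 * 7

    def test_deterministic_for_fixed_seed(self, tiny_design):
        t1 = rs.simulate_cohort_amplitudes(tiny_design)
        t2 = rs.simulate_cohort_amplitudes(tiny_design)
        pd.testing.assert_frame_equal(t1, t2)
        w1, _ = rs.simulate_cohort(tiny_design)
        w2, _ = rs.simulate_cohort(tiny_design)
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a.samples_uV, b.samples_uV)

    def test_no_variability_means_identical_records_across_time(self):
        design = rs.CohortDesign(
            n_per_group={g: 2 for g in rs.GROUPS},
            growth_end={g: 1.0 for g in rs.GROUPS},
            between_subject_cv=0.0,
            record_cv=0.0,
            growth_slope_sd=0.0,
            seed=1,
        )
        truth = rs.simulate_cohort_amplitudes(design)
        for _, g in truth.groupby("subject_id"):
            assert g["rm_p3_true_uV"].nunique() == 1
            assert g["p2_amp_true_uV"].nunique() == 1

    def test_growth_ratio_exact_by_construction(self):
        design = rs.CohortDesign(
            n_per_group={"HOM_LDOPA": 3, "WT_LDOPA": 3},
            record_cv=0.0,
            growth_slope_sd=0.0,
            seed=2,
        )
        truth = rs.simulate_cohort_amplitudes(design)
        piv = truth.pivot_table(index="subject_id", columns="time_min", values="p2_amp_true_uV")
        ratios = piv[30.0] / piv[0.0]
        grp = truth.drop_duplicates("subject_id").set_index("subject_id")["group"]
        assert ratios[grp == "HOM_LDOPA"].to_numpy() == pytest.approx(1.47)
        assert ratios[grp == "WT_LDOPA"].to_numpy() == pytest.approx(1.16)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            rs.CohortDesign(n_per_group={"WT_VEH": 1})
        with pytest.raises(ValueError, match="empty"):
            rs.CohortDesign(n_per_group={})

    def test_growth_curve_must_start_at_one(self):
        with pytest.raises(ValueError, match="t=0"):
            rs.CohortDesign(
                growth_curves={"WT_VEH": [1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7]}
            )

    def test_within_subject_correlation_exceeds_between_when_cv_positive(self):
        # Repeated-measures structure: the subject scaler is drawn once and
        # reused, so amplitudes within a subject co-vary more than across.
        design = rs.CohortDesign(
            n_per_group={"WT_VEH": 100, "WT_LDOPA": 100},
            growth_end={g: 1.0 for g in rs.GROUPS},
            between_subject_cv=0.15,
            record_cv=0.06,
            growth_slope_sd=0.0,
            seed=3,
        )
        truth = rs.simulate_cohort_amplitudes(design)
        piv = truth.pivot_table(index="subject_id", columns="time_min", values="p2_amp_true_uV")
        var_between = piv.mean(axis=1).var()
        var_within = piv.sub(piv.mean(axis=1), axis=0).to_numpy().var()
        icc = var_between / (var_between + var_within)
        assert icc > 0.5

    def test_ground_truth_matches_generative_oracle(self, acq):
        design = rs.CohortDesign(n_per_group={"HOM_VEH": 2}, seed=4)
        base = replace(rs.WaveformModelParams(), noise_sd_uV=0.0)
        waves, truth = rs.simulate_cohort(design, base, acq)
        t = acq.time_grid()
        for w, row in zip(waves, truth.itertuples(index=False)):
            params = replace(
                base,
                p3=replace(base.p3, rm_p3_uV=row.rm_p3_true_uV),
                p2_amp_uV=row.p2_amp_true_uV,
            )
            comps = generative_components(params, t)
            # stored truth equals the analytic component amplitudes exactly
            assert np.max(comps["p2"]) == pytest.approx(row.p2_amp_true_uV, rel=1e-9)
            assert -np.min(comps["p3"]) == pytest.approx(
                row.rm_p3_true_uV * (1 - np.exp(-(10**2.07) * base.p3.sensitivity_S
                                               * (t[-1] - base.p3.t_delay_s) ** 2)),
                rel=1e-9,
            )


def test_lognormal_factor_mean_one():
    rng = np.random.default_rng(0)
    x = _lognormal_factor(rng, 0.15, size=200_000)
    assert np.mean(x) == pytest.approx(1.0, abs=5e-3)
    assert np.std(x) == pytest.approx(0.15, abs=5e-3)


class TestOCTCohort:
    def test_degenerate_design_reproduces_means_exactly(self):
        layers = {
            "OPL": rs.OCTLayerSpec(18.0, 0.0, 0.0, 0.0),
            "ONL": rs.OCTLayerSpec(60.0, 0.0, 0.0, 0.0),
        }
        design = rs.OCTCohortDesign(layers=layers, remeasure_sd_um=0.0, seed=0)
        t = rs.simulate_oct_cohort(design)
        assert t.loc[t.measure == "OPL", "value"].to_numpy() == pytest.approx(18.0)
        assert t.loc[t.measure == "TRT", "value"].to_numpy() == pytest.approx(18 + 60 + 30.0)

    def test_hom_offset_is_exact_group_difference_when_noiseless(self):
        layers = {"ONL": rs.OCTLayerSpec(60.0, 0.0, -6.0, 0.0)}
        design = rs.OCTCohortDesign(layers=layers, remeasure_sd_um=0.0, seed=0)
        t = rs.simulate_oct_cohort(design)
        onl = t[t.measure == "ONL"].groupby("genotype")["value"].mean()
        assert onl["HOM"] - onl["WT"] == pytest.approx(-6.0)

    def test_trt_additivity_in_every_record(self):
        t = rs.simulate_oct_cohort(rs.OCTCohortDesign(seed=5))
        piv = t.pivot_table(index=["subject_id", "time_min"], columns="measure", values="value")
        component_sum = piv[["RNFL", "GCIPL", "INL", "OPL", "ONL"]].sum(axis=1) + 30.0
        np.testing.assert_allclose(piv["TRT"], component_sum, rtol=1e-12)

    def test_default_design_opl_thins_over_time_in_all_groups(self):
        t = rs.simulate_oct_cohort(rs.OCTCohortDesign(seed=6))
        opl = t[t.measure == "OPL"].pivot_table(
            index=["genotype", "treatment"], columns="time_min", values="value"
        )
        assert (opl[30.0] < opl[0.0]).all()

    def test_inconsistent_parameters_raise(self):
        layers = {"OPL": rs.OCTLayerSpec(1.0, 0.0, 0.0, 5.0)}  # thins below zero
        with pytest.raises(ValueError, match="non-positive"):
            rs.simulate_oct_cohort(rs.OCTCohortDesign(layers=layers, remeasure_sd_um=0.0, seed=0))

    def test_trt_cannot_be_configured(self):
        with pytest.raises(ValueError, match="TRT"):
            rs.OCTCohortDesign(layers={"TRT": rs.OCTLayerSpec(200.0, 1.0)})
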