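"""Generator contracts: determinism, degenerate cases, spectral fidelity,
clinical-course/classifier consistency, cohort shape and attrition."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import lombscargle

from sepsishrv import (
    Group,
    SimulationConfig,
    classify_outcome,
    render_ecg,
    simulate_cohort,
    simulate_nn_series,
    simulate_patient_course,
)
from sepsishrv.synthetic import ATTRITION_SCHEDULE, _draw_dropout


class TestSimulateNN:
    def test_degenerate_modulation_gives_constant_intervals(self):
        cfg = SimulationConfig(
            record_duration=300.0,
            band_amplitudes={"ULF": 0, "VLF": 0, "LF": 0, "HF": 0},
            ectopic_rate=0.0,
            missed_beat_rate=0.0,
            mean_nn=800.0,
        )
        nn, truth = simulate_nn_series(cfg, seed=1)
        assert np.all(nn.values == 800.0)
        assert np.all(truth.true_nn == 800.0)
        assert len(truth.injected_artifact_indices) == 0

    def test_true_nn_matches_peak_time_differences(self, quiet_config):
        nn, truth = simulate_nn_series(quiet_config, seed=2)
        np.testing.assert_allclose(
            np.diff(truth.true_peak_times) * 1000.0, truth.true_nn, rtol=1e-12
        )

    def test_single_band_modulation_peaks_in_band(self, quiet_config):
        """Independent periodogram of an LF-only series peaks within 0.04-0.15 Hz."""
        nn, _ = simulate_nn_series(quiet_config, seed=3)
        y = nn.values - nn.values.mean()
        freqs = np.linspace(0.01, 0.4, 2000)
        p = lombscargle(nn.end_times, y, 2 * np.pi * freqs)
        fpeak = freqs[np.argmax(p)]
        assert 0.04 <= fpeak <= 0.15

    @pytest.mark.parametrize("band,lo,hi", [("LF", 0.04, 0.15), ("HF", 0.15, 0.4)])
    def test_spectral_fidelity_single_band(self, band, lo, hi):
        """>= 80% of 0.04-0.4 Hz power lands in the modulated band."""
        amps = {"ULF": 0.0, "VLF": 0.0, "LF": 0.0, "HF": 0.0}
        amps[band] = 40.0
        cfg = SimulationConfig(
            record_duration=600.0, band_amplitudes=amps, ectopic_rate=0, missed_beat_rate=0
        )
        nn, _ = simulate_nn_series(cfg, seed=4)
        y = nn.values - nn.values.mean()
        freqs = np.linspace(0.04, 0.4, 3000)
        p = lombscargle(nn.end_times, y, 2 * np.pi * freqs)
        in_band = (freqs >= lo) & (freqs < hi)
        assert p[in_band].sum() / p.sum() >= 0.8

    def test_determinism_same_seed(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, ectopic_rate=0.02, missed_beat_rate=0.01)
        a, ta = simulate_nn_series(cfg, seed=7)
        b, tb = simulate_nn_series(cfg, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.end_times, b.end_times)
        np.testing.assert_array_equal(
            ta.injected_artifact_indices, tb.injected_artifact_indices
        )

    def test_artifacts_recorded_in_ground_truth(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, ectopic_rate=0.05, missed_beat_rate=0.02)
        nn, truth = simulate_nn_series(cfg, seed=8)
        idx = truth.injected_artifact_indices
        assert len(idx) > 0
        assert idx.max() < len(nn)
        # ectopic pairs: shortened interval well below, lengthened well above baseline
        assert nn.values[idx].min() < 0.7 * 800 or nn.values[idx].max() > 1.3 * 800

    @pytest.mark.parametrize("kwargs", [
        {"mean_nn": -5.0}, {"record_duration": 0.0}, {"ectopic_rate": 1.5},
        {"band_freqs": {"ULF": 0.002, "VLF": 0.02, "LF": 0.2, "HF": 0.3}},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestRenderECG:
    def test_empty_peak_list_gives_noise_only_record(self, quiet_config):
        rec = render_ecg(np.array([]), quiet_config, duration=2.0, seed=0)
        assert len(rec.samples) == 1000
        assert np.abs(rec.samples).max() < 0.5  # noise + wander only, no QRS

    def test_sample_count_at_500hz(self, quiet_config):
        rec = render_ecg(np.array([1.0, 2.0]), quiet_config, duration=10.0, seed=0)
        assert rec.sampling_rate == 500.0
        assert len(rec.samples) == 5000

    def test_argmax_near_each_peak(self):
        cfg = SimulationConfig(record_duration=60.0, ecg_noise_sd=0.0, baseline_wander_mv=0.0)
        peaks = np.arange(60) * 1.0 + 0.5
        rec = render_ecg(peaks, cfg, duration=61.0)
        fs = rec.sampling_rate
        for tp in peaks:
            lo, hi = int((tp - 0.3) * fs), int((tp + 0.3) * fs)
            am = (lo + np.argmax(rec.samples[lo:hi])) / fs
            assert abs(am - tp) <= 1.0 / fs + 1e-9  # within one sample (2 ms)

    def test_non_increasing_peaks_rejected(self, quiet_config):
        with pytest.raises(ValueError, match="increasing"):
            render_ecg(np.array([1.0, 1.0, 2.0]), quiet_config)


class TestPatientCourse:
    @pytest.mark.parametrize("group", ["NOD", "SOD", "POD"])
    def test_round_trip_classification(self, group):
        """Intended label survives classification over 100 seeds per group."""
        for seed in range(100):
            rec = simulate_patient_course(group, seed)
            assert classify_outcome(rec).label is Group(group), (group, seed)

    def test_nod_labs_all_normal(self):
        rec = simulate_patient_course("NOD", 42)
        days = rec.days
        assert (days["creatinine"] < rec.baseline_creatinine + 25.6).all()
        assert (days["bilirubin"] <= 35.2).all()
        assert (days["spo2"] >= 90).all()
        assert not days["ventilated"].any()

    def test_pod_aki_trigger_realises_creatinine_rise(self):
        """When the AKI trigger is drawn, the rise is >= 25.6 umol/L post-admission."""
        found = 0
        for seed in range(200):
            rec = simulate_patient_course("POD", seed)
            lab = classify_outcome(rec)
            if lab.trigger == "de_novo_aki":
                found += 1
                day = rec.days[rec.days["day"] == lab.trigger_day].iloc[0]
                rise = day["creatinine"] - rec.baseline_creatinine
                assert rise >= 25.6 or day["creatinine"] >= 1.5 * rec.baseline_creatinine
        assert found > 0

    def test_sod_dysfunction_present_from_day0(self):
        for seed in range(50):
            rec = simulate_patient_course("SOD", seed)
            assert rec.icu_admission_time_h is None
            assert rec.death_time_h is None


@pytest.fixture(scope="module")
def small_cohort():
    cfg = SimulationConfig(
        record_duration=300.0,
        group_sizes={"NOD": 12, "SOD": 5, "POD": 5},
        dropout_times=[48.0],
        seed=9,
    )
    return simulate_cohort(cfg)


class TestCohort:
    def test_default_group_sizes_match_study(self):
        cfg = SimulationConfig()
        assert cfg.group_sizes == {"NOD": 119, "SOD": 38, "POD": 11}

    def test_requested_group_sizes_delivered(self, small_cohort):
        gt = small_cohort.ground_truth_frame()
        counts = gt["intended_group"].value_counts().to_dict()
        assert counts == {"NOD": 12, "SOD": 5, "POD": 5}

    def test_full_duration_when_no_dropout(self, small_cohort):
        for p in small_cohort.patients:
            assert p.dropout_time_h >= 48.0
            assert p.nn.end_times[-1] >= 295.0  # record runs to its full length

    def test_injected_mean_nn_effect_direction(self):
        """POD patients' generated mean NN sits below NOD's (effect x0.85)."""
        cfg = SimulationConfig(
            record_duration=120.0, group_sizes={"NOD": 25, "SOD": 0, "POD": 25},
            dropout_times=[48.0], seed=10,
        )
        gt = simulate_cohort(cfg).ground_truth_frame()
        nod = gt.loc[gt["intended_group"] == "NOD", "true_mean_nn"]
        pod = gt.loc[gt["intended_group"] == "POD", "true_mean_nn"]
        assert pod.mean() < nod.mean()

    def test_cohort_determinism(self):
        cfg = SimulationConfig(record_duration=120.0,
                               group_sizes={"NOD": 3, "SOD": 2, "POD": 2}, seed=11)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for pa, pb in zip(a.patients, b.patients):
            np.testing.assert_array_equal(pa.nn.values, pb.nn.values)
            assert pa.dropout_time_h == pb.dropout_time_h
            assert pa.course.days.equals(pb.course.days)

    def test_zero_patients_rejected(self):
        cfg = SimulationConfig(group_sizes={"NOD": 0, "SOD": 0, "POD": 0})
        with pytest.raises(ValueError, match="zero total"):
            simulate_cohort(cfg)

    def test_dropout_schedule_matches_attrition_fractions(self):
        """Empirical survival at 12/24/48 h tracks the 168/105/69/25 attrition."""
        rng = np.random.default_rng(0)
        draws = np.array([_draw_dropout(rng) for _ in range(4000)])
        for hours, frac in ATTRITION_SCHEDULE[1:]:
            emp = np.mean(draws >= hours)
            assert abs(emp - frac) < 0.03, (hours, emp, frac)
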