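"""Feature bank: hand-checked values, degenerate cases, block
cardinalities and scaling behavior."""

import numpy as np
import pytest

from pdsense import (
    SyntheticConfig,
    assemble_feature_table,
    axis_correlations,
    dwt_features,
    extract_recording_features,
    frequency_domain_features,
    generate_cohort,
    generate_patient,
    metadata_features,
    stft_window_features,
    time_domain_features,
    windowed_range_entropy_features,
)
from pdsense.features import (
    BLOCK_CARDINALITIES,
    _window_starts,
    apply_zscore,
    fit_zscore,
)
from pdsense.preprocess import SpectrumEstimate, estimate_psd

FS = 50.0


def _tone(freq, n=1500):
    return np.sin(2 * np.pi * freq * np.arange(n) / FS)


class TestTimeDomain:
    def test_hand_arithmetic(self):
        f = time_domain_features(np.array([1.0, 1.0, 2.0, 2.0]))
        assert f["Mean"] == pytest.approx(1.5)
        assert f["Power"] == pytest.approx(2.5)
        assert f["Absolute mean difference"] == pytest.approx(1.0)
        assert f["Median"] == pytest.approx(1.5)

    def test_constant_sequence_degenerates_cleanly(self):
        f = time_domain_features(np.full(100, 5.0))
        assert f["Standard deviation"] == 0.0
        assert f["Interquartile range"] == 0.0
        assert f["Max"] == f["Min"] == 5.0
        assert f["Skewness"] == f["Kurtosis"] == 0.0
        assert f["Approximate entropy"] == f["Sample entropy"] == 0.0

    def test_gaussian_moments(self, rng):
        f = time_domain_features(rng.normal(size=10_000))
        assert abs(f["Skewness"]) < 0.1
        assert abs(f["Kurtosis"]) < 0.2

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            time_domain_features(np.array([1.0, 2.0]))


class TestFrequencyDomain:
    def test_tone_centroid_and_peak(self):
        spec = estimate_psd(_tone(5.0), FS)
        f = frequency_domain_features(spec)
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(f["Spectral centroid"] - 5.0) <= df
        assert abs(f["Frequency of max power"] - 5.0) <= df

    def test_zero_signal_gives_all_zero(self):
        f = frequency_domain_features(estimate_psd(np.zeros(1500), FS))
        assert all(v == 0.0 for v in f.values())

    def test_two_equal_tones_centroid_at_midpoint(self):
        spec = estimate_psd(_tone(4.0) + _tone(8.0), FS)
        f = frequency_domain_features(spec)
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(f["Spectral centroid"] - 6.0) <= df


class TestSTFT:
    def test_thirty_seconds_gives_fourteen_windows(self):
        assert len(list(_window_starts(1500, FS))) == 14

    def test_stationary_noise_has_low_window_variability(self, rng):
        f = stft_window_features(rng.normal(size=1500), FS)
        cv = (
            f["Standard deviation of mean PSD (0-25 Hz)"]
            / f["Mean of mean PSD (0-25 Hz)"]
        )
        assert cv < 0.5

    def test_zero_signal(self):
        f = stft_window_features(np.zeros(1500), FS)
        assert all(v == 0.0 for v in f.values())

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            stft_window_features(np.ones(100), FS)


class TestWindowedRangeEntropy:
    def test_constant_signal_all_zero_ranges(self):
        f = windowed_range_entropy_features(np.full(1500, 2.0), FS)
        for stat in ("Mean", "Min", "Max", "Standard deviation"):
            assert f[f"{stat} of value range (4 s window)"] == 0.0

    def test_single_loud_window_dominates_max_range(self, rng):
        x = 0.01 * rng.normal(size=1500)
        x[600:800] += 5.0 * np.sin(np.arange(200))
        f = windowed_range_entropy_features(x, FS)
        assert (
            f["Max of value range (4 s window)"]
            > 10 * f["Min of value range (4 s window)"]
        )

    def test_uniform_noise_more_entropic_than_square_wave(self, rng):
        uniform = rng.uniform(-1, 1, size=1500)
        square = np.sign(_tone(2.0))
        fu = windowed_range_entropy_features(uniform, FS)
        fs_ = windowed_range_entropy_features(square, FS)
        assert (
            fu["Mean of entropy (4 s window)"]
            > fs_["Mean of entropy (4 s window)"]
        )


class TestDWT:
    def test_zero_signal(self):
        f = dwt_features(np.zeros(1500))
        assert all(v == 0.0 for v in f.values())

    def test_white_noise_detail_energy_ordering(self):
        # an orthonormal DWT spreads white noise evenly per coefficient,
        # so the level energies order by coefficient count: the D1 band
        # (half the spectrum, ~n/2 coefficients) carries more total
        # energy than D3 (~n/8)
        import pywt

        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=1500)
            coeffs = pywt.wavedec(x, "db10", mode="symmetric", level=3)
            e1 = np.sum(coeffs[-1] ** 2)
            e3 = np.sum(coeffs[-3] ** 2)
            if e1 > e3:
                wins += 1
        assert wins > 10

    def test_deterministic(self):
        x = np.sin(np.arange(1500) * 0.1)
        assert dwt_features(x) == dwt_features(x)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            dwt_features(np.ones(10))


class TestCorrelations:
    def test_identical_and_inverted_axes(self, rng):
        x = rng.normal(size=300)
        f = axis_correlations(x, x, -x)
        assert f["Correlation (X,Y)"] == pytest.approx(1.0)
        assert f["Correlation (X,Z)"] == pytest.approx(-1.0)

    def test_independent_axes_nearly_uncorrelated(self, rng):
        f = axis_correlations(*rng.normal(size=(3, 1500)))
        assert all(abs(v) < 0.1 for v in f.values())

    def test_constant_channel_maps_to_zero(self, rng):
        f = axis_correlations(np.ones(100), rng.normal(size=100),
                              rng.normal(size=100))
        assert f["Correlation (X,Y)"] == 0.0


class TestMetadata:
    def test_one_hot_encoding(self):
        profile = generate_patient(SyntheticConfig(n_patients=50, seed=2), 3)
        f = metadata_features(profile, profile.age_at_baseline + 1.0)
        for name, vocab, value in (
            ("Affected side", ("left", "right", "both"), profile.affected_side),
            ("Handedness", ("left", "right"), profile.handedness),
        ):
            block = [f[f"{name} = {c}"] for c in vocab]
            assert sum(block) == 1.0
            assert f[f"{name} = {value}"] == 1.0
        assert f["Years since diagnosis"] == pytest.approx(
            profile.years_since_diagnosis + 1.0
        )
        assert f["Age at examination"] == pytest.approx(
            profile.age_at_baseline + 1.0
        )

    def test_unknown_category_leaves_block_zero(self):
        profile = generate_patient(SyntheticConfig(n_patients=1, seed=0), 0)
        profile = type(profile)(
            **{**profile.__dict__, "group": "unknown-group"}
        )
        f = metadata_features(profile, 60.0)
        assert sum(v for k, v in f.items() if k.startswith("Group =")) == 0.0


class TestRecordingBank:
    def test_block_cardinalities_match_printed_counts(self, sample_recording):
        f = extract_recording_features(sample_recording)
        counts = dict.fromkeys(BLOCK_CARDINALITIES, 0)
        for name in f:
            param = name.split("/", 3)[3] if name.count("/") >= 3 else ""
            if "Correlation" in name:
                counts["correlation"] += 1
            elif "mean PSD" in param:
                counts["stft"] += 1
            elif "4 s window" in param:
                counts["windowed"] += 1
            elif param.startswith("D") and (
                "mean" in param or "deviation" in param
            ):
                counts["dwt"] += 1
            elif "Hz)" in param:
                counts["frequency"] += 1
            else:
                counts["time"] += 1
        assert counts == BLOCK_CARDINALITIES
        assert len(f) == sum(BLOCK_CARDINALITIES.values()) == 323

    def test_entropy_switch_drops_axis_entropies(self, sample_recording):
        f = extract_recording_features(
            sample_recording, entropy_all_channels=False
        )
        assert len(f) == 323 - 6

    def test_deterministic(self, sample_recording):
        a = extract_recording_features(sample_recording)
        b = extract_recording_features(sample_recording)
        assert a == b

    def test_amplitude_scaling_behavior(self, sample_recording):
        rec = sample_recording
        scaled = type(rec)(
            device=rec.device, sensor=rec.sensor, hand=rec.hand,
            exercise=rec.exercise, x=3.0 * rec.x, y=3.0 * rec.y,
            z=3.0 * rec.z,
        )
        fa = extract_recording_features(rec)
        fb = extract_recording_features(scaled)
        prefix = "Phone-ACC-#1/Right"
        assert fb[f"{prefix}/X/Standard deviation"] == pytest.approx(
            3.0 * fa[f"{prefix}/X/Standard deviation"]
        )
        assert fb[f"{prefix}/X/Power"] == pytest.approx(
            9.0 * fa[f"{prefix}/X/Power"]
        )
        assert fb[f"{prefix}/-/Correlation (X,Y)"] == pytest.approx(
            fa[f"{prefix}/-/Correlation (X,Y)"]
        )
        assert fb[f"{prefix}/X/Spectral centroid (0-25 Hz)"] == pytest.approx(
            fa[f"{prefix}/X/Spectral centroid (0-25 Hz)"], rel=1e-6
        )


class TestFeatureTable:
    def test_single_block_column_count(self, small_cohort):
        table = assemble_feature_table(
            small_cohort, blocks=[("phone", "accelerometer", "right", 1)],
            include_metadata=False,
        )
        assert table.features.shape[1] == 323

    def test_two_blocks_double_sensor_columns_metadata_fixed(self, small_cohort):
        one = assemble_feature_table(
            small_cohort, blocks=[("phone", "accelerometer", "right", 1)]
        )
        two = assemble_feature_table(
            small_cohort,
            blocks=[
                ("phone", "accelerometer", "right", 1),
                ("phone", "accelerometer", "right", 3),
            ],
        )
        assert len(two.sensor_columns()) == 2 * len(one.sensor_columns())
        assert two.metadata_columns() == one.metadata_columns()

    def test_rows_align_with_labels_and_patients(self, small_cohort):
        table = assemble_feature_table(small_cohort)
        assert list(table.features.index) == list(table.labels.index)
        assert list(table.features.index) == list(table.patient_ids.index)
        assert not table.features.isna().any().any()

    def test_missing_block_drops_row_with_reason(self, small_cohort):
        wanted = [("phone", "accelerometer", "right", 1)]
        exam = small_cohort.examinations[0]
        removed = exam.recordings.pop(wanted[0])
        try:
            table = assemble_feature_table(small_cohort, blocks=wanted)
            assert any(e == exam.exam_id for e, _ in table.dropped)
            assert exam.exam_id not in table.features.index
        finally:
            exam.recordings[wanted[0]] = removed

    def test_zscore_normalizes_training_columns(self, rng):
        import pandas as pd

        df = pd.DataFrame(rng.normal(5, 3, size=(50, 4)))
        z = apply_zscore(df, fit_zscore(df))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-12)
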