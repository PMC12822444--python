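"""Spectral features, cough detection/alarm, and the two classifiers."""

import numpy as np
import pytest

from airtherm.features_detect import (
    AlarmState,
    CoughEvent,
    CoughThresholds,
    alarm_rule,
    build_speech_features,
    default_cough_thresholds,
    detect_coughs,
    fusion_features,
    fusion_label,
    train_fusion_classifier,
    train_speech_classifier,
    voltage_spectrum,
)
from airtherm.physio_synth import gen_cough_train, gen_fusion_dataset
from airtherm.thermo_response import AIR, DevicePlate, FlowSignal, VoltageTrace, simulate_response


def make_trace(t, V):
    return VoltageTrace(t=t, T_upper=np.zeros_like(t), dT_TED=np.zeros_like(t),
                        V=V, T_lower=293.15)


class TestVoltageSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        fs, f0 = 100.0, 2.0
        t = np.arange(0, 10, 1 / fs)
        tr = make_trace(t, np.sin(2 * np.pi * f0 * t))
        sf = voltage_spectrum(tr, frame_len=2.0, hop=0.5, f_max=None)
        for row in sf.magnitude:
            assert sf.freqs[int(np.argmax(row))] == pytest.approx(f0, abs=0.5)

    def test_zero_trace_zero_magnitude(self):
        t = np.arange(0, 5, 0.01)
        sf = voltage_spectrum(make_trace(t, np.zeros_like(t)))
        assert np.all(sf.magnitude == 0)

    def test_parseval_per_frame(self):
        """Windowed frame energy agrees between time and frequency domain."""
        from scipy.signal import get_window

        fs = 100.0
        rng = np.random.default_rng(0)
        t = np.arange(0, 6, 1 / fs)
        y = rng.normal(size=len(t))
        frame_len, hop = 1.0, 0.5
        sf = voltage_spectrum(make_trace(t, y), frame_len, hop, f_max=None)
        n = int(frame_len * fs)
        w = get_window("hann", n, fftbins=True)
        for k, row in enumerate(sf.magnitude):
            frame = y[k * int(hop * fs): k * int(hop * fs) + n] * w
            e_time = np.sum(frame**2)
            # rfft energy: DC and (even-n) Nyquist bins counted once
            e_freq = (row[0] ** 2 + 2 * np.sum(row[1:-1] ** 2) + row[-1] ** 2) / n
            assert e_freq == pytest.approx(e_time, rel=1e-6)

    def test_fixed_length_across_durations(self):
        t1 = np.arange(0, 4, 0.01)
        t2 = np.arange(0, 9, 0.01)
        v1 = voltage_spectrum(make_trace(t1, np.sin(t1))).flattened_vector
        v2 = voltage_spectrum(make_trace(t2, np.sin(t2))).flattened_vector
        assert v1.shape == v2.shape

    def test_short_trace_rejected(self):
        t = np.arange(0, 0.2, 0.01)
        with pytest.raises(ValueError):
            voltage_spectrum(make_trace(t, np.zeros_like(t)), frame_len=1.0, hop=0.5)


class TestCoughDetection:
    @pytest.mark.parametrize("intensity", ["mild", "moderate", "severe"])
    def test_count_and_grade_match_generator(self, intensity):
        plate = DevicePlate()
        flow = gen_cough_train(intensity, 3, 5.0, 100.0, seed=8)
        tr = simulate_response(plate, AIR, flow, plate.T_lower)
        events = detect_coughs(tr)
        assert len(events) == 3
        assert all(e.intensity == intensity for e in events)
        assert all(0 <= e.time <= 5.0 for e in events)

    def test_quiet_baseline_no_events(self):
        plate = DevicePlate()
        flow = gen_cough_train("severe", 0, 5.0, 100.0, seed=1)
        tr = simulate_response(plate, AIR, flow, plate.T_lower)
        assert detect_coughs(tr) == []

    def test_breathing_not_mistaken_for_coughs(self):
        from airtherm.physio_synth import NORMAL_BREATH, gen_breath_flow

        plate = DevicePlate()
        flow = gen_breath_flow(NORMAL_BREATH, 20.0, 100.0, seed=2)
        tr = simulate_response(plate, AIR, flow, plate.T_lower)
        assert detect_coughs(tr) == []

    def test_mixed_train_counts_per_intensity(self):
        plate = DevicePlate()
        mild = gen_cough_train("mild", 2, 4.0, 100.0, seed=3)
        severe = gen_cough_train("severe", 3, 4.0, 100.0, seed=4)
        t = np.arange(0, 8.0, 0.01)
        v = np.concatenate([mild.v, severe.v])
        T_air = np.concatenate([mild.T_air, severe.T_air])
        tr = simulate_response(plate, AIR, FlowSignal(t=t, v=v, T_air=T_air),
                               293.15)
        events = detect_coughs(tr)
        counts = {k: sum(e.intensity == k for e in events)
                  for k in ("mild", "moderate", "severe")}
        assert counts == {"mild": 2, "moderate": 0, "severe": 3}

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            CoughThresholds(detect=1.0, moderate=0.5, severe=2.0)


def ev(t, intensity="severe"):
    return CoughEvent(time=t, peak_voltage=1e-3, intensity=intensity)


class TestAlarmRule:
    def test_three_severe_in_window_triggers(self):
        state = alarm_rule([ev(0.5), ev(2.0), ev(4.5)])
        assert state.active and state.trigger_time == 4.5
        assert len(state.contributing_events) == 3

    def test_two_severe_insufficient(self):
        assert not alarm_rule([ev(0.5), ev(4.0)]).active

    def test_mild_never_contributes(self):
        events = [ev(t, "mild") for t in (0.5, 1.0, 1.5, 2.0, 2.5)]
        assert not alarm_rule(events).active
        mixed = events + [ev(3.0), ev(3.5)]
        assert not alarm_rule(mixed).active

    def test_exhaustive_truth_table(self):
        """Alarm fires iff >= 3 severe events share some 5 s window."""
        for n_severe in range(6):
            for spread in (1.0, 4.9, 5.0, 6.0, 12.0):
                times = np.linspace(0.0, spread, n_severe) if n_severe > 1 else [0.0][:n_severe]
                events = [ev(float(t)) for t in times]
                state = alarm_rule(events)
                should = n_severe >= 3 and any(
                    times[i + 2] - times[i] <= 5.0 for i in range(n_severe - 2)
                )
                assert state.active == should, (n_severe, spread)

    def test_minimal_triggering_count_is_three(self):
        assert not alarm_rule([ev(1.0), ev(2.0)]).active
        assert alarm_rule([ev(1.0), ev(2.0), ev(3.0)]).active

    def test_window_spanning_events_trigger_late(self):
        # first three span > 5 s; a fourth closes a valid window
        state = alarm_rule([ev(0.0), ev(3.0), ev(6.0), ev(7.5)])
        assert state.active and state.trigger_time == 7.5


class TestFusionLabel:
    @pytest.mark.parametrize(
        "ted,hb,expected",
        [
            ("A-TEDS", "A-HBS", "abnormal"),
            ("A-TEDS", "normal", "normal"),
            ("normal", "A-HBS", "normal"),
            ("normal", "normal", "normal"),
        ],
    )
    def test_rule_table(self, ted, hb, expected):
        assert fusion_label(ted, hb) == expected

    def test_unknown_tokens_rejected(self):
        with pytest.raises(ValueError):
            fusion_label("weird", "normal")
        with pytest.raises(ValueError):
            fusion_label("normal", "weird")


class TestSpeechClassifier:
    def test_accuracy_on_separable_classes(self):
        feats, labels = build_speech_features(10, 100.0, seed=0)
        _, report = train_speech_classifier(feats, labels, seed=0)
        assert report.accuracy >= 0.8  # single seed; the 20-seed mean is checked elsewhere

    def test_deterministic_report(self):
        feats, labels = build_speech_features(10, 100.0, seed=1)
        _, r1 = train_speech_classifier(feats, labels, seed=1)
        _, r2 = train_speech_classifier(feats, labels, seed=1)
        assert r1.accuracy == r2.accuracy
        assert np.array_equal(r1.confusion_matrix, r2.confusion_matrix)

    def test_single_class_rejected(self):
        feats, labels = build_speech_features(10, 100.0, seed=0)
        ten = [f for f, l in zip(feats, labels) if l == "HELP"]
        with pytest.raises(ValueError):
            train_speech_classifier(ten, ["HELP"] * len(ten), seed=0)

    def test_undersized_class_rejected(self):
        feats, labels = build_speech_features(9, 100.0, seed=0)
        with pytest.raises(ValueError):
            train_speech_classifier(feats, labels, seed=0)

    def test_memorization_of_training_sample(self):
        feats, labels = build_speech_features(10, 100.0, seed=2)
        model, _ = train_speech_classifier(feats, labels, seed=2)
        X0 = feats[0].flattened_vector.reshape(1, -1)
        assert model.predict(X0)[0] == labels[0]

    def test_confusion_matrix_bookkeeping(self):
        feats, labels = build_speech_features(10, 100.0, seed=3)
        _, report = train_speech_classifier(feats, labels, seed=3)
        assert report.confusion_matrix.sum() == 5  # one held-out sample per class
        assert np.all(report.confusion_matrix.sum(axis=1) == 1)


@pytest.fixture(scope="module")
def dataset():
    return gen_fusion_dataset(25, fs=100.0, seed=0, duration=6.0)


class TestFusionClassifier:

    def test_feature_vector_concatenates_both_channels(self, dataset):
        rec = dataset[0]
        x = fusion_features(rec)
        n_ted = len(voltage_spectrum(rec.ted_trace).flattened_vector)
        n_hb = len(voltage_spectrum(rec.hb_trace).flattened_vector)
        assert len(x) == n_ted + n_hb

    def test_deterministic_report(self, dataset):
        _, r1 = train_fusion_classifier(dataset, seed=4)
        _, r2 = train_fusion_classifier(dataset, seed=4)
        assert r1.accuracy == r2.accuracy
        assert np.array_equal(r1.confusion_matrix, r2.confusion_matrix)

    def test_confusion_row_sums_match_test_counts(self, dataset):
        _, report = train_fusion_classifier(dataset, seed=1)
        n_test = report.confusion_matrix.sum()
        assert n_test == 25  # 25% stratified hold-out of 100 recordings
        # stratified: abnormal is 1/4 of the data
        idx = report.labels.index("abnormal")
        assert report.confusion_matrix[idx].sum() == pytest.approx(n_test / 4, abs=1)

    def test_single_class_rejected(self, dataset):
        normals = [r for r in dataset if r.fused_label == "normal"]
        with pytest.raises(ValueError):
            train_fusion_classifier(normals, seed=0)

    def test_shuffled_labels_drop_to_chance(self, dataset):
        """Null control: permuted labels destroy the signal, so accuracy falls
        to the chance band of a 1:3 class split (majority rate 0.75)."""
        import copy

        rng = np.random.default_rng(0)
        shuffled = copy.copy(list(dataset))
        labs = [r.fused_label for r in shuffled]
        perm = rng.permutation(len(labs))
        shuffled = [copy.copy(r) for r in shuffled]
        for r, j in zip(shuffled, perm):
            r.fused_label = labs[j]
        _, real = train_fusion_classifier(dataset, seed=0)
        _, null = train_fusion_classifier(shuffled, seed=0)
        assert null.accuracy <= 0.9
        assert null.accuracy < real.accuracy
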