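"""Feature extraction, cough-alarm logic, and recognition models.

Four layers sit on top of the simulated TED voltage traces:

* short-time Fourier (spectrogram) features of the voltage signal, flattened
  to a fixed-length log-magnitude vector;
* a cough detector (derivative + amplitude peak picking) with amplitude-band
  intensity grading, feeding a sliding-window alarm rule — an alarm fires
  when three or more *severe* coughs fall inside any 5 s window, severe
  being a necessary condition;
* a fully-connected neural-network speech classifier trained on spectral
  vectors with a 9-train / 1-test split per class;
* the multi-source fusion layer: a hard labeling rule (abnormal iff the TED
  signal AND the heartbeat are abnormal) and a gradient-boosted tree
  classifier on concatenated TED + heartbeat spectral features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.signal import find_peaks, get_window
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from airtherm.physio_synth import HeartbeatTrace, LabeledRecording
from airtherm.thermo_response import VoltageTrace

# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------


@dataclass
class SpectralFeatures:
    """Short-time magnitude spectrum of a voltage trace.

    ``magnitude`` is a (frames × frequencies) non-negative matrix;
    ``flattened_vector`` is the log-magnitude resampled onto a fixed
    (n_frames × n_freqs) grid so that every sample of a dataset yields the
    same feature length regardless of its duration.
    """

    frame_times: NDArray[np.float64]
    freqs: NDArray[np.float64]
    magnitude: NDArray[np.float64]
    flattened_vector: NDArray[np.float64]


def _frame_signal(x: NDArray, n_frame: int, n_hop: int) -> NDArray:
    n_frames = 1 + (len(x) - n_frame) // n_hop
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    return x[idx]


def voltage_spectrum(
    trace: VoltageTrace | HeartbeatTrace,
    frame_len: float = 0.5,
    hop: float = 0.25,
    *,
    n_frames_out: int = 12,
    n_freqs_out: int = 16,
    f_max: float | None = 15.0,
) -> SpectralFeatures:
    """Hann-windowed magnitude spectrogram of a uniformly sampled trace.

    The flattened feature vector is log10(magnitude + eps) restricted to
    frequencies up to ``f_max`` (physiological signals — breathing, pulse
    harmonics, burst transients — live well below 15 Hz) and bilinearly
    resampled to an ``n_frames_out × n_freqs_out`` grid, giving a
    fixed-length descriptor for classification. ``magnitude`` itself keeps
    the full band.
    """
    if not frame_len > hop > 0:
        raise ValueError("require frame_len > hop > 0")
    y = trace.V if isinstance(trace, VoltageTrace) else trace.y
    t = trace.t
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
        raise ValueError("trace must be uniformly sampled")
    fs = 1.0 / dt[0]
    n_frame = int(round(frame_len * fs))
    n_hop = int(round(hop * fs))
    if len(y) < n_frame:
        raise ValueError("trace shorter than one analysis frame")

    frames = _frame_signal(np.asarray(y, dtype=float), n_frame, n_hop)
    window = get_window("hann", n_frame, fftbins=True)
    spec = np.fft.rfft(frames * window, axis=1)
    magnitude = np.abs(spec)
    freqs = np.fft.rfftfreq(n_frame, d=1.0 / fs)
    frame_times = t[0] + (np.arange(frames.shape[0]) * n_hop + n_frame / 2) / fs

    logmag = np.log10(magnitude + 1e-12)
    if f_max is not None:
        keep = max(2, int(np.searchsorted(freqs, f_max, side="right")))
        logmag = logmag[:, :keep]
    # bilinear resample onto the fixed output grid
    fi = np.linspace(0, logmag.shape[0] - 1, n_frames_out)
    qi = np.linspace(0, logmag.shape[1] - 1, n_freqs_out)
    rows = np.empty((logmag.shape[0], n_freqs_out))
    for r in range(logmag.shape[0]):
        rows[r] = np.interp(qi, np.arange(logmag.shape[1]), logmag[r])
    grid = np.empty((n_frames_out, n_freqs_out))
    for c in range(n_freqs_out):
        grid[:, c] = np.interp(fi, np.arange(rows.shape[0]), rows[:, c])

    return SpectralFeatures(
        frame_times=frame_times,
        freqs=freqs,
        magnitude=magnitude,
        flattened_vector=grid.ravel(),
    )


# ---------------------------------------------------------------------------
# cough detection and alarm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoughEvent:
    """A detected cough transient: its time (s), peak voltage (V), and the
    intensity band {mild, moderate, severe} assigned by amplitude."""

    time: float
    peak_voltage: float
    intensity: str


@dataclass(frozen=True)
class CoughThresholds:
    """Voltage-rate bands separating cough intensities.

    A cough is a fast, strong convective transient: the surface temperature —
    and hence the voltage — jumps during the ≈0.25 s event and then holds, so
    the discriminative quantity is the high-passed voltage *rate* dV/dt, not
    the voltage level. ``detect`` is the minimum rate peak (V/s) for an event
    to count as a cough; ``moderate`` and ``severe`` are the lower band
    edges. Values are calibrated against the generator's intensity peaks via
    :func:`default_cough_thresholds` and carried in config, not hard-coded.
    """

    detect: float
    moderate: float
    severe: float
    min_spacing: float = 0.35  # s between events
    highpass_window: float = 0.75  # s moving-average subtracted before picking

    def __post_init__(self) -> None:
        if not 0 < self.detect < self.moderate < self.severe:
            raise ValueError("require 0 < detect < moderate < severe")

    def grade(self, rate_peak: float) -> str:
        if rate_peak >= self.severe:
            return "severe"
        if rate_peak >= self.moderate:
            return "moderate"
        return "mild"


#: Fraction of the ideal rate peak surviving the moving-average high-pass
#: and discrete sampling for a 0.25 s cough transient (calibrated once
#: against the generator at 100 Hz).
_HP_ATTENUATION = 0.74


def default_cough_thresholds(
    plate: "DevicePlate | None" = None,
    fluid: "FluidProperties | None" = None,
) -> CoughThresholds:
    """Intensity bands derived from the forward model.

    A cough of peak speed v drives the surface at a maximum rate
    f(v)·(T_exhale − T_upper) ≈ f(v)·(38 °C − T_lower), so the voltage-rate
    peak is alpha·f(v)·ΔT_drive scaled by the high-pass attenuation. Band
    edges sit midway between the predicted responses of the generator's
    mild / moderate / severe peaks (3 / 4.5 / 6 m/s); the detect floor is
    half the mild response.
    """
    from airtherm.physio_synth import COUGH_PEAKS, EXHALE_T
    from airtherm.thermo_response import AIR, DevicePlate
    from airtherm.thermo_response import convective_coefficient, thermal_rate

    plate = plate or DevicePlate()
    fluid = fluid or AIR
    drive = EXHALE_T - plate.T_lower

    def rate_peak(v: float) -> float:
        f = thermal_rate(convective_coefficient(fluid, plate.L, v), plate)
        return _HP_ATTENUATION * plate.alpha_device * f * drive

    r_mild = rate_peak(COUGH_PEAKS["mild"])
    r_mod = rate_peak(COUGH_PEAKS["moderate"])
    r_sev = rate_peak(COUGH_PEAKS["severe"])
    return CoughThresholds(
        detect=0.5 * r_mild,
        moderate=0.5 * (r_mild + r_mod),
        severe=0.5 * (r_mod + r_sev),
    )


def _moving_average(x: NDArray, n: int) -> NDArray:
    kernel = np.ones(n) / n
    pad = n // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad : pad + len(x)]


def detect_coughs(
    trace: VoltageTrace, thresholds: CoughThresholds | None = None
) -> list[CoughEvent]:
    """Peak-pick cough transients on the high-passed voltage rate.

    dV/dt is computed, its slow component (moving average over
    ``highpass_window``) is subtracted so breathing-scale variation drops
    out, and peaks above the detect floor with the minimum spacing become
    events graded by rate amplitude.
    """
    thresholds = thresholds or default_cough_thresholds()
    fs = trace.fs
    V = np.asarray(trace.V, dtype=float)
    dVdt = np.gradient(V, trace.t)
    n_hp = max(3, int(round(thresholds.highpass_window * fs)))
    resid = dVdt - _moving_average(dVdt, n_hp)
    distance = max(1, int(round(thresholds.min_spacing * fs)))
    peaks, _ = find_peaks(resid, height=thresholds.detect, distance=distance)
    return [
        CoughEvent(
            time=float(trace.t[p]),
            peak_voltage=float(V[p]),
            intensity=thresholds.grade(float(resid[p])),
        )
        for p in peaks
    ]


@dataclass
class AlarmState:
    """Outcome of the cough-alarm rule: whether it fired, when, and which
    severe events contributed."""

    active: bool
    trigger_time: float | None
    contributing_events: list[CoughEvent] = field(default_factory=list)


def alarm_rule(
    events: Sequence[CoughEvent], window: float = 5.0, min_count: int = 3
) -> AlarmState:
    """Sliding-window cough alarm.

    Only *severe* coughs count (severe intensity is a necessary condition);
    the alarm activates at the earliest time at which ``min_count`` or more
    severe events fall within any closed ``window``-second interval, and the
    trigger time is the time of the event completing that count.
    """
    severe = sorted(
        (e for e in events if e.intensity == "severe"), key=lambda e: e.time
    )
    if len(severe) < min_count:
        return AlarmState(active=False, trigger_time=None)
    for i in range(min_count - 1, len(severe)):
        start = severe[i - min_count + 1]
        if severe[i].time - start.time <= window:
            contributing = severe[i - min_count + 1 : i + 1]
            return AlarmState(
                active=True,
                trigger_time=severe[i].time,
                contributing_events=list(contributing),
            )
    return AlarmState(active=False, trigger_time=None)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


@dataclass
class ClassifierReport:
    """Held-out evaluation summary: accuracy, label×label confusion counts
    (rows = true, columns = predicted), per-class recall, and the label
    ordering of the matrix axes."""

    accuracy: float
    confusion_matrix: NDArray[np.int64]
    per_class_recall: dict[str, float]
    labels: list[str]
    params: dict = field(default_factory=dict)


def _report(y_true: np.ndarray, y_pred: np.ndarray, labels: list[str],
            params: dict) -> ClassifierReport:
    from sklearn.metrics import confusion_matrix as sk_confusion

    cm = sk_confusion(y_true, y_pred, labels=labels)
    with np.errstate(invalid="ignore"):
        recall = np.diag(cm) / cm.sum(axis=1)
    return ClassifierReport(
        accuracy=float((y_true == y_pred).mean()),
        confusion_matrix=cm,
        per_class_recall={
            lab: float(r) for lab, r in zip(labels, recall) if not np.isnan(r)
        },
        labels=labels,
        params=params,
    )


def train_speech_classifier(
    features: Sequence[SpectralFeatures],
    labels: Sequence[str],
    seed: int = 0,
    *,
    hidden: tuple[int, int] = (64, 32),
    max_iter: int = 600,
):
    """Train the fully-connected speech network with the 9/1 per-class split.

    Every class must contribute at least 10 samples; exactly one per class is
    held out (chosen by the seed) and the rest train a two-hidden-layer
    feed-forward network with softmax output on standardized spectral
    vectors. Returns (fitted model, ClassifierReport on the held-out set).
    Deterministic for a fixed (features, labels, seed).
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two speech classes")
    X = np.vstack([f.flattened_vector for f in features])
    if len(X) != len(labels):
        raise ValueError("features and labels length mismatch")

    rng = np.random.default_rng(seed)
    test_idx = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 10:
            raise ValueError(
                f"class {c!r} has {len(idx)} samples; the 9/1 split needs >= 10"
            )
        test_idx.append(int(rng.choice(idx)))
    test_mask = np.zeros(len(labels), dtype=bool)
    test_mask[test_idx] = True

    model = make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=hidden,
            activation="relu",
            max_iter=max_iter,
            random_state=seed,
        ),
    )
    model.fit(X[~test_mask], labels[~test_mask])
    y_pred = model.predict(X[test_mask])
    report = _report(
        labels[test_mask], y_pred, classes,
        params={"hidden": hidden, "max_iter": max_iter, "seed": seed},
    )
    return model, report


def build_speech_features(
    n_per_class: int = 10,
    fs: float = 100.0,
    seed: int = 0,
    *,
    duration: float = 3.0,
    plate=None,
    templates: dict | None = None,
) -> tuple[list[SpectralFeatures], list[str]]:
    """Generate the labeled spectral dataset for the speech classifier.

    For each phrase template, ``n_per_class`` airflow realizations are drawn
    (seeds split from ``seed``), run through the thermoelectric forward
    model, and converted to spectral vectors. Returns (features, labels).
    """
    from airtherm.physio_synth import SPEECH_TEMPLATES, gen_speech_flow
    from airtherm.thermo_response import AIR, DevicePlate, simulate_response

    plate = plate or DevicePlate()
    templates = templates or SPEECH_TEMPLATES
    child = np.random.SeedSequence(seed).generate_state(
        len(templates) * n_per_class, dtype=np.uint32
    ) % (2**31)
    feats: list[SpectralFeatures] = []
    labels: list[str] = []
    i = 0
    for label, tpl in templates.items():
        for _ in range(n_per_class):
            flow = gen_speech_flow(tpl, fs, int(child[i]), duration=duration)
            i += 1
            trace = simulate_response(plate, AIR, flow, plate.T_lower)
            feats.append(voltage_spectrum(trace))
            labels.append(label)
    return feats, labels


def fusion_label(ted_state: str, hb_state: str) -> str:
    """Hard fusion rule: "abnormal" iff the TED signal is abnormal (A-TEDS)
    AND the heartbeat is abnormal (A-HBS); the other three combinations are
    "normal"."""
    if ted_state not in {"normal", "A-TEDS"}:
        raise ValueError(f"unknown TED state {ted_state!r}")
    if hb_state not in {"normal", "A-HBS"}:
        raise ValueError(f"unknown heartbeat state {hb_state!r}")
    return "abnormal" if (ted_state == "A-TEDS" and hb_state == "A-HBS") else "normal"


def fusion_features(rec: LabeledRecording, **spectrum_kw) -> NDArray[np.float64]:
    """Concatenated spectral vectors of the TED voltage and heartbeat traces."""
    f_ted = voltage_spectrum(rec.ted_trace, **spectrum_kw)
    f_hb = voltage_spectrum(rec.hb_trace, **spectrum_kw)
    return np.concatenate([f_ted.flattened_vector, f_hb.flattened_vector])


def train_fusion_classifier(
    dataset: Sequence[LabeledRecording],
    seed: int = 0,
    *,
    test_fraction: float = 0.25,
    n_estimators: int = 200,
    max_depth: int = 3,
    learning_rate: float = 0.1,
    colsample_bytree: float = 0.3,
    subsample: float = 0.8,
):
    """Train the gradient-boosted fusion classifier on fused labels.

    Features are concatenated TED + heartbeat spectral vectors; evaluation is
    a stratified hold-out of ``test_fraction``. Column subsampling is kept
    aggressive (0.3) so individual trees are forced to draw on both the TED
    and the heartbeat blocks — the fused label is a conjunction, and without
    it the greedy ensemble over-commits to whichever channel gives the
    largest early gain. Deterministic for a fixed (dataset, seed). Returns
    (fitted model, ClassifierReport).
    """
    from sklearn.model_selection import train_test_split

    y = np.asarray([r.fused_label for r in dataset])
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("fusion dataset must contain both fused classes")
    X = np.vstack([fusion_features(r) for r in dataset])
    y_codes = np.asarray([classes.index(lab) for lab in y])

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y_codes, test_size=test_fraction, stratify=y_codes, random_state=seed
    )
    model = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        colsample_bytree=colsample_bytree,
        subsample=subsample,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    model.fit(X_tr, y_tr)
    y_pred = model.predict(X_te)
    report = _report(
        np.asarray([classes[i] for i in y_te]),
        np.asarray([classes[i] for i in y_pred]),
        classes,
        params={
            "n_estimators": n_estimators,
            "max_depth": max_depth,
            "learning_rate": learning_rate,
            "seed": seed,
        },
    )
    return model, report
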