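"""Seeded generators of synthetic physiological inputs.

Produces the signal families the recognition pipeline consumes: periodic
exhale/inhale breathing airflow, per-word speech airflow bursts, cough
trains of graded intensity, PPG-like heartbeat pulse traces, and balanced
labeled datasets for multi-source fusion training.

Every generator is a pure function of its parameters and an integer seed
(identical inputs give identical arrays). Airflow follows the measured
physiological envelope: normal-breathing peak speeds sit inside 0.5–2.5 m/s
and exhaled air is ≈38 °C (311.15 K); inhaled/ambient air defaults to 20 °C.
Waveform shapes (half-sinusoid breath lobes, sinusoidal bursts per spoken
word, two-Gaussian PPG pulses) are parameterized templates whose obligations
are determinism, class separability, and those physiological ranges — they
are not acoustic or fluid-mechanical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from airtherm.thermo_response import (
    AIR,
    DevicePlate,
    FlowSignal,
    VoltageTrace,
    simulate_response,
)

EXHALE_T = 311.15  # 38 °C, human exhaled air
AMBIENT_T = 293.15  # 20 °C


# ---------------------------------------------------------------------------
# breathing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreathPattern:
    """Breathing waveform parameters.

    kind: one of {"normal", "feeble", "weightless", "cough"};
    rate in breaths/min; peak_exhale_v in m/s (normal breathing must stay in
    the measured 0.5–2.5 m/s range); exhale_T / ambient_T in kelvin.
    """

    kind: str = "normal"
    rate: float = 15.0
    peak_exhale_v: float = 1.5
    exhale_T: float = EXHALE_T
    ambient_T: float = AMBIENT_T

    def __post_init__(self) -> None:
        if self.kind not in {"normal", "feeble", "weightless", "cough"}:
            raise ValueError(f"unknown breath kind {self.kind!r}")
        if not self.peak_exhale_v > 0:
            raise ValueError("peak_exhale_v must be strictly positive")
        if self.kind == "normal" and not 0.5 <= self.peak_exhale_v <= 2.5:
            raise ValueError("normal breathing peak must lie in [0.5, 2.5] m/s")


NORMAL_BREATH = BreathPattern("normal", rate=15.0, peak_exhale_v=1.5)
#: Feeble respiration (breathing-resistor surrogate): strongly reduced flow.
FEEBLE_BREATH = BreathPattern("feeble", rate=18.0, peak_exhale_v=0.3)
#: Weightless respiration: a short flow gap followed by an exhale transient.
WEIGHTLESS_BREATH = BreathPattern("weightless", rate=15.0, peak_exhale_v=1.5)


def gen_breath_flow(
    pattern: BreathPattern, duration: float, fs: float, seed: int
) -> FlowSignal:
    """Cyclic breathing airflow: half-sinusoid exhale lobes at exhale_T
    alternating with (weaker) inhale lobes at ambient_T, plus seeded Gaussian
    amplitude noise and slow baseline drift.

    A "weightless" pattern additionally blanks the flow for ≈0.5 s mid-record
    and follows the gap with a sharp exhale transient (drop surrogate); a
    "cough" pattern superposes three sharp high-velocity transients.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if fs < 20:
        raise ValueError("sampling rate must be at least 20 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    period = 60.0 / pattern.rate
    phase = (t % period) / period  # 0..1 within each breath cycle
    v = np.where(
        phase < 0.5,
        pattern.peak_exhale_v * np.sin(2 * np.pi * phase),          # exhale lobe
        0.8 * pattern.peak_exhale_v * np.sin(2 * np.pi * (phase - 0.5)),  # inhale
    )
    exhaling = phase < 0.5
    T_air = np.where(exhaling, pattern.exhale_T, pattern.ambient_T)

    if pattern.kind == "weightless":
        gap_start = 0.4 * duration
        gap = (t >= gap_start) & (t < gap_start + 0.5)
        v = np.where(gap, 0.0, v)
        burst = (t >= gap_start + 0.5) & (t < gap_start + 0.8)
        tb = (t - gap_start - 0.5) / 0.3
        v = np.where(burst, 3.2 * np.sin(np.pi * np.clip(tb, 0, 1)), v)
        T_air = np.where(burst, pattern.exhale_T, T_air)
    elif pattern.kind == "cough":
        for k in range(3):
            onset = 0.25 * duration + 0.6 * k
            ev = (t >= onset) & (t < onset + 0.25)
            te = (t - onset) / 0.25
            v = np.where(ev, 5.0 * np.sin(np.pi * np.clip(te, 0, 1)), v)
            T_air = np.where(ev, pattern.exhale_T, T_air)

    v = v + rng.normal(0.0, 0.02 * pattern.peak_exhale_v, size=n)
    v += 0.01 * pattern.peak_exhale_v * np.sin(2 * np.pi * 0.05 * t)  # drift
    hi = 2.5 if pattern.kind == "normal" else np.inf
    v = np.clip(v, 0.0, hi)
    return FlowSignal(t=t, v=v, T_air=T_air)


# ---------------------------------------------------------------------------
# speech
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeechTemplate:
    """Airflow burst template for one spoken phrase.

    ``bursts`` is a time-ordered, non-overlapping tuple of
    (onset s, duration s, peak velocity m/s) — one burst per spoken word.
    """

    label: str
    bursts: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.bursts) == 0:
            raise ValueError("template needs at least one burst")
        end = -np.inf
        for onset, dur, peak in self.bursts:
            if onset < end:
                raise ValueError("bursts must be time-ordered and non-overlapping")
            if dur <= 0 or peak <= 0:
                raise ValueError("burst duration and peak must be positive")
            end = onset + dur

    @property
    def span(self) -> float:
        onset, dur, _ = self.bursts[-1]
        return onset + dur


#: Canonical five-class speech set used by the classifier.
SPEECH_TEMPLATES: dict[str, SpeechTemplate] = {
    "HELP": SpeechTemplate("HELP", ((0.20, 0.45, 3.2),)),
    "YES": SpeechTemplate("YES", ((0.20, 0.30, 1.4),)),
    "NO": SpeechTemplate("NO", ((0.30, 0.22, 1.0),)),
    "no pains no gains": SpeechTemplate(
        "no pains no gains",
        ((0.20, 0.18, 1.2), (0.50, 0.30, 1.8), (0.95, 0.18, 1.1), (1.30, 0.32, 1.9)),
    ),
    "How are you": SpeechTemplate(
        "How are you", ((0.20, 0.22, 0.9), (0.55, 0.20, 1.3), (0.90, 0.28, 1.6))
    ),
}

#: Additional phrases: distress shouts for fusion datasets plus extras.
EXTRA_TEMPLATES: dict[str, SpeechTemplate] = {
    "Ah": SpeechTemplate("Ah", ((0.20, 0.50, 3.5),)),
    "Oy": SpeechTemplate("Oy", ((0.20, 0.35, 3.0),)),
    "A": SpeechTemplate("A", ((0.20, 0.50, 0.8),)),
    "Good idea": SpeechTemplate("Good idea", ((0.20, 0.25, 1.2), (0.60, 0.45, 1.6))),
    "Help me": SpeechTemplate("Help me", ((0.20, 0.40, 2.1), (0.75, 0.25, 1.5))),
}

DISTRESS_LABELS = ("HELP", "Ah", "Oy")


def gen_speech_flow(
    template: SpeechTemplate,
    fs: float,
    seed: int,
    duration: float | None = None,
) -> FlowSignal:
    """Speech airflow: sinusoidal per-word bursts at exhale temperature over a
    quiet ambient baseline, with seeded Gaussian noise.

    If ``duration`` is given the trace is padded with baseline to that length
    (so a dataset of mixed phrases has a common sample count); otherwise the
    trace ends 0.3 s after the last burst.
    """
    if fs < 20:
        raise ValueError("sampling rate must be at least 20 Hz")
    total = template.span + 0.3 if duration is None else duration
    if total < template.span:
        raise ValueError("duration shorter than the template span")
    rng = np.random.default_rng(seed)
    n = int(round(total * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    T_air = np.full(n, AMBIENT_T)
    for onset, dur, peak in template.bursts:
        jitter = rng.normal(0.0, 0.02)  # small onset jitter per burst
        mask = (t >= onset + jitter) & (t < onset + jitter + dur)
        tb = (t[mask] - onset - jitter) / dur
        v[mask] += peak * np.sin(np.pi * tb)
        T_air[mask] = EXHALE_T
    v = np.clip(v + rng.normal(0.0, 0.03, size=n), 0.0, None)
    return FlowSignal(t=t, v=v, T_air=T_air)


# ---------------------------------------------------------------------------
# coughs
# ---------------------------------------------------------------------------

#: Peak airflow speed per cough intensity, m/s (ordered mild < moderate < severe).
COUGH_PEAKS = {"mild": 3.0, "moderate": 4.5, "severe": 6.0}
_COUGH_DUR = 0.25  # s per cough transient
_MIN_SPACING = 0.5  # s between cough onsets


def gen_cough_train(
    intensity: str, count: int, window: float, fs: float, seed: int
) -> FlowSignal:
    """`count` sharp high-velocity cough transients placed inside [0, window].

    Onsets are jittered around evenly spaced slots, keeping a minimum spacing
    so events never merge. count = 0 yields only the quiet noisy baseline.
    """
    if intensity not in COUGH_PEAKS:
        raise ValueError(f"unknown cough intensity {intensity!r}")
    if count < 0:
        raise ValueError("count must be non-negative")
    if not window > 0:
        raise ValueError("window must be positive")
    if count * _MIN_SPACING > window:
        raise ValueError(
            f"{count} coughs with {_MIN_SPACING} s spacing do not fit in {window} s"
        )
    rng = np.random.default_rng(seed)
    n = int(round(window * fs))
    t = np.arange(n) / fs
    v = np.clip(rng.normal(0.05, 0.02, size=n), 0.0, None)  # quiet baseline
    T_air = np.full(n, AMBIENT_T)
    peak = COUGH_PEAKS[intensity]
    if count > 0:
        slot = window / count
        jitter_amp = max(0.0, (slot - _MIN_SPACING) / 2 - _COUGH_DUR / 2)
        for k in range(count):
            onset = k * slot + slot / 2 + rng.uniform(-jitter_amp, jitter_amp)
            onset = min(onset, window - _COUGH_DUR)
            mask = (t >= onset) & (t < onset + _COUGH_DUR)
            te = (t[mask] - onset) / _COUGH_DUR
            amp = peak * (1.0 + rng.normal(0.0, 0.03))
            v[mask] += amp * np.sin(np.pi * te)
            T_air[mask] = EXHALE_T
    return FlowSignal(t=t, v=v, T_air=T_air)


# ---------------------------------------------------------------------------
# heartbeat (PPG-like)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeartbeatPattern:
    """PPG pulse-train parameters.

    kind: {"resting", "exercising", "abnormal"}; rate in bpm; pulse_shape =
    (systolic amplitude, dicrotic amplitude, systolic width s, dicrotic width
    s); jitter is the beat-interval coefficient of variation. The abnormal
    kind (pain-stimulus surrogate) carries elevated jitter plus a transient
    amplitude dip mid-record.
    """

    kind: str = "resting"
    rate: float = 60.0
    pulse_shape: tuple[float, float, float, float] = (1.0, 0.35, 0.05, 0.08)
    jitter: float = 0.03

    def __post_init__(self) -> None:
        if self.kind not in {"resting", "exercising", "abnormal"}:
            raise ValueError(f"unknown heartbeat kind {self.kind!r}")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if any(a <= 0 for a in self.pulse_shape):
            raise ValueError("pulse_shape entries must be positive")
        if self.kind == "abnormal" and self.jitter <= 0.05:
            raise ValueError("abnormal heartbeat requires elevated jitter (> 0.05)")


RESTING_HB = HeartbeatPattern("resting", rate=60.0, jitter=0.03)
EXERCISING_HB = HeartbeatPattern("exercising", rate=120.0, jitter=0.04)
ABNORMAL_HB = HeartbeatPattern("abnormal", rate=80.0, jitter=0.25)


@dataclass
class HeartbeatTrace:
    """PPG-like amplitude time series with the beat times that generated it."""

    t: NDArray[np.float64]
    y: NDArray[np.float64]
    beat_times: NDArray[np.float64] = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.t)


def gen_heartbeat(
    pattern: HeartbeatPattern, duration: float, fs: float, seed: int
) -> HeartbeatTrace:
    """Sum of per-beat two-Gaussian pulses (systolic peak + dicrotic wave) at
    jittered beat times, with additive noise and slow baseline drift.

    The abnormal kind scales beat amplitudes down to 40 % inside a ≈2 s
    disturbance window starting at 40 % of the record (the pain-stimulus
    surrogate) on top of its elevated interval jitter.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    mean_ibi = 60.0 / pattern.rate

    beats = []
    tb = rng.uniform(0.0, mean_ibi)
    while tb < duration:
        beats.append(tb)
        tb += max(0.2 * mean_ibi, rng.normal(mean_ibi, pattern.jitter * mean_ibi))
    beats = np.asarray(beats)

    amp_sys, amp_dic, w_sys, w_dic = pattern.pulse_shape
    y = np.zeros(n)
    dip_lo, dip_hi = 0.4 * duration, 0.4 * duration + 3.0
    for tb in beats:
        scale = 1.0 + rng.normal(0.0, 0.05)
        if pattern.kind == "abnormal" and dip_lo <= tb < dip_hi:
            scale *= 0.25
        y += scale * amp_sys * np.exp(-0.5 * ((t - tb) / w_sys) ** 2)
        y += scale * amp_dic * np.exp(-0.5 * ((t - tb - 0.25 * mean_ibi) / w_dic) ** 2)
    y += 0.03 * np.sin(2 * np.pi * 0.1 * t) + rng.normal(0.0, 0.01, size=n)
    return HeartbeatTrace(t=t, y=y, beat_times=beats)


# ---------------------------------------------------------------------------
# fusion dataset
# ---------------------------------------------------------------------------

TED_NORMAL = "normal"
TED_ABNORMAL = "A-TEDS"
HB_NORMAL = "normal"
HB_ABNORMAL = "A-HBS"


@dataclass
class LabeledRecording:
    """Paired TED-voltage and heartbeat traces with ground-truth states.

    ``fused_label`` is "abnormal" iff ted_state is A-TEDS *and* hb_state is
    A-HBS; every other combination is "normal".
    """

    ted_trace: VoltageTrace
    hb_trace: HeartbeatTrace
    ted_state: str
    hb_state: str
    fused_label: str
    source: str = ""
    seed: int = 0


_NORMAL_TED_SOURCES = ("breath:normal", "speech:YES", "speech:NO", "speech:How are you")
_ABNORMAL_TED_SOURCES = (
    "speech:HELP",
    "speech:Ah",
    "speech:Oy",
    "breath:feeble",
    "breath:weightless",
)


def _ted_flow(source: str, duration: float, fs: float, seed: int) -> FlowSignal:
    kind, _, name = source.partition(":")
    if kind == "speech":
        tpl = SPEECH_TEMPLATES.get(name) or EXTRA_TEMPLATES[name]
        return gen_speech_flow(tpl, fs, seed, duration=duration)
    pattern = {
        "normal": NORMAL_BREATH,
        "feeble": FEEBLE_BREATH,
        "weightless": WEIGHTLESS_BREATH,
    }[name]
    return gen_breath_flow(pattern, duration, fs, seed)


def gen_fusion_dataset(
    n_per_combo: int,
    fs: float = 100.0,
    seed: int = 0,
    *,
    duration: float = 6.0,
    plate: DevicePlate | None = None,
) -> list[LabeledRecording]:
    """Balanced labeled dataset over the four (TED-state, heartbeat-state)
    combinations, 4·n_per_combo recordings in total.

    Abnormal TED signals are drawn from distress speech ("HELP"/"Ah"/"Oy"),
    feeble respiration and weightless respiration; normal ones from calm
    speech and normal breathing. Airflow is run through the thermoelectric
    forward model so every TED trace obeys V = alpha·ΔT pointwise. Heartbeats
    pair resting/exercising (normal) against the pain-stimulus abnormal kind.
    """
    from airtherm.features_detect import fusion_label

    if n_per_combo < 1:
        raise ValueError("n_per_combo must be at least 1")
    plate = plate or DevicePlate()
    combos = [
        (TED_NORMAL, HB_NORMAL),
        (TED_NORMAL, HB_ABNORMAL),
        (TED_ABNORMAL, HB_NORMAL),
        (TED_ABNORMAL, HB_ABNORMAL),
    ]
    child_seeds = np.random.SeedSequence(seed).generate_state(
        4 * n_per_combo * 3, dtype=np.uint32
    ) % (2**31)
    recs: list[LabeledRecording] = []
    i = 0
    for ted_state, hb_state in combos:
        for _ in range(n_per_combo):
            s_pick, s_flow, s_hb = (int(child_seeds[i]), int(child_seeds[i + 1]),
                                    int(child_seeds[i + 2]))
            i += 3
            pick = np.random.default_rng(s_pick)
            sources = (
                _ABNORMAL_TED_SOURCES if ted_state == TED_ABNORMAL
                else _NORMAL_TED_SOURCES
            )
            source = sources[pick.integers(len(sources))]
            flow = _ted_flow(source, duration, fs, s_flow)
            ted = simulate_response(plate, AIR, flow, T_upper0=plate.T_lower)
            hb_pattern = (
                ABNORMAL_HB if hb_state == HB_ABNORMAL
                else (RESTING_HB, EXERCISING_HB)[pick.integers(2)]
            )
            hb = gen_heartbeat(hb_pattern, duration, fs, s_hb)
            recs.append(
                LabeledRecording(
                    ted_trace=ted,
                    hb_trace=hb,
                    ted_state=ted_state,
                    hb_state=hb_state,
                    fused_label=fusion_label(ted_state, hb_state),
                    source=source,
                    seed=s_flow,
                )
            )
    return recs
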