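"""Seeded synthetic sEMG drinking-study generator.

Emulates the statistical structure of a two-day fluid-intake study:
``n_subjects`` subjects drink five cued volumes (12 sips each) and perform
four non-drinking tasks (talking, coughing, saliva and solid swallows)
while two neck-surface EMG channels (left/right) record at ``fs`` Hz.

Each event is an amplitude-modulated burst of band-limited Gaussian noise
under a smooth unimodal (Hann) envelope, superimposed on Gaussian baseline
noise.  Class identity controls burst duration, amplitude and carrier band;
for drinking events the sip volume additionally scales amplitude and
duration (the effect the regression stage is meant to recover).  Multiplica-
tive subject gains, between-day drift and a fixed left/right asymmetry
emulate the nuisance structure that makes cross-day transfer harder than
within-day cross-validation.

All randomness descends from one root seed through ``numpy`` seed
sequences keyed by (subject, day, side, role), so identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy import signal


class ParameterError(ValueError):
    """Invalid study design or generator parameters."""


@dataclass(frozen=True)
class StudyDesign:
    """Experimental layout of a synthetic study.

    Defaults reproduce the study design the pipeline targets: 11 subjects,
    2 days, 2 channels, 2200 Hz sampling, five cued volumes of 12 sips each
    (60 drinking events) plus 10 events for each of four non-drinking
    classes (40 events) per subject-day.
    """

    n_subjects: int = 11
    n_days: int = 2
    sides: tuple[str, ...] = ("right", "left")
    fs: float = 2200.0
    volumes: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)
    sips_per_volume: int = 12
    nondrink_classes: tuple[str, ...] = ("talk", "cough", "saliva", "solid")
    events_per_nondrink_class: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1 or not self.sides:
            raise ParameterError("need at least one subject, day and side")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.sips_per_volume < 0 or self.events_per_nondrink_class < 0:
            raise ParameterError("event counts must be nonnegative")
        if any(v <= 0 for v in self.volumes):
            raise ParameterError("volumes must be positive (mL)")

    @property
    def n_drink_events(self) -> int:
        return len(self.volumes) * self.sips_per_volume

    @property
    def n_nondrink_events(self) -> int:
        return len(self.nondrink_classes) * self.events_per_nondrink_class

    @property
    def n_events(self) -> int:
        return self.n_drink_events + self.n_nondrink_events


@dataclass(frozen=True)
class ClassSignature:
    """Burst morphology of one event class."""

    duration_mean_s: float
    duration_sd_s: float
    amplitude: float
    band: tuple[float, float]
    n_subbursts: int = 1  # >1 gives an intermittent train (talking)

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0.0 < lo < hi < fs / 2.0):
            raise ParameterError(
                f"carrier band {self.band} must satisfy 0 < low < high < fs/2"
            )
        if self.duration_mean_s <= 0 or self.duration_sd_s < 0:
            raise ParameterError("burst duration mean must be > 0 and sd >= 0")
        if self.amplitude <= 0:
            raise ParameterError("burst amplitude must be positive")


def _default_signatures() -> dict[str, ClassSignature]:
    # Chosen once to make the five classes separable but overlapping:
    # saliva/solid sit close to drinking in duration, amplitude and band;
    # coughing is short, loud and wide-band; talking is a long low-amplitude
    # train of sub-bursts.
    return {
        "drink": ClassSignature(1.00, 0.15, 1.00, (30.0, 300.0)),
        "saliva": ClassSignature(0.95, 0.18, 1.05, (30.0, 300.0)),
        "solid": ClassSignature(1.20, 0.22, 1.25, (25.0, 250.0)),
        "cough": ClassSignature(0.35, 0.08, 2.20, (60.0, 450.0)),
        "talk": ClassSignature(1.80, 0.30, 0.55, (40.0, 350.0), n_subbursts=6),
    }


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable statistical structure of the generator.

    ``volume_amplitude_slope`` / ``volume_duration_slope`` are the effect
    sizes the regression stage recovers: relative amplitude gain per mL and
    seconds per mL.  Setting both to 0 gives volume-uninformative drinking
    bursts (null-effect mode).  ``sip_jitter_sd`` is the per-event lognormal
    amplitude jitter that keeps single-sip volume estimation imperfect.
    """

    class_signatures: dict[str, ClassSignature] = field(
        default_factory=_default_signatures
    )
    volume_amplitude_slope: float = 0.04
    volume_duration_slope: float = 0.010
    sip_jitter_sd: float = 0.10
    baseline_noise_sd: float = 0.06
    subject_gain_sd: float = 0.15
    day_drift_sd: float = 0.12
    side_asymmetry: float = 1.15
    inter_event_gap_s: float = 2.0

    def validate(self, design: StudyDesign) -> None:
        for name, sig in self.class_signatures.items():
            sig.validate(design.fs)
        for cls in ("drink", *design.nondrink_classes):
            if cls not in self.class_signatures:
                raise ParameterError(f"no class signature for {cls!r}")
        if min(self.sip_jitter_sd, self.baseline_noise_sd,
               self.subject_gain_sd, self.day_drift_sd) < 0:
            raise ParameterError("variability parameters must be >= 0")
        if self.side_asymmetry <= 0:
            raise ParameterError("side_asymmetry must be positive")
        if self.inter_event_gap_s <= 0:
            raise ParameterError("inter_event_gap_s must be positive")


@dataclass
class EventAnnotation:
    """One labeled event: nominal center time, class, volume (drink only)."""

    event_index: int
    time_s: float
    label: str
    volume_ml: Optional[float] = None


@dataclass
class Recording:
    """One subject-day-side raw sEMG trace."""

    samples: np.ndarray
    fs: float
    subject: int
    day: int
    side: str

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Session:
    """One subject-day: one recording per side, one shared annotation list."""

    subject: int
    day: int
    recordings: dict[str, Recording]
    annotations: list[EventAnnotation]


@dataclass
class StudyData:
    design: StudyDesign
    params: GeneratorParams
    sessions: list[Session]

    def iter_recordings(self) -> Iterator[tuple[Recording, list[EventAnnotation]]]:
        for sess in self.sessions:
            for side in self.design.sides:
                yield sess.recordings[side], sess.annotations


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``."""
    white = rng.standard_normal(n + 400)  # margin absorbs filter transients
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)[200:200 + n]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _synth_burst(rng: np.random.Generator, sig: ClassSignature, duration_s: float,
                 amplitude: float, fs: float) -> np.ndarray:
    """One burst: Hann-enveloped band-limited noise; peak at the center.

    For multi-sub-burst classes the envelope is a train of short Hann lobes
    with randomized relative heights (the center lobe kept highest so the
    annotated center stays the envelope peak).
    """
    n = max(int(round(duration_s * fs)), 8)
    if sig.n_subbursts <= 1:
        env = np.hanning(n)
    else:
        env = np.zeros(n)
        k = sig.n_subbursts
        seg = n // k
        heights = 0.4 + 0.6 * rng.random(k)
        heights[k // 2] = 1.0  # keep the peak at the nominal center
        for i in range(k):
            m = max(int(seg * (0.5 + 0.5 * rng.random())), 4)
            start = min(i * seg + rng.integers(0, max(seg - m, 1)), n - m)
            env[start:start + m] += heights[i] * np.hanning(m)
        env /= env.max()
    carrier = _band_noise(rng, n, sig.band, fs)
    return amplitude * env * carrier


def _layout_events(design: StudyDesign, params: GeneratorParams,
                   rng: np.random.Generator) -> tuple[list[EventAnnotation],
                                                      list[float], list[float]]:
    """Shuffled event schedule for one subject-day.

    Returns annotations plus per-event sampled durations and base amplitudes
    (shared across the two channels of the session).
    """
    labels: list[tuple[str, Optional[float]]] = []
    for v in design.volumes:
        labels += [("drink", v)] * design.sips_per_volume
    for cls in design.nondrink_classes:
        labels += [(cls, None)] * design.events_per_nondrink_class
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    annotations, durations, amplitudes = [], [], []
    cursor = params.inter_event_gap_s
    for idx, (label, volume) in enumerate(labels):
        sig = params.class_signatures[label]
        dur = sig.duration_mean_s + sig.duration_sd_s * rng.standard_normal()
        amp = sig.amplitude
        if volume is not None:
            dur += params.volume_duration_slope * volume
            amp *= 1.0 + params.volume_amplitude_slope * volume
        dur = max(dur, 0.1)
        amp *= np.exp(params.sip_jitter_sd * rng.standard_normal())
        center = cursor + dur / 2.0
        annotations.append(EventAnnotation(idx, center, label, volume))
        durations.append(dur)
        amplitudes.append(amp)
        cursor += dur + params.inter_event_gap_s
    return annotations, durations, amplitudes


def generate_session(design: StudyDesign, params: GeneratorParams,
                     subject: int, day: int) -> Session:
    """Generate one subject-day: identical schedule on both channels."""
    sched_rng = _rng(design.seed, subject, day, 0)
    annotations, durations, amplitudes = _layout_events(design, params, sched_rng)

    total_s = (annotations[-1].time_s + durations[-1] / 2.0
               + params.inter_event_gap_s) if annotations else 2.0
    n_total = int(round(total_s * design.fs))

    subj_gain = np.exp(params.subject_gain_sd
                       * _rng(design.seed, subject, 0, 1).standard_normal())
    day_gain = np.exp(params.day_drift_sd
                      * _rng(design.seed, subject, day, 2).standard_normal())

    recordings: dict[str, Recording] = {}
    for s_idx, side in enumerate(design.sides):
        side_gain = params.side_asymmetry ** (0.5 if s_idx == 0 else -0.5)
        rng = _rng(design.seed, subject, day, 10 + s_idx)
        x = params.baseline_noise_sd * rng.standard_normal(n_total)
        gain = subj_gain * day_gain * side_gain
        for ann, dur, amp in zip(annotations, durations, amplitudes):
            burst = _synth_burst(rng, params.class_signatures[ann.label],
                                 dur, gain * amp, design.fs)
            start = int(round(ann.time_s * design.fs)) - len(burst) // 2
            lo, hi = max(start, 0), min(start + len(burst), n_total)
            x[lo:hi] += burst[lo - start:hi - start]
        recordings[side] = Recording(x, design.fs, subject, day, side)
    return Session(subject, day, recordings, annotations)


def generate_study(design: StudyDesign | None = None,
                   params: GeneratorParams | None = None) -> StudyData:
    """Generate the full study: one session per (subject, day)."""
    design = design or StudyDesign()
    params = params or GeneratorParams()
    params.validate(design)
    sessions = [
        generate_session(design, params, subject, day)
        for subject in range(1, design.n_subjects + 1)
        for day in range(1, design.n_days + 1)
    ]
    return StudyData(design, params, sessions)


def null_effect_params(**overrides) -> GeneratorParams:
    """Generator parameters with volume-uninformative drinking bursts."""
    return GeneratorParams(volume_amplitude_slope=0.0,
                           volume_duration_slope=0.0, **overrides)


def design_as_dict(design: StudyDesign) -> dict:
    return dataclasses.asdict(design)
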