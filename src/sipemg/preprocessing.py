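"""Filtering, rectified-envelope computation and burst-window extraction.

The pipeline mirrors standard sEMG practice: a zero-phase Butterworth
band-pass (10-400 Hz by default), full-wave rectification followed by a
zero-phase low-pass to obtain the amplitude envelope, and a fixed-duration
window (2 s by default) cut from the *band-passed* signal, centered on the
envelope peak nearest each annotated event.  Zero-phase (forward-backward)
filtering is used throughout so envelope peaks are not delayed relative to
the underlying burst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .synthetic import EventAnnotation, ParameterError, Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering and segmentation settings.

    ``window_s`` is the burst-window duration (1 s before and after the
    envelope peak at the 2 s default); ``search_halfwidth_s`` bounds the
    envelope-peak search around each annotated event time.
    """

    bp_low: float = 10.0
    bp_high: float = 400.0
    filter_order: int = 4
    # envelope cutoff ~ reciprocal of the longest burst duration: smoothing
    # must suppress rectified-noise ripple for the peak to be localizable
    # at the tens-of-milliseconds scale
    envelope_cutoff: float = 1.5
    window_s: float = 2.0
    search_halfwidth_s: float = 1.5

    def validate(self, fs: float) -> None:
        if not (0.0 < self.bp_low < self.bp_high):
            raise ParameterError("need 0 < bp_low < bp_high")
        if self.bp_high >= fs / 2.0:
            raise ParameterError(
                f"bp_high={self.bp_high} must be below the Nyquist "
                f"frequency {fs / 2.0}")
        if self.filter_order < 1:
            raise ParameterError("filter_order must be >= 1")
        if not (0.0 < self.envelope_cutoff < fs / 2.0):
            raise ParameterError("envelope_cutoff must lie in (0, fs/2)")
        if self.window_s <= 0 or self.search_halfwidth_s <= 0:
            raise ParameterError("window_s and search_halfwidth_s must be > 0")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_s * fs))


@dataclass
class BurstWindow:
    """Fixed-length band-passed segment centered on a detected burst peak."""

    samples: np.ndarray
    fs: float
    peak_index: int
    label: str
    volume_ml: Optional[float]
    subject: int
    day: int
    side: str
    event_index: int = 0
    peak_time_s: float = 0.0
    padded: bool = False


def bandpass(recording: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    cfg.validate(recording.fs)
    sos = signal.butter(cfg.filter_order, (cfg.bp_low, cfg.bp_high),
                        btype="bandpass", fs=recording.fs, output="sos")
    y = signal.sosfiltfilt(sos, recording.samples)
    return Recording(y, recording.fs, recording.subject, recording.day,
                     recording.side)


def envelope(recording: Recording, cfg: PreprocessConfig) -> Recording:
    """Rectify and zero-phase low-pass; tiny negative ringing clipped to 0."""
    cfg.validate(recording.fs)
    sos = signal.butter(cfg.filter_order, cfg.envelope_cutoff,
                        btype="lowpass", fs=recording.fs, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(recording.samples))
    return Recording(np.clip(env, 0.0, None), recording.fs, recording.subject,
                     recording.day, recording.side)


def extract_bursts(recording: Recording,
                   annotations: Sequence[EventAnnotation],
                   cfg: PreprocessConfig,
                   filtered: Optional[Recording] = None,
                   env: Optional[Recording] = None) -> list[BurstWindow]:
    """Cut one fixed-length window per annotation, centered on the envelope
    peak found within ``search_halfwidth_s`` of the annotated time.

    Windows are cut from the band-passed (not rectified) signal.  Windows
    reaching past either end of the recording are zero-padded and flagged;
    annotations wholly outside the recording are skipped with a log entry.
    Pass precomputed ``filtered``/``env`` recordings to avoid re-filtering.
    """
    cfg.validate(recording.fs)
    fs = recording.fs
    filtered = filtered if filtered is not None else bandpass(recording, cfg)
    env = env if env is not None else envelope(filtered, cfg)
    n = len(filtered.samples)
    nwin = cfg.window_samples(fs)
    half = nwin // 2
    out: list[BurstWindow] = []
    for ann in annotations:
        center = int(round(ann.time_s * fs))
        if center < 0 or center >= n:
            logger.warning(
                "event %d at %.3f s outside recording (%.3f s): skipped",
                ann.event_index, ann.time_s, n / fs)
            continue
        lo = max(center - int(round(cfg.search_halfwidth_s * fs)), 0)
        hi = min(center + int(round(cfg.search_halfwidth_s * fs)) + 1, n)
        peak = lo + int(np.argmax(env.samples[lo:hi]))
        start = peak - half
        stop = start + nwin
        seg = np.zeros(nwin, dtype=filtered.samples.dtype)
        src_lo, src_hi = max(start, 0), min(stop, n)
        seg[src_lo - start:src_hi - start] = filtered.samples[src_lo:src_hi]
        out.append(BurstWindow(
            samples=seg, fs=fs, peak_index=peak - start, label=ann.label,
            volume_ml=ann.volume_ml, subject=recording.subject,
            day=recording.day, side=recording.side,
            event_index=ann.event_index, peak_time_s=peak / fs,
            padded=(start < 0 or stop > n)))
    return out
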