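"""The 26-feature sEMG catalog: time-domain, model-based and spectral
scalars computed from one fixed-length burst window per event.

Canonical definitions (``x`` the window, ``N`` its length, ``P_j`` the
Welch PSD at frequency ``f_j``):

========  =============================================================
MAV       mean absolute value, ``mean(|x|)``
WL        waveform length, ``sum(|x[i+1]-x[i]|)``
AAC       average amplitude change, ``WL / (N-1)``
DASDV     ``sqrt(mean((x[i+1]-x[i])**2))``
VAR       unbiased sample variance
LOG       log detector, ``exp(mean(log |x|))`` (|x| floored at tiny)
ZC        sign changes with ``|x[i]-x[i+1]| >= theta_zc``
WAMP      Willison amplitude: count of ``|x[i]-x[i+1]| >= theta_wamp``
MYOP      myopulse percentage rate: fraction of ``|x[i]| >= theta_myop``
Skew      standardized third sample moment
Kurt      standardized fourth sample moment (Pearson, normal -> 3)
Entropy   Shannon entropy of the 64-bin amplitude histogram
ECDF      mean empirical CDF over 10 equally spaced amplitudes
CC        temporal centroid ``sum(t_i x_i^2)/sum(x_i^2)`` (seconds)
AC        first coefficient of an order-4 Yule-Walker AR model
          (Levinson-Durbin on the biased autocorrelation)
LPCC      mean of linear-prediction cepstral coefficients c1..c4
MFCC      mean of the first 12 mel-cepstral coefficients over frames
MNF       mean (power-weighted) frequency of the PSD
MDF       median frequency: smallest f with cumulative PSD >= half total
PKF       peak frequency of the PSD
MNP       mean PSD power
FR        PSD power ratio, 10-250 Hz over 250-500 Hz
SC        spectral centroid of the full-window magnitude spectrum
SE        normalized spectral (Shannon) entropy of the PSD, in [0, 1]
SF        power-weighted mean over short-time frames of each frame's
          peak frequency
PW        spectral spread ``sqrt(sum((f_j-SC)^2 P_j)/sum(P_j))``
========  =============================================================

Amplitude thresholds (ZC/WAMP/MYOP) are expressed as multiples of the
window RMS so they track overall signal scale.  All spectral windows are
symmetric Hann tapers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.fft
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocessing import BurstWindow

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "AC", "AAC", "CC", "DASDV", "Entropy", "ECDF", "FR", "LPCC", "LOG",
    "Kurt", "MNP", "MNF", "MDF", "MAV", "MYOP", "MFCC", "PKF", "PW",
    "Skew", "SC", "SE", "SF", "VAR", "WL", "WAMP", "ZC",
)

#: features that require a non-degenerate (non-constant) window
SPECTRAL_NAMES = frozenset(
    {"AC", "LPCC", "MFCC", "MNF", "MDF", "PKF", "MNP", "FR", "SC", "SE",
     "SF", "PW", "CC"})

META_COLUMNS = ("label", "volume_ml", "subject", "day", "side", "event_index")


class DegenerateWindowError(ValueError):
    """Constant (or all-zero) window: spectral features are undefined."""


class InputError(ValueError):
    """NaN/Inf samples or malformed input."""


@dataclass(frozen=True)
class SpectralConfig:
    """All numeric settings of the feature catalog.

    PSD: Welch with 256-sample symmetric-Hann segments, 50% overlap,
    zero-padded FFT (``psd_nfft``) for a sub-2 Hz frequency grid.
    Thresholds are multiples of window RMS.
    """

    psd_nperseg: int = 256
    psd_overlap: float = 0.5
    psd_nfft: int = 2048
    fr_low_band: tuple[float, float] = (10.0, 250.0)
    fr_high_band: tuple[float, float] = (250.0, 500.0)
    ar_order: int = 4
    lpcc_order: int = 4
    mfcc_n_filters: int = 20
    mfcc_n_coeffs: int = 12
    mfcc_frame: int = 256
    mfcc_overlap: float = 0.5
    sf_frame: int = 256
    sf_overlap: float = 0.5
    sf_nfft: int = 512
    zc_threshold: float = 0.05
    wamp_threshold: float = 0.5
    myop_threshold: float = 0.5
    entropy_bins: int = 64
    ecdf_points: int = 10

    def validate(self, fs: float) -> None:
        if self.ar_order < 1 or self.lpcc_order < 1:
            raise ValueError("model orders must be >= 1")
        for lo, hi in (self.fr_low_band, self.fr_high_band):
            if not (0 <= lo < hi):
                raise ValueError("bands must satisfy 0 <= low < high")
        if self.fr_low_band[1] > self.fr_high_band[0]:
            raise ValueError("FR bands must be disjoint")
        if self.fr_high_band[0] >= fs / 2 and fs > 0:
            raise ValueError("FR high band lies entirely above Nyquist")


def _validate_names(names: Sequence[str]) -> list[str]:
    unknown = [n for n in names if n not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature names: {unknown}")
    return list(names)


def _frame(X: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """(n, N) -> (n, n_frames, frame), trailing remainder discarded."""
    n, N = X.shape
    if N < frame:
        return X[:, None, :]
    n_frames = 1 + (N - frame) // hop
    idx = (np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None])
    return X[:, idx]


def _levinson(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Levinson-Durbin, batched.  ``r``: (n, p+1) biased autocorrelations.

    Returns the error-filter polynomial coefficients ``a`` (n, p+1) with
    ``a[:, 0] = 1`` (so the AR predictor coefficients are ``-a[:, 1:]``)
    and the final prediction-error powers.
    """
    n, p1 = r.shape
    p = p1 - 1
    a = np.zeros((n, p1))
    a[:, 0] = 1.0
    e = r[:, 0].copy()
    if np.any(e <= 0):
        raise DegenerateWindowError("zero-power window: AR model undefined")
    for m in range(1, p + 1):
        acc = r[:, m].copy()
        if m > 1:
            acc += np.einsum("ij,ij->i", a[:, 1:m], r[:, m - 1:0:-1])
        k = -acc / e
        prev = a[:, 1:m].copy()
        a[:, 1:m] = prev + k[:, None] * prev[:, ::-1]
        a[:, m] = k
        e = e * (1.0 - k**2)
        if np.any(e <= 0):
            raise DegenerateWindowError("singular autocorrelation in AR fit")
    return a, e


def _mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_inv(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(fs: float, nfft: int, n_filters: int) -> np.ndarray:
    """Triangular mel filterbank spanning 0..fs/2 on the rfft grid."""
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(fs / 2.0), n_filters + 2))
    fb = np.zeros((n_filters, len(freqs)))
    for i in range(n_filters):
        lo, center, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / (center - lo)
        down = (hi - freqs) / (hi - center)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _welch_psd(X: np.ndarray, fs: float,
               cfg: SpectralConfig) -> tuple[np.ndarray, np.ndarray]:
    nper = min(cfg.psd_nperseg, X.shape[1])
    nover = int(round(nper * cfg.psd_overlap))
    f, P = signal.welch(X, fs=fs, window=np.hanning(nper), nperseg=nper,
                        noverlap=nover, nfft=max(cfg.psd_nfft, nper),
                        detrend=False, axis=-1)
    return f, P


def compute_features(X: np.ndarray, fs: float,
                     names: Sequence[str] | None = None,
                     cfg: SpectralConfig | None = None) -> pd.DataFrame:
    """Compute features for a stack of equal-length windows.

    Parameters
    ----------
    X : (n_windows, n_samples) array of band-passed signal windows.
    fs : sampling rate in Hz.
    names : feature subset (default: all 26, catalog order).
    cfg : numeric settings; defaults to :class:`SpectralConfig`.

    Raises
    ------
    InputError
        on NaN/Inf samples.
    DegenerateWindowError
        if a spectral feature is requested on a constant window.
    """
    cfg = cfg or SpectralConfig()
    cfg.validate(fs)
    names = _validate_names(names if names is not None else FEATURE_NAMES)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise InputError("windows must contain at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite samples in input windows")

    n, N = X.shape
    if SPECTRAL_NAMES.intersection(names):
        if np.any(np.ptp(X, axis=1) == 0):
            raise DegenerateWindowError(
                "constant window: spectral features undefined")

    out: dict[str, np.ndarray] = {}
    absx = np.abs(X)
    dx = np.diff(X, axis=1)
    absdx = np.abs(dx)
    rms = np.sqrt(np.mean(X**2, axis=1))

    wl = absdx.sum(axis=1)
    if "MAV" in names:
        out["MAV"] = absx.mean(axis=1)
    if "WL" in names:
        out["WL"] = wl
    if "AAC" in names:
        out["AAC"] = wl / (N - 1)
    if "DASDV" in names:
        out["DASDV"] = np.sqrt(np.mean(dx**2, axis=1))
    if "VAR" in names:
        out["VAR"] = X.var(axis=1, ddof=1)
    if "LOG" in names:
        out["LOG"] = np.exp(np.mean(
            np.log(np.maximum(absx, np.finfo(float).tiny)), axis=1))
    if "ZC" in names:
        theta = cfg.zc_threshold * rms
        out["ZC"] = np.sum((X[:, :-1] * X[:, 1:] < 0)
                           & (absdx >= theta[:, None]), axis=1).astype(float)
    if "WAMP" in names:
        theta = cfg.wamp_threshold * rms
        out["WAMP"] = np.sum(absdx >= theta[:, None], axis=1).astype(float)
    if "MYOP" in names:
        theta = cfg.myop_threshold * rms
        out["MYOP"] = np.mean(absx >= theta[:, None], axis=1)
    if "Skew" in names or "Kurt" in names:
        xc = X - X.mean(axis=1, keepdims=True)
        m2 = np.mean(xc**2, axis=1)
        safe = np.where(m2 > 0, m2, 1.0)
        if "Skew" in names:
            out["Skew"] = np.where(m2 > 0,
                                   np.mean(xc**3, axis=1) / safe**1.5, 0.0)
        if "Kurt" in names:
            out["Kurt"] = np.where(m2 > 0,
                                   np.mean(xc**4, axis=1) / safe**2, 0.0)
    if "Entropy" in names:
        ent = np.empty(n)
        for i in range(n):
            lo, hi = X[i].min(), X[i].max()
            if hi == lo:
                ent[i] = 0.0
                continue
            counts, _ = np.histogram(X[i], bins=cfg.entropy_bins,
                                     range=(lo, hi))
            p = counts[counts > 0] / N
            ent[i] = -np.sum(p * np.log(p))
        out["Entropy"] = ent
    if "ECDF" in names:
        vals = np.empty(n)
        for i in range(n):
            lo, hi = X[i].min(), X[i].max()
            t = np.linspace(lo, hi, cfg.ecdf_points)
            xs = np.sort(X[i])
            vals[i] = np.mean(np.searchsorted(xs, t, side="right") / N)
        out["ECDF"] = vals
    if "CC" in names:
        t = np.arange(N) / fs
        power = X**2
        out["CC"] = power @ t / power.sum(axis=1)

    if "AC" in names or "LPCC" in names:
        p = max(cfg.ar_order, cfg.lpcc_order)
        r = np.empty((n, p + 1))
        for k in range(p + 1):
            r[:, k] = np.einsum("ij,ij->i", X[:, :N - k], X[:, k:]) / N
        if "AC" in names:
            a_ar, _ = _levinson(r[:, :cfg.ar_order + 1])
            out["AC"] = -a_ar[:, 1]
        if "LPCC" in names:
            a_lp, _ = _levinson(r[:, :cfg.lpcc_order + 1])
            q = cfg.lpcc_order
            c = np.zeros((n, q + 1))
            for m in range(1, q + 1):
                acc = np.zeros(n)
                for k in range(1, m):
                    acc += (k / m) * c[:, k] * a_lp[:, m - k]
                c[:, m] = -a_lp[:, m] - acc
            out["LPCC"] = c[:, 1:].mean(axis=1)

    if "MFCC" in names:
        hop = max(int(round(cfg.mfcc_frame * (1 - cfg.mfcc_overlap))), 1)
        frames = _frame(X, cfg.mfcc_frame, hop)
        flen = frames.shape[-1]
        spec = np.abs(np.fft.rfft(frames * np.hanning(flen), axis=-1))**2
        fb = mel_filterbank(fs, flen, cfg.mfcc_n_filters)
        energies = np.maximum(spec @ fb.T, np.finfo(float).tiny)
        cep = scipy.fft.dct(np.log(energies), type=2, norm="ortho", axis=-1)
        ncof = min(cfg.mfcc_n_coeffs, cfg.mfcc_n_filters - 1)
        out["MFCC"] = cep[..., 1:1 + ncof].mean(axis=(1, 2))

    psd_names = {"MNF", "MDF", "PKF", "MNP", "FR", "SE", "PW"}
    if psd_names.intersection(names) or "SC" in names:
        if "SC" in names or "PW" in names:
            mag = np.abs(np.fft.rfft(X, axis=-1))
            fmag = np.fft.rfftfreq(N, d=1.0 / fs)
            sc = mag @ fmag / mag.sum(axis=1)
            if "SC" in names:
                out["SC"] = sc
        if psd_names.intersection(names):
            f, P = _welch_psd(X, fs, cfg)
            total = P.sum(axis=1)
            if np.any(total <= 0):
                raise DegenerateWindowError("zero-power PSD")
            if "MNF" in names:
                out["MNF"] = P @ f / total
            if "MDF" in names:
                cum = np.cumsum(P, axis=1)
                idx = np.argmax(cum >= total[:, None] / 2.0, axis=1)
                out["MDF"] = f[idx]
            if "PKF" in names:
                out["PKF"] = f[np.argmax(P, axis=1)]
            if "MNP" in names:
                out["MNP"] = P.mean(axis=1)
            if "FR" in names:
                lo_b, hi_b = cfg.fr_low_band, cfg.fr_high_band
                low = P[:, (f >= lo_b[0]) & (f < lo_b[1])].sum(axis=1)
                high = P[:, (f >= hi_b[0]) & (f <= hi_b[1])].sum(axis=1)
                if np.any(high <= 0):
                    raise DegenerateWindowError("no power in FR high band")
                out["FR"] = low / high
            if "SE" in names:
                prob = P / total[:, None]
                plogp = np.where(prob > 0, prob * np.log(prob,
                                 where=prob > 0, out=np.zeros_like(prob)), 0.0)
                out["SE"] = -plogp.sum(axis=1) / np.log(P.shape[1])
            if "PW" in names:
                dev = (f[None, :] - sc[:, None])**2
                out["PW"] = np.sqrt(np.einsum("ij,ij->i", dev, P) / total)

    if "SF" in names:
        hop = max(int(round(cfg.sf_frame * (1 - cfg.sf_overlap))), 1)
        frames = _frame(X, cfg.sf_frame, hop)
        flen = frames.shape[-1]
        nfft = max(cfg.sf_nfft, flen)
        spec = np.abs(np.fft.rfft(frames * np.hanning(flen), n=nfft,
                                  axis=-1))**2
        fgrid = np.fft.rfftfreq(nfft, d=1.0 / fs)
        weights = spec.sum(axis=-1)
        peaks = fgrid[np.argmax(spec, axis=-1)]
        out["SF"] = (weights * peaks).sum(axis=1) / weights.sum(axis=1)

    return pd.DataFrame({name: out[name] for name in names})


def extract(window: BurstWindow | np.ndarray, fs: float | None = None,
            names: Sequence[str] | None = None,
            cfg: SpectralConfig | None = None) -> dict[str, float]:
    """Feature row for a single window (thin wrapper over the batch path)."""
    if isinstance(window, BurstWindow):
        x, fs = window.samples, window.fs
    else:
        if fs is None:
            raise InputError("fs is required for bare arrays")
        x = np.asarray(window, dtype=float)
    row = compute_features(x[None, :], fs, names=names, cfg=cfg)
    return {k: float(v) for k, v in row.iloc[0].items()}


def extract_all(windows: Sequence[BurstWindow],
                names: Sequence[str] | None = None,
                cfg: SpectralConfig | None = None) -> pd.DataFrame:
    """Feature matrix for a list of burst windows.

    One row per window in input order, feature columns followed by metadata
    columns (label, volume_ml, subject, day, side, event_index).  Windows
    on which extraction fails (e.g. constant signal) are excluded with a
    log entry; an empty input yields an empty frame with the full schema.
    """
    names = _validate_names(names if names is not None else FEATURE_NAMES)
    rows, meta = [], []
    for w in windows:
        try:
            row = compute_features(w.samples[None, :], w.fs, names=names,
                                   cfg=cfg)
        except (DegenerateWindowError, InputError) as exc:
            logger.warning("event %d (subject %s day %s side %s): %s — "
                           "excluded", w.event_index, w.subject, w.day,
                           w.side, exc)
            continue
        rows.append(row)
        meta.append({"label": w.label, "volume_ml": w.volume_ml,
                     "subject": w.subject, "day": w.day, "side": w.side,
                     "event_index": w.event_index})
    if not rows:
        return pd.DataFrame(columns=list(names) + list(META_COLUMNS))
    feats = pd.concat(rows, ignore_index=True)
    return pd.concat([feats, pd.DataFrame(meta)], axis=1)


class EMGFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn transformer view of the feature catalog.

    ``transform`` maps an (n_windows, n_samples) array of equal-length
    band-passed windows to an (n_windows, n_features) matrix; column order
    follows ``features`` (default: the full 26-name catalog).
    """

    def __init__(self, fs: float = 2200.0,
                 features: Sequence[str] | None = None,
                 config: SpectralConfig | None = None):
        self.fs = fs
        self.features = features
        self.config = config

    def fit(self, X, y=None):
        names = _validate_names(self.features if self.features is not None
                                else FEATURE_NAMES)
        (self.config or SpectralConfig()).validate(self.fs)
        self.feature_names_out_ = np.asarray(names, dtype=object)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit(X)
        frame = compute_features(X, self.fs, names=list(self.feature_names_out_),
                                 cfg=self.config)
        return frame.to_numpy()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return self.feature_names_out_
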