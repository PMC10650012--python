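"""Independent direct-from-definition feature oracle.

Every feature is recomputed here straight from its published definition,
deliberately avoiding the package's code paths (loops and explicit
formulas instead of the batched implementations; Yule-Walker via a
Toeplitz solve instead of Levinson-Durbin; LPC cepstrum from polynomial
roots instead of the recursion; DCT by explicit cosine sums).  Used to
freeze expected values in tests.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import toeplitz

from sipemg.features import SpectralConfig


def _hann(m: int) -> np.ndarray:
    if m == 1:
        return np.ones(1)
    n = np.arange(m)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (m - 1)))


def _welch(x: np.ndarray, fs: float, nper: int, overlap: float, nfft: int):
    """Welch PSD, one-sided density scaling, mean over segments."""
    nper = min(nper, len(x))
    nfft = max(nfft, nper)
    step = nper - int(round(nper * overlap))
    w = _hann(nper)
    scale = 1.0 / (fs * np.sum(w * w))
    n_seg = (len(x) - nper) // step + 1
    acc = None
    for s in range(n_seg):
        seg = x[s * step:s * step + nper] * w
        spec = np.abs(np.fft.rfft(seg, n=nfft))**2 * scale
        spec[1:] *= 2.0
        if nfft % 2 == 0:
            spec[-1] /= 2.0
        acc = spec if acc is None else acc + spec
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, acc / n_seg


def _frames(x: np.ndarray, frame: int, overlap: float):
    if len(x) < frame:
        return [x]
    hop = max(int(round(frame * (1.0 - overlap))), 1)
    n_frames = 1 + (len(x) - frame) // hop
    return [x[i * hop:i * hop + frame] for i in range(n_frames)]


def _yule_walker_phi(x: np.ndarray, order: int) -> np.ndarray:
    """AR predictor coefficients from the biased autocorrelation."""
    N = len(x)
    r = np.array([np.sum(x[:N - k] * x[k:]) / N for k in range(order + 1)])
    return np.linalg.solve(toeplitz(r[:order]), r[1:order + 1])


def _lpc_cepstrum_from_roots(x: np.ndarray, order: int) -> np.ndarray:
    """c_1..c_order of the all-pole model via the zeros of the error filter.

    log(1/A(z)) = sum_n c_n z^-n with c_n = sum_i z_i^n / n over the roots
    z_i of A(z) = 1 - sum_k phi_k z^-k.
    """
    phi = _yule_walker_phi(x, order)
    roots = np.roots(np.concatenate(([1.0], -phi)))
    return np.array([np.sum(roots**n).real / n for n in range(1, order + 1)])


def _mel(f):
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _mel_filters(fs: float, nfft: int, n_filters: int) -> np.ndarray:
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mel_pts = np.linspace(0.0, _mel(fs / 2.0), n_filters + 2)
    hz = 700.0 * (10.0**(mel_pts / 2595.0) - 1.0)
    fb = np.zeros((n_filters, len(freqs)))
    for i in range(n_filters):
        for j, f in enumerate(freqs):
            if hz[i] <= f <= hz[i + 1]:
                fb[i, j] = (f - hz[i]) / (hz[i + 1] - hz[i])
            elif hz[i + 1] < f <= hz[i + 2]:
                fb[i, j] = (hz[i + 2] - f) / (hz[i + 2] - hz[i + 1])
    return fb


def _dct2_ortho(v: np.ndarray) -> np.ndarray:
    M = len(v)
    out = np.zeros(M)
    for k in range(M):
        acc = 0.0
        for m in range(M):
            acc += v[m] * np.cos(np.pi * k * (2 * m + 1) / (2 * M))
        out[k] = 2.0 * acc
    # orthonormal scaling of the type-II DCT
    out[0] *= np.sqrt(1.0 / (4.0 * M))
    out[1:] *= np.sqrt(1.0 / (2.0 * M))
    return out


def oracle_features(x: np.ndarray, fs: float,
                    cfg: SpectralConfig | None = None) -> dict[str, float]:
    cfg = cfg or SpectralConfig()
    x = np.asarray(x, dtype=float)
    N = len(x)
    out: dict[str, float] = {}
    rms = np.sqrt(np.mean(x**2))

    out["MAV"] = float(np.mean(np.abs(x)))
    wl = float(np.sum(np.abs(np.diff(x))))
    out["WL"] = wl
    out["AAC"] = wl / (N - 1)
    out["DASDV"] = float(np.sqrt(np.mean(np.diff(x)**2)))
    out["VAR"] = float(np.var(x, ddof=1))
    out["LOG"] = float(np.exp(np.mean(
        np.log(np.maximum(np.abs(x), np.finfo(float).tiny)))))

    t_zc, t_wamp, t_myop = (cfg.zc_threshold * rms, cfg.wamp_threshold * rms,
                            cfg.myop_threshold * rms)
    zc = wamp = 0
    for i in range(N - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= t_zc:
            zc += 1
        if abs(x[i] - x[i + 1]) >= t_wamp:
            wamp += 1
    out["ZC"] = float(zc)
    out["WAMP"] = float(wamp)
    out["MYOP"] = float(np.mean(np.abs(x) >= t_myop))

    m2 = np.mean((x - x.mean())**2)
    out["Skew"] = float(np.mean((x - x.mean())**3) / m2**1.5)
    out["Kurt"] = float(np.mean((x - x.mean())**4) / m2**2)

    lo, hi = x.min(), x.max()
    edges = np.linspace(lo, hi, cfg.entropy_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                  cfg.entropy_bins - 1)
    counts = np.bincount(idx, minlength=cfg.entropy_bins)
    p = counts[counts > 0] / N
    out["Entropy"] = float(-np.sum(p * np.log(p)))

    pts = np.linspace(lo, hi, cfg.ecdf_points)
    out["ECDF"] = float(np.mean([np.sum(x <= t) / N for t in pts]))

    t = np.arange(N) / fs
    out["CC"] = float(np.sum(t * x**2) / np.sum(x**2))

    out["AC"] = float(_yule_walker_phi(x, cfg.ar_order)[0])
    out["LPCC"] = float(np.mean(_lpc_cepstrum_from_roots(x, cfg.lpcc_order)))

    # MFCC: framed, mel filterbank, log energies, DCT-II (ortho), mean of
    # coefficients 1..n over frames
    frames = _frames(x, cfg.mfcc_frame, cfg.mfcc_overlap)
    fb = _mel_filters(fs, len(frames[0]), cfg.mfcc_n_filters)
    coeffs = []
    for fr in frames:
        spec = np.abs(np.fft.rfft(fr * _hann(len(fr))))**2
        energies = np.maximum(fb @ spec, np.finfo(float).tiny)
        cep = _dct2_ortho(np.log(energies))
        ncof = min(cfg.mfcc_n_coeffs, cfg.mfcc_n_filters - 1)
        coeffs.append(cep[1:1 + ncof])
    out["MFCC"] = float(np.mean(coeffs))

    freqs, P = _welch(x, fs, cfg.psd_nperseg, cfg.psd_overlap, cfg.psd_nfft)
    total = P.sum()
    out["MNF"] = float(np.sum(freqs * P) / total)
    cum = 0.0
    for j in range(len(P)):
        cum += P[j]
        if cum >= total / 2.0:
            out["MDF"] = float(freqs[j])
            break
    out["PKF"] = float(freqs[int(np.argmax(P))])
    out["MNP"] = float(np.mean(P))
    low = sum(P[j] for j in range(len(P))
              if cfg.fr_low_band[0] <= freqs[j] < cfg.fr_low_band[1])
    high = sum(P[j] for j in range(len(P))
               if cfg.fr_high_band[0] <= freqs[j] <= cfg.fr_high_band[1])
    out["FR"] = float(low / high)
    pr = P / total
    out["SE"] = float(-np.sum(pr[pr > 0] * np.log(pr[pr > 0]))
                      / np.log(len(P)))

    mag = np.abs(np.fft.rfft(x))
    fmag = np.fft.rfftfreq(N, d=1.0 / fs)
    sc = float(np.sum(fmag * mag) / np.sum(mag))
    out["SC"] = sc
    out["PW"] = float(np.sqrt(np.sum((freqs - sc)**2 * P) / total))

    sf_num = sf_den = 0.0
    for fr in _frames(x, cfg.sf_frame, cfg.sf_overlap):
        nfft = max(cfg.sf_nfft, len(fr))
        spec = np.abs(np.fft.rfft(fr * _hann(len(fr)), n=nfft))**2
        fgrid = np.fft.rfftfreq(nfft, d=1.0 / fs)
        w = spec.sum()
        sf_num += w * fgrid[int(np.argmax(spec))]
        sf_den += w
    out["SF"] = sf_num / sf_den
    return out
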