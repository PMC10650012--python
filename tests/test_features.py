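import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from sipemg.features import (FEATURE_NAMES, DegenerateWindowError,
                             EMGFeatureExtractor, InputError, SpectralConfig,
                             compute_features, extract, extract_all)
from sipemg.preprocessing import BurstWindow

from oracle_features import oracle_features

FS = 2200.0
SCALE_LINEAR = ("MAV", "WL", "AAC", "DASDV", "LOG")
SCALE_INVARIANT = ("Skew", "Kurt", "SE", "MYOP", "ZC", "WAMP", "MNF", "MDF",
                   "PKF", "SC", "CC", "AC", "Entropy", "ECDF", "FR", "SF")


def window(n=1024, seed=0, scale=1.0):
    return scale * np.random.default_rng(seed).standard_normal(n)


def as_burst(x, label="drink", volume=10.0, **kw):
    defaults = dict(fs=FS, peak_index=len(x) // 2, label=label,
                    volume_ml=volume, subject=1, day=1, side="right")
    defaults.update(kw)
    return BurstWindow(samples=np.asarray(x, float), **defaults)


def test_hand_computable_example():
    """x = [1,-1,1,-1] with zero thresholds, straight from the definitions."""
    cfg = SpectralConfig(zc_threshold=0.0, wamp_threshold=0.0,
                         myop_threshold=0.0)
    row = extract(np.array([1.0, -1.0, 1.0, -1.0]), fs=FS,
                  names=["MAV", "WL", "ZC", "WAMP", "MYOP", "AAC", "DASDV"],
                  cfg=cfg)
    assert row == {"MAV": 1.0, "WL": 6.0, "ZC": 3.0, "WAMP": 3.0,
                   "MYOP": 1.0, "AAC": 2.0, "DASDV": 2.0}


def test_sinusoid_spectral_features():
    t = np.arange(int(2.0 * FS)) / FS
    x = np.sin(2 * np.pi * 100.0 * t)
    row = extract(x, fs=FS, names=["MNF", "MDF", "PKF", "SC"])
    for name in ("MNF", "MDF", "PKF"):
        assert abs(row[name] - 100.0) < 2.0, name
    assert abs(row["SC"] - 100.0) < 5.0


def test_oracle_equivalence_sample():
    """Quick oracle check; the full 200-window suite lives in acceptance."""
    for seed in range(8):
        x = window(n=1024 if seed % 2 else 4400, seed=seed,
                   scale=0.1 + seed / 7)
        ours = compute_features(x[None], FS).iloc[0]
        ref = oracle_features(x, FS)
        for name in FEATURE_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-9), name


@settings(derandomize=True, max_examples=15, deadline=None)
@given(c=st.floats(0.01, 100.0), seed=st.integers(0, 50))
def test_scale_behaviour(c, seed):
    """Amplitude features are homogeneous of degree 1; shape and frequency
    features are scale-invariant (thresholds track window RMS)."""
    x = window(seed=seed)
    a = compute_features(x[None], FS).iloc[0]
    b = compute_features((c * x)[None], FS).iloc[0]
    for name in SCALE_LINEAR:
        assert b[name] == pytest.approx(c * a[name], rel=1e-9), name
    for name in SCALE_INVARIANT:
        assert b[name] == pytest.approx(a[name], rel=1e-7, abs=1e-10), name


def test_time_reversal_moves_only_the_temporal_centroid():
    # window length chosen so the 256/128 framing tiles the signal exactly
    x = window(n=1024, seed=5)
    a = compute_features(x[None], FS).iloc[0]
    b = compute_features(x[::-1].copy()[None], FS).iloc[0]
    for name in FEATURE_NAMES:
        if name == "CC":
            assert b[name] == pytest.approx((len(x) - 1) / FS - a[name],
                                            rel=1e-9)
        else:
            assert b[name] == pytest.approx(a[name], rel=1e-9), name


def test_bounded_features_within_range(small_fm):
    feats = small_fm
    assert feats["MYOP"].between(0, 1).all()
    assert feats["SE"].between(0, 1).all()
    for name in ("MNF", "MDF", "PKF", "SC"):
        assert feats[name].between(0, FS / 2).all(), name
    assert (feats["MNP"] >= 0).all()
    assert (feats["PW"] >= 0).all()


def test_median_frequency_bisects_power():
    from sipemg.features import _welch_psd
    cfg = SpectralConfig()
    X = np.vstack([window(4400, s) for s in range(5)])
    f, P = _welch_psd(X, FS, cfg)
    mdf = compute_features(X, FS, names=["MDF"])["MDF"].to_numpy()
    for i in range(len(X)):
        total = P[i].sum()
        below = P[i][f <= mdf[i]].sum()
        above = P[i][f >= mdf[i]].sum()
        binp = P[i].max()
        assert below >= total / 2 - binp
        assert above >= total / 2 - binp


def test_constant_window_spectral_error():
    with pytest.raises(DegenerateWindowError):
        compute_features(np.full((1, 512), 3.0), FS, names=["MNF"])
    # time-domain features remain defined
    row = compute_features(np.full((1, 512), 3.0), FS,
                           names=["MAV", "WL"]).iloc[0]
    assert row["MAV"] == 3.0 and row["WL"] == 0.0


def test_nan_rejected():
    x = window(512)
    x[5] = np.nan
    with pytest.raises(InputError):
        compute_features(x[None], FS)


def test_extract_all_routes_failures(caplog):
    windows = [as_burst(window(512, s), event_index=s) for s in range(4)]
    windows.insert(2, as_burst(np.zeros(512), event_index=99))
    with caplog.at_level(logging.WARNING):
        fm = extract_all(windows)
    assert len(fm) == 4
    assert 99 not in fm["event_index"].to_numpy()
    assert "99" in caplog.text


def test_extract_all_empty_keeps_schema():
    fm = extract_all([])
    assert list(fm.columns[:26]) == list(FEATURE_NAMES)
    assert len(fm) == 0


def test_extract_all_deterministic(small_windows):
    a = extract_all(small_windows[:30])
    b = extract_all(small_windows[:30])
    pd.testing.assert_frame_equal(a, b)


def test_unknown_feature_rejected():
    with pytest.raises(ValueError, match="unknown feature"):
        compute_features(window(512)[None], FS, names=["RMSX"])


class TestSklearnTransformer:
    def test_transform_shape_and_names(self):
        X = np.vstack([window(1024, s) for s in range(6)])
        est = EMGFeatureExtractor(fs=FS)
        out = est.fit_transform(X)
        assert out.shape == (6, 26)
        assert list(est.get_feature_names_out()) == list(FEATURE_NAMES)

    def test_subset_and_clone(self):
        est = EMGFeatureExtractor(fs=FS, features=["MAV", "MNF"])
        est2 = clone(est)
        X = np.vstack([window(1024, s) for s in range(3)])
        out = est2.fit_transform(X)
        assert out.shape == (3, 2)
        assert est2.get_params()["features"] == ["MAV", "MNF"]

    def test_matches_function_api(self):
        X = np.vstack([window(1024, s) for s in range(4)])
        est = EMGFeatureExtractor(fs=FS)
        np.testing.assert_allclose(est.fit_transform(X),
                                   compute_features(X, FS).to_numpy())
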