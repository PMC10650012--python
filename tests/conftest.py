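import numpy as np
import pandas as pd
import pytest

from sipemg import (GeneratorParams, PreprocessConfig, StudyDesign,
                    extract_all, extract_bursts, generate_study,
                    null_effect_params)


@pytest.fixture(scope="session")
def small_study():
    """Default-mode generator at reduced subject count (2 x 2 days x 2
    sides, full 100-event sessions)."""
    design = StudyDesign(n_subjects=2, n_days=2, seed=11)
    return generate_study(design)


@pytest.fixture(scope="session")
def small_windows(small_study):
    cfg = PreprocessConfig()
    out = []
    for rec, anns in small_study.iter_recordings():
        out.extend(extract_bursts(rec, anns, cfg))
    return out


@pytest.fixture(scope="session")
def small_fm(small_windows) -> pd.DataFrame:
    return extract_all(small_windows)


@pytest.fixture(scope="session")
def cell_fm(small_fm) -> pd.DataFrame:
    """One subject-day-side cell: 60 drink + 40 nondrink rows."""
    return small_fm[(small_fm["subject"] == 1) & (small_fm["day"] == 1)
                    & (small_fm["side"] == "right")].reset_index(drop=True)


@pytest.fixture(scope="session")
def null_fm() -> pd.DataFrame:
    """Feature matrix of a volume-uninformative (null-effect) session."""
    design = StudyDesign(n_subjects=1, n_days=1, seed=7)
    data = generate_study(design, null_effect_params())
    cfg = PreprocessConfig()
    rec, anns = next(iter(data.iter_recordings()))
    return extract_all(extract_bursts(rec, anns, cfg))


def planted_matrix(n_pos: int = 60, n_neg: int = 40, n_noise: int = 7,
                   noise_sd: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Feature matrix with one feature equal to the class indicator plus
    tiny noise and the rest pure noise."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    y = np.array(["drink"] * n_pos + ["talk"] * n_neg)
    fm = pd.DataFrame({"signal": (y == "drink").astype(float)
                       + noise_sd * rng.standard_normal(n)})
    for i in range(n_noise):
        fm[f"noise{i}"] = rng.standard_normal(n)
    fm["label"] = y
    fm["volume_ml"] = np.nan
    fm["subject"] = 1
    fm["day"] = 1
    fm["side"] = "right"
    return fm
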