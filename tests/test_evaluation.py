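import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from sipemg import evaluation as ev
from sipemg.evaluation import (EvalProtocol, ProtocolError, cross_day,
                               cv_classify, cv_regress, enumerate_subsets,
                               subset_search, summarize)

from conftest import planted_matrix


def regression_matrix(n_per_volume=12, informative=True, noise_sd=0.0,
                      seed=0):
    """Drink-only feature matrix with a volume-linked feature."""
    rng = np.random.default_rng(seed)
    volumes = np.repeat([5.0, 10.0, 15.0, 20.0, 25.0], n_per_volume)
    rng.shuffle(volumes)
    x = 0.3 * volumes if informative else rng.standard_normal(len(volumes))
    fm = pd.DataFrame({
        "feat": x + noise_sd * rng.standard_normal(len(volumes)),
        "other": rng.standard_normal(len(volumes)),
        "label": "drink", "volume_ml": volumes,
        "subject": 1, "day": 1, "side": "right"})
    return fm


class TestCvClassify:
    def test_separable_feature_near_perfect(self):
        fm = planted_matrix(noise_sd=0.01)
        for model in ("LDA", "KNN1", "SVC"):
            rec = cv_classify(fm, ["signal"], model, seed=0)
            assert rec.score >= 0.99, model

    def test_sample_composition(self, cell_fm):
        assert (cell_fm["label"] == "drink").sum() == 60
        assert (cell_fm["label"] != "drink").sum() == 40
        rec = cv_classify(cell_fm, ["MAV", "MDF"], "LDA", seed=1)
        assert 0.0 <= rec.score <= 1.0
        assert len(rec.fold_scores) == 5

    def test_permuted_labels_fall_in_null_band(self):
        """Observed permuted-label F sits inside a 200-permutation null."""
        fm = planted_matrix(noise_sd=0.01, seed=3)
        rng = np.random.default_rng(42)
        perm = fm.copy()
        perm["label"] = rng.permutation(perm["label"].to_numpy())
        observed = cv_classify(perm, ["signal"], "LDA", seed=0).score
        null = []
        for _ in range(200):
            shuffled = fm.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            null.append(cv_classify(shuffled, ["signal"], "LDA", seed=0).score)
        lo, hi = np.percentile(null, [1, 99])
        assert lo <= observed <= hi

    def test_single_class_rejected(self):
        fm = planted_matrix(n_neg=0)
        with pytest.raises(ProtocolError):
            cv_classify(fm, ["signal"], "LDA")

    def test_too_few_samples_rejected(self):
        fm = planted_matrix(n_pos=2, n_neg=2)
        with pytest.raises(ProtocolError):
            cv_classify(fm, ["signal"], "LDA")


class TestCvRegress:
    def test_noiseless_linear_recovery(self):
        rec = cv_regress(regression_matrix(), ["feat"], "LR", seed=0)
        assert rec.score <= 0.5

    def test_uninformative_feature_near_null_rmse(self):
        """Pure-noise feature: linear fit approaches the analytic mean-
        predictor floor sqrt(50) ~ 7.07 mL for balanced volumes 5..25."""
        rec = cv_regress(regression_matrix(informative=False), ["feat"],
                         "LR", seed=0)
        assert 6.3 <= rec.score <= 7.8
        # explicit mean-predictor baseline against the closed form
        fm = regression_matrix(informative=False)
        y = fm["volume_ml"].to_numpy()
        folds = ev.regression_folds(len(y), EvalProtocol("regress", seed=0))
        rmse = np.mean([np.sqrt(np.mean((y[te] - y[tr].mean())**2))
                        for tr, te in folds])
        assert rmse == pytest.approx(np.sqrt(50.0), abs=0.45)

    def test_missing_volume_rejected(self):
        fm = regression_matrix()
        fm.loc[3, "volume_ml"] = np.nan
        with pytest.raises(ProtocolError):
            cv_regress(fm, ["feat"], "LR")

    def test_parameter_recovery_under_strong_effect(self):
        """Large volume effect, low noise: the ANN recovers sip volume to
        under 2 mL from the best single feature."""
        from sipemg import (GeneratorParams, PreprocessConfig, StudyDesign,
                            extract_all, extract_bursts, generate_study)
        params = GeneratorParams(volume_amplitude_slope=0.2,
                                 volume_duration_slope=0.02,
                                 sip_jitter_sd=0.01, baseline_noise_sd=0.01)
        design = StudyDesign(n_subjects=1, n_days=1, seed=7)
        rec, anns = next(iter(generate_study(design, params)
                              .iter_recordings()))
        fm = extract_all(extract_bursts(rec, anns, PreprocessConfig()))
        amplitude_feats = ("MAV", "WL", "DASDV", "VAR", "LOG")
        best = min(cv_regress(fm, [f], "ANN", seed=0).score
                   for f in amplitude_feats)
        assert best < 2.0

    def test_ann_topology(self):
        est = ev.make_regressor("ANN")
        assert est.hidden_layer_sizes == (36, 16)

    def test_knn_is_single_neighbour(self):
        assert ev.make_classifier("KNN1").n_neighbors == 1
        assert ev.make_regressor("KNN1").n_neighbors == 1


class TestSubsetSearch:
    def test_enumeration_counts(self):
        from sipemg import FEATURE_NAMES
        assert len(enumerate_subsets(FEATURE_NAMES, 1)) == 26
        assert len(enumerate_subsets(FEATURE_NAMES, 2)) == 325
        assert len(enumerate_subsets(FEATURE_NAMES, 3)) == 2600

    def test_planted_feature_wins_for_every_model(self):
        fm = planted_matrix(noise_sd=0.01, seed=1)
        names = [c for c in fm.columns if c.startswith(("signal", "noise"))]
        res = subset_search(fm, ev.CLASSIFIER_NAMES, k_max=1,
                            feature_names=names, engine="sklearn",
                            protocol=EvalProtocol(seed=0))
        for _, row in res.per_cell_best.iterrows():
            assert row["features"] == ("signal",), row["model"]

    def test_brute_force_re_enumeration_agrees(self, cell_fm):
        """Search bookkeeping vs an independent itertools enumeration."""
        names = ["AAC", "CC", "FR", "Kurt", "MAV", "MDF", "SE", "WL"]
        proto = EvalProtocol(seed=2)
        res = subset_search(cell_fm, ("LDA", "QDA", "KNN1", "SVC", "RF"),
                            k_max=2, feature_names=names, engine="sklearn",
                            protocol=proto)
        for model in ("LDA", "QDA", "KNN1", "SVC", "RF"):
            best_score, best_set = -1.0, None
            for k in (1, 2):
                for subset in itertools.combinations(sorted(names), k):
                    s = cv_classify(cell_fm, list(subset), model, proto).score
                    if s > best_score:
                        best_score, best_set = s, subset
            cell = res.per_cell_best
            got = cell[(cell["model"] == model)]
            top = got.loc[got["score"].idxmax()]
            assert top["score"] == pytest.approx(best_score, abs=1e-12)
            assert tuple(top["features"]) == best_set

    def test_subject_best_dominates_global_best(self, small_fm):
        res = subset_search(small_fm, ("LDA", "KNN1"), k_max=2,
                            engine="fast", protocol=EvalProtocol(seed=0))
        lookup = {k: dict(zip(res.subsets[kk], res.scores[k][kk]))
                  for k in res.scores for kk in res.subsets}
        subsets = res.subsets
        for _, g in res.global_best.iterrows():
            for (subject, day, side, model), per_k in res.scores.items():
                if day != g["day"] or side != g["side"] \
                        or model != g["model"]:
                    continue
                k = g["k"]
                idx = subsets[k].index(g["features"])
                global_on_subject = per_k[k][idx]
                cell = res.per_cell_best
                best = cell[(cell["subject"] == subject) & (cell["day"] == day)
                            & (cell["side"] == side) & (cell["model"] == model)
                            & (cell["k"] == k)]["score"].iloc[0]
                assert best >= global_on_subject - 1e-12

    def test_k_max_out_of_range(self, cell_fm):
        with pytest.raises(ValueError):
            subset_search(cell_fm, ("LDA",), k_max=27)

    def test_greedy_k4_contains_forward_extensions(self):
        fm = planted_matrix(noise_sd=0.3, seed=4)
        names = [c for c in fm.columns if c.startswith(("signal", "noise"))]
        res = subset_search(fm, ("LDA",), k_max=4, feature_names=names,
                            engine="sklearn", protocol=EvalProtocol(seed=0),
                            k4_top=3)
        assert 4 in res.subsets and len(res.subsets[4]) > 0
        assert all(len(s) == 4 for s in res.subsets[4])


class TestCrossDay:
    def _two_day_fm(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for day in (1, 2):
            fm = planted_matrix(noise_sd=0.4, seed=seed + day)
            fm["day"] = day
            fm["signal"] += shift * (day - 1)
            frames.append(fm)
        return pd.concat(frames, ignore_index=True)

    def test_direction_symmetry(self):
        fm = self._two_day_fm(seed=1)
        table = cross_day(fm, ("signal",), ("LDA",), EvalProtocol(seed=0))
        swapped = fm.copy()
        swapped["day"] = swapped["day"].map({1: 2, 2: 1})
        table2 = cross_day(swapped, ("signal",), ("LDA",),
                           EvalProtocol(seed=0))
        a = table.set_index(["train_day", "test_day"])["score"]
        b = table2.set_index(["train_day", "test_day"])["score"]
        assert a.loc[(1, 2)].tolist() == b.loc[(2, 1)].tolist()
        assert a.loc[(2, 1)].tolist() == b.loc[(1, 2)].tolist()

    def test_lone_subject_excluded(self, caplog):
        fm = self._two_day_fm(seed=2)
        extra = planted_matrix(seed=9)
        extra["subject"] = 7  # only present on day 1
        fm = pd.concat([fm, extra], ignore_index=True)
        with caplog.at_level(logging.WARNING):
            table = cross_day(fm, ("signal",), ("LDA",), EvalProtocol(seed=0))
        assert "subject 7" in caplog.text
        assert 7 not in table["subject"].to_numpy()


class TestSummarize:
    def test_single_record_passthrough(self):
        rec = ev.EvalRecord("LDA", ("MAV",), 0.8, 0.02, (0.8,) * 5,
                            "within_day_classify", 1, 1, "right")
        out = summarize([rec])
        assert len(out) == 1
        assert out["mean"].iloc[0] == pytest.approx(0.8)

    def test_identical_records_zero_se(self):
        rec = ev.EvalRecord("LDA", ("MAV",), 0.8, 0.02, (0.8,) * 5,
                            "within_day_classify", 1, 1, "right")
        out = summarize([rec, rec])
        assert out["se"].iloc[0] == 0.0

    def test_deterministic(self, cell_fm):
        recs = [cv_classify(cell_fm, ["MAV"], "LDA", seed=3)
                for _ in range(2)]
        a, b = summarize([recs[0]]), summarize([recs[1]])
        pd.testing.assert_frame_equal(a, b)
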