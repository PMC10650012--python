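"""Model-evaluation machinery: 5-fold CV classification (F-score of the
drinking class), sip-volume regression (RMSE in mL), exhaustive
feature-subset search, and cross-day twofold validation.

Five classifiers (SVC, RF, KNN with k=1, LDA, QDA) and eight regressors
(SVR, RF, KNN1, linear regression, decision tree, lasso, ridge, and an
MLP with two hidden layers of 36 and 16 units) are evaluated on z-scored
features; all standardization statistics come from training folds only.

Subset search is exhaustive for set sizes 1-3 (26 + 325 + 2600 = 2951
sets over the full catalog) and, by default, greedy for size 4 (forward
extension of the top size-3 sets).  Per-cell (subject, day, side, model)
bests and global bests (argmax of the across-subject mean score) are both
reported.  Two evaluation backends exist: the sklearn estimators above,
and a fast vectorized engine (:mod:`sipemg._engine`) with the same model
definitions used for large searches.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.metrics import f1_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeRegressor

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES: tuple[str, ...] = ("SVC", "RF", "KNN1", "LDA", "QDA")
REGRESSOR_NAMES: tuple[str, ...] = ("SVR", "RF", "KNN1", "LR", "DT",
                                    "Lasso", "Ridge", "ANN")

#: regressors whose targets are standardized on training folds
_SCALE_TARGET = frozenset({"ANN", "SVR"})

CELL_KEYS = ("subject", "day", "side")


class ProtocolError(ValueError):
    """Evaluation protocol cannot be applied to the given data."""


@dataclass(frozen=True)
class EvalProtocol:
    """Cross-validation protocol settings."""

    task: str = "classify"
    cv_folds: int = 5
    positive_class: str = "drink"
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.task not in ("classify", "regress"):
            raise ProtocolError(f"unknown task {self.task!r}")
        if self.cv_folds < 2:
            raise ProtocolError("cv_folds must be >= 2")


@dataclass
class EvalRecord:
    """One score: (cell, model, feature set, protocol) -> value ± SE."""

    model: str
    features: tuple[str, ...]
    score: float
    se: float
    fold_scores: tuple[float, ...]
    protocol: str
    subject: Optional[int] = None
    day: Optional[int] = None
    side: Optional[str] = None


def make_classifier(name: str, seed: int = 0, rf_trees: int = 100):
    """Documented fixed-default classifier instances (no tuning)."""
    if name == "SVC":
        return SVC(C=1.0, kernel="rbf", gamma="scale", cache_size=8)
    if name == "RF":
        return RandomForestClassifier(n_estimators=rf_trees, random_state=seed,
                                      n_jobs=1)
    if name == "KNN1":
        return KNeighborsClassifier(n_neighbors=1)
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "QDA":
        # tiny ridge keeps exactly collinear subsets (the catalog contains
        # WL and AAC, proportional by definition) evaluable
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)
    raise ValueError(f"unknown classifier {name!r}")


def make_regressor(name: str, seed: int = 0, rf_trees: int = 100,
                   ann_max_iter: int = 2000):
    """Documented fixed-default regressor instances.

    The ANN topology is fixed at two hidden layers of 36 and 16 units,
    trained full-batch with L-BFGS to convergence (``ann_max_iter`` cap).
    """
    if name == "SVR":
        return SVR(C=1.0, kernel="rbf", gamma="scale", cache_size=8)
    if name == "RF":
        return RandomForestRegressor(n_estimators=rf_trees, random_state=seed,
                                     n_jobs=1)
    if name == "KNN1":
        return KNeighborsRegressor(n_neighbors=1)
    if name == "LR":
        return LinearRegression()
    if name == "DT":
        return DecisionTreeRegressor(random_state=seed)
    if name == "Lasso":
        return Lasso(alpha=0.1)
    if name == "Ridge":
        return Ridge(alpha=1.0)
    if name == "ANN":
        # L2 penalty sized for a ~700-parameter network trained on ~50
        # sips: without it the net memorizes uninformative features and
        # scores far above the mean-predictor floor
        return MLPRegressor(hidden_layer_sizes=(36, 16), solver="lbfgs",
                            alpha=0.5, max_iter=ann_max_iter,
                            random_state=seed)
    raise ValueError(f"unknown regressor {name!r}")


def _binary_labels(fm: pd.DataFrame, positive: str) -> np.ndarray:
    return (fm["label"].to_numpy() == positive).astype(int)


def classification_folds(y: np.ndarray, protocol: EvalProtocol):
    """Deterministic fold indices shared by both evaluation backends."""
    if protocol.stratified:
        cv = StratifiedKFold(protocol.cv_folds, shuffle=True,
                             random_state=protocol.seed)
    else:
        cv = KFold(protocol.cv_folds, shuffle=True, random_state=protocol.seed)
    return list(cv.split(np.zeros((len(y), 1)), y))


def regression_folds(n: int, protocol: EvalProtocol):
    cv = KFold(protocol.cv_folds, shuffle=True, random_state=protocol.seed)
    return list(cv.split(np.zeros((n, 1))))


def _check_classification_data(y: np.ndarray, protocol: EvalProtocol) -> None:
    if len(np.unique(y)) < 2:
        raise ProtocolError("classification needs both classes present")
    if len(y) < protocol.cv_folds:
        raise ProtocolError(
            f"{len(y)} samples < {protocol.cv_folds} folds")
    if np.bincount(y).min() < protocol.cv_folds and protocol.stratified:
        raise ProtocolError("minority class smaller than the fold count")


def cv_classify(fm: pd.DataFrame, subset: Sequence[str], model: str = "LDA",
                protocol: EvalProtocol | None = None, seed: int | None = None,
                rf_trees: int = 100) -> EvalRecord:
    """Stratified seeded 5-fold CV; mean F-score of the drinking class.

    Labels are binarized (``positive_class`` vs. all others); features are
    z-scored with training-fold statistics only.
    """
    protocol = protocol or EvalProtocol()
    if seed is not None:
        protocol = EvalProtocol(protocol.task, protocol.cv_folds,
                                protocol.positive_class, protocol.stratified,
                                seed)
    protocol.validate()
    subset = list(subset)
    if not subset:
        raise ProtocolError("empty feature subset")
    X = fm[subset].to_numpy(dtype=float)
    y = _binary_labels(fm, protocol.positive_class)
    _check_classification_data(y, protocol)
    scores = []
    for tr, te in classification_folds(y, protocol):
        scaler = StandardScaler().fit(X[tr])
        est = make_classifier(model, seed=protocol.seed, rf_trees=rf_trees)
        est.fit(scaler.transform(X[tr]), y[tr])
        pred = est.predict(scaler.transform(X[te]))
        scores.append(f1_score(y[te], pred, pos_label=1, zero_division=0))
    scores = np.asarray(scores)
    return EvalRecord(model, tuple(subset), float(scores.mean()),
                      float(scores.std(ddof=1) / np.sqrt(len(scores))),
                      tuple(scores), "within_day_classify",
                      *_cell_of(fm))


def cv_regress(fm: pd.DataFrame, subset: Sequence[str], model: str = "ANN",
               protocol: EvalProtocol | None = None, seed: int | None = None,
               rf_trees: int = 100, ann_max_iter: int = 2000) -> EvalRecord:
    """Seeded 5-fold CV RMSE (mL) of sip-volume prediction on drink rows.

    For ANN and SVR the targets are standardized on training folds and
    predictions are transformed back to mL.
    """
    protocol = protocol or EvalProtocol(task="regress")
    if seed is not None:
        protocol = EvalProtocol("regress", protocol.cv_folds,
                                protocol.positive_class, protocol.stratified,
                                seed)
    subset = list(subset)
    if not subset:
        raise ProtocolError("empty feature subset")
    drink = fm[fm["label"] == protocol.positive_class] \
        if "label" in fm.columns else fm
    if drink["volume_ml"].isna().any():
        raise ProtocolError("missing volume label on a drinking event")
    if len(drink) < protocol.cv_folds:
        raise ProtocolError(f"{len(drink)} drink rows < folds")
    X = drink[subset].to_numpy(dtype=float)
    y = drink["volume_ml"].to_numpy(dtype=float)
    scores = []
    for tr, te in regression_folds(len(y), protocol):
        scaler = StandardScaler().fit(X[tr])
        est = make_regressor(model, seed=protocol.seed, rf_trees=rf_trees,
                             ann_max_iter=ann_max_iter)
        with warnings.catch_warnings():
            # the MLP regressor is run to its fixed iteration cap by design
            warnings.filterwarnings("ignore", message=".*Stochastic Optimizer"
                                    ".*|.*lbfgs failed to converge.*")
            if model in _SCALE_TARGET:
                mu, sd = y[tr].mean(), y[tr].std()
                sd = sd if sd > 0 else 1.0
                est.fit(scaler.transform(X[tr]), (y[tr] - mu) / sd)
                pred = est.predict(scaler.transform(X[te])) * sd + mu
            else:
                est.fit(scaler.transform(X[tr]), y[tr])
                pred = est.predict(scaler.transform(X[te]))
        scores.append(float(np.sqrt(np.mean((pred - y[te])**2))))
    scores = np.asarray(scores)
    return EvalRecord(model, tuple(subset), float(scores.mean()),
                      float(scores.std(ddof=1) / np.sqrt(len(scores))),
                      tuple(scores), "within_day_regress",
                      *_cell_of(fm))


def _cell_of(fm: pd.DataFrame):
    out = []
    for key in CELL_KEYS:
        vals = fm[key].unique() if key in fm.columns else []
        out.append(vals[0] if len(vals) == 1 else None)
    return out


def enumerate_subsets(names: Sequence[str], k: int) -> list[tuple[str, ...]]:
    """All size-k subsets in lexicographic feature-name order."""
    return list(itertools.combinations(sorted(names), k))


@dataclass
class SearchResult:
    """Outcome of a feature-subset search.

    ``per_cell_best`` has one row per (subject, day, side, model, k);
    ``global_best`` one per (day, side, model, k), where the winning set
    maximizes the mean score across subjects.  ``scores`` keeps the full
    per-cell score vectors for every enumerated subset (classification:
    F-score, higher is better; regression: RMSE, lower is better).
    """

    task: str
    subsets: dict[int, list[tuple[str, ...]]]
    scores: dict[tuple, dict[int, np.ndarray]]  # (subject, day, side, model)
    per_cell_best: pd.DataFrame = field(default_factory=pd.DataFrame)
    global_best: pd.DataFrame = field(default_factory=pd.DataFrame)


def _best_index(values: np.ndarray, maximize: bool) -> int:
    # first optimum wins; subsets are enumerated lexicographically
    return int(np.argmax(values) if maximize else np.argmin(values))


def subset_search(fm: pd.DataFrame, models: Sequence[str] | None = None,
                  k_max: int = 4, protocol: EvalProtocol | None = None,
                  feature_names: Sequence[str] | None = None,
                  engine: str = "auto", k4_exhaustive: bool = False,
                  k4_top: int = 50, rf_trees: int | None = None,
                  ann_max_iter: int = 2000) -> SearchResult:
    """Exhaustive feature-subset search over every (subject, day, side) cell.

    Sizes 1..min(3, k_max) are enumerated exhaustively; size 4 by greedy
    forward extension of the ``k4_top`` best size-3 sets per cell (set
    ``k4_exhaustive`` to enumerate all 14950).  ``engine='fast'`` uses the
    vectorized backend (classification only); ``'sklearn'`` the estimator
    backend; ``'auto'`` picks fast for classification searches.
    """
    protocol = protocol or EvalProtocol()
    protocol.validate()
    names = sorted(feature_names if feature_names is not None
                   else [c for c in fm.columns if c in FEATURE_NAMES])
    if not names:
        raise ValueError("no feature columns found")
    if k_max < 1 or k_max > len(names):
        raise ValueError(f"k_max must lie in [1, {len(names)}]")
    if models is None:
        models = CLASSIFIER_NAMES if protocol.task == "classify" \
            else REGRESSOR_NAMES
    if engine == "auto":
        engine = "fast" if protocol.task == "classify" else "sklearn"

    subsets = {k: enumerate_subsets(names, k)
               for k in range(1, min(k_max, 3) + 1)}
    if k_max >= 4 and k4_exhaustive:
        subsets[4] = enumerate_subsets(names, 4)

    cells = sorted(fm.groupby(list(CELL_KEYS)).groups)
    scores: dict[tuple, dict[int, np.ndarray]] = {}
    for cell in cells:
        sub_fm = fm[(fm["subject"] == cell[0]) & (fm["day"] == cell[1])
                    & (fm["side"] == cell[2])]
        for model in models:
            key = (*cell, model)
            scores[key] = {
                k: _score_subsets(sub_fm, subsets[k], model, protocol,
                                  engine, rf_trees, ann_max_iter)
                for k in subsets
            }

    if k_max >= 4 and not k4_exhaustive:
        _greedy_k4(fm, subsets, scores, models, protocol, engine, k4_top,
                   rf_trees, ann_max_iter)

    maximize = protocol.task == "classify"
    cell_rows, global_rows = [], []
    for (subject, day, side, model), per_k in sorted(scores.items()):
        for k, vals in per_k.items():
            i = _best_index(vals, maximize)
            cell_rows.append({"subject": subject, "day": day, "side": side,
                              "model": model, "k": k,
                              "features": subsets[k][i],
                              "score": float(vals[i])})
    day_sides = sorted({(d, s) for _, d, s, _ in scores})
    for day, side in day_sides:
        for model in models:
            keys = [k for k in scores if k[1] == day and k[2] == side
                    and k[3] == model]
            for k in subsets:
                mean_scores = np.mean([scores[key][k] for key in keys], axis=0)
                i = _best_index(mean_scores, maximize)
                global_rows.append({"day": day, "side": side, "model": model,
                                    "k": k, "features": subsets[k][i],
                                    "score": float(mean_scores[i])})
    return SearchResult(protocol.task, subsets, scores,
                        pd.DataFrame(cell_rows), pd.DataFrame(global_rows))


def _score_subsets(sub_fm: pd.DataFrame, subset_list, model: str,
                   protocol: EvalProtocol, engine: str,
                   rf_trees: int | None, ann_max_iter: int) -> np.ndarray:
    if engine == "fast" and protocol.task == "classify":
        from . import _engine
        return _engine.evaluate_subsets(sub_fm, subset_list, model, protocol,
                                        rf_trees=rf_trees or 25)
    if engine == "fast" and model == "RF":
        # regression: only the forest needs the JIT backend for speed
        from . import _engine
        return _engine.fast_rf_regression_scores(sub_fm, subset_list, protocol,
                                                 n_trees=rf_trees or 100)
    trees = rf_trees or 100
    fn = cv_classify if protocol.task == "classify" else cv_regress
    kwargs = {"rf_trees": trees}
    if protocol.task == "regress":
        kwargs["ann_max_iter"] = ann_max_iter
    return np.array([fn(sub_fm, list(s), model, protocol, **kwargs).score
                     for s in subset_list])


def _greedy_k4(fm, subsets, scores, models, protocol, engine, k4_top,
               rf_trees, ann_max_iter) -> None:
    """Size-4 sets by forward extension of the best size-3 sets per cell."""
    maximize = protocol.task == "classify"
    names = sorted({n for s in subsets[3] for n in s})
    size3 = subsets[3]
    candidates: set[tuple[str, ...]] = set()
    for key, per_k in scores.items():
        order = np.argsort(per_k[3])
        top = order[::-1][:k4_top] if maximize else order[:k4_top]
        for i in top:
            base = size3[i]
            for extra in names:
                if extra not in base:
                    candidates.add(tuple(sorted((*base, extra))))
    subset4 = sorted(candidates)
    subsets[4] = subset4
    for key in list(scores):
        subject, day, side, model = key
        sub_fm = fm[(fm["subject"] == subject) & (fm["day"] == day)
                    & (fm["side"] == side)]
        scores[key][4] = _score_subsets(sub_fm, subset4, model, protocol,
                                        engine, rf_trees, ann_max_iter)


def cross_day(fm: pd.DataFrame, sets, models: Sequence[str] | None = None,
              protocol: EvalProtocol | None = None, days: tuple[int, int] = (1, 2),
              rf_trees: int = 100, ann_max_iter: int = 2000) -> pd.DataFrame:
    """Twofold cross-day validation.

    For each direction (train on all of day A, test on day B, per subject
    per side), the model is fit with the day-A feature set and scored on
    day B.  ``sets`` is either one feature tuple used everywhere or a dict
    ``{(day, side, model): features}`` (day-A-selected sets).  Subjects
    present on one day only are excluded with a log entry.  Returns a long
    table with one row per (direction, subject, side, model) plus the
    per-direction means.
    """
    protocol = protocol or EvalProtocol()
    protocol.validate()
    if models is None:
        models = CLASSIFIER_NAMES if protocol.task == "classify" \
            else REGRESSOR_NAMES
    day_a, day_b = days
    subj_a = set(fm.loc[fm["day"] == day_a, "subject"].unique())
    subj_b = set(fm.loc[fm["day"] == day_b, "subject"].unique())
    for missing in sorted((subj_a ^ subj_b)):
        logger.warning("subject %s present on one day only: excluded", missing)
    subjects = sorted(subj_a & subj_b)
    if not subjects:
        raise ProtocolError("no subject present on both days")
    sides = sorted(fm["side"].unique())
    rows = []
    for train_day, test_day in ((day_a, day_b), (day_b, day_a)):
        for side in sides:
            for model in models:
                subset = sets if not isinstance(sets, dict) \
                    else sets[(train_day, side, model)]
                for subject in subjects:
                    tr_fm = fm[(fm["day"] == train_day) & (fm["side"] == side)
                               & (fm["subject"] == subject)]
                    te_fm = fm[(fm["day"] == test_day) & (fm["side"] == side)
                               & (fm["subject"] == subject)]
                    score = _fit_score_transfer(tr_fm, te_fm, list(subset),
                                                model, protocol, rf_trees,
                                                ann_max_iter)
                    rows.append({"train_day": train_day, "test_day": test_day,
                                 "subject": subject, "side": side,
                                 "model": model,
                                 "features": tuple(subset), "score": score})
    return pd.DataFrame(rows)


def _fit_score_transfer(tr_fm, te_fm, subset, model, protocol, rf_trees,
                        ann_max_iter) -> float:
    if protocol.task == "classify":
        ytr = _binary_labels(tr_fm, protocol.positive_class)
        yte = _binary_labels(te_fm, protocol.positive_class)
        Xtr = tr_fm[subset].to_numpy(dtype=float)
        Xte = te_fm[subset].to_numpy(dtype=float)
        scaler = StandardScaler().fit(Xtr)
        est = make_classifier(model, seed=protocol.seed, rf_trees=rf_trees)
        est.fit(scaler.transform(Xtr), ytr)
        pred = est.predict(scaler.transform(Xte))
        return float(f1_score(yte, pred, pos_label=1, zero_division=0))
    tr = tr_fm[tr_fm["label"] == protocol.positive_class]
    te = te_fm[te_fm["label"] == protocol.positive_class]
    Xtr, ytr = tr[subset].to_numpy(dtype=float), tr["volume_ml"].to_numpy()
    Xte, yte = te[subset].to_numpy(dtype=float), te["volume_ml"].to_numpy()
    scaler = StandardScaler().fit(Xtr)
    est = make_regressor(model, seed=protocol.seed, rf_trees=rf_trees,
                         ann_max_iter=ann_max_iter)
    if model in _SCALE_TARGET:
        mu, sd = ytr.mean(), ytr.std() if ytr.std() > 0 else 1.0
        est.fit(scaler.transform(Xtr), (ytr - mu) / sd)
        pred = est.predict(scaler.transform(Xte)) * sd + mu
    else:
        est.fit(scaler.transform(Xtr), ytr)
        pred = est.predict(scaler.transform(Xte))
    return float(np.sqrt(np.mean((pred - yte)**2)))


def summarize(records: Sequence[EvalRecord] | pd.DataFrame,
              by: Sequence[str] = ("day", "side", "model")) -> pd.DataFrame:
    """Grouped mean ± standard error of scores.

    Accepts a list of :class:`EvalRecord` or any long-format score table
    with a ``score`` column.  ``k`` (feature-set size) is derived from the
    ``features`` column when present.
    """
    if isinstance(records, pd.DataFrame):
        table = records.copy()
    else:
        if not records:
            raise ValueError("no records to summarize")
        table = pd.DataFrame([{
            "subject": r.subject, "day": r.day, "side": r.side,
            "model": r.model, "features": r.features, "score": r.score,
        } for r in records])
    if "features" in table.columns and "k" not in table.columns:
        table["k"] = table["features"].map(len)
    keys = [c for c in (*by, "k") if c in table.columns]
    grouped = table.groupby(keys)["score"]
    out = grouped.agg(mean="mean", n="count",
                      se=lambda s: s.std(ddof=1) / np.sqrt(len(s))
                      if len(s) > 1 else 0.0)
    return out.reset_index()
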