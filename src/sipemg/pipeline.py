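"""End-to-end orchestration: simulate -> preprocess -> features ->
evaluate -> cross-day -> summarize, as one seeded, logged, reproducible
run that writes delimited tables, JSON summaries and a checksummed
manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import evaluation as ev
from .features import FEATURE_NAMES, SpectralConfig, extract_all
from .preprocessing import PreprocessConfig, extract_bursts
from .synthetic import (GeneratorParams, ParameterError, StudyDesign,
                        generate_study)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""


@dataclass
class RunConfig:
    """Complete, serializable specification of one pipeline run."""

    design: StudyDesign = field(default_factory=StudyDesign)
    params: GeneratorParams = field(default_factory=GeneratorParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    classifiers: tuple[str, ...] = ev.CLASSIFIER_NAMES
    regressors: tuple[str, ...] = ev.REGRESSOR_NAMES
    k_max: int = 3
    regression_k_max: int = 1
    cv_folds: int = 5
    engine: str = "auto"
    search_rf_trees: int = 25
    ann_max_iter: int = 2000
    crossday_top_models: int = 3
    seed: int = 0

    def validate(self) -> None:
        self.preprocess.validate(self.design.fs)
        self.spectral.validate(self.design.fs)
        self.params.validate(self.design)
        for name in self.classifiers:
            if name not in ev.CLASSIFIER_NAMES:
                raise ParameterError(f"unknown classifier {name!r}")
        for name in self.regressors:
            if name not in ev.REGRESSOR_NAMES:
                raise ParameterError(f"unknown regressor {name!r}")
        if not (1 <= self.k_max <= len(FEATURE_NAMES)):
            raise ParameterError("k_max out of range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"]["class_signatures"] = {
            k: dataclasses.asdict(v)
            for k, v in self.params.class_signatures.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .synthetic import ClassSignature
        d = dict(d)
        if "design" in d:
            dd = dict(d["design"])
            for key in ("sides", "volumes", "nondrink_classes"):
                if key in dd:
                    dd[key] = tuple(dd[key])
            d["design"] = StudyDesign(**dd)
        if "params" in d:
            pp = dict(d["params"])
            if "class_signatures" in pp:
                pp["class_signatures"] = {
                    k: ClassSignature(**{**v, "band": tuple(v["band"])})
                    for k, v in pp["class_signatures"].items()}
            d["params"] = GeneratorParams(**pp)
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "spectral" in d:
            sp = dict(d["spectral"])
            for key in ("fr_low_band", "fr_high_band"):
                if key in sp:
                    sp[key] = tuple(sp[key])
            d["spectral"] = SpectralConfig(**sp)
        for key in ("classifiers", "regressors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(cfg.to_dict(), default=float)),
                       fh, sort_keys=True)


def build_feature_matrix(cfg: RunConfig, data=None) -> pd.DataFrame:
    """Stages 1-3: simulate (unless given), segment, extract features."""
    data = data if data is not None else generate_study(cfg.design, cfg.params)
    frames = []
    for rec, anns in data.iter_recordings():
        windows = extract_bursts(rec, anns, cfg.preprocess)
        frames.append(extract_all(windows, cfg=cfg.spectral))
    return pd.concat(frames, ignore_index=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fmt_sets(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["features"] = out["features"].map(lambda s: "+".join(s))
    return out


def run(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; return (and write) the output manifest.

    Re-running with an identical config reproduces identical summary
    checksums.  On stage failure, a StageError names the stage and partial
    outputs already written remain on disk, marked in the manifest.
    """
    cfg.validate()  # fail fast before any compute
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config.yaml")
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                      "stages": {}, "files": {}, "status": "running"}
    proto_c = ev.EvalProtocol("classify", cv_folds=cfg.cv_folds,
                              seed=cfg.seed)
    proto_r = ev.EvalProtocol("regress", cv_folds=cfg.cv_folds, seed=cfg.seed)

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["status"] = f"failed at stage {name}"
            _write_manifest(manifest, outdir)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: %.2fs", name, manifest["stages"][name])
        return result

    fm = _stage("features", lambda: build_feature_matrix(cfg))
    fm.to_csv(outdir / "features.csv", index=False, float_format="%.10g")

    search = _stage("classification_search", lambda: ev.subset_search(
        fm, cfg.classifiers, k_max=cfg.k_max, protocol=proto_c,
        engine=cfg.engine, rf_trees=cfg.search_rf_trees))
    _fmt_sets(search.per_cell_best).to_csv(
        outdir / "classification_subject_best.csv", index=False)
    _fmt_sets(search.global_best).to_csv(
        outdir / "classification_global_best.csv", index=False)

    reg_engine = "fast" if cfg.engine in ("auto", "fast") else "sklearn"
    reg_search = _stage("regression_search", lambda: ev.subset_search(
        fm, cfg.regressors, k_max=cfg.regression_k_max, protocol=proto_r,
        engine=reg_engine, ann_max_iter=cfg.ann_max_iter))
    _fmt_sets(reg_search.per_cell_best).to_csv(
        outdir / "regression_subject_best.csv", index=False)
    _fmt_sets(reg_search.global_best).to_csv(
        outdir / "regression_global_best.csv", index=False)

    cross_tables = {}
    if cfg.design.n_days >= 2:
        cross_tables = _stage("crossday", lambda: _crossday_stage(
            cfg, fm, search, reg_search, proto_c, proto_r))
        for name, table in cross_tables.items():
            _fmt_sets(table).to_csv(outdir / f"{name}.csv", index=False)

    summary = _stage("summarize", lambda: _summaries(search, reg_search,
                                                     cross_tables))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)

    for path in sorted(outdir.glob("*.csv")) + [outdir / "summary.json",
                                                outdir / "config.yaml"]:
        manifest["files"][path.name] = _sha256(path)
    manifest["status"] = "ok"
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _crossday_stage(cfg, fm, search, reg_search, proto_c, proto_r):
    """Train day A with its best global sets, test day B (both directions).

    Classification uses each day's best global feature set per (side,
    model) at k = k_max; regression uses the best single global feature
    per (side, model)."""
    out = {}
    gb = search.global_best
    k_use = min(cfg.k_max, 3)
    sets_c = {(int(r["day"]), r["side"], r["model"]): r["features"]
              for _, r in gb[gb["k"] == k_use].iterrows()}
    out["crossday_classification"] = ev.cross_day(
        fm, sets_c, cfg.classifiers, proto_c, rf_trees=100)
    rb = reg_search.global_best
    sets_r = {(int(r["day"]), r["side"], r["model"]): r["features"]
              for _, r in rb[rb["k"] == 1].iterrows()}
    out["crossday_regression"] = ev.cross_day(
        fm, sets_r, cfg.regressors, proto_r,
        ann_max_iter=cfg.ann_max_iter)
    return out


def _summaries(search, reg_search, cross_tables) -> dict:
    summary = {
        "classification_global_best":
            _fmt_sets(search.global_best).to_dict("records"),
        "classification_subject_mean": ev.summarize(
            search.per_cell_best).to_dict("records"),
        "regression_global_best":
            _fmt_sets(reg_search.global_best).to_dict("records"),
        "regression_subject_mean": ev.summarize(
            reg_search.per_cell_best).to_dict("records"),
    }
    for name, table in cross_tables.items():
        summary[name + "_mean"] = ev.summarize(
            table, by=("model", "side")).to_dict("records")
    return summary
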