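"""Plain-text persistence for synthetic study datasets.

Layout under a dataset directory:

* ``manifest.json`` — design, generator parameters, file list.
* ``signals_s<subject>_d<day>.csv`` — one column per channel, ``# fs=<hz>``
  header line, fixed-precision scientific notation.
* ``annotations.csv`` — subject, day, event_index, time_s, label, volume_ml.

``read_dataset(write_dataset(d))`` reproduces annotations exactly and
samples to the written text precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (ClassSignature, EventAnnotation, GeneratorParams,
                        Recording, Session, StudyData, StudyDesign)

_PRECISION = "%.8e"


class FormatError(ValueError):
    """Malformed or inconsistent dataset files."""


def write_dataset(data: StudyData, directory: str | Path) -> dict:
    """Write a study dataset as delimited text; return the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    rows = []
    for sess in data.sessions:
        name = f"signals_s{sess.subject}_d{sess.day}.csv"
        cols = {side: sess.recordings[side].samples for side in data.design.sides}
        n = len(next(iter(cols.values())))
        arr = np.column_stack([cols[s] for s in data.design.sides])
        with open(directory / name, "w") as fh:
            fh.write(f"# fs={data.design.fs}\n")
            fh.write(",".join(data.design.sides) + "\n")
            np.savetxt(fh, arr, fmt=_PRECISION, delimiter=",")
        files.append({"file": name, "subject": sess.subject, "day": sess.day,
                      "n_samples": n})
        for ann in sess.annotations:
            rows.append({"subject": sess.subject, "day": sess.day,
                         "event_index": ann.event_index, "time_s": ann.time_s,
                         "label": ann.label,
                         "volume_ml": ann.volume_ml if ann.volume_ml is not None
                         else ""})
    pd.DataFrame(rows).to_csv(directory / "annotations.csv", index=False,
                              float_format="%.17g")

    params = dataclasses.asdict(data.params)
    params["class_signatures"] = {
        k: dataclasses.asdict(v) for k, v in data.params.class_signatures.items()
    }
    manifest = {
        "design": dataclasses.asdict(data.design),
        "params": params,
        "signal_files": files,
        "annotation_file": "annotations.csv",
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _parse_annotations(path: Path, design: StudyDesign) -> dict:
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise FormatError(f"missing annotation file {path}")
    by_session: dict[tuple[int, int], list[EventAnnotation]] = {}
    for i, row in table.iterrows():
        label = str(row["label"])
        vol = row["volume_ml"]
        has_vol = pd.notna(vol) and str(vol) != ""
        if label == "drink" and not has_vol:
            raise FormatError(f"{path} line {i + 2}: drink event without volume")
        if label != "drink" and has_vol:
            raise FormatError(
                f"{path} line {i + 2}: volume given for {label!r} event")
        vol_f = float(vol) if has_vol else None
        if vol_f is not None and vol_f not in design.volumes:
            raise FormatError(
                f"{path} line {i + 2}: volume {vol_f} not in design volumes")
        key = (int(row["subject"]), int(row["day"]))
        by_session.setdefault(key, []).append(
            EventAnnotation(int(row["event_index"]), float(row["time_s"]),
                            label, vol_f))
    return by_session


def read_dataset(directory: str | Path) -> StudyData:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest in {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    d = dict(manifest["design"])
    for key in ("sides", "volumes", "nondrink_classes"):
        d[key] = tuple(d[key])
    design = StudyDesign(**d)
    p = dict(manifest["params"])
    p["class_signatures"] = {
        k: ClassSignature(**{**v, "band": tuple(v["band"])})
        for k, v in p["class_signatures"].items()
    }
    params = GeneratorParams(**p)

    annotations = _parse_annotations(directory / manifest["annotation_file"],
                                     design)
    sessions = []
    for entry in manifest["signal_files"]:
        path = directory / entry["file"]
        if not path.exists():
            raise FormatError(f"missing signal file {path}")
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# fs="):
                raise FormatError(f"{path} line 1: expected '# fs=' header")
            fs = float(header.split("=", 1)[1])
            if fs != design.fs:
                raise FormatError(
                    f"{path} line 1: fs {fs} does not match manifest {design.fs}")
            sides = fh.readline().strip().split(",")
            if tuple(sides) != design.sides:
                raise FormatError(f"{path} line 2: channel names {sides} "
                                  f"do not match design {design.sides}")
            try:
                arr = np.loadtxt(fh, delimiter=",", ndmin=2)
            except ValueError as exc:
                raise FormatError(f"{path}: malformed numeric row ({exc})")
        if arr.shape[0] != entry["n_samples"]:
            raise FormatError(f"{path}: {arr.shape[0]} samples, manifest says "
                              f"{entry['n_samples']}")
        subject, day = entry["subject"], entry["day"]
        recs = {side: Recording(arr[:, j], design.fs, subject, day, side)
                for j, side in enumerate(design.sides)}
        anns = annotations.get((subject, day), [])
        anns.sort(key=lambda a: a.event_index)
        sessions.append(Session(subject, day, recs, anns))
    return StudyData(design, params, sessions)
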