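"""Readers and writers for every artefact the pipeline produces.

Formats
-------
* ROI time series: CSV, header row of node ids, T numeric rows.
* Atlas mapping: TSV with columns ``node_id`` and ``system``.
* Subject table: CSV indexed by ``subject_id``.
* Layer stacks: a directory holding ``layers.npy`` (W x R x R float),
  ``retained.npy`` (bool) and ``meta.json`` (width, step, alpha, policy,
  node ids).  Plain ``.npy`` is used rather than a zip container so the
  bytes are deterministic and checksummable.
* Community assignments: a directory with one ``rep_###.tsv`` integer table
  (R rows x W columns) per repetition plus ``runs.json`` (seed, gamma,
  omega and quality per repetition).
* Pipeline configuration: YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import CommunityAssignment
from .connectivity import LayerStack, RoiTimeSeries
from .errors import ParseError

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_atlas",
    "write_atlas",
    "read_subjects",
    "write_subjects",
    "read_layer_stack",
    "write_layer_stack",
    "read_assignments",
    "write_assignments",
    "read_config",
    "write_config",
    "file_checksum",
]


def write_timeseries(ts: RoiTimeSeries, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(ts.values, columns=ts.node_ids)
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_timeseries(path, atlas: pd.DataFrame | None = None, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a delimited T x R table with a node-id header.

    Ragged rows, non-numeric cells and duplicate node ids raise
    :class:`ParseError` naming the offending line.  When ``atlas`` is given,
    columns are reordered to match its node order.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ParseError(f"{path}: duplicate node id {dup!r} in header")
    try:
        frame = pd.read_csv(path, header=0, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - normalize to a parse error
        raise ParseError(f"{path}: cannot parse ({exc})") from exc
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            row = int(np.argmax(pd.to_numeric(frame[col], errors="coerce").isna())) + 2
            raise ParseError(f"{path}: non-numeric value in column {col!r}, line {row}")
    if frame.isna().any().any():
        row = int(np.argmax(frame.isna().any(axis=1))) + 2  # header is line 1
        raise ParseError(f"{path}: missing value at line {row}")
    if atlas is not None:
        wanted = [str(n) for n in atlas["node_id"]]
        missing = set(wanted) - set(map(str, frame.columns))
        if missing:
            raise ParseError(f"{path}: columns missing for atlas nodes {sorted(missing)}")
        frame = frame[wanted]
    sid = subject_id if subject_id is not None else path.stem
    return RoiTimeSeries(
        values=frame.to_numpy(dtype=float),
        node_ids=[str(c) for c in frame.columns],
        subject_id=sid,
    )


def write_atlas(atlas: pd.DataFrame, path) -> Path:
    path = Path(path)
    atlas[["node_id", "system"]].to_csv(path, sep="\t", index=False)
    return path


def read_atlas(path) -> pd.DataFrame:
    path = Path(path)
    atlas = pd.read_csv(path, sep="\t", dtype=str)
    if {"node_id", "system"} - set(atlas.columns):
        raise ParseError(f"{path}: atlas needs 'node_id' and 'system' columns")
    if atlas["node_id"].duplicated().any():
        dup = atlas["node_id"][atlas["node_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate node_id {dup!r}")
    return atlas


def write_subjects(subjects: pd.DataFrame, path) -> Path:
    path = Path(path)
    subjects.to_csv(path, float_format="%.17g")
    return path


def read_subjects(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), index_col="subject_id")


def write_layer_stack(stack: LayerStack, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "layers.npy", stack.layers)
    np.save(outdir / "retained.npy", stack.retained)
    meta = {
        "window_width": stack.window_width,
        "step": stack.step,
        "alpha": stack.alpha,
        "negatives": stack.negatives,
        "node_ids": stack.node_ids,
        "subject_id": stack.subject_id,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return outdir


def read_layer_stack(indir) -> LayerStack:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    return LayerStack(
        layers=np.load(indir / "layers.npy"),
        retained=np.load(indir / "retained.npy"),
        window_width=meta["window_width"],
        step=meta["step"],
        alpha=meta["alpha"],
        negatives=meta["negatives"],
        node_ids=meta["node_ids"],
        subject_id=meta["subject_id"],
    )


def write_assignments(
    assignments: list[CommunityAssignment], outdir, gamma: float, omega: float
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runs = []
    for i, a in enumerate(assignments):
        np.savetxt(outdir / f"rep_{i:03d}.tsv", a.labels, fmt="%d", delimiter="\t")
        runs.append({"rep": i, "seed": a.seed, "quality": a.quality})
    (outdir / "runs.json").write_text(
        json.dumps({"gamma": gamma, "omega": omega, "runs": runs}, indent=1)
    )
    return outdir


def read_assignments(indir) -> tuple[list[CommunityAssignment], dict]:
    indir = Path(indir)
    meta = json.loads((indir / "runs.json").read_text())
    out = []
    for run in meta["runs"]:
        labels = np.loadtxt(indir / f"rep_{run['rep']:03d}.tsv", dtype=int, delimiter="\t", ndmin=2)
        out.append(
            CommunityAssignment(labels=labels, quality=run["quality"], seed=run["seed"])
        )
    return out, meta


def write_config(config: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def file_checksum(path) -> str:
    """SHA-256 of a file's bytes (all pipeline formats are deterministic)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
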