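"""File formats: HDF5 time-series/matrix containers, TSV tables, config.

Time series and connectivity matrices live in an HDF5 container (one group
per subject: ``subj_<id>/data`` with attributes ``fs`` and ``labels``;
matrices under ``subj_<id>/conn/<band>``).  All tabular data (scores,
partition, edge counts, statistics) are long-format TSV.  Run configuration
is a plain-text INI file.
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import RoiTimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "list_subjects",
    "write_connectivity",
    "read_connectivity",
    "write_scores",
    "read_scores",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
]

_STR = h5py.string_dtype(encoding="utf-8")


def write_timeseries(path, subjects: "list[RoiTimeSeries] | RoiTimeSeries", mode="a") -> None:
    """Write subjects to the HDF5 container (``subj_<id>/data`` + attrs)."""
    if isinstance(subjects, RoiTimeSeries):
        subjects = [subjects]
    with h5py.File(path, mode) as f:
        for ts in subjects:
            if not ts.subject_id:
                raise ValueError("subject_id required to write a time series")
            grp = f.require_group(f"subj_{ts.subject_id}")
            if "data" in grp:
                del grp["data"]
            d = grp.create_dataset("data", data=ts.data)
            d.attrs["fs"] = float(ts.fs)
            d.attrs["labels"] = np.array(ts.labels, dtype=_STR)
            if ts.group:
                d.attrs["group"] = ts.group


def list_subjects(path) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(k[len("subj_"):] for k in f if k.startswith("subj_"))


def read_timeseries(path, subject: str) -> RoiTimeSeries:
    """Read one subject back; bit-exact round trip for data, fs, labels."""
    with h5py.File(path, "r") as f:
        key = f"subj_{subject}"
        if key not in f:
            raise KeyError(f"no subject {subject!r} in {path}")
        grp = f[key]
        if "data" not in grp:
            raise KeyError(f"container {path} group {key} has no 'data' dataset")
        d = grp["data"]
        for attr in ("fs", "labels"):
            if attr not in d.attrs:
                raise KeyError(f"dataset {key}/data is missing required attribute {attr!r}")
        labels = [l.decode() if isinstance(l, bytes) else str(l) for l in d.attrs["labels"]]
        group = d.attrs.get("group", "")
        group = group.decode() if isinstance(group, bytes) else str(group)
        return RoiTimeSeries(d[()], float(d.attrs["fs"]), labels,
                             subject_id=subject, group=group)


def write_connectivity(path, subject: str, band_name: str, values: np.ndarray,
                       labels=None) -> None:
    with h5py.File(path, "a") as f:
        grp = f.require_group(f"subj_{subject}/conn")
        if band_name in grp:
            del grp[band_name]
        d = grp.create_dataset(band_name, data=np.asarray(values))
        if labels is not None:
            d.attrs["labels"] = np.array(list(labels), dtype=_STR)


def read_connectivity(path, subject: str, band_name: str) -> np.ndarray:
    with h5py.File(path, "r") as f:
        key = f"subj_{subject}/conn/{band_name}"
        if key not in f:
            raise KeyError(f"no connectivity {key} in {path}")
        return f[key][()]


def write_scores(path, scores: pd.DataFrame) -> None:
    """Write the clinical-scores table (subject_id group bdi hamd asrm ymrs)."""
    cols = ["subject_id", "group"] + [c for c in scores.columns
                                      if c not in ("subject_id", "group")]
    scores[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"scores table {path} missing column {col!r}")
    return df


def write_timeseries_tsv(path, ts: RoiTimeSeries) -> None:
    """Delimited-text fallback: one ROI per row (label + samples), sidecar fs.

    The sidecar ``<path>.json`` records fs, subject id and group.  Floats
    are written with 17 significant digits so the round trip is exact to
    1e-12 or better.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for label, row in zip(ts.labels, ts.data):
            fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
    sidecar = {"fs": ts.fs, "subject_id": ts.subject_id, "group": ts.group}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_timeseries_tsv(path) -> RoiTimeSeries:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path} (holds the sampling rate)")
    sidecar = json.loads(sidecar_path.read_text())
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    return RoiTimeSeries(np.vstack(rows), float(sidecar["fs"]), labels,
                         subject_id=sidecar.get("subject_id", ""),
                         group=sidecar.get("group", ""))


def read_config(path) -> configparser.ConfigParser:
    """Parse a plain-text ``key = value`` config with sections."""
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    return cp
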