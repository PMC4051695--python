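"""Readers and writers for the pipeline's plain-text and TIFF formats.

Formats:

* profile CSV — ``position_um,intensity`` (+ header comment with pixel
  size and channel is avoided; calibration travels in the positions);
* image TIFF — plain grayscale, written via :mod:`tifffile`;
* pulse-chase CSV — ``label,timepoint_h,compartment,intensity`` with
  compartment ``z`` or ``body``;
* Ct CSV — ``sample_id,genotype,day,gene,replicate,ct``;
* geotaxis CSV — ``line,vial,day,rep,successes,n_flies``;
* annotation TSV — ``gene<TAB>term``; edge TSV — ``gene<TAB>gene<TAB>kind``;
* JSON truth sidecars for every synthetic dataset.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .morphometry import IntensityProfile
from .turnover import PulseChaseSeries

__all__ = [
    "write_profile_csv",
    "read_profile_csv",
    "write_image_tiff",
    "read_image_tiff",
    "write_pulse_chase_csv",
    "read_pulse_chase_csv",
    "write_ct_csv",
    "read_ct_csv",
    "write_geotaxis_csv",
    "read_geotaxis_csv",
    "write_annotations_tsv",
    "read_annotations_tsv",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_truth_json",
    "read_truth_json",
]


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"position_um": profile.positions, "intensity": profile.intensities}
    ).to_csv(path, index=False)


def read_profile_csv(path: str | Path, channel: str = "phalloidin") -> IntensityProfile:
    df = pd.read_csv(path)
    if not {"position_um", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns position_um,intensity")
    pos = df["position_um"].to_numpy(dtype=float)
    spacing = np.diff(pos)
    if pos.size < 2 or spacing.min() <= 0:
        raise ValueError(f"{path}: positions must be strictly increasing")
    return IntensityProfile(
        pos, df["intensity"].to_numpy(dtype=float), pixel_size=float(spacing.mean()),
        channel=channel,
    )


def write_image_tiff(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_pulse_chase_csv(series: PulseChaseSeries, path: str | Path) -> None:
    rows = []
    for t, z, b in zip(series.timepoints, series.z_intensity, series.body_intensity):
        for v in z:
            rows.append({"label": series.label, "timepoint_h": t, "compartment": "z", "intensity": v})
        for v in b:
            rows.append({"label": series.label, "timepoint_h": t, "compartment": "body", "intensity": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pulse_chase_csv(path: str | Path, label: str | None = None) -> PulseChaseSeries:
    df = pd.read_csv(path)
    required = {"label", "timepoint_h", "compartment", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if label is not None:
        df = df[df["label"] == label]
    labels = df["label"].unique()
    if len(labels) != 1:
        raise ValueError(f"{path}: expected a single label, found {list(labels)}")
    timepoints = np.sort(df["timepoint_h"].unique())
    z, body = [], []
    for t in timepoints:
        sub = df[df["timepoint_h"] == t]
        z.append(sub.loc[sub["compartment"] == "z", "intensity"].to_numpy(dtype=float))
        body.append(sub.loc[sub["compartment"] == "body", "intensity"].to_numpy(dtype=float))
    return PulseChaseSeries(timepoints=timepoints, z_intensity=z, body_intensity=body,
                            label=str(labels[0]))


def write_ct_csv(ct_table: pd.DataFrame, path: str | Path) -> None:
    ct_table.to_csv(path, index=False)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"genotype", "day", "gene", "replicate", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def write_geotaxis_csv(dataset: pd.DataFrame, path: str | Path) -> None:
    dataset.to_csv(path, index=False)


def read_geotaxis_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"line", "vial", "day", "rep", "successes", "n_flies"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def write_annotations_tsv(annotations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_annotations_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, term = line.split("\t")
            ann.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in ann.items()}


def write_edges_tsv(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, kind in edges:
            fh.write(f"{u}\t{v}\t{kind}\n")


def read_edges_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, v, kind = line.split("\t")
            out.append((u, v, kind))
    return out


def write_truth_json(truth, path: str | Path) -> None:
    """JSON sidecar holding a ground-truth record (any dataclass)."""
    if dataclasses.is_dataclass(truth):
        payload = {"type": type(truth).__name__, **dataclasses.asdict(truth)}
    else:
        payload = dict(truth)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def read_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
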