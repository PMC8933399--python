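"""On-disk formats: labelled matrix CSV, time-series CSV with a JSON sidecar,
and the cohort table.

Matrix dialect: first row and first column carry ROI labels, cells are
weights, UTF-8 with '.' decimal. The reader validates squareness and (for
connectivity matrices) symmetry. Time series are rows = labelled regions,
columns = samples, with sampling rate and band carried in ``<name>.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    BandTimeSeries,
    SubjectRecord,
    TractographySample,
    WeightedNetwork,
    get_band,
)

__all__ = [
    "write_matrix_csv",
    "read_matrix_csv",
    "write_network",
    "read_network",
    "write_tractography",
    "read_tractography",
    "write_timeseries",
    "read_timeseries",
    "write_cohort_table",
    "read_cohort_table",
]


def write_matrix_csv(path, matrix: np.ndarray, labels: Sequence[str]) -> None:
    df = pd.DataFrame(np.asarray(matrix, dtype=float), index=labels, columns=labels)
    df.to_csv(path, encoding="utf-8")


def read_matrix_csv(path, require_symmetric: bool = False) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0, encoding="utf-8", float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    m = df.to_numpy(dtype=float)
    if require_symmetric and not np.allclose(m, m.T, atol=1e-10, rtol=0):
        raise ValueError(f"{path}: matrix is not symmetric")
    return m, [str(c) for c in df.columns]


def write_network(path, net: WeightedNetwork) -> None:
    write_matrix_csv(path, net.weights, net.roi_labels)


def read_network(path, modality: str = "structural", band=None) -> WeightedNetwork:
    m, labels = read_matrix_csv(path, require_symmetric=True)
    band = get_band(band) if band is not None else None
    return WeightedNetwork(m, labels, modality=modality, band=band)


def write_tractography(counts_path, sizes_path, sample: TractographySample) -> None:
    write_matrix_csv(counts_path, sample.counts, sample.roi_labels)
    pd.DataFrame(
        {"roi_label": sample.roi_labels, "size_voxels": sample.roi_sizes}
    ).to_csv(sizes_path, index=False, encoding="utf-8")


def read_tractography(counts_path, sizes_path) -> TractographySample:
    counts, labels = read_matrix_csv(counts_path)
    sizes_df = pd.read_csv(sizes_path, encoding="utf-8", float_precision="round_trip")
    sizes = (
        sizes_df.set_index("roi_label")
        .loc[labels, "size_voxels"]
        .to_numpy(dtype=float)
    )
    return TractographySample(counts, sizes, labels)


def write_timeseries(path, ts: BandTimeSeries) -> None:
    path = Path(path)
    df = pd.DataFrame(ts.data, index=ts.roi_labels)
    df.to_csv(path, header=False, encoding="utf-8")
    sidecar = {"fs": ts.fs, "band": ts.band.name if ts.band else None}
    path.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")


def read_timeseries(path) -> BandTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, header=None, encoding="utf-8", float_precision="round_trip")
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    band = get_band(meta["band"]) if meta.get("band") else None
    return BandTimeSeries(
        df.to_numpy(dtype=float), float(meta["fs"]), band, [str(i) for i in df.index]
    )


def write_cohort_table(path, records: Sequence[SubjectRecord]) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "gf": r.gf,
                "age": r.age,
                "sex": r.sex,
                "education": r.education,
            }
            for r in records
        ]
    ).to_csv(path, index=False, encoding="utf-8")


def read_cohort_table(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    required = {"subject_id", "group", "gf", "age", "sex", "education"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            group=str(row.group),
            gf=float(row.gf),
            age=float(row.age),
            sex=str(row.sex),
            education=float(row.education),
        )
        for row in df.itertuples()
    ]
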