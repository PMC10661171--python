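"""Reading and writing the analysis' file formats.

Tabular data travel as delimited text (TSV/CSV); volumetric data as NIfTI
pairs - a 4-D BOLD volume plus a 3-D integer label volume following the
1000-parcel atlas convention - handled through nibabel.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import TimeSeriesMatrix


def write_timeseries(ts: TimeSeriesMatrix, path) -> None:
    """Time x units matrix as TSV with unit ids in the header."""

    pd.DataFrame(ts.data, columns=[str(u) for u in ts.unit_ids]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_timeseries(path, dt: float, meta: dict | None = None) -> TimeSeriesMatrix:
    table = pd.read_csv(path, sep=None, engine="python")
    return TimeSeriesMatrix(
        table.to_numpy(dtype=float), dt=dt, unit_ids=list(table.columns), meta=meta or {}
    )


def write_matrix(m: np.ndarray, path, labels=None) -> None:
    """Dense matrix as TSV, optionally with row/column labels."""

    labels = None if labels is None else [str(x) for x in labels]
    pd.DataFrame(m, index=labels, columns=labels).to_csv(
        path, sep="\t", index=labels is not None, float_format="%.10g"
    )


def read_fln(path) -> tuple[np.ndarray, list[str]]:
    """Regions x regions connectivity matrix with a header row of names."""

    table = pd.read_csv(path, sep=None, engine="python", index_col=0)
    names = [str(c) for c in table.columns]
    m = table.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("connectivity matrix must be square")
    return m, names


def read_hierarchy(path) -> tuple[np.ndarray, list[str]]:
    """Two-column table (region, h) of hierarchy values."""

    table = pd.read_csv(path, sep=None, engine="python")
    return table.iloc[:, 1].to_numpy(dtype=float), [str(x) for x in table.iloc[:, 0]]


def to_nifti(
    ts: TimeSeriesMatrix,
    voxel_labels: np.ndarray,
    bold_path,
    labels_path,
    shape: tuple[int, int, int] | None = None,
) -> None:
    """Write a voxel series and its parcel labels as a NIfTI pair.

    Voxels are packed into a cuboid grid (padded with zeros / label 0).
    """

    n_vox = ts.data.shape[1]
    if shape is None:
        side = int(np.ceil(n_vox ** (1 / 3)))
        shape = (side, side, int(np.ceil(n_vox / side**2)))
    total = int(np.prod(shape))
    if total < n_vox:
        raise ValueError("grid too small for the voxel count")
    bold = np.zeros((total, ts.data.shape[0]), dtype=np.float32)
    bold[:n_vox] = ts.data.T
    labels = np.zeros(total, dtype=np.int32)
    labels[:n_vox] = np.asarray(voxel_labels, dtype=np.int32)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(bold.reshape(*shape, -1), affine), str(bold_path))
    nib.save(nib.Nifti1Image(labels.reshape(shape), affine), str(labels_path))


def from_nifti(bold_path, labels_path, dt: float) -> tuple[TimeSeriesMatrix, np.ndarray]:
    """Voxel series (time x voxels) and labels from a NIfTI pair.

    Voxels with label 0 (background) are dropped.
    """

    bold = np.asanyarray(nib.load(str(bold_path)).dataobj)
    labels = np.asanyarray(nib.load(str(labels_path)).dataobj)
    if bold.ndim != 4:
        raise ValueError("BOLD volume must be 4-D")
    if labels.shape != bold.shape[:3]:
        raise ValueError("label volume must match the BOLD grid")
    flat = labels.reshape(-1)
    keep = flat > 0
    data = bold.reshape(-1, bold.shape[3])[keep].T
    ts = TimeSeriesMatrix(
        data, dt=dt, unit_ids=[f"v{i}" for i in range(int(keep.sum()))],
        meta={"source": str(Path(bold_path).name)},
    )
    return ts, flat[keep].astype(int)
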