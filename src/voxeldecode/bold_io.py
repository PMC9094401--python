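"""Reading BOLD volumes and single-voxel series.

This module handles the plumbing around the decoding method: loading 4D NIfTI
volumes, mapping MNI (mm) peak coordinates to voxel indices through the image
affine, extracting one voxel's time-series, and (de)serializing labeled series
collections as TSV tables.  A packaged peak table of 25 activation maxima from
a blocked-design SI-vs-VG finger-tapping contrast ships with the package and
is the default set of target voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeSeries",
    "PeakVoxel",
    "BoldSeries",
    "LabeledDataset",
    "FormatError",
    "read_volume_series",
    "mni_to_index",
    "index_to_mni",
    "extract_voxel_series",
    "load_peak_table",
    "packaged_peak_table",
    "read_series_table",
    "write_series_table",
]


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class VolumeSeries:
    """A 4D BOLD acquisition: (x, y, z, time) intensities plus geometry."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 1:
            raise FormatError("time dimension must have length >= 1")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("affine is not invertible")
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class PeakVoxel:
    """One row of an activation peak table: a labeled MNI coordinate."""

    id: int
    region_name: str
    n_voxels: int
    t_value: float
    mni_xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError(f"peak {self.id}: n_voxels must be positive")


@dataclass
class BoldSeries:
    """One voxel's BOLD time-series with sampling interval and provenance.

    ``state_label`` is the task state of the run the series came from
    ("SI" self-initiated, the positive class; "VG" visually guided).
    """

    values: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    state_label: str = ""
    voxel_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a BOLD series must be a 1D vector of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD series contains non-finite values")
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class LabeledDataset:
    """A collection of single-voxel series with state labels per series."""

    series: list[BoldSeries] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.series)

    @property
    def labels(self) -> list[str]:
        return [s.state_label for s in self.series]

    @property
    def subjects(self) -> list[str]:
        return [s.subject_id for s in self.series]

    @property
    def tr_seconds(self) -> float:
        if not self.series:
            raise ValueError("empty dataset has no TR")
        return self.series[0].tr_seconds

    @property
    def n_timepoints(self) -> int:
        if not self.series:
            raise ValueError("empty dataset has no length")
        return len(self.series[0])

    def values_matrix(self) -> np.ndarray:
        """Stack all series into an (n_series, T) matrix."""
        return np.stack([s.values for s in self.series])

    def validate_rectangular(self) -> None:
        lengths = {len(s) for s in self.series}
        if len(lengths) > 1:
            raise FormatError(f"mixed series lengths in dataset: {sorted(lengths)}")
        trs = {s.tr_seconds for s in self.series}
        if len(trs) > 1:
            raise FormatError(f"mixed TR values in dataset: {sorted(trs)}")


def read_volume_series(path: str | Path, tr_seconds: float | None = None) -> VolumeSeries:
    """Read a 4D NIfTI file into a :class:`VolumeSeries`.

    The TR is taken from the header's fourth zoom unless ``tr_seconds``
    overrides it (some converters leave the header TR at 0 or 1).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path.name}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path.name}: expected a 4D volume, got {data.ndim}D")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr_seconds <= 0:
            raise FormatError(
                f"{path.name}: header TR is {tr_seconds}; pass tr_seconds explicitly"
            )
    return VolumeSeries(data=data, affine=np.asarray(img.affine), tr_seconds=tr_seconds)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (unlike banker's rounding)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def mni_to_index(
    affine: np.ndarray,
    mni_xyz: Sequence[float],
    shape: Sequence[int] | None = None,
) -> tuple[int, int, int]:
    """Map a world-space (mm) coordinate to the nearest voxel index.

    Applies the inverse affine and rounds each axis to the nearest integer,
    ties away from zero.  If ``shape`` is given the index is bounds-checked.
    """
    affine = np.asarray(affine, dtype=float)
    homog = np.append(np.asarray(mni_xyz, dtype=float), 1.0)
    voxel = np.linalg.solve(affine, homog)[:3]
    idx = tuple(int(v) for v in _round_half_away(voxel))
    if shape is not None:
        for axis, (i, n) in enumerate(zip(idx, shape[:3])):
            if not 0 <= i < n:
                raise IndexError(
                    f"MNI coordinate {tuple(mni_xyz)} maps to voxel {idx}, outside "
                    f"volume bounds on axis {axis} (size {n})"
                )
    return idx


def index_to_mni(affine: np.ndarray, index: Sequence[int]) -> tuple[float, float, float]:
    """Map a voxel index to its world-space (mm) coordinate."""
    affine = np.asarray(affine, dtype=float)
    homog = np.append(np.asarray(index, dtype=float), 1.0)
    return tuple(float(v) for v in (affine @ homog)[:3])


def extract_voxel_series(
    volume: VolumeSeries,
    index: Sequence[int],
    subject_id: str = "",
    state_label: str = "",
    voxel_id: str = "",
) -> BoldSeries:
    """Pull the single-voxel time-series at ``index`` out of a 4D volume."""
    i, j, k = (int(v) for v in index)
    nx, ny, nz, _ = volume.shape
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        raise IndexError(f"voxel index {(i, j, k)} out of bounds for shape {volume.shape[:3]}")
    return BoldSeries(
        values=np.asarray(volume.data[i, j, k, :], dtype=float),
        tr_seconds=volume.tr_seconds,
        subject_id=subject_id,
        state_label=state_label,
        voxel_id=voxel_id,
    )


_PEAK_COLUMNS = ["id", "region", "n_voxels", "t_value", "x", "y", "z"]


def load_peak_table(
    path: str | Path,
    axis_signs: tuple[int, int, int] = (1, 1, 1),
) -> list[PeakVoxel]:
    """Load a peak-voxel table (TSV or CSV) into a list of :class:`PeakVoxel`.

    Columns: id, region, n_voxels, t_value, x, y, z.  Coordinates are kept
    exactly as printed in the source table; ``axis_signs`` applies an optional
    per-axis sign flip for tables published with unsigned coordinates (left
    hemisphere / posterior structures normally carry negative MNI x / y).
    """
    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        logger.warning("peak table %s is empty", path.name)
        return []
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing peak-table columns {missing}")
    peaks: list[PeakVoxel] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            xyz = tuple(
                float(getattr(row, ax)) * sign
                for ax, sign in zip(("x", "y", "z"), axis_signs)
            )
            peaks.append(
                PeakVoxel(
                    id=int(row.id),
                    region_name=str(row.region),
                    n_voxels=int(row.n_voxels),
                    t_value=float(row.t_value),
                    mni_xyz=xyz,
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path.name}, line {row_no}: {exc}") from exc
    ids = [p.id for p in peaks]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path.name}: duplicate peak ids")
    return peaks


def packaged_peak_table(axis_signs: tuple[int, int, int] = (1, 1, 1)) -> list[PeakVoxel]:
    """The 25-peak SI-vs-VG activation table shipped with the package."""
    ref = resources.files("voxeldecode").joinpath("data/peaks_si_vg.tsv")
    with resources.as_file(ref) as p:
        return load_peak_table(p, axis_signs=axis_signs)


def write_series_table(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a labeled series collection as a wide TSV, one series per row.

    Columns: subject_id, state_label, voxel_id, tr_seconds, v0..v{T-1}.
    """
    dataset.validate_rectangular()
    if not dataset.series:
        raise ValueError("refusing to write an empty dataset")
    t = dataset.n_timepoints
    rows = []
    for s in dataset.series:
        row = {
            "subject_id": s.subject_id,
            "state_label": s.state_label,
            "voxel_id": s.voxel_id,
            "tr_seconds": s.tr_seconds,
        }
        row.update({f"v{i}": s.values[i] for i in range(t)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_series_table(path: str | Path) -> LabeledDataset:
    """Read a series-table TSV back into a :class:`LabeledDataset`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["subject_id", "state_label", "voxel_id", "tr_seconds"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    value_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    value_cols.sort(key=lambda c: int(c[1:]))
    if not value_cols:
        raise FormatError(f"{path.name}: no series value columns (v0, v1, ...)")
    values = df[value_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{path.name}: ragged or incomplete series (NaN values found)")
    series = [
        BoldSeries(
            values=values[i],
            tr_seconds=float(df["tr_seconds"].iloc[i]),
            subject_id=str(df["subject_id"].iloc[i]),
            state_label=str(df["state_label"].iloc[i]),
            voxel_id=str(df["voxel_id"].iloc[i]),
        )
        for i in range(len(df))
    ]
    ds = LabeledDataset(series=series)
    ds.validate_rectangular()
    return ds
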