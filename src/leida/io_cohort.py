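"""Cohort I/O: parcellated time series, manifests, structural matrices, result files.

All analysis inputs are plain delimited text.  A cohort is described by a
manifest table (``subject_id``, ``group``, ``path``, ``tr``) whose ``path``
column points at per-subject parcels-by-frames matrices; results are written
back as TSV (matrices, tidy per-subject metrics) and JSON (comparisons,
configuration) so that every artifact round-trips losslessly through text.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "ParcelTimeSeries",
    "ManifestRecord",
    "CohortManifest",
    "StructuralMatrix",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "load_cohort",
    "read_structural",
    "read_matrix",
    "write_matrix",
    "write_json",
    "read_json",
    "write_results",
]


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class ParcelTimeSeries:
    """One subject's parcellated BOLD recording, stored parcels x frames.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        Free-form group label (e.g. a clinical or performance group).
    data : ndarray, shape (n_parcels, n_frames)
        Signal matrix in arbitrary units; rows are brain parcels.
    tr : float
        Repetition time between frames, in seconds.
    parcel_names : list of str, optional
        Parcel labels, length ``n_parcels``.
    """

    subject_id: str
    group: str
    data: np.ndarray
    tr: float
    parcel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D parcels x frames matrix")
        n, t = self.data.shape
        if n < 2:
            raise ValueError(f"need at least 2 parcels, got {n}")
        if t < 3:
            raise ValueError(f"need at least 3 frames, got {t}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite entries")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.parcel_names is not None and len(self.parcel_names) != n:
            raise ValueError(
                f"parcel_names has length {len(self.parcel_names)}, expected {n}"
            )

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ManifestRecord:
    subject_id: str
    group: str
    path: str
    tr: float


@dataclass
class CohortManifest:
    """Ordered list of subject records; subject ids are unique."""

    records: list[ManifestRecord]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate subject_id(s) in manifest: {sorted(dupes)}")
        for r in self.records:
            if not r.tr > 0:
                raise ValueError(f"subject {r.subject_id}: tr must be > 0, got {r.tr}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.group not in seen:
                seen.append(r.group)
        return seen


@dataclass
class StructuralMatrix:
    """Structural connectome: symmetric non-negative N x N weight matrix."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("structural matrix must be square")
        if np.max(np.abs(self.data - self.data.T)) > 1e-9:
            raise ValueError("structural matrix must be symmetric (tol 1e-9)")
        off = self.data - np.diag(np.diag(self.data))
        if np.any(off < 0):
            raise ValueError("structural weights must be non-negative")


def _read_table(path: Path, delimiter: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, header=None, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed table: {exc}") from exc
    return df


def read_timeseries(
    path: str | os.PathLike,
    orientation: str = "parcels_by_frames",
    *,
    tr: float = 2.0,
    subject_id: str | None = None,
    group: str = "",
    delimiter: str | None = None,
) -> ParcelTimeSeries:
    """Read a delimited numeric matrix into a :class:`ParcelTimeSeries`.

    The matrix is stored internally as parcels x frames regardless of the
    on-disk layout; ``orientation`` declares the layout explicitly (no
    auto-detection: square-ish matrices are ambiguous).
    """
    if orientation not in ("parcels_by_frames", "frames_by_parcels"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    raw = _read_table(path, _delimiter_for(path, delimiter))
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        cell = raw.iat[i, j]
        what = "missing cell" if pd.isna(cell) else f"non-numeric cell {cell!r}"
        raise ValueError(f"{path}: {what} at row {i + 1}, column {j + 1}")
    # str -> float via numpy (correctly rounded); pandas' fast parser is not
    mat = raw.to_numpy().astype(float)
    if orientation == "frames_by_parcels":
        mat = mat.T
    return ParcelTimeSeries(
        subject_id=subject_id if subject_id is not None else path.stem,
        group=group,
        data=mat,
        tr=tr,
    )


def write_timeseries(ts: ParcelTimeSeries, path: str | os.PathLike,
                     delimiter: str | None = None) -> None:
    path = Path(path)
    np.savetxt(path, ts.data, delimiter=_delimiter_for(path, delimiter),
               fmt="%.17g")


_MANIFEST_COLUMNS = ("subject_id", "group", "path", "tr")


def read_manifest(path: str | os.PathLike, delimiter: str | None = None) -> CohortManifest:
    """Read a cohort manifest (header: subject_id, group, path, tr)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            tr = float(row["tr"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: non-numeric tr {row['tr']!r} for subject {row['subject_id']}"
            ) from exc
        records.append(ManifestRecord(str(row["subject_id"]), str(row["group"]),
                                      str(row["path"]), tr))
    return CohortManifest(records)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike,
                   delimiter: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(r) for r in manifest.records],
                      columns=list(_MANIFEST_COLUMNS))
    df.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


def load_cohort(manifest: CohortManifest, base_dir: str | os.PathLike | None = None,
                orientation: str = "parcels_by_frames") -> list[ParcelTimeSeries]:
    """Load every subject referenced by a manifest.

    Relative paths are resolved against ``base_dir`` (defaults to the
    current working directory).
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    out = []
    for rec in manifest.records:
        p = Path(rec.path)
        if not p.is_absolute():
            p = base / p
        out.append(read_timeseries(p, orientation, tr=rec.tr,
                                   subject_id=rec.subject_id, group=rec.group))
    return out


def read_matrix(path: str | os.PathLike, delimiter: str | None = None) -> np.ndarray:
    path = Path(path)
    raw = _read_table(path, _delimiter_for(path, delimiter))
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: non-numeric cell at row {i + 1}, column {j + 1}")
    return raw.to_numpy().astype(float)


def write_matrix(mat: np.ndarray, path: str | os.PathLike,
                 delimiter: str | None = None) -> None:
    path = Path(path)
    np.savetxt(path, np.asarray(mat, dtype=float),
               delimiter=_delimiter_for(path, delimiter), fmt="%.17g")


def read_structural(path: str | os.PathLike, delimiter: str | None = None) -> StructuralMatrix:
    return StructuralMatrix(read_matrix(path, delimiter))


def write_json(obj, path: str | os.PathLike) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")


def read_json(path: str | os.PathLike):
    with open(path) as fh:
        return json.load(fh)


def write_results(out_dir: str | os.PathLike, *, state_model=None,
                  pooled=None, metrics: pd.DataFrame | None = None,
                  comparisons=None, config: dict | None = None) -> dict[str, Path]:
    """Write a result bundle to ``out_dir``; returns name -> path of files written.

    Centroids go to TSV (states x parcels), pooled frame labels to a tidy TSV,
    per-subject metrics to a tidy TSV (one row per subject x state), and
    comparisons / run configuration to JSON.  Values are written at full
    precision so a read-back reproduces them exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if state_model is not None:
        p = out / "centroids.tsv"
        write_matrix(state_model.centroids, p)
        written["centroids"] = p
        if pooled is not None:
            q = out / "labels.tsv"
            pd.DataFrame({
                "subject_id": pooled.subject_index,
                "frame_index": pooled.frame_index,
                "state": state_model.labels,
            }).to_csv(q, sep="\t", index=False)
            written["labels"] = q
        r = out / "state_model.json"
        write_json({
            "k": state_model.k,
            "dunn": state_model.dunn,
            "occupancy": state_model.occupancy,
            "distance": state_model.distance,
        }, r)
        written["state_model"] = r
    if metrics is not None:
        p = out / "metrics.tsv"
        metrics.to_csv(p, sep="\t", index=False, float_format="%.17g")
        written["metrics"] = p
    if comparisons is not None:
        p = out / "comparisons.json"
        write_json(comparisons, p)
        written["comparisons"] = p
    if config is not None:
        p = out / "config.json"
        write_json(config, p)
        written["config"] = p
    return written
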