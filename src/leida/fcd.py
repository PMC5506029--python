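"""Functional connectivity dynamics: time-versus-time similarity of dFC snapshots.

FCD(tx, ty) measures how much the connectivity pattern at frame tx resembles
the one at frame ty.  Four variants are supported, crossing two feature
choices (the N-element leading eigenvector, or the N(N-1)/2 upper-triangle
elements of the full coherence frame) with two similarity measures (cosine
similarity, i.e. the normalized inner product, or Pearson correlation).
Pooling the upper triangle of subjects' FCD matrices gives the group-level
sample of FCD values whose distribution separates cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_cohort import ParcelTimeSeries
from .phase_dfc import EigenvectorSeries, coherence_matrix, estimate_phases

__all__ = [
    "FCDMatrix",
    "PooledFcdSample",
    "dfc_features",
    "fcd_from_features",
    "fcd_matrix",
    "pool_fcd",
]

METHODS = ("cosine", "pearson")
FEATURES = ("eigenvector", "upper_triangle")


@dataclass
class FCDMatrix:
    """Frame x frame similarity matrix for one subject, one method variant."""

    matrix: np.ndarray
    method: str
    features: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.features not in FEATURES:
            raise ValueError(f"features must be one of {FEATURES}")
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("FCD matrix must be square")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PooledFcdSample:
    """Flat sample of off-diagonal FCD values pooled across one group's subjects."""

    values: np.ndarray
    group: str
    n_subjects: int
    n_values: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_values:
            raise ValueError("n_values does not match the stored sample")


def dfc_features(source: ParcelTimeSeries | EigenvectorSeries,
                 features: str = "eigenvector", drop_edges: int = 1) -> np.ndarray:
    """Per-retained-frame dFC feature vectors, one row per frame.

    ``eigenvector`` features come directly from an :class:`EigenvectorSeries`
    (length N per frame); ``upper_triangle`` features are the strictly upper
    triangular coherence values (length N(N-1)/2) and require the raw time
    series, from which phases are re-estimated.
    """
    if features not in FEATURES:
        raise ValueError(f"features must be one of {FEATURES}")
    if features == "eigenvector":
        if isinstance(source, EigenvectorSeries):
            return source.vectors
        from .phase_dfc import eigenvector_series
        return eigenvector_series(source, drop_edges=drop_edges).vectors
    if isinstance(source, EigenvectorSeries):
        raise TypeError("upper_triangle features need the raw ParcelTimeSeries")
    phases = estimate_phases(source)
    retained = np.arange(drop_edges, source.n_frames - drop_edges)
    if retained.size < 2:
        raise ValueError("fewer than 2 retained frames")
    n = source.n_parcels
    iu = np.triu_indices(n, k=1)
    out = np.empty((retained.size, iu[0].size))
    for i, t in enumerate(retained):
        out[i] = coherence_matrix(phases.theta[:, t])[iu]
    return out


def fcd_from_features(feature_rows: np.ndarray, method: str = "cosine") -> np.ndarray:
    """All-pairs similarity of feature rows (cosine or Pearson)."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    f = np.asarray(feature_rows, dtype=float)
    if f.ndim != 2 or f.shape[0] < 2:
        raise ValueError("need a 2-D array with >= 2 feature rows")
    if method == "pearson":
        if np.any(f.std(axis=1) == 0):
            raise ValueError("zero-variance feature vector: Pearson undefined")
        s = np.corrcoef(f)
    else:
        norms = np.linalg.norm(f, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero-norm feature vector: cosine undefined")
        u = f / norms
        s = u @ u.T
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return np.clip(s, -1.0, 1.0)


def fcd_matrix(source: ParcelTimeSeries | EigenvectorSeries,
               method: str = "cosine", features: str = "eigenvector",
               drop_edges: int = 1) -> FCDMatrix:
    """FCD matrix of one subject in the requested method variant."""
    rows = dfc_features(source, features=features, drop_edges=drop_edges)
    return FCDMatrix(fcd_from_features(rows, method=method), method=method,
                     features=features, subject_id=source.subject_id)


def pool_fcd(fcds: list[FCDMatrix], exclusion_band: int = 0,
             group: str = "") -> PooledFcdSample:
    """Pool off-diagonal FCD entries across subjects of one group.

    Only pairs with ``|tx - ty| > exclusion_band`` enter the sample; the
    diagonal is always excluded.  All matrices must share method and features.
    """
    if not fcds:
        raise ValueError("no FCD matrices to pool")
    if exclusion_band < 0:
        raise ValueError("exclusion_band must be >= 0")
    method, features = fcds[0].method, fcds[0].features
    chunks = []
    for f in fcds:
        if (f.method, f.features) != (method, features):
            raise ValueError(
                f"mixed FCD variants: ({f.method}, {f.features}) vs ({method}, {features})"
            )
        iu = np.triu_indices(f.n_frames, k=exclusion_band + 1)
        chunks.append(f.matrix[iu])
    values = np.concatenate(chunks) if chunks else np.empty(0)
    return PooledFcdSample(values=values, group=group, n_subjects=len(fcds),
                           n_values=values.size)
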