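"""Phase-coherence dynamic FC and its leading eigenvector.

The instantaneous coupling between two parcels n and p at frame t is the
cosine of their analytic-signal phase difference,

    dFC(n, p, t) = cos(theta(n, t) - theta(p, t)),

which equals 1 for phase-aligned signals, 0 for orthogonal ones and -1 in
anti-phase.  Writing c = cos(theta(:, t)) and s = sin(theta(:, t)), the frame
is exactly c c^T + s s^T: a positive semidefinite matrix of rank at most 2
whose eigenvalues sum to its trace N.  Its leading eigenvector V1(t) therefore
always carries at least half of the total eigenvalue mass, which is what
justifies summarizing each frame by V1(t) alone (N numbers instead of
N(N-1)/2).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.signal import butter, hilbert, sosfiltfilt

from .io_cohort import ParcelTimeSeries

__all__ = [
    "PhaseSeries",
    "CoherenceFrame",
    "EigenvectorSeries",
    "bandpass",
    "estimate_phases",
    "coherence_frame",
    "coherence_matrix",
    "leading_eigenvector",
    "eigenvector_series",
    "static_fc",
    "canonicalize_sign",
]

logger = logging.getLogger(__name__)


@dataclass
class PhaseSeries:
    """Instantaneous analytic-signal phases, radians, shape (n_parcels, n_frames)."""

    theta: np.ndarray
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be 2-D (parcels x frames)")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta contains non-finite values")

    @property
    def n_parcels(self) -> int:
        return self.theta.shape[0]

    @property
    def n_frames(self) -> int:
        return self.theta.shape[1]


@dataclass
class CoherenceFrame:
    """One instantaneous phase-coherence matrix (symmetric, unit diagonal, PSD rank <= 2)."""

    matrix: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("coherence frame must be square")
        if np.max(np.abs(m - m.T)) > 1e-12:
            raise ValueError("coherence frame must be symmetric (tol 1e-12)")
        if np.max(np.abs(np.diag(m) - 1.0)) > 1e-12:
            raise ValueError("coherence frame diagonal must be 1")


def canonicalize_sign(v: np.ndarray) -> np.ndarray:
    """Return v or -v so the majority of elements are negative.

    Both signs of an eigenvector describe the same bipartition of parcels;
    a fixed convention is needed so that pooled vectors cluster reproducibly.
    On an exact tie in sign counts the element of largest magnitude (first
    such index on a further tie) is made non-positive.  The map is total and
    idempotent: canonicalize_sign(v) == canonicalize_sign(-v).
    """
    v = np.asarray(v, dtype=float)
    n_neg = int(np.sum(v < 0))
    n_pos = int(np.sum(v > 0))
    if n_neg > n_pos:
        return v.copy()
    if n_pos > n_neg:
        return -v
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] > 0 else v.copy()


def bandpass(ts: ParcelTimeSeries, low: float, high: float, order: int = 2) -> ParcelTimeSeries:
    """Zero-phase Butterworth band-pass, applied forward-backward per parcel.

    ``low``/``high`` are in Hz; the admissible band is (0, Nyquist) with
    Nyquist = 1 / (2 * tr).  The default second-order filter matches the
    gentle roll-off conventionally used on BOLD signals (0.01-0.08 Hz).
    """
    nyq = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq:g} Hz)"
        )
    if ts.n_frames <= 3 * order:
        raise ValueError(
            f"series too short ({ts.n_frames} frames) for order-{order} filtering"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    filtered = sosfiltfilt(sos, ts.data, axis=1)
    return ParcelTimeSeries(ts.subject_id, ts.group, filtered, ts.tr, ts.parcel_names)


def estimate_phases(ts: ParcelTimeSeries) -> PhaseSeries:
    """Instantaneous phase per parcel via the analytic signal (Hilbert transform).

    Each parcel series is mean-centered over the full recording, the analytic
    signal is formed over the whole series (no windowing or tapering), and its
    angle is returned in (-pi, pi].
    """
    sd = ts.data.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        name = (ts.parcel_names[zero[0]] if ts.parcel_names is not None
                else f"#{zero[0]}")
        raise ValueError(f"parcel {name} has zero variance; phase is undefined")
    centered = ts.data - ts.data.mean(axis=1, keepdims=True)
    theta = np.angle(hilbert(centered, axis=1))
    return PhaseSeries(theta=theta, tr=ts.tr, subject_id=ts.subject_id)


def coherence_matrix(theta_t: np.ndarray) -> np.ndarray:
    """cos(theta_n - theta_p) for one frame's phase vector (exactly symmetric)."""
    theta_t = np.asarray(theta_t, dtype=float)
    return np.cos(theta_t[:, None] - theta_t[None, :])


def coherence_frame(phases: PhaseSeries, t: int) -> CoherenceFrame:
    """Phase-coherence matrix at frame ``t``."""
    if not (0 <= t < phases.n_frames):
        raise IndexError(f"frame {t} out of range [0, {phases.n_frames})")
    return CoherenceFrame(coherence_matrix(phases.theta[:, t]), frame_index=t)


_DEGENERACY_TOL = 1e-9


def leading_eigenvector(frame: CoherenceFrame | np.ndarray) -> tuple[np.ndarray, float, float]:
    """Leading eigenpair of a coherence frame.

    Returns ``(vector, eigenvalue, fraction)`` where ``vector`` is the
    unit-norm, sign-canonical eigenvector of the largest eigenvalue and
    ``fraction`` is that eigenvalue's share of the eigenvalue sum (= trace).
    Fraction is always >= 0.5: the frame has rank <= 2, so the two nonzero
    eigenvalues sum to N and the larger one is at least N/2.
    """
    m = frame.matrix if isinstance(frame, CoherenceFrame) else np.asarray(frame, float)
    n = m.shape[0]
    if m.ndim != 2 or m.shape[1] != n:
        raise ValueError("input must be square")
    if np.max(np.abs(m - m.T)) > 1e-9:
        raise ValueError("matrix is not symmetric within tolerance")
    if n == 2:
        vals, vecs = eigh(m)
    else:
        vals, vecs = eigh(m, subset_by_index=[n - 2, n - 1])
    lam1, lam2 = float(vals[-1]), float(vals[-2])
    if abs(lam1 - lam2) <= _DEGENERACY_TOL * n:
        warnings.warn(
            f"degenerate leading eigenvalue (lambda1={lam1:.6g}, lambda2={lam2:.6g}); "
            "eigenvector choice is solver-determined",
            RuntimeWarning,
        )
    v = vecs[:, -1]
    v = v / np.linalg.norm(v)
    trace = float(np.trace(m))
    return canonicalize_sign(v), lam1, lam1 / trace


@dataclass
class EigenvectorSeries:
    """Per-frame leading eigenvectors of one subject's coherence frames.

    ``vectors`` has one unit-norm, sign-canonical row per retained frame;
    ``retained_frames`` indexes those rows back into the original recording.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    eigenvalue_fraction: np.ndarray
    retained_frames: np.ndarray
    subject_id: str
    tr: float
    group: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvalue_fraction = np.asarray(self.eigenvalue_fraction, dtype=float)
        self.retained_frames = np.asarray(self.retained_frames, dtype=int)
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-10:
            raise ValueError("eigenvector rows must be unit norm")
        if np.min(self.eigenvalue_fraction) < 0.5 - 1e-9:
            raise ValueError("eigenvalue fraction below 0.5 — not a coherence frame series")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.vectors.shape[1]


def eigenvector_series(ts: ParcelTimeSeries, drop_edges: int = 1) -> EigenvectorSeries:
    """Leading-eigenvector time course of a (band-limited) recording.

    The analytic signal distorts the first and last frames, so ``drop_edges``
    frames are discarded at each end (default 1).  The input is assumed
    band-limited already; call :func:`bandpass` first otherwise.
    """
    if drop_edges < 0:
        raise ValueError("drop_edges must be >= 0")
    retained = np.arange(drop_edges, ts.n_frames - drop_edges)
    if retained.size < 2:
        raise ValueError(
            f"only {retained.size} frames retained after dropping {drop_edges} per edge"
        )
    phases = estimate_phases(ts)
    n = ts.n_parcels
    vectors = np.empty((retained.size, n))
    eigenvalues = np.empty(retained.size)
    fractions = np.empty(retained.size)
    for i, t in enumerate(retained):
        v, lam, frac = leading_eigenvector(coherence_frame(phases, int(t)))
        vectors[i] = v
        eigenvalues[i] = lam
        fractions[i] = frac
    logger.info(
        "eigenvector_series subject=%s n_parcels=%d frames_retained=%d drop_edges=%d",
        ts.subject_id, n, retained.size, drop_edges,
    )
    return EigenvectorSeries(vectors, eigenvalues, fractions, retained,
                             subject_id=ts.subject_id, tr=ts.tr, group=ts.group)


def static_fc(ts: ParcelTimeSeries) -> np.ndarray:
    """Static FC: Pearson (zero-lag) correlation of parcel signals over the recording."""
    sd = ts.data.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        name = (ts.parcel_names[zero[0]] if ts.parcel_names is not None
                else f"#{zero[0]}")
        raise ValueError(f"parcel {name} has zero variance; correlation is undefined")
    fc = np.corrcoef(ts.data)
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)
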