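"""Gaussian hidden Markov model over leading-eigenvector sequences.

Alternative state estimator to pooled k-means: each state emits eigenvectors
from a Gaussian with a state-specific mean and one covariance matrix shared
by all states (tied covariance), and a Markov chain governs the state
sequence.  Unlike k-means this respects the temporal order of frames, which
in practice yields slightly longer state visits.  Subject boundaries are
respected during fitting — no transition is counted across subjects.

The EM machinery is hmmlearn's ``GaussianHMM`` with ``covariance_type="tied"``;
initialization comes from a seeded k-means solution so that a fit is fully
determined by its seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .phase_dfc import EigenvectorSeries

__all__ = ["HmmModel", "fit_hmm", "decode_states"]

logger = logging.getLogger(__name__)


@dataclass
class HmmModel:
    """Fitted tied-covariance Gaussian HMM.

    ``transition`` rows sum to 1, ``initial`` sums to 1, and the EM
    log-likelihood trace is non-decreasing (up to numerical slack).
    """

    k: int
    means: np.ndarray
    shared_covariance: np.ndarray
    transition: np.ndarray
    initial: np.ndarray
    log_likelihood_trace: np.ndarray
    _hmm: GaussianHMM = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.shared_covariance = np.asarray(self.shared_covariance, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.log_likelihood_trace = np.asarray(self.log_likelihood_trace, dtype=float)
        if np.max(np.abs(self.transition.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > 1e-10:
            raise ValueError("initial probabilities must sum to 1")


def _as_rows(sequences) -> tuple[np.ndarray, np.ndarray]:
    rows, lengths = [], []
    for s in sequences:
        x = s.vectors if isinstance(s, EigenvectorSeries) else np.asarray(s, float)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValueError("each sequence must be 2-D with >= 2 frames")
        rows.append(x)
        lengths.append(x.shape[0])
    if not rows:
        raise ValueError("no sequences supplied")
    return np.vstack(rows), np.asarray(lengths, dtype=int)


def _kmeans_init(x: np.ndarray, lengths: np.ndarray, k: int, seed: int):
    """Means/startprob/transmat/tied covariance from a seeded k-means labeling."""
    from sklearn.cluster import KMeans

    n, d = x.shape
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=5, random_state=int(seed) % (2**31))
        labels = km.fit_predict(x)
    means = np.vstack([x[labels == c].mean(axis=0) if np.any(labels == c)
                       else x[np.random.default_rng(seed + c).integers(n)]
                       for c in range(k)])
    # pooled within-class scatter, ridge-stabilized
    resid = x - means[labels]
    cov = resid.T @ resid / max(n - 1, 1)
    cov += np.eye(d) * (1e-6 * np.trace(cov) / d + 1e-12)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    startprob = np.bincount(labels[starts], minlength=k) + 1.0
    startprob /= startprob.sum()
    trans = np.ones((k, k))  # add-one smoothing
    for s, ln in zip(starts, lengths):
        seq = labels[s:s + ln]
        np.add.at(trans, (seq[:-1], seq[1:]), 1.0)
    trans /= trans.sum(axis=1, keepdims=True)
    return means, startprob, trans, cov


def fit_hmm(sequences, k: int, seed: int = 0, max_iter: int = 100,
            tol: float = 1e-4) -> HmmModel:
    """Fit a k-state tied-covariance Gaussian HMM to per-subject sequences.

    ``sequences`` is a list of :class:`EigenvectorSeries` or raw
    (frames x parcels) arrays; EM runs over the joint multi-sequence
    likelihood, stopping when the gain drops below ``tol`` or after
    ``max_iter`` iterations.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x, lengths = _as_rows(sequences)
    means, startprob, trans, cov = _kmeans_init(x, lengths, k, seed)
    hmm = GaussianHMM(n_components=k, covariance_type="tied", n_iter=max_iter,
                      tol=tol, random_state=int(seed) % (2**31),
                      init_params="", params="stmc", min_covar=1e-6)
    hmm.startprob_ = startprob
    hmm.transmat_ = trans
    hmm.means_ = means
    hmm.covars_ = cov
    hmm.fit(x, lengths)
    trace = np.asarray(hmm.monitor_.history, dtype=float)
    logger.info("fit_hmm k=%d n_rows=%d n_sequences=%d iters=%d loglik=%.6g",
                k, x.shape[0], len(lengths), trace.size,
                trace[-1] if trace.size else float("nan"))
    return HmmModel(k=k, means=hmm.means_.copy(),
                    shared_covariance=np.asarray(hmm.covars_)[0].copy()
                    if np.asarray(hmm.covars_).ndim == 3 else np.asarray(hmm.covars_).copy(),
                    transition=hmm.transmat_.copy(), initial=hmm.startprob_.copy(),
                    log_likelihood_trace=trace, _hmm=hmm)


def decode_states(model: HmmModel, sequences, algorithm: str = "viterbi") -> list[np.ndarray]:
    """Most-probable state path per subject, labels in 1..k.

    ``algorithm`` is ``"viterbi"`` (joint most-probable path, default) or
    ``"map"`` (per-frame posterior argmax).
    """
    if algorithm not in ("viterbi", "map"):
        raise ValueError("algorithm must be 'viterbi' or 'map'")
    if model._hmm is None:
        raise ValueError("model carries no fitted decoder")
    out = []
    for s in sequences:
        x = s.vectors if isinstance(s, EigenvectorSeries) else np.asarray(s, float)
        if x.shape[1] != model.means.shape[1]:
            raise ValueError(
                f"sequence has {x.shape[1]} parcels, model expects {model.means.shape[1]}"
            )
        if algorithm == "viterbi":
            _, path = model._hmm.decode(x, algorithm="viterbi")
        else:
            path = model._hmm.predict_proba(x).argmax(axis=1)
        out.append(path.astype(int) + 1)
    return out
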