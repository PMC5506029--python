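"""Recurrent FC states: pooled k-means on leading eigenvectors.

Leading eigenvectors of all subjects' retained frames are pooled into one
matrix and clustered; each cluster centroid V_C is a recurrent dominant
connectivity pattern ("FC state") whose sign structure bipartitions the
parcels into two communities.  The number of states is chosen by the Dunn
validity index (minimum between-cluster distance over maximum cluster
diameter), states are ranked by their pooled probability of occurrence, and
the static FC can be approximated as the occupancy-weighted sum of either
the centroid outer products V_C V_C^T or the per-state mean coherence frames.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .io_cohort import StructuralMatrix
from .phase_dfc import EigenvectorSeries, canonicalize_sign

__all__ = [
    "PooledEigenvectors",
    "StateModel",
    "StateMeanDfc",
    "ReconstructionResult",
    "pool_eigenvectors",
    "cluster_states",
    "dunn_score",
    "select_k",
    "state_mean_dfc",
    "reconstruct_static_fc",
    "sc_similarity",
]

logger = logging.getLogger(__name__)

DISTANCES = ("cosine", "euclidean")


@dataclass
class PooledEigenvectors:
    """All subjects' leading eigenvectors stacked row-wise, with provenance."""

    matrix: np.ndarray
    subject_index: np.ndarray  # per-row subject id (object array of str)
    frame_index: np.ndarray    # per-row retained-frame index in the recording

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.subject_index = np.asarray(self.subject_index)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if not (len(self.matrix) == len(self.subject_index) == len(self.frame_index)):
            raise ValueError("row metadata length mismatch")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


def pool_eigenvectors(series: list[EigenvectorSeries]) -> PooledEigenvectors:
    """Stack per-subject eigenvector series into one pooled matrix."""
    if not series:
        raise ValueError("no eigenvector series to pool")
    mats = [s.vectors for s in series]
    subj = np.concatenate([np.repeat(s.subject_id, s.n_frames) for s in series])
    frames = np.concatenate([s.retained_frames for s in series])
    return PooledEigenvectors(np.vstack(mats), subj, frames)


@dataclass
class StateModel:
    """k-means solution over pooled eigenvectors, occupancy-ranked.

    ``centroids[c]`` is the renormalized, sign-canonical mean vector of state
    c+1; ``labels`` assigns every pooled row a state in 1..k; ``occupancy``
    is non-increasing and the centroid order matches it.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    dunn: float
    occupancy: np.ndarray
    distance: str = "cosine"
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.centroids.shape[0] != self.k or self.occupancy.shape[0] != self.k:
            raise ValueError("centroid/occupancy count must equal k")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if abs(self.occupancy.sum() - 1.0) > 1e-12:
            raise ValueError("occupancy must sum to 1")
        if np.any(np.diff(self.occupancy) > 1e-15):
            raise ValueError("occupancy must be non-increasing after ranking")


def _pairwise(x: np.ndarray, y: np.ndarray, distance: str) -> np.ndarray:
    if distance == "cosine":
        return cdist(x, y, metric="cosine")
    return cdist(x, y, metric="euclidean")


def _assign(x: np.ndarray, centroids: np.ndarray, distance: str) -> tuple[np.ndarray, np.ndarray]:
    d = _pairwise(x, centroids, distance)
    labels = d.argmin(axis=1)
    return labels, d[np.arange(len(x)), labels]


def _distinct_row_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random row sampling, resampled until the k seeds are pairwise distinct."""
    n = x.shape[0]
    for _ in range(50):
        idx = rng.choice(n, size=k, replace=False)
        seeds = x[idx]
        if len(np.unique(seeds.round(12), axis=0)) == k:
            return seeds.copy()
    return seeds.copy()  # fewer than k distinct rows exist; let Lloyd handle it


def _lloyd_cosine(x: np.ndarray, k: int, rng: np.random.Generator,
                  max_iter: int = 300, reseed_attempts: int = 5):
    """One spherical k-means run: cosine assignment, renormalized mean update."""
    n = x.shape[0]
    for _ in range(reseed_attempts):
        centroids = _distinct_row_init(x, k, rng)
        labels = np.full(n, -1)
        degenerate = False
        for _ in range(max_iter):
            new_labels, dmin = _assign(x, centroids, "cosine")
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = x[labels == c]
                if members.shape[0] == 0:
                    degenerate = True
                    break
                mu = members.mean(axis=0)
                norm = np.linalg.norm(mu)
                if norm == 0:
                    degenerate = True
                    break
                centroids[c] = mu / norm
            if degenerate:
                break
        if degenerate:
            logger.info("empty cluster during spherical k-means; re-seeding replicate")
            continue
        _, dmin = _assign(x, centroids, "cosine")
        return labels, centroids, float(dmin.sum())
    raise RuntimeError("all re-seed attempts produced an empty cluster")


def cluster_states(pooled: PooledEigenvectors, k: int, replicates: int = 20,
                   distance: str = "cosine", seed: int = 0) -> StateModel:
    """Best-of-``replicates`` k-means over pooled eigenvectors.

    The cosine metric (default, natural for unit-norm vectors) uses a
    spherical Lloyd iteration; the euclidean metric delegates to
    scikit-learn's KMeans.  The replicate with the lowest within-cluster
    dissimilarity sum wins; its centroids are renormalized means,
    sign-canonicalized, and states are relabeled in descending order of
    pooled occupancy.
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if k < 2:
        raise ValueError("k must be >= 2")
    x = pooled.matrix
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the {x.shape[0]} pooled rows")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    if distance == "euclidean":
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=k, n_init=replicates, init="random",
                    random_state=int(seed) % (2**31))
        labels0 = km.fit_predict(x)
        centroids0 = km.cluster_centers_.copy()
        inertia = float(km.inertia_)
    else:
        ss = np.random.SeedSequence([int(seed), k])
        best = None
        for child in ss.spawn(replicates):
            rng = np.random.default_rng(child)
            try:
                labels_r, centroids_r, inertia_r = _lloyd_cosine(x, k, rng)
            except RuntimeError:
                logger.info("replicate degenerate (persistent empty cluster); skipped")
                continue
            if best is None or inertia_r < best[2]:
                best = (labels_r, centroids_r, inertia_r)
        if best is None:
            raise RuntimeError(f"all {replicates} k-means replicates degenerate at k={k}")
        labels0, centroids0, inertia = best

    # occupancy ranking (stable: ties keep original cluster order)
    counts = np.bincount(labels0, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels0] + 1
    centroids = centroids0[order]
    occupancy = counts[order] / counts.sum()

    # canonical stored form: renormalized means with the majority-negative sign
    norms = np.linalg.norm(centroids, axis=1, keepdims=True)
    centroids = centroids / np.where(norms == 0, 1.0, norms)
    centroids = np.array([canonicalize_sign(c) for c in centroids])

    dunn = dunn_score(x, labels, distance=distance)
    logger.info("cluster_states k=%d replicates=%d distance=%s inertia=%.6g dunn=%.6g",
                k, replicates, distance, inertia, dunn)
    return StateModel(k=k, centroids=centroids, labels=labels, dunn=dunn,
                      occupancy=occupancy, distance=distance, inertia=inertia)


def dunn_score(x: np.ndarray, labels: np.ndarray, distance: str = "cosine") -> float:
    """Dunn validity index: min inter-cluster distance / max cluster diameter.

    Inter-cluster distance is single linkage (minimum pairwise distance
    between the two point sets); diameter is the maximum intra-cluster
    pairwise distance.  Returns +inf when every cluster has zero diameter.
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Dunn score needs >= 2 clusters")
    groups = [x[labels == c] for c in uniq]
    if any(g.shape[0] == 0 for g in groups):
        raise ValueError("empty cluster")
    min_inter = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            min_inter = min(min_inter, _pairwise(groups[i], groups[j], distance).min())
    max_diam = 0.0
    for g in groups:
        if g.shape[0] > 1:
            max_diam = max(max_diam, _pairwise(g, g, distance).max())
    if max_diam == 0.0:
        return float("inf")
    return float(min_inter / max_diam)


def select_k(pooled: PooledEigenvectors, k_range, replicates: int = 20,
             distance: str = "cosine", seed: int = 0) -> tuple[StateModel, pd.DataFrame]:
    """Fit every k in ``k_range`` and return the Dunn-best model (ties -> smaller k)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    rows = []
    best_model = None
    for k in ks:
        model = cluster_states(pooled, k, replicates=replicates,
                               distance=distance, seed=seed)
        occ = model.occupancy
        entropy = float(-(occ[occ > 0] * np.log(occ[occ > 0])).sum())
        rows.append({"k": k, "dunn": model.dunn, "inertia": model.inertia,
                     "occupancy_entropy": entropy})
        if best_model is None or model.dunn > best_model.dunn:
            best_model = model
    return best_model, pd.DataFrame(rows)


@dataclass
class StateMeanDfc:
    """Per-state elementwise mean of the coherence frames assigned to it."""

    per_state: np.ndarray  # (k, N, N)
    counts: np.ndarray     # frames per state

    def __post_init__(self) -> None:
        self.per_state = np.asarray(self.per_state, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.per_state.ndim != 3:
            raise ValueError("per_state must be (k, N, N)")

    @property
    def k(self) -> int:
        return self.per_state.shape[0]


def state_mean_dfc(frames, labels, k: int | None = None) -> StateMeanDfc:
    """Average coherence frames per assigned state.

    ``frames`` is an array (n, N, N) or any iterable of N x N matrices
    aligned with ``labels`` (states in 1..k); iterables are consumed
    streamingly so whole-cohort frame stacks never need to be materialized.
    """
    labels = np.asarray(labels, dtype=int)
    if k is None:
        k = int(labels.max())
    if labels.min() < 1 or labels.max() > k:
        raise ValueError("labels must lie in 1..k")
    sums = None
    counts = np.zeros(k, dtype=int)
    for mat, lab in zip(frames, labels, strict=True):
        mat = np.asarray(mat, dtype=float)
        if sums is None:
            sums = np.zeros((k,) + mat.shape)
        sums[lab - 1] += mat
        counts[lab - 1] += 1
    if sums is None:
        raise ValueError("no frames supplied")
    if np.any(counts == 0):
        missing = np.flatnonzero(counts == 0) + 1
        raise ValueError(f"state(s) {missing.tolist()} have zero frames")
    return StateMeanDfc(sums / counts[:, None, None], counts)


@dataclass
class ReconstructionResult:
    outer_product: np.ndarray
    mean_dfc: np.ndarray | None = None
    r_outer: float | None = None
    r_mean_dfc: float | None = None


def _triu_vec(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    return m[np.triu_indices(n, k=1)]


def reconstruct_static_fc(model: StateModel, mean_dfc: StateMeanDfc | None = None,
                          static_fc: np.ndarray | None = None) -> ReconstructionResult:
    """Occupancy-weighted reconstructions of the static FC from state patterns.

    The outer-product reconstruction is sum_c P_c V_c V_c^T (symmetric PSD);
    with ``mean_dfc`` given, sum_c P_c FC_c is also formed.  If a static FC is
    supplied, the Pearson correlation between each reconstruction's upper
    triangle and the static FC's is reported.
    """
    if abs(model.occupancy.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must sum to 1")
    outer = np.einsum("c,ci,cj->ij", model.occupancy, model.centroids, model.centroids)
    outer = (outer + outer.T) / 2.0
    mean_recon = None
    if mean_dfc is not None:
        if mean_dfc.k != model.k:
            raise ValueError("mean_dfc state count does not match the model")
        mean_recon = np.tensordot(model.occupancy, mean_dfc.per_state, axes=1)
        mean_recon = (mean_recon + mean_recon.T) / 2.0
    r_outer = r_mean = None
    if static_fc is not None:
        target = _triu_vec(np.asarray(static_fc, dtype=float))
        r_outer = float(pearsonr(_triu_vec(outer), target)[0])
        if mean_recon is not None:
            r_mean = float(pearsonr(_triu_vec(mean_recon), target)[0])
    return ReconstructionResult(outer, mean_recon, r_outer, r_mean)


def sc_similarity(sc: StructuralMatrix | np.ndarray, mean_dfc: StateMeanDfc) -> np.ndarray:
    """Cosine similarity between the SC and each state's mean FC (upper triangles)."""
    mat = sc.data if isinstance(sc, StructuralMatrix) else np.asarray(sc, dtype=float)
    if mat.shape[0] != mean_dfc.per_state.shape[1]:
        raise ValueError("structural matrix size does not match the states")
    a = _triu_vec(mat)
    na = np.linalg.norm(a)
    if na == 0:
        raise ValueError("structural matrix upper triangle has zero norm")
    out = np.empty(mean_dfc.k)
    for c in range(mean_dfc.k):
        b = _triu_vec(mean_dfc.per_state[c])
        nb = np.linalg.norm(b)
        if nb == 0:
            raise ValueError(f"state {c + 1} mean FC upper triangle has zero norm")
        out[c] = float(a @ b / (na * nb))
    return out
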