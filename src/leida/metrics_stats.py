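"""Switching metrics per subject and group-level statistics.

From a subject's state label sequence we derive: fractional occupancy (the
probability of occurrence of each state), mean lifetimes (mean duration of
maximal runs, in seconds), the switching frequency (reciprocal of the overall
mean lifetime, in Hz), and the transition matrix over observed switches
(self-transitions excluded, rows renormalized).  Groups are compared with a
two-sample Kolmogorov-Smirnov test on pooled FCD values and with unpaired
permutation t-tests (label shuffles, add-one p estimator) on per-subject
metrics — metrics are always computed per subject first and compared across
subjects, never pooled across subjects before testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectStateMetrics",
    "GroupComparison",
    "KsResult",
    "occupancy",
    "lifetimes",
    "switching_frequency",
    "transition_matrix",
    "subject_state_metrics",
    "metrics_table",
    "ks_compare",
    "permutation_ttest",
    "compare_state_metrics",
]


def _check_labels(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or labels.size < 1:
        raise ValueError("labels must be a non-empty 1-D sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    return labels


def occupancy(labels, k: int) -> np.ndarray:
    """Fractional occupancy: fraction of frames spent in each state (sums to 1)."""
    labels = _check_labels(labels, k)
    return np.bincount(labels, minlength=k + 1)[1:] / labels.size


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encoding: (state of each run, length of each run)."""
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return labels[starts], ends - starts


def lifetimes(labels, tr: float, k: int | None = None,
              include_truncated: bool = True) -> tuple[np.ndarray, float]:
    """Mean state lifetimes in seconds: per state and overall.

    A lifetime is the duration of a maximal run of consecutive identical
    labels, ``run length x tr``.  The first and last runs are truncated by
    the recording window; they are included by default and can be dropped
    with ``include_truncated=False``.  States never visited get NaN (not 0).
    Returns ``(per_state_mean_s, overall_mean_s)``.
    """
    if not tr > 0:
        raise ValueError("tr must be positive")
    labels = np.asarray(labels, dtype=int)
    if k is None:
        k = int(labels.max())
    labels = _check_labels(labels, k)
    run_states, run_lengths = _runs(labels)
    if not include_truncated:
        run_states = run_states[1:-1]
        run_lengths = run_lengths[1:-1]
    per_state = np.full(k, np.nan)
    for c in range(1, k + 1):
        mask = run_states == c
        if mask.any():
            per_state[c - 1] = run_lengths[mask].mean() * tr
    overall = run_lengths.mean() * tr if run_lengths.size else float("nan")
    return per_state, float(overall)


def switching_frequency(labels, tr: float) -> float:
    """Transitions per second: reciprocal of the overall mean lifetime.

    A recording with no transitions is one full-length run, so the frequency
    is 1 / (T * tr).
    """
    _, overall = lifetimes(labels, tr)
    return 1.0 / overall


def transition_matrix(labels, k: int) -> np.ndarray:
    """Switching profile: probability of moving from each state to each other state.

    Consecutive same-state pairs are ignored; each row with at least one
    observed switch is normalized to sum to 1, the diagonal is 0, and rows
    with no switches are NaN (undefined, not zero).
    """
    labels = _check_labels(labels, k)
    counts = np.zeros((k, k))
    a, b = labels[:-1], labels[1:]
    switch = a != b
    np.add.at(counts, (a[switch] - 1, b[switch] - 1), 1.0)
    row_sums = counts.sum(axis=1)
    out = np.full((k, k), np.nan)
    defined = row_sums > 0
    out[defined] = counts[defined] / row_sums[defined, None]
    return out


@dataclass
class SubjectStateMetrics:
    """All switching metrics of one subject's label sequence."""

    subject_id: str
    group: str
    occupancy: np.ndarray
    mean_lifetime_s: np.ndarray      # per state, NaN where unvisited
    overall_lifetime_s: float
    switching_frequency_hz: float
    transition: np.ndarray           # k x k, NaN rows where undefined


def subject_state_metrics(labels, k: int, tr: float, subject_id: str = "",
                          group: str = "") -> SubjectStateMetrics:
    labels = _check_labels(labels, k)
    occ = occupancy(labels, k)
    per_state, overall = lifetimes(labels, tr, k)
    return SubjectStateMetrics(
        subject_id=subject_id, group=group, occupancy=occ,
        mean_lifetime_s=per_state, overall_lifetime_s=overall,
        switching_frequency_hz=1.0 / overall,
        transition=transition_matrix(labels, k),
    )


def metrics_table(metrics: list[SubjectStateMetrics]) -> pd.DataFrame:
    """Tidy per-subject metrics: one row per subject x state."""
    rows = []
    for m in metrics:
        for c in range(len(m.occupancy)):
            rows.append({
                "subject_id": m.subject_id,
                "group": m.group,
                "state": c + 1,
                "occupancy": m.occupancy[c],
                "mean_lifetime_s": m.mean_lifetime_s[c],
                "overall_lifetime_s": m.overall_lifetime_s,
                "switching_frequency_hz": m.switching_frequency_hz,
            })
    return pd.DataFrame(rows)


@dataclass
class KsResult:
    ks_distance: float
    p_value: float
    n_a: int
    n_b: int


def ks_compare(sample_a, sample_b) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test: sup |ECDF_a - ECDF_b|, asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KsResult(float(res.statistic), float(res.pvalue), a.size, b.size)


@dataclass
class GroupComparison:
    metric: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    n_a: int = 0
    n_b: int = 0


def _tstat(ma, mb, va, vb, na, nb):
    """Pooled-variance two-sample t; 0/0 (no variance, equal means) -> 0."""
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        signed_inf = np.where(np.asarray(diff) > 0, np.inf, -np.inf)
        return np.where(denom == 0, np.where(diff == 0, 0.0, signed_inf), t)


def permutation_ttest(values_a, values_b, n_permutations: int = 5000,
                      seed: int = 0, metric: str = "") -> GroupComparison:
    """Unpaired two-sample permutation t-test with the add-one p estimator.

    The observed pooled-variance t statistic is referenced to a null built by
    shuffling group labels ``n_permutations`` times; the two-sided p-value is
    ``(1 + #{|t_perm| >= |t_obs|}) / (n_permutations + 1)``, which is bounded
    below by 1/(n_permutations + 1) and never exactly zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    na, nb = a.size, b.size
    t_obs = float(_tstat(a.mean(), b.mean(), a.var(ddof=1), b.var(ddof=1), na, nb))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_permutations, 1)), axis=1)
    pa, pb = perms[:, :na], perms[:, na:]
    t_null = _tstat(pa.mean(1), pb.mean(1), pa.var(1, ddof=1), pb.var(1, ddof=1), na, nb)
    count = int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))
    p = (1.0 + count) / (n_permutations + 1.0)
    return GroupComparison(
        metric=metric, mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)), sem_b=float(stats.sem(b)),
        statistic=t_obs, p_value=float(p), n_permutations=n_permutations,
        seed=seed, n_a=na, n_b=nb,
    )


def compare_state_metrics(table: pd.DataFrame, group_a: str, group_b: str,
                          n_permutations: int = 5000, seed: int = 0) -> list[GroupComparison]:
    """Permutation t-tests on every per-state and subject-level metric.

    ``table`` is the tidy frame from :func:`metrics_table`.  Per-state
    occupancy and lifetime are tested state by state; overall lifetime and
    switching frequency once per subject.  Subjects with an undefined value
    (state never visited) are dropped from that state's test.
    """
    results = []
    rng = np.random.default_rng(seed)
    states = sorted(table["state"].unique())

    def _vals(g, col, state=None):
        sub = table[table["group"] == g]
        if state is not None:
            sub = sub[sub["state"] == state]
        else:
            sub = sub.drop_duplicates("subject_id")
        return sub[col].dropna().to_numpy()

    for col in ("occupancy", "mean_lifetime_s"):
        for s in states:
            a, b = _vals(group_a, col, s), _vals(group_b, col, s)
            results.append(permutation_ttest(
                a, b, n_permutations, seed=int(rng.integers(2**31)),
                metric=f"{col}[state {s}]"))
    for col in ("overall_lifetime_s", "switching_frequency_hz"):
        a, b = _vals(group_a, col), _vals(group_b, col)
        results.append(permutation_ttest(
            a, b, n_permutations, seed=int(rng.integers(2**31)), metric=col))
    return results
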