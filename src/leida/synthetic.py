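"""Synthetic switching cohorts with planted phase-locking ground truth.

Each subject is a narrow-band multivariate signal that switches among a small
set of planted sign patterns via a Markov chain.  Within a frame, every
parcel oscillates on a common carrier (default 0.04 Hz, the center of the
0.01-0.08 Hz BOLD band) and parcels on the negative side of the active
pattern are offset by pi, so the noiseless phase-coherence matrix of that
frame is exactly the pattern's outer product s s^T and its leading
eigenvector is the (canonicalized) pattern itself.  Independent Gaussian
phase noise and multiplicative amplitude noise corrupt the readout; the two
cohort groups differ only in their transition matrices (dwell structure),
never in pattern shape.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_cohort import (CohortManifest, ManifestRecord, ParcelTimeSeries,
                        write_json, write_manifest, write_timeseries)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "planted_sign_patterns",
    "dwell_transition",
    "sample_state_sequence",
    "render_bold",
    "simulate_cohort",
    "generate_cohort",
]


def planted_sign_patterns(n_parcels: int, k: int, margin: int | None = None) -> np.ndarray:
    """k mutually orthogonal +/-1 phase-locking patterns, each majority-negative.

    Each pattern splits the parcels into two anti-phase communities.  Two
    deliberate geometric properties make the patterns well-behaved under the
    leading-eigenvector readout:

    * exact orthogonality — for orthogonal sign patterns the phase-coherence
      matrix of a frame caught mid-transition is diagonal in the span of the
      two patterns, so the leading eigenvector jumps abruptly from one
      pattern to the other instead of rotating through intermediates (the
      abrupt eigenvector switching characteristic of real recordings);
    * a strict negative sign majority — an exactly balanced community split
      sits on the sign-canonicalization tie boundary, where noise flips the
      canonical orientation frame by frame and splits one planted pattern
      into two antipodal clusters.

    Both hold at once because multiplying Hadamard rows elementwise by one
    fixed sign mask preserves their pairwise orthogonality while shifting
    every row's element sum; a deterministic search finds a mask that gives
    every row an element sum of at most ``-margin`` (default
    ``n_parcels // 4 + 2`` rounded to even, uniform across rows when the
    random search finds such a mask quickly, otherwise relaxed by a local
    search).  Requires ``n_parcels`` to be a power of two with
    ``k < n_parcels``; pass explicit ``patterns`` for other geometries.
    """
    from scipy.linalg import hadamard

    if k < 1:
        raise ValueError("k must be >= 1")
    if n_parcels < 2 or (n_parcels & (n_parcels - 1)) != 0:
        raise ValueError("n_parcels must be a power of two for Hadamard patterns")
    if k >= n_parcels:
        raise ValueError("need k < n_parcels orthogonal non-global patterns")
    if margin is None:
        margin = n_parcels // 4 + 2
    margin += margin % 2  # element sums of +/-1 vectors are even
    rows = hadamard(n_parcels)[1:k + 1].astype(int)  # skip the all-ones row
    rng = np.random.default_rng(8128)  # fixed: the construction is deterministic
    for target in range(margin, 0, -2):  # shrink if the requested margin is infeasible
        for _ in range(200_000):
            mask = rng.choice([-1, 1], n_parcels)
            if np.all(rows @ mask == -target):
                return (rows * mask).astype(float)
        # uniform target not found: greedy local search for sums <= -target
        for _ in range(100):
            mask = rng.choice([-1, 1], n_parcels)
            for _ in range(2_000):
                sums = rows @ mask
                penalty = np.maximum(sums + target, 0).sum()
                if penalty == 0:
                    return (rows * mask).astype(float)
                # effect of flipping mask element j on every row sum
                delta = -2 * rows * mask[None, :]
                new_pen = np.maximum(sums[:, None] + delta + target, 0).sum(axis=0)
                j = int(np.argmin(new_pen))
                if new_pen[j] < penalty:
                    mask[j] *= -1
                else:
                    mask[rng.integers(n_parcels)] *= -1  # plateau: random kick
    raise RuntimeError(
        f"no majority-negative sign mask found for k={k}, N={n_parcels}"
    )


def dwell_transition(k: int, dwell_frames: float | np.ndarray) -> np.ndarray:
    """Row-stochastic matrix with expected dwell ``dwell_frames`` per state.

    Self-transition probability is 1 - 1/dwell; the remaining mass is spread
    uniformly over the other states.
    """
    dwell = np.broadcast_to(np.asarray(dwell_frames, dtype=float), (k,))
    if np.any(dwell < 1):
        raise ValueError("dwell_frames must be >= 1")
    t = np.zeros((k, k))
    for c in range(k):
        stay = 1.0 - 1.0 / dwell[c]
        t[c] = (1.0 - stay) / max(k - 1, 1)
        t[c, c] = stay if k > 1 else 1.0
    return t


def _check_stochastic(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(t < 0) or np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-9:
        raise ValueError("transition rows must be non-negative and sum to 1")
    return t


@dataclass
class SyntheticSpec:
    """Generative settings for one cohort.

    Defaults describe the reference study conditions used throughout the
    test-bed: 32 parcels carrying 4 mutually orthogonal majority-negative
    sign patterns, 500 frames at TR = 2 s, a 0.04 Hz carrier with small
    per-subject jitter inside the 0.01-0.08 Hz band, 0.3 rad phase noise,
    5% amplitude noise, and 10 subjects per group.  Group A dwells ~10
    frames (20 s) in every state; group B dwells only ~4 frames in state 1,
    so the planted group difference lives entirely in the switching
    dynamics, never in pattern shape.
    """

    n_parcels: int = 32
    n_frames: int = 500
    tr: float = 2.0
    band: tuple[float, float] = (0.01, 0.08)
    patterns: np.ndarray | None = None
    transition: np.ndarray | None = None
    group_b_transition: np.ndarray | None = None
    phase_noise_sd: float = 0.3
    amplitude_noise_sd: float = 0.05
    n_subjects_per_group: int = 10
    carrier_hz: float = 0.04
    carrier_jitter_hz: float = 0.005
    slew_frames: int = 0
    group_names: tuple[str, str] = ("A", "B")
    n_states: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patterns is None:
            self.patterns = planted_sign_patterns(self.n_parcels, self.n_states)
        self.patterns = np.asarray(self.patterns, dtype=float)
        k, n = self.patterns.shape
        self.n_states, self.n_parcels = k, n
        norms = np.linalg.norm(self.patterns, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero pattern")
        unit = self.patterns / norms[:, None]
        cos = unit @ unit.T
        off = np.abs(cos - np.eye(k))
        if k > 1 and off.max() >= 0.95:
            raise ValueError("patterns must be pairwise distinct (|cosine| < 0.95)")
        if self.transition is None:
            self.transition = dwell_transition(k, 10.0)
        self.transition = _check_stochastic(self.transition)
        if self.group_b_transition is None:
            dwell = np.full(k, 10.0)
            dwell[0] = 4.0
            self.group_b_transition = dwell_transition(k, dwell)
        self.group_b_transition = _check_stochastic(self.group_b_transition)
        low, high = self.band
        nyq = 1.0 / (2.0 * self.tr)
        if not (0 < low < high < nyq):
            raise ValueError("band must lie inside (0, Nyquist)")
        if not (low <= self.carrier_hz <= high):
            raise ValueError(f"carrier {self.carrier_hz} Hz outside band {self.band}")


@dataclass
class GroundTruth:
    """Planted labels and generative parameters of a simulated cohort."""

    labels: dict[str, np.ndarray]          # subject_id -> planted state per frame
    patterns: np.ndarray
    transitions: dict[str, np.ndarray]     # group -> transition matrix
    expected_dwell_frames: dict[str, np.ndarray]
    groups: dict[str, str]                 # subject_id -> group

    def occupancy(self, subject_id: str) -> np.ndarray:
        lab = self.labels[subject_id]
        k = self.patterns.shape[0]
        return np.bincount(lab, minlength=k + 1)[1:] / lab.size


def sample_state_sequence(transition: np.ndarray, initial: np.ndarray | None,
                          n_frames: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample a Markov label sequence (states 1..k) of length ``n_frames``."""
    t = _check_stochastic(transition)
    k = t.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if initial is None:
        initial = np.full(k, 1.0 / k)
    initial = np.asarray(initial, dtype=float)
    if abs(initial.sum() - 1.0) > 1e-9 or np.any(initial < 0):
        raise ValueError("initial must be a probability vector")
    labels = np.empty(n_frames, dtype=int)
    state = rng.choice(k, p=initial)
    cum = np.cumsum(t, axis=1)
    for i in range(n_frames):
        labels[i] = state + 1
        if i < n_frames - 1:
            state = int(np.searchsorted(cum[state], rng.random(), side="right"))
            state = min(state, k - 1)
    return labels


def render_bold(spec: SyntheticSpec, labels: np.ndarray,
                seed: int | np.random.Generator = 0,
                carrier_hz: float | None = None) -> np.ndarray:
    """Render the (n_parcels x n_frames) signal implied by a planted label path.

    Parcel n's phase at frame t is carrier phase + an offset that tracks
    pi * (1 - v_n)/2 for the active pattern value v_n (so +1 -> 0, -1 -> pi,
    graded values in between) plus Gaussian phase noise; the emitted sample
    is the cosine of that phase, scaled by 1 + amplitude noise.

    After a state switch the offset does not jump: it slews upward toward
    the new target at a bounded rate of pi / ``slew_frames`` per frame, so
    the emitted signal stays phase-continuous (near band-limited) and the
    analytic-signal readout remains faithful.  Because the planted patterns
    are mutually orthogonal, frames caught mid-slew still read out as one of
    the two endpoint patterns (eigenvector bistability), not as a blend.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    k = spec.patterns.shape[0]
    if labels.min() < 1 or labels.max() > k:
        raise ValueError("labels must lie in 1..k for this spec")
    f = spec.carrier_hz if carrier_hz is None else float(carrier_hz)
    low, high = spec.band
    if not (low <= f <= high):
        raise ValueError(f"carrier {f} Hz outside band {spec.band}")
    t_sec = np.arange(labels.size) * spec.tr
    phi = 2.0 * np.pi * f * t_sec + rng.uniform(0.0, 2.0 * np.pi)
    targets = np.pi * (1.0 - np.clip(spec.patterns, -1.0, 1.0)) / 2.0  # (k, N)
    two_pi = 2.0 * np.pi
    if spec.slew_frames > 0:
        step = np.pi / spec.slew_frames
        offsets = np.empty((labels.size, spec.n_parcels))
        o = targets[labels[0] - 1].copy()
        offsets[0] = o
        for t in range(1, labels.size):
            delta = np.mod(targets[labels[t] - 1] - o, two_pi)
            o = o + np.minimum(delta, step)
            offsets[t] = o
        theta = phi[None, :] + offsets.T
    else:
        theta = phi[None, :] + targets[labels - 1].T
    if spec.phase_noise_sd > 0:
        theta = theta + rng.normal(0.0, spec.phase_noise_sd, size=theta.shape)
    x = np.cos(theta)
    if spec.amplitude_noise_sd > 0:
        x = x * (1.0 + rng.normal(0.0, spec.amplitude_noise_sd, size=x.shape))
    return x


def simulate_cohort(spec: SyntheticSpec) -> tuple[list[ParcelTimeSeries], GroundTruth]:
    """Simulate both groups in memory; fully determined by ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    ga, gb = spec.group_names
    transitions = {ga: spec.transition, gb: spec.group_b_transition}
    subjects: list[ParcelTimeSeries] = []
    labels: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    children = root.spawn(2 * spec.n_subjects_per_group)
    i = 0
    for group in (ga, gb):
        trans = transitions[group]
        for j in range(spec.n_subjects_per_group):
            rng = np.random.default_rng(children[i])
            i += 1
            sid = f"sub-{group}{j + 1:02d}"
            lab = sample_state_sequence(trans, None, spec.n_frames, rng)
            carrier = spec.carrier_hz + rng.uniform(-spec.carrier_jitter_hz,
                                                   spec.carrier_jitter_hz)
            carrier = float(np.clip(carrier, spec.band[0], spec.band[1]))
            data = render_bold(spec, lab, rng, carrier_hz=carrier)
            subjects.append(ParcelTimeSeries(sid, group, data, spec.tr))
            labels[sid] = lab
            groups[sid] = group
    with np.errstate(divide="ignore"):
        dwell = {g: np.where(np.diag(t) < 1.0, 1.0 / (1.0 - np.diag(t)), np.inf)
                 for g, t in transitions.items()}
    truth = GroundTruth(labels=labels, patterns=spec.patterns.copy(),
                        transitions=transitions, expected_dwell_frames=dwell,
                        groups=groups)
    return subjects, truth


def generate_cohort(spec: SyntheticSpec, out_dir) -> tuple[CohortManifest, GroundTruth]:
    """Simulate a cohort and write it to disk in the analysis input formats.

    Writes one parcels-by-frames TSV per subject, a ``manifest.tsv`` with
    relative paths, and ``ground_truth.json`` with planted labels, patterns
    and transition matrices.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, truth = simulate_cohort(spec)
    records = []
    for ts in subjects:
        fname = f"{ts.subject_id}.tsv"
        write_timeseries(ts, out / fname)
        records.append(ManifestRecord(ts.subject_id, ts.group, fname, spec.tr))
    manifest = CohortManifest(records)
    write_manifest(manifest, out / "manifest.tsv")
    write_json({
        "patterns": truth.patterns,
        "transitions": {g: t for g, t in truth.transitions.items()},
        "expected_dwell_frames": {g: d for g, d in truth.expected_dwell_frames.items()},
        "labels": {s: lab for s, lab in truth.labels.items()},
        "groups": truth.groups,
        "seed": spec.seed,
    }, out / "ground_truth.json")
    return manifest, truth
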