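# Methods

## Pipeline model and assumptions

The package analyses parcellated BOLD recordings under the phase-locking
view of dynamic functional connectivity: after band-limiting to
0.01–0.08 Hz, each parcel signal is treated as a narrow-band oscillation
whose instantaneous phase θ(n, t) is well defined through the analytic
signal. The instantaneous coupling of two parcels is the cosine of their
phase difference, so each frame's connectivity matrix is

    dFC(t) = c cᵀ + s sᵀ,   c = cos θ(·, t),  s = sin θ(·, t).

This matrix is positive semidefinite, has unit diagonal, rank at most 2,
and its eigenvalues sum to its trace N. Consequently the leading eigenvalue
is at least N/2: the leading eigenvector V₁(t) always summarizes at least
half of the spectral mass, which justifies reducing each frame from
N(N−1)/2 couplings to N numbers. The sign structure of V₁ bipartitions the
parcels into two anti-phase communities.

Assumptions worth keeping in mind: the phase is meaningful only for
band-limited signals (the band-pass is a precondition, not a cosmetic);
phases are estimated over the whole recording with no windowing; the
analytic signal distorts the series boundaries, so `drop_edges` frames
(default 1) are discarded at each end — the edge count is exposed because
there is no canonical choice.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| band (low, high) | 0.01, 0.08 | Hz | standard BOLD fluctuation band; Nyquist = 1/(2·TR) bounds it |
| filter order | 2 | — | gentle zero-phase Butterworth (applied forward–backward) |
| drop_edges | 1 | frames | minimal trim of analytic-signal boundary distortion |
| k range | 2–8 (CLI) | — | candidate state counts; the Dunn index picks the argmax, ties to smaller k |
| replicates | 20 | — | seeded k-means restarts; best replicate by within-cluster dissimilarity sum |
| distance | cosine | — | natural for unit-norm eigenvectors; euclidean available (scikit-learn) |
| exclusion band (FCD pooling) | 0 | frames | near-diagonal pairs are trivially similar; kept configurable |
| n_permutations | 5000 | — | group tests; add-one estimator bounds p ≥ 1/(n+1) |

Sign canonicalization flips each eigenvector so that the majority of its
elements are negative; on an exact tie the element of largest magnitude
(first such index) is made non-positive. The rule is total and idempotent,
which is what pooled clustering needs — both orientations of an eigenvector
describe the same bipartition.

The "paired" flavor of the permutation test is not implementable for
unequal group sizes; the test is an unpaired two-sample permutation t-test
(pooled-variance statistic, label shuffles). Per-subject metrics are always
computed first and compared across subjects; frames are never pooled across
subjects for testing. States never visited by a subject yield NaN (not 0)
lifetimes and are dropped pairwise from that state's test.

## The synthetic cohort generator

`leida.synthetic` emulates the target data class: multichannel narrow-band
signals that switch among a small set of anti-phase sign patterns via a
Markov chain, with two groups differing only in transition structure.
Parcel n at frame t emits `cos(2π f t·TR + φ₀ + π·(1 − v_n)/2 + η)` scaled
by `1 + amplitude noise`, where v is the active pattern and η is white
Gaussian phase noise. The defaults are the package's reference study
conditions: N = 32 parcels, 4 patterns, T = 500 frames, TR = 2 s, carrier
0.04 Hz with ±0.005 Hz per-subject jitter, phase noise 0.3 rad, amplitude
noise 5%, 10 subjects per group; group A dwells ~10 frames (20 s) in every
state — comparable to lifetimes reported for resting FC states — and group
B dwells ~4 frames in state 1 only.

Two geometric properties of the planted patterns are deliberate design
choices, arrived at by analysing how the eigenvector readout behaves
through state switches:

* **Exact orthogonality.** For two orthogonal ±1 patterns, the coherence
  matrix of a frame caught mid-transition (the flipping community at an
  intermediate phase γ) is exactly diagonal in span{s_old, s_new}; the
  cross-term `((1+cos γ)(1−cos γ) − sin²γ)/4` vanishes identically. The
  leading eigenvector therefore jumps abruptly from one pattern to the
  other instead of rotating through intermediates — the abrupt eigenvector
  switching that motivates the method — and planted clusters stay separated
  for validity scoring. Non-orthogonal patterns produce bridge frames that
  ruin the single-linkage Dunn numerator.
* **A strict negative sign majority.** Exactly balanced community splits
  sit on the canonicalization tie boundary: noise then flips the canonical
  orientation frame by frame and splits one planted pattern into two
  antipodal clusters. Multiplying Hadamard rows elementwise by one fixed
  sign mask preserves orthogonality while shifting every row's element sum;
  a deterministic search finds a mask giving each pattern the same negative
  margin (default N/4 + 2, relaxed automatically when combinatorially
  infeasible).

What the generator does **not** emulate: hemodynamic convolution, scanner
and physiological noise spectra, head motion, spatially correlated noise,
graded (non-binary) community membership in the default patterns, and any
pattern-shape difference between groups. Passing the recovery tests
therefore shows the pipeline is correct and sensitive under its own model
class; it does not certify effect sizes or power on real fMRI cohorts.

## Numerical choices

* Leading eigenpairs come from `scipy.linalg.eigh` restricted to the top
  two eigenvalues (the second is needed for the degeneracy check); a
  degenerate leading pair (gap ≤ 1e−9·N) logs a warning and keeps the
  solver's eigenvector — measure zero on real data.
* Spherical (cosine) k-means is a hand-written Lloyd iteration: seeded
  random row initialization (resampled when the drawn seeds coincide),
  renormalized mean updates, empty clusters re-seed the replicate, and a
  replicate failing five re-seeds is skipped. The euclidean path delegates
  to `sklearn.cluster.KMeans`.
* The Dunn index uses the clustering distance, single-linkage between-set
  minima and maximum intra-set diameters; all-zero diameters return +inf.
  Ties across k go to the smaller k.
* The HMM is `hmmlearn`'s Gaussian HMM with tied covariance (one
  covariance shared by all states), initialized from a seeded k-means
  solution (means, smoothed bigram transitions, pooled within-class scatter
  with ridge 1e−6·trace/N) so a fit is fully determined by its seed.
  Decoding is the most-probable joint path by default; per-frame posterior
  argmax behind a flag.
* Permutation p-values use the add-one estimator
  `(1 + #{|t_perm| ≥ |t_obs|})/(n_perm + 1)`; a degenerate 0/0 statistic
  (no variance, equal means) is defined as t = 0, giving p = 1.
* FCD matrices are clipped to [−1, 1], symmetrized, and given an exact unit
  diagonal; the Pearson-on-eigenvector variant centers the N elements
  before correlating even though the vectors are unit norm.

## Scale of the shipped validation runs

The recovery suite runs the full pipeline on the reference synthetic cohort
(2 × 10 subjects × 500 frames, k-range 2–8, 20 k-means replicates,
5000-permutation group test; ~15 s on one core), calibrates the permutation
test on 1000 null cohorts of 15 vs 15 subjects at 199 permutations each,
and fits the HMM on ten 300-frame sequences. These sizes were chosen so the
entire suite completes in about a minute while keeping every estimate's
sampling error far from the asserted bounds.

## Known limitations

* The Dunn index with single-linkage numerator is intrinsically sensitive
  to even a handful of points between clusters; on data whose transitions
  produce intermediate frames (including real recordings), the selected k
  can vary with the clustering seed. Inspect the per-k report rather than
  trusting the argmax blindly.
* Switching metrics inherit the frame resolution: dwell times shorter than
  ~2 frames are systematically absorbed into neighbouring states by the
  analytic-signal readout.
* The KS test on pooled FCD values treats frame pairs as independent
  samples, which they are not; its p-values should be read as descriptive,
  as is conventional for FCD distribution comparisons.
* No multiple-testing correction is applied across states and transitions
  by default; the comparison report carries every raw p-value so any
  correction can be applied downstream.
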