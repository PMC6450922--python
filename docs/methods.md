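# Methods

This note documents the models implemented in `connfp`, the conventions
that had to be frozen where the field has no single standard, what the
synthetic cohort generator does and does not emulate, and the numerical
choices that affect results.

## Preprocessing

Each run (a T × n matrix of region time series with sampling interval
TR) is conditioned in a fixed order: per-column least-squares detrending
(which also removes the mean), then zero-phase band-pass filtering. The
filter is a Butterworth band-pass of design order 2 applied
forward-backward (`sosfiltfilt`), so the effective order is 4 and the
phase response is exactly zero — windowed analyses are not shifted in
time. The default passband is 0.01634–0.15 Hz, the conventional
resting-state fluctuation band at TR = 0.72 s; its low edge fixes the
default sliding-window length, since a window must span at least one
period of the slowest passband component (1/0.01634 Hz ≈ 61 s ≈ 85
samples). The configuration is validated against the Nyquist frequency
of the run it is applied to.

Motion quality control operates on per-subject run-averaged framewise
displacement (FD, mm): a subject is excluded when their mean FD exceeds
the cohort mean by more than four cohort standard deviations (unbiased
denominator, strict inequality). Two consequences are worth knowing: a
zero-spread cohort excludes nobody, and several simultaneous extreme
movers inflate the standard deviation and can mask one another — the
rule is a gross-outlier screen, not a robust estimator.

## Connectivity estimators

* **Pearson sFC.** Full-run pairwise Pearson correlation, element-wise
  Fisher transformation `z = atanh(r)`, zero diagonal. Marginal
  correlation mixes direct and indirect (via third regions) dependence.
* **Partial sFC.** The sample covariance (unbiased, T−1) is inverted and
  normalized: `r_ij = −P_ij/√(P_ii P_jj)`. This is the correlation of i
  and j after regressing out all other regions, i.e. an estimate of the
  direct connection. Plain matrix inversion is used (no shrinkage); an
  optional ridge term exists for ill-conditioned inputs and defaults to
  0. The estimator refuses to run when T ≤ n or when the covariance
  condition number exceeds 1e12 — partial correlation from short series
  is unreliable, and the package says so rather than guessing.
* **Pearson dFC.** The run is z-scored per column (Pearson is invariant
  to this; it only improves conditioning), windows of `window_tr`
  samples are taken every `step_tr` samples, a window is used only if it
  fits entirely (count = ⌊(T − w)/s⌋ + 1), and each window yields a
  Fisher-z Pearson FC vector. The window vectors — pooled across the
  runs of a session, because averaging two independently clustered
  *sets* of centroids is ill-defined while pooling windows is not — are
  clustered with squared-Euclidean K-means (scikit-learn: seeded, 10
  restarts, best within-cluster sum of squares, 300-iteration cap,
  empty clusters re-seeded at the farthest points). Cluster centroids
  become the K state matrices, sorted by window occupancy descending;
  occupancy ties break on the first window index assigned to the state,
  so results are deterministic given the seed.

Fisher transformation: correlations are clipped to |r| ≤ 1 − 1e−7
before `atanh`, so perfectly correlated pairs map to a large finite z
(≈ 8.4) instead of infinity and every downstream cosine similarity
stays finite.

## Fingerprint matching

Fingerprints are the row-major upper-triangle vectorizations of the FC
matrices (length n(n−1)/2; 4005 for 90 nodes). The ordering is a frozen
convention: every statistic in the package is invariant to it, but file
round-trips and per-edge reports need one fixed order.

Similarity is the cosine of the two fingerprint vectors. For dynamic FC
a single number must summarize two K-state sets; no canonical reduction
exists, so two are provided and results record which was used:
`rank` (default) pairs states in occupancy order and averages the K
cosines; `best_match` maximizes the mean cosine over one-to-one state
assignments (exhaustive, K ≤ 8). Identification assigns each target the
baseline with the highest similarity, ties broken by the lowest
baseline index.

The identification experiment repeats, `runs` times, a seeded random
choice of one baseline session per subject, matching all remaining
sessions as targets; it reports per-run accuracy, mean accuracy, the
worst-run misidentification count, and the identities of misidentified
subjects. Subjects are processed in sorted-id order, which makes the
result invariant to input ordering at identical seeds. A variant takes
baselines and targets from two different cohorts (e.g. rest vs task, or
two scanners) matched by subject id. Sex classification compares each
subject's chosen-session FC with male and female group averages
computed without that subject (leave-one-out); exact similarity ties
are counted as errors. Group averages are element-wise; for dynamic FC
the members' states are averaged rank-matched with mean occupancies — a
declared convention, not a canon.

## Edge statistics

Per-edge standard deviation across subjects uses the unbiased
denominator. Consistency (low tail) and variability (high tail) masks
use linearly interpolated percentiles with inclusive comparisons at the
threshold, so the 5th/95th percentile of stds 1..100 select exactly
five edges each, and a constant std vector selects every edge in both
modes (degenerate but well-defined).

Differential power follows the mean-based definition given in the
README. Comparisons are strict, so a cohort of identical fingerprints
has DP ≡ 0; norms cancel, so DP is invariant to positive rescaling of
any subject's fingerprint. The implementation is a broadcast over
(i, j, e) and is tested edge-by-edge against an independent triple-loop
enumeration. For sex-level analysis the same formula is applied with
the two group-average fingerprints as the two units (N = 2), giving
per-edge values in {0, 0.5, 1} for each group.

Network contributions credit a within-network edge fully to its
network and a between-network edge half to each endpoint network, the
simplest rule under which per-network percentages sum to exactly 100.
The block grid reports the percentage of selected edges per
network-pair block, normalized by the total number of selected edges
(not by block size); its unique blocks also sum to 100.

## Synthetic cohorts

The generator produces N subjects × 2 sessions × 2 runs of zero-mean
multivariate Gaussian time series whose precision matrix is

    Ω = Ω_base + subject_effect·Δ_subject + sex_effect·Δ_sex
        + session_noise·Δ_session,

with the diagonal set to 1 + the row sum of absolute off-diagonals
(strict diagonal dominance, hence positive definite by construction).
`Ω_base` has dense positive within-network weights (uniform 0.15–0.30
over contiguous near-equal network blocks) and sparse between-network
entries (density 0.05). Positive weights matter: they build up shared
*indirect* marginal correlations along network paths, so the implied
covariance has Pearson-visible structure at node pairs whose direct
(partial) connection is exactly zero — the confound that
distinguishes marginal from direct connectivity estimation.
Sign-alternating weights would cancel these path products and remove
the confound.

`Δ_subject` is a sparse unit-scale perturbation on a per-subject fixed
random edge subset (default 15% of edges), identical in every session
and run of that subject — the fingerprint. `Δ_sex` lives on a fixed
edge set disjoint from all subject sets (so the two signals are
separable), with distinct male and female patterns. `Δ_session` is a
sparse Gaussian jitter redrawn per subject and session. Per-subject
mean FD is drawn log-normal (median 0.15 mm, σ = 0.25 in log space)
with optional injected outliers for exercising the motion screen.
Sampling is i.i.d. over time by default — every downstream statistic is
zero-lag — with an optional AR(1) kernel (same stationary covariance)
for tests where temporal structure matters. Everything is deterministic
given the configuration, including its seed.

The dynamic variant switches between `n_states` shared state templates
with a first-order Markov chain (stay probability 1 − 1/dwell). State
templates share the within-network support but have state-specific
random sign patterns and weights in 0.25–0.45, giving well-separated
recurring states, and every state carries the subject's fingerprint
component. The true state sequence of every run is recorded.

What the generator does *not* emulate: hemodynamics, physiological or
scanner noise, spatial structure, family/twin relatedness, and any
systematic scanner differences. Passing tests therefore demonstrate the
correctness and calibration of the estimators and experiments under the
stated statistical model, not performance on real fMRI.

## Study conditions used by the tests and the acceptance script

Desk-scale cohorts use 30 nodes in 5 networks, 600-sample runs
(~7 min at TR 0.72 s), 2 runs × 2 sessions. Named conditions:

| condition    | subject_effect | session_noise | other                     |
|--------------|---------------:|--------------:|---------------------------|
| fingerprint  | 0.6            | 0.05          | N = 40                    |
| chance       | 0.0            | 0.3           | N = 40                    |
| confounded   | 0.45           | 0.3           | N = 40, T = 1200          |
| sex null     | 0.3 (sex 0.0)  | 0.2           | N = 60                    |
| sex strong   | 0.15 (sex 0.8) | 0.05          | N = 60                    |
| two-state    | 0.2            | 0.0           | 20 nodes, T = 2400, dwell 150 |

These sizes keep the full test suite and the acceptance script in the
tens of seconds while leaving each experiment in its intended regime:
near-ceiling identification for the fingerprint cohort, 100/N for the
chance cohort, ~50% for null sex classification, and ~16 dwell
segments per run so realized state occupancies are stable.

On the confounded cohort the method comparison reproduces the
qualitative ordering partial sFC ≥ Pearson dFC ≥ Pearson sFC − 2
points. Two honest caveats. First, under this Gaussian model with a
diagonally dominant precision, the implied covariance is weakly
coupled, so partial and Pearson sFC face nearly identical
signal-to-noise and their accuracies are close (both near ceiling at
the chosen effect sizes); the structural advantage of partial
correlation shows up directly in edge recovery (true-zero partial
edges vs confounded Pearson edges) rather than as a large
identification gap. Second, on temporally i.i.d. data the dFC windows
are simply noisier estimates of the static FC, so dynamic FC can only
tie, not beat, static Pearson here; its real-data advantage requires
genuinely state-switching dynamics, which the dynamic generator
provides for the state-recovery analyses.

## Numerical conventions and degenerate inputs

* Fisher clip 1e−7; correlations with |r| > 1 + 1e−12 are errors.
* Covariance/std: unbiased (n−1) everywhere.
* Percentiles: linear interpolation; inclusive threshold comparisons.
* K-means: seed, 10 restarts, tol 1e−6, max 300 iterations; identical
  seeds and inputs are bit-reproducible.
* Zero-norm fingerprints (e.g. the average of two opposite FC matrices)
  raise an error rather than returning NaN similarities.
* Zero-variance node series are rejected with the node named.
* All file I/O is delimited text at full double precision; FC files
  carry a one-line metadata header (method tag, size).
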