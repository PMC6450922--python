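# connfp — functional-connectivity fingerprinting

`connfp` is a Python package for studying how well different
functional-connectivity (FC) estimators capture the *intrinsic individual
connectivity pattern* — the "fingerprint" — in brain-region time series,
and for using that fingerprint to re-identify subjects across scanning
sessions and to classify biological sex.

It is aimed at researchers working with parcellated resting-state fMRI
(one time-series matrix per run, rows = time points, columns = regions of
an atlas grouped into resting-state networks), but nothing in the package
requires imaging data: a synthetic multi-subject cohort generator with
full ground truth is a first-class module, so every stage of the pipeline
can be exercised and validated on a laptop.

## What it computes

Three FC estimators, applied per run after detrending/demeaning and
zero-phase band-pass filtering (default 0.01634–0.15 Hz):

* **Pearson sFC** — full-run pairwise Pearson correlation, Fisher-z
  transformed (`z = atanh(r)`).
* **Partial sFC** — partial correlation from the precision matrix
  `P = Σ⁻¹`: `r_ij = −P_ij / √(P_ii P_jj)`, Fisher-z transformed.
  Regresses out all other regions, so it estimates *direct* connections;
  requires more time points than nodes.
* **Pearson dFC** — sliding-window Pearson correlation (default window
  85 samples ≈ 61.2 s at TR = 0.72 s, step 5 samples), clustered with
  K-means into K = 4 recurring connectivity *states* ordered by occupancy.

A subject's fingerprint is the vector `X` of the `n(n−1)/2` upper-triangle
edge strengths. Two fingerprints are compared with cosine similarity

    CS(i, j) = (X_i · X_j) / (‖X_i‖ ‖X_j‖)  ∈ [−1, 1].

**Subject identification**: one session per subject is drawn at random as
the known baseline; every remaining session is an unknown target matched
to the baseline with the highest cosine similarity. Repeating the random
split many times yields a mean accuracy and a worst-run misidentification
count. **Sex classification** compares each subject with leave-one-out
male and female group-average FC matrices.

Edge-level statistics locate where the fingerprint lives:

* **edge consistency / variability** — the bottom / top percentile tail of
  the per-edge standard deviation across subjects;
* **differential power** — for edge `e`, with
  `φ_ij(e) = X_i^{S1}(e) · X_j^{S2}(e) / (‖X_i^{S1}‖ ‖X_j^{S2}‖)`,

      P_i(e) = ( |φ_ii > φ_ij| + |φ_ii > φ_ji| ) / 2(N−1),
      DP(e)  = (1/N) Σ_i P_i(e)  ∈ [0, 1],

  the empirical probability that a subject's within-subject cross-session
  edge product beats the between-subject ones (mean-based variant: no
  undefined values at zero probabilities);
* **network contributions** — percentages of selected edges per network
  (between-network edges credit 0.5 to each endpoint network) and per
  network-pair block.

## Worked example

```python
import numpy as np
from connfp.synthetic import SyntheticConfig, simulate_cohort
from connfp.fingerprint import build_cohort_fc, run_identification_experiment
from connfp.edges import differential_power
from connfp.io_core import vectorize_upper

cfg = SyntheticConfig(n_subjects=12, n_nodes=20, n_networks=4, t_per_run=400,
                      subject_effect=0.6, session_noise=0.05, seed=11)
cohort = simulate_cohort(cfg)

for method in ("pearson", "partial"):
    fc = build_cohort_fc(cohort.runs_by_subject(), cohort.sex_of(), method)
    res = run_identification_experiment(fc, runs=100, seed=7)
    print(f"{method:8s} mean accuracy {res.mean_accuracy:6.2f} %   "
          f"worst run missed {res.max_misidentifications} of {cfg.n_subjects}")

fc = build_cohort_fc(cohort.runs_by_subject(), cohort.sex_of(), "partial")
subs = fc.sorted_subjects()
s1 = [vectorize_upper(s.sessions["S1"]) for s in subs]
s2 = [vectorize_upper(s.sessions["S2"]) for s in subs]
dp = differential_power(s1, s2)
signal = np.unique(np.concatenate(list(cohort.truth["subject_edge_sets"].values())))
null = np.setdiff1d(np.arange(dp.size), signal)
print(f"mean DP on fingerprint edges {dp[signal].mean():.3f} "
      f"vs other edges {dp[null].mean():.3f}")
```

prints

```
pearson  mean accuracy 100.00 %   worst run missed 0 of 12
partial  mean accuracy 100.00 %   worst run missed 0 of 12
mean DP on fingerprint edges 0.594 vs other edges 0.495
```

With a subject effect (0.6) far above the session noise (0.05), both
static estimators re-identify every subject in every one of the 100
randomized baseline/target splits, and the differential power is visibly
higher on the edges that actually carry the subject-specific structure.

## Command line

```bash
connfp simulate --subjects 40 --nodes 90 --networks 14 --t 1200 \
    --subject-effect 0.4 --session-noise 0.1 --seed 11 --out cohort/
connfp preprocess --tr 0.72 --in cohort/sub000_S1_R1.tsv --out clean.tsv
connfp fc --method dfc --tr 0.72 --window 85 --step 5 --k 4 \
    --in cohort/sub000_S1_R1.tsv --in cohort/sub000_S1_R2.tsv --out fc/
connfp identify --cohort cohort/manifest.tsv --method partial --runs 1000 --seed 7
connfp sex      --cohort cohort/manifest.tsv --method partial --runs 1000 --seed 7
connfp edges    --cohort cohort/manifest.tsv --method partial \
    --atlas cohort/atlas.tsv --out report/
```

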