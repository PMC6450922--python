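"""Cosine-similarity fingerprint matching and identification experiments.

A subject's connectivity "fingerprint" is the vectorized upper triangle of
an FC matrix. Similarity between two fingerprints X_i, X_j is the cosine

    CS(i, j) = (X_i . X_j) / (||X_i|| ||X_j||),

in [-1, 1]. Subject identification picks, for each unknown target session,
the baseline session with the largest cosine similarity; the experiment
drivers repeat this over many randomized baseline/target session splits and
report mean accuracy and the worst-run misidentification count. Sex
classification compares each subject to leave-one-out male and female
group-average FC matrices.

Dynamic-FC representations carry K state matrices instead of one; two state
sets are compared either rank-matched (states paired in occupancy order,
mean cosine — the default) or by the best one-to-one assignment of states.
Neither reduction is canonical; results record which was used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fc import DFCConfig, DynamicStates, dfc_for_run, partial_sfc, pearson_sfc
from .io_core import FCMatrix, FCVector, TimeSeriesMatrix, ValidationError, vectorize_upper
from .preprocessing import average_runs

__all__ = [
    "CohortFC",
    "SubjectFC",
    "IdentificationResult",
    "cosine_similarity",
    "dfc_similarity",
    "identify",
    "run_identification_experiment",
    "cross_condition_experiment",
    "group_average_fc",
    "classify_sex",
    "build_cohort_fc",
]

def _as_state_array(rep) -> np.ndarray:
    """Canonical (K, n_edges) array for any FC representation (K=1 if static)."""
    if isinstance(rep, DynamicStates):
        return rep.state_vectors()
    if isinstance(rep, FCMatrix):
        return vectorize_upper(rep).values[None, :]
    if isinstance(rep, FCVector):
        return rep.values[None, :]
    arr = np.asarray(rep, dtype=float)
    if arr.ndim == 1:
        return arr[None, :]
    raise ValidationError(f"unsupported FC representation: {type(rep)!r}")


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValidationError("zero-norm FC vector: similarity undefined")
    return x / norms


def cosine_similarity(x, y) -> float:
    """Inner product of the two fingerprint vectors divided by their norms."""
    xv = _as_state_array(x).ravel()
    yv = _as_state_array(y).ravel()
    if xv.shape != yv.shape:
        raise ValidationError("fingerprint vectors differ in length")
    nx, ny = np.linalg.norm(xv), np.linalg.norm(yv)
    if nx == 0 or ny == 0:
        raise ValidationError("zero-norm FC vector: similarity undefined")
    return float(np.dot(xv, yv) / (nx * ny))


def dfc_similarity(a: DynamicStates, b: DynamicStates, mode: str = "rank") -> float:
    """One similarity value for two K-state sets.

    ``rank``: mean cosine over states paired in occupancy order.
    ``best_match``: maximum mean cosine over one-to-one state assignments
    (exhaustive over K! permutations; intended for K <= 8).
    """
    if a.n_states != b.n_states:
        raise ValidationError("state-count mismatch")
    av = _normalize_rows(a.state_vectors())
    bv = _normalize_rows(b.state_vectors())
    if mode == "rank":
        return float(np.mean(np.sum(av * bv, axis=1)))
    if mode == "best_match":
        cs = av @ bv.T  # (K, K) pairwise state cosines
        k = a.n_states
        if k > 8:
            raise ValidationError("best_match mode is exhaustive; K must be <= 8")
        return max(
            float(np.mean(cs[np.arange(k), list(perm)]))
            for perm in itertools.permutations(range(k))
        )
    raise ValidationError(f"unknown mode {mode!r}")


def _stack_representations(reps: Sequence) -> np.ndarray:
    arrays = [_as_state_array(r) for r in reps]
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise ValidationError("representations differ in K or edge count")
    return np.stack(arrays)  # (N, K, E)


def _similarity_matrix(targets: np.ndarray, baselines: np.ndarray,
                       mode: str = "rank") -> np.ndarray:
    """(n_targets, n_baselines) matrix of similarities between stacked reps."""
    tn = _normalize_rows(targets)
    bn = _normalize_rows(baselines)
    k = tn.shape[1]
    if mode == "rank" or k == 1:
        per_state = np.einsum("tke,bke->tbk", tn, bn)
        return per_state.mean(axis=2)
    if mode == "best_match":
        if k > 8:
            raise ValidationError("best_match mode is exhaustive; K must be <= 8")
        per_pair = np.einsum("tie,bje->tbij", tn, bn)
        perms = list(itertools.permutations(range(k)))
        idx = np.arange(k)
        scores = np.stack(
            [per_pair[:, :, idx, list(p)].mean(axis=2) for p in perms], axis=0
        )
        return scores.max(axis=0)
    raise ValidationError(f"unknown mode {mode!r}")


def identify(baselines: Sequence, targets: Sequence, mode: str = "rank") -> np.ndarray:
    """Assign each target the baseline index with maximal cosine similarity.

    Ties are broken by the lowest baseline index (argmax convention).
    """
    if len(baselines) == 0:
        raise ValidationError("empty baseline set")
    b = _stack_representations(baselines)
    t = _stack_representations(targets)
    if b.shape[1:] != t.shape[1:]:
        raise ValidationError("baseline/target representation mismatch")
    return np.argmax(_similarity_matrix(t, b, mode=mode), axis=1)


# ---------------------------------------------------------------------------
# cohort container and experiment drivers
# ---------------------------------------------------------------------------

@dataclass
class SubjectFC:
    subject_id: str
    sex: str  # "M" or "F"
    sessions: dict  # session_id -> FCMatrix | DynamicStates


@dataclass
class CohortFC:
    """Per-subject, per-session FC representations plus sex labels."""

    subjects: list[SubjectFC]
    method_tag: str = ""

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in cohort")
        for s in self.subjects:
            if s.sex not in ("M", "F"):
                raise ValidationError(f"subject {s.subject_id}: sex must be M or F")

    def sorted_subjects(self) -> list[SubjectFC]:
        return sorted(self.subjects, key=lambda s: s.subject_id)

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.sorted_subjects()]


@dataclass
class IdentificationResult:
    """Aggregate of repeated randomized identification runs."""

    runs: int
    per_run_accuracy: np.ndarray           # percent, one entry per run
    mean_accuracy: float                   # percent
    max_misidentifications: int
    misidentified: list[list[str]]         # per run, subject ids missed
    mode: str = "rank"

    @property
    def misidentification_counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.misidentified])


def _session_arrays(cohort: CohortFC) -> tuple[list[str], list[str], np.ndarray]:
    """Stack every subject's two sessions -> (subject_ids, session_ids, (N,2,K,E))."""
    subjects = cohort.sorted_subjects()
    session_ids = None
    reps = []
    for s in subjects:
        keys = sorted(s.sessions)
        if len(keys) != 2:
            raise ValidationError(
                f"subject {s.subject_id} has {len(keys)} sessions; "
                "identification experiments need exactly 2"
            )
        if session_ids is None:
            session_ids = keys
        elif keys != session_ids:
            raise ValidationError("session ids differ across subjects")
        reps.append(_stack_representations([s.sessions[k] for k in keys]))
    return [s.subject_id for s in subjects], session_ids, np.stack(reps)


def _score_runs(per_run_correct: list[np.ndarray], subject_of_target,
                mode: str) -> IdentificationResult:
    accs, missed = [], []
    for correct in per_run_correct:
        accs.append(100.0 * correct.mean())
        missed.append([subject_of_target(t) for t in np.flatnonzero(~correct)])
    accs = np.array(accs)
    return IdentificationResult(
        runs=len(accs),
        per_run_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        max_misidentifications=int(max(len(m) for m in missed)),
        misidentified=missed,
        mode=mode,
    )


def run_identification_experiment(cohort: CohortFC, runs: int = 1000,
                                  seed: int = 0, mode: str = "rank") -> IdentificationResult:
    """Repeated random baseline/target session splits within one cohort.

    Per run, one of the two sessions of every subject is drawn (uniformly,
    seeded) as the known baseline; the other sessions are the unknown
    targets. A target is correct when its most-similar baseline belongs to
    the same subject. Subjects are processed in sorted-id order so the
    result does not depend on input ordering.
    """
    ids, _, reps = _session_arrays(cohort)   # (N, 2, K, E)
    n = len(ids)
    rng = np.random.default_rng(seed)
    rows = np.arange(n)
    per_run_correct = []
    for _ in range(runs):
        pick = rng.integers(0, 2, size=n)
        baselines = reps[rows, pick]          # (N, K, E)
        targets = reps[rows, 1 - pick]
        assigned = np.argmax(_similarity_matrix(targets, baselines, mode=mode), axis=1)
        per_run_correct.append(assigned == rows)
    return _score_runs(per_run_correct, lambda t: ids[t], mode)


def cross_condition_experiment(baseline_cohort: CohortFC, target_cohort: CohortFC,
                               runs: int = 1000, seed: int = 0,
                               mode: str = "rank") -> IdentificationResult:
    """Match every session of ``target_cohort`` against randomly chosen
    baseline sessions of the same subjects in ``baseline_cohort``.

    Used for cross-scanner / cross-months and rest-vs-task matching: the
    baseline cohort contributes one randomly selected session per subject
    per run, the target cohort contributes all of its sessions as targets.
    """
    b_ids, _, b_reps = _session_arrays(baseline_cohort)
    t_subjects = target_cohort.sorted_subjects()
    t_ids = [s.subject_id for s in t_subjects]
    if set(t_ids) != set(b_ids):
        raise ValidationError("baseline and target cohorts list different subjects")
    targets, target_owner = [], []
    for s in t_subjects:
        for k in sorted(s.sessions):
            targets.append(s.sessions[k])
            target_owner.append(b_ids.index(s.subject_id))
    t_arr = _stack_representations(targets)
    owner = np.array(target_owner)
    rng = np.random.default_rng(seed)
    n = len(b_ids)
    per_run_correct = []
    for _ in range(runs):
        pick = rng.integers(0, 2, size=n)
        baselines = b_reps[np.arange(n), pick]
        assigned = np.argmax(_similarity_matrix(t_arr, baselines, mode=mode), axis=1)
        per_run_correct.append(assigned == owner)
    return _score_runs(per_run_correct, lambda t: b_ids[owner[t]], mode)


def group_average_fc(reps: Sequence):
    """Element-wise mean FC of a group.

    Static representations average to an FCMatrix; dynamic state sets are
    averaged rank-matched (state k of the average is the mean of every
    member's k-th state in occupancy order) with mean occupancies.
    """
    if len(reps) == 0:
        raise ValidationError("empty group")
    if isinstance(reps[0], DynamicStates):
        arr = _stack_representations(reps).mean(axis=0)  # (K, E)
        counts = np.stack([r.counts for r in reps]).mean(axis=0)
        from .io_core import devectorize
        states = [devectorize(arr[k], method_tag="dfc_state") for k in range(arr.shape[0])]
        order = np.argsort(-counts, kind="stable")
        return DynamicStates(
            states=[states[k] for k in order],
            counts=np.round(counts[order]).astype(int),
            window_assignments=np.repeat(
                np.arange(len(order)), np.round(counts[order]).astype(int)
            ),
        )
    if isinstance(reps[0], FCMatrix):
        vals = np.mean([r.values for r in reps], axis=0)
        return FCMatrix(values=vals, method_tag=reps[0].method_tag,
                        node_ids=reps[0].node_ids)
    arr = _stack_representations(reps).mean(axis=0)
    return FCVector(values=arr.ravel(), n_nodes=_n_from_edges(arr.shape[-1]))


def _n_from_edges(e: int) -> int:
    from .io_core import _n_from_triangular
    return _n_from_triangular(e)


def classify_sex(cohort: CohortFC, runs: int = 1000, seed: int = 0,
                 mode: str = "rank") -> IdentificationResult:
    """Leave-one-out sex classification against group-average fingerprints.

    Per run, one session is drawn per subject; each subject's FC is compared
    with the male and the female group average computed *without* that
    subject, and the sex with the higher cosine similarity is predicted.
    Exact ties are counted as incorrect (undecided).
    """
    ids, _, reps = _session_arrays(cohort)    # (N, 2, K, E)
    subjects = cohort.sorted_subjects()
    is_male = np.array([s.sex == "M" for s in subjects])
    if is_male.sum() < 2 or (~is_male).sum() < 2:
        raise ValidationError("need at least 2 subjects of each sex")
    n = len(ids)
    rng = np.random.default_rng(seed)
    rows = np.arange(n)
    per_run_correct = []
    for _ in range(runs):
        pick = rng.integers(0, 2, size=n)
        x = reps[rows, pick]                  # (N, K, E)
        sums = {True: x[is_male].sum(axis=0), False: x[~is_male].sum(axis=0)}
        counts = {True: int(is_male.sum()), False: int((~is_male).sum())}
        correct = np.zeros(n, dtype=bool)
        for i in range(n):
            sims = {}
            for male in (True, False):
                if is_male[i] == male:
                    avg = (sums[male] - x[i]) / (counts[male] - 1)
                else:
                    avg = sums[male] / counts[male]
                sims[male] = _similarity_matrix(x[i][None], avg[None], mode=mode)[0, 0]
            if sims[True] == sims[False]:
                correct[i] = False            # undecided counts as an error
            else:
                correct[i] = (sims[True] > sims[False]) == is_male[i]
        per_run_correct.append(correct)
    return _score_runs(per_run_correct, lambda t: ids[t], mode)


# ---------------------------------------------------------------------------
# cohort assembly from raw runs
# ---------------------------------------------------------------------------

def build_cohort_fc(runs_by_subject: Mapping[str, Mapping[str, Sequence[TimeSeriesMatrix]]],
                    sex_of: Mapping[str, str], method: str,
                    dfc_cfg: DFCConfig | None = None,
                    ridge: float = 0.0) -> CohortFC:
    """Estimate one FC representation per subject and session.

    ``runs_by_subject[subject_id][session_id]`` is the list of runs of that
    session. Static methods ('pearson', 'partial') estimate one FC matrix
    per run and average the runs element-wise; 'dfc' pools the window
    vectors of the session's runs into a single K-means clustering.
    """
    if method not in ("pearson", "partial", "dfc"):
        raise ValidationError("method must be 'pearson', 'partial' or 'dfc'")
    if method == "dfc":
        dfc_cfg = dfc_cfg or DFCConfig()
    subjects = []
    for sid in sorted(runs_by_subject):
        sessions = {}
        for sess in sorted(runs_by_subject[sid]):
            runs = list(runs_by_subject[sid][sess])
            if method == "dfc":
                sessions[sess] = dfc_for_run(runs, dfc_cfg)
            else:
                est = pearson_sfc if method == "pearson" else \
                    (lambda ts: partial_sfc(ts, ridge=ridge))
                fcs = [est(ts) for ts in runs]
                fc = fcs[0]
                for other in fcs[1:]:
                    fc = average_runs(fc, other)
                sessions[sess] = fc
        subjects.append(SubjectFC(subject_id=sid, sex=sex_of[sid], sessions=sessions))
    tag = {"pearson": "pearson_sfc", "partial": "partial_sfc", "dfc": "dfc_state"}[method]
    return CohortFC(subjects=subjects, method_tag=tag)
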