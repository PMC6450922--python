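"""Synthetic multi-subject cohorts with known connectivity ground truth.

The generator emulates the statistical structure a fingerprinting study
relies on, without any imaging data:

* Every subject's runs are draws from a zero-mean multivariate Gaussian
  whose *precision* matrix (inverse covariance) is built from

      Omega = Omega_base                      (shared network backbone)
            + subject_effect  * Delta_subject (the stable fingerprint)
            + sex_effect      * Delta_sex     (group effect, M/F patterns)
            + session_noise   * Delta_session (per-session jitter)

  with the diagonal inflated to strict diagonal dominance, hence SPD.
* ``Omega_base`` has dense within-network off-diagonals and sparse
  between-network entries, so the implied covariance carries *indirect*
  correlations at node pairs whose direct (partial) connection is exactly
  zero — the confound that separates Pearson from partial correlation.
* Effects perturb the precision, i.e. direct connections; the subject and
  sex edge sets are disjoint by construction so the two signals are
  separable.
* Per-subject mean framewise displacement is drawn log-normal, with
  optional injected outliers, to exercise the motion-QC rule.
* A dynamic variant switches between shared state templates with a
  first-order Markov chain (mean dwell time in samples) while keeping each
  subject's fingerprint component present in every state.

Everything is deterministic given the config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .fc import fisher_z
from .io_core import NetworkAtlas, TimeSeriesMatrix, ValidationError

__all__ = [
    "SyntheticConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "make_atlas",
    "build_precision",
    "simulate_run",
    "simulate_cohort",
    "simulate_dynamic_cohort",
    "true_partial_vector",
    "fingerprint_cohort_config",
    "chance_cohort_config",
    "confounded_cohort_config",
    "sex_null_cohort_config",
    "sex_strong_cohort_config",
    "dynamic_two_state_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generation settings.

    Effect magnitudes scale unit-level precision perturbations; 0 disables
    the component. ``fraction_subject_edges`` (and the session analog) set
    the support size of the sparse perturbations as a fraction of all
    n(n-1)/2 edges.
    """

    n_subjects: int = 40
    n_nodes: int = 90
    n_networks: int = 14
    t_per_run: int = 1200
    tr_seconds: float = 0.72
    runs_per_session: int = 2
    n_sessions: int = 2
    subject_effect: float = 0.3
    sex_effect: float = 0.0
    session_noise: float = 0.1
    fraction_subject_edges: float = 0.15
    fraction_sex_edges: float = 0.10
    fraction_session_edges: float = 0.15
    between_density: float = 0.05
    n_states: int = 1
    state_dwell: int = 100
    ar_coeff: float = 0.0
    n_fd_outliers: int = 0
    fd_outlier_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("need at least 2 subjects")
        if self.n_networks > self.n_nodes:
            raise ValidationError("more networks than nodes")
        for name in ("subject_effect", "sex_effect", "session_noise"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_states < 1:
            raise ValidationError("n_states must be >= 1")
        if self.state_dwell < 1:
            raise ValidationError("state_dwell must be >= 1 sample")
        if not (0 <= self.ar_coeff < 1):
            raise ValidationError("ar_coeff must lie in [0, 1)")


@dataclass
class SyntheticSubject:
    subject_id: str
    sex: str
    mean_fd: float
    # runs[session_id][run_id] -> TimeSeriesMatrix
    runs: dict


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    atlas: NetworkAtlas
    subjects: list[SyntheticSubject]
    truth: dict = field(default_factory=dict)

    def runs_by_subject(self) -> dict:
        """Mapping subject_id -> session_id -> [runs], for cohort assembly."""
        return {
            s.subject_id: {sess: list(runs.values()) for sess, runs in s.runs.items()}
            for s in self.subjects
        }

    def sex_of(self) -> dict:
        return {s.subject_id: s.sex for s in self.subjects}

    def motion_records(self):
        from .preprocessing import MotionRecord
        return [MotionRecord(s.subject_id, s.mean_fd) for s in self.subjects]


def make_atlas(n_nodes: int, n_networks: int, seed: int = 0) -> NetworkAtlas:
    """Contiguous near-equal network blocks (sizes differ by at most 1)."""
    if n_networks > n_nodes:
        raise ValidationError("n_networks must not exceed n_nodes")
    base, extra = divmod(n_nodes, n_networks)
    sizes = [base + (1 if k < extra else 0) for k in range(n_networks)]
    node_ids, network_of = [], {}
    node = 0
    for k, size in enumerate(sizes):
        name = f"NET{k + 1:02d}"
        for _ in range(size):
            nid = f"node{node:03d}"
            node_ids.append(nid)
            network_of[nid] = name
            node += 1
    return NetworkAtlas(node_ids=node_ids, network_of=network_of)


# ---------------------------------------------------------------------------
# precision-matrix construction
# ---------------------------------------------------------------------------

def _edge_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _symmetric_from_edges(n: int, edge_values: np.ndarray) -> np.ndarray:
    m = np.zeros((n, n))
    iu = _edge_indices(n)
    m[iu] = edge_values
    return m + m.T


def _inflate_diagonal(off: np.ndarray) -> np.ndarray:
    """Strict diagonal dominance: diag = 1 + row sum of |off-diagonals|."""
    out = off.copy()
    np.fill_diagonal(out, 0.0)
    np.fill_diagonal(out, 1.0 + np.abs(out).sum(axis=1))
    return out


@dataclass
class _CohortComponents:
    """Seeded, per-cohort precision ingredients (edge-space vectors)."""

    base_edges: np.ndarray            # (E,)
    subject_edge_sets: dict           # subject_id -> (k,) edge indices
    subject_deltas: dict              # subject_id -> (E,) sparse vector
    sex_edge_set: np.ndarray
    sex_deltas: dict                  # "M"/"F" -> (E,) sparse vector
    session_deltas: dict              # (subject_id, session_id) -> (E,)


def _draw_components(cfg: SyntheticConfig, atlas: NetworkAtlas,
                     rng: np.random.Generator,
                     subject_ids: list[str]) -> _CohortComponents:
    n = cfg.n_nodes
    iu, ju = _edge_indices(n)
    e = iu.shape[0]
    net = np.array([atlas.network_index_of(nid) for nid in atlas.node_ids])
    within = net[iu] == net[ju]

    # positive within-network weights build up shared *indirect* marginal
    # correlations along network paths -- the confound that separates
    # marginal (Pearson) from direct (partial) connectivity
    base = np.zeros(e)
    base[within] = rng.uniform(0.15, 0.30, size=int(within.sum()))
    between = ~within
    keep = rng.random(int(between.sum())) < cfg.between_density
    vals = rng.uniform(0.10, 0.20, size=int(between.sum()))
    base[between] = np.where(keep, vals, 0.0)

    n_sex = max(1, round(cfg.fraction_sex_edges * e))
    sex_set = rng.choice(e, size=n_sex, replace=False)
    pool = np.setdiff1d(np.arange(e), sex_set)
    sex_deltas = {}
    for label in ("M", "F"):
        d = np.zeros(e)
        d[sex_set] = rng.uniform(0.5, 1.0, n_sex) * rng.choice([-1.0, 1.0], n_sex)
        sex_deltas[label] = d

    n_subj_edges = max(1, round(cfg.fraction_subject_edges * e))
    n_sess_edges = max(1, round(cfg.fraction_session_edges * e))
    subject_edge_sets, subject_deltas, session_deltas = {}, {}, {}
    for sid in subject_ids:
        edges = rng.choice(pool, size=n_subj_edges, replace=False)
        d = np.zeros(e)
        d[edges] = rng.uniform(0.5, 1.0, n_subj_edges) * rng.choice([-1.0, 1.0], n_subj_edges)
        subject_edge_sets[sid] = np.sort(edges)
        subject_deltas[sid] = d
        for sess in range(cfg.n_sessions):
            s_edges = rng.choice(e, size=n_sess_edges, replace=False)
            ds = np.zeros(e)
            ds[s_edges] = rng.standard_normal(n_sess_edges)
            session_deltas[(sid, f"S{sess + 1}")] = ds
    return _CohortComponents(
        base_edges=base, subject_edge_sets=subject_edge_sets,
        subject_deltas=subject_deltas, sex_edge_set=np.sort(sex_set),
        sex_deltas=sex_deltas, session_deltas=session_deltas,
    )


def _assemble_precision(cfg: SyntheticConfig, comp: _CohortComponents,
                        subject_id: str, sex: str, session_id: str,
                        base_edges: np.ndarray | None = None) -> np.ndarray:
    edges = (comp.base_edges if base_edges is None else base_edges).copy()
    edges += cfg.subject_effect * comp.subject_deltas[subject_id]
    edges += cfg.sex_effect * comp.sex_deltas[sex]
    edges += cfg.session_noise * comp.session_deltas[(subject_id, session_id)]
    return _inflate_diagonal(_symmetric_from_edges(cfg.n_nodes, edges))


def build_precision(cfg: SyntheticConfig, subject_index: int, sex: str,
                    session: int) -> np.ndarray:
    """SPD precision matrix for one subject/session under ``cfg``.

    Convenience wrapper that draws the whole cohort's seeded components and
    returns the requested matrix; ``simulate_cohort`` uses the same
    construction for all subjects at once.
    """
    atlas = make_atlas(cfg.n_nodes, cfg.n_networks, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    ids = [f"sub{k:03d}" for k in range(cfg.n_subjects)]
    comp = _draw_components(cfg, atlas, rng, ids)
    return _assemble_precision(cfg, comp, ids[subject_index], sex, f"S{session}")


def true_partial_vector(precision: np.ndarray) -> np.ndarray:
    """Fisher-z true partial correlations implied by a precision matrix,
    vectorized over the upper triangle."""
    d = np.sqrt(np.diag(precision))
    r = -precision / np.outer(d, d)
    iu = _edge_indices(precision.shape[0])
    return np.asarray(fisher_z(np.clip(r[iu], -1.0, 1.0)))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_gaussian(chol_lower: np.ndarray, t: int,
                     rng: np.random.Generator) -> np.ndarray:
    """t rows with covariance Omega^-1, given the Cholesky factor of Omega."""
    z = rng.standard_normal((t, chol_lower.shape[0]))
    # x = z L^{-1}  =>  cov(x) = L^{-T} L^{-1} = (L L^T)^{-1} = Omega^{-1}
    return solve_triangular(chol_lower.T, z.T, lower=False).T


def simulate_run(precision: np.ndarray, t: int, seed: int | np.random.Generator,
                 tr_seconds: float = 0.72, ar_coeff: float = 0.0,
                 node_ids: list[str] | None = None, **labels) -> TimeSeriesMatrix:
    """Draw a T x n run from the Gaussian with covariance ``precision``^-1.

    ``ar_coeff`` > 0 adds an AR(1) temporal kernel with the same stationary
    covariance (innovations scaled by sqrt(1 - rho^2)).
    """
    precision = np.asarray(precision, dtype=float)
    try:
        chol = cholesky(precision, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise ValidationError("precision matrix is not positive definite") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = _sample_gaussian(chol, t, rng)
    if ar_coeff > 0:
        rho = ar_coeff
        scale = np.sqrt(1.0 - rho * rho)
        out = np.empty_like(x)
        out[0] = x[0]
        for k in range(1, t):
            out[k] = rho * out[k - 1] + scale * x[k]
        x = out
    n = precision.shape[0]
    node_ids = node_ids or [f"node{k:03d}" for k in range(n)]
    return TimeSeriesMatrix(values=x, tr_seconds=tr_seconds, node_ids=node_ids, **labels)


def _cohort_scaffold(cfg: SyntheticConfig):
    atlas = make_atlas(cfg.n_nodes, cfg.n_networks, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    ids = [f"sub{k:03d}" for k in range(cfg.n_subjects)]
    sexes = ["M" if k % 2 == 0 else "F" for k in range(cfg.n_subjects)]
    comp = _draw_components(cfg, atlas, rng, ids)
    fd = rng.lognormal(mean=np.log(0.15), sigma=0.25, size=cfg.n_subjects)
    if cfg.n_fd_outliers:
        fd[-cfg.n_fd_outliers:] *= cfg.fd_outlier_scale
    return atlas, rng, ids, sexes, comp, fd


def simulate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Static cohort: subjects x sessions x runs of i.i.d. Gaussian draws."""
    atlas, rng, ids, sexes, comp, fd = _cohort_scaffold(cfg)
    subjects = []
    precisions = {}
    for sid, sex, mean_fd in zip(ids, sexes, fd):
        runs: dict = {}
        for sess in range(cfg.n_sessions):
            session_id = f"S{sess + 1}"
            omega = _assemble_precision(cfg, comp, sid, sex, session_id)
            precisions[(sid, session_id)] = omega
            chol = cholesky(omega, lower=True)
            runs[session_id] = {}
            for run in range(cfg.runs_per_session):
                run_id = f"R{run + 1}"
                x = _sample_gaussian(chol, cfg.t_per_run, rng)
                if cfg.ar_coeff > 0:
                    rho, scale = cfg.ar_coeff, np.sqrt(1 - cfg.ar_coeff ** 2)
                    out = np.empty_like(x)
                    out[0] = x[0]
                    for k in range(1, cfg.t_per_run):
                        out[k] = rho * out[k - 1] + scale * x[k]
                    x = out
                runs[session_id][run_id] = TimeSeriesMatrix(
                    values=x, tr_seconds=cfg.tr_seconds,
                    node_ids=list(atlas.node_ids), subject_id=sid,
                    session_id=session_id, run_id=run_id,
                )
        subjects.append(SyntheticSubject(sid, sex, float(mean_fd), runs))
    truth = {
        "base_edges": comp.base_edges,
        "subject_edge_sets": comp.subject_edge_sets,
        "sex_edge_set": comp.sex_edge_set,
        "precisions": precisions,
    }
    return SyntheticCohort(config=cfg, atlas=atlas, subjects=subjects, truth=truth)


def simulate_dynamic_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """State-switching cohort: a first-order Markov chain over shared state
    templates, each carrying the subject's fingerprint component.

    ``n_states = 1`` degenerates to the static generator. The true state
    sequence of every run is recorded in ``truth['state_sequences']``.
    """
    if cfg.n_states == 1:
        return simulate_cohort(cfg)
    atlas, rng, ids, sexes, comp, fd = _cohort_scaffold(cfg)
    iu = _edge_indices(cfg.n_nodes)
    e = iu[0].shape[0]
    net = np.array([atlas.network_index_of(nid) for nid in atlas.node_ids])
    within = net[iu[0]] == net[iu[1]]
    # per-state network backbones: same support, state-specific sign patterns
    # and weights, so the recurring states are well separated in FC space
    state_bases = []
    for _ in range(cfg.n_states):
        base = np.zeros(e)
        signs = rng.choice([-1.0, 1.0], int(within.sum()))
        base[within] = signs * rng.uniform(0.25, 0.45, int(within.sum()))
        state_bases.append(base)

    stay = 1.0 - 1.0 / cfg.state_dwell
    subjects = []
    sequences: dict = {}
    state_precisions: dict = {}
    for sid, sex, mean_fd in zip(ids, sexes, fd):
        runs: dict = {}
        for sess in range(cfg.n_sessions):
            session_id = f"S{sess + 1}"
            chols = []
            for s, base in enumerate(state_bases):
                omega = _assemble_precision(cfg, comp, sid, sex, session_id,
                                            base_edges=base)
                state_precisions[(sid, session_id, s)] = omega
                chols.append(cholesky(omega, lower=True))
            runs[session_id] = {}
            for run in range(cfg.runs_per_session):
                run_id = f"R{run + 1}"
                seq = np.empty(cfg.t_per_run, dtype=int)
                seq[0] = rng.integers(cfg.n_states)
                for t in range(1, cfg.t_per_run):
                    if rng.random() < stay:
                        seq[t] = seq[t - 1]
                    else:
                        others = [s for s in range(cfg.n_states) if s != seq[t - 1]]
                        seq[t] = others[rng.integers(len(others))]
                x = np.empty((cfg.t_per_run, cfg.n_nodes))
                for s in range(cfg.n_states):
                    mask = seq == s
                    if mask.any():
                        x[mask] = _sample_gaussian(chols[s], int(mask.sum()), rng)
                sequences[(sid, session_id, run_id)] = seq
                runs[session_id][run_id] = TimeSeriesMatrix(
                    values=x, tr_seconds=cfg.tr_seconds,
                    node_ids=list(atlas.node_ids), subject_id=sid,
                    session_id=session_id, run_id=run_id,
                )
        subjects.append(SyntheticSubject(sid, sex, float(mean_fd), runs))
    truth = {
        "state_bases": state_bases,
        "subject_edge_sets": comp.subject_edge_sets,
        "sex_edge_set": comp.sex_edge_set,
        "state_precisions": state_precisions,
        "state_sequences": sequences,
    }
    return SyntheticCohort(config=cfg, atlas=atlas, subjects=subjects, truth=truth)


# ---------------------------------------------------------------------------
# named study conditions (desk scale)
# ---------------------------------------------------------------------------
# Desk-scale cohorts share a 30-node / 5-network atlas with 600-sample runs,
# two runs per session and two sessions, mirroring the cohort layout of a
# two-day rfMRI protocol at a size where the full pipeline runs in seconds.

_DESK = dict(n_nodes=30, n_networks=5, t_per_run=600, tr_seconds=0.72,
             runs_per_session=2, n_sessions=2)


def fingerprint_cohort_config(n_subjects: int = 40, seed: int = 0) -> SyntheticConfig:
    """Strong, stable fingerprints: subject effect far above session noise."""
    return SyntheticConfig(n_subjects=n_subjects, subject_effect=0.6,
                           sex_effect=0.0, session_noise=0.05, seed=seed, **_DESK)


def chance_cohort_config(n_subjects: int = 40, seed: int = 0) -> SyntheticConfig:
    """No subject-specific structure at all: identification is at chance."""
    return SyntheticConfig(n_subjects=n_subjects, subject_effect=0.0,
                           sex_effect=0.0, session_noise=0.3, seed=seed, **_DESK)


def confounded_cohort_config(n_subjects: int = 40, seed: int = 0) -> SyntheticConfig:
    """Sparse direct fingerprints plus indirect-correlation confounds with
    full-length (1200-sample) runs and substantial session noise."""
    desk = dict(_DESK)
    desk["t_per_run"] = 1200
    return SyntheticConfig(n_subjects=n_subjects, subject_effect=0.45,
                           sex_effect=0.0, session_noise=0.3, seed=seed, **desk)


def sex_null_cohort_config(n_subjects: int = 60, seed: int = 0) -> SyntheticConfig:
    """No sex effect: sex classification should sit at 50%."""
    return SyntheticConfig(n_subjects=n_subjects, subject_effect=0.3,
                           sex_effect=0.0, session_noise=0.2, seed=seed, **_DESK)


def sex_strong_cohort_config(n_subjects: int = 60, seed: int = 0) -> SyntheticConfig:
    """Sex effect dominating subject idiosyncrasy."""
    return SyntheticConfig(n_subjects=n_subjects, subject_effect=0.15,
                           sex_effect=0.8, session_noise=0.05, seed=seed, **_DESK)


def dynamic_two_state_config(n_subjects: int = 3, seed: int = 0) -> SyntheticConfig:
    """Two well-separated states with dwell times much longer than the
    sliding window, for state-recovery checks. Runs are long enough
    (~16 dwell segments) for realized occupancies to be stable."""
    return SyntheticConfig(
        n_subjects=n_subjects, n_nodes=20, n_networks=4, t_per_run=2400,
        tr_seconds=0.72, runs_per_session=1, n_sessions=1,
        subject_effect=0.2, sex_effect=0.0, session_noise=0.0,
        n_states=2, state_dwell=150, seed=seed,
    )
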