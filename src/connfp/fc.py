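"""Connectivity estimators: Pearson sFC, partial-correlation sFC, and
sliding-window dynamic FC with K-means state extraction.

Three estimators of the node-by-node connectivity matrix from a run's time
series:

``pearson_sfc``
    Pairwise Pearson correlation over the full run, Fisher-z transformed.
    Simple, but marginal correlation mixes direct and indirect connections.

``partial_sfc``
    Partial correlation from the inverse sample covariance (precision)
    matrix: ``r_ij = -P_ij / sqrt(P_ii P_jj)``, Fisher-z transformed.
    Regresses out all other nodes, so it estimates *direct* connections.
    Requires more time points than nodes.

``sliding_windows`` + ``cluster_states``
    Windowed Pearson correlation (Fisher-z, vectorized), clustered with
    K-means into K recurring connectivity states ordered by occupancy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .io_core import (
    FCMatrix,
    FCVector,
    TimeSeriesMatrix,
    ValidationError,
    devectorize,
    vectorize_upper,
)

__all__ = [
    "DFCConfig",
    "DynamicStates",
    "fisher_z",
    "pearson_sfc",
    "partial_sfc",
    "sliding_windows",
    "window_count",
    "cluster_states",
    "dfc_for_run",
]

#: clip applied before atanh so that |r| = 1 maps to a large finite z
FISHER_CLIP_EPS = 1e-7


def fisher_z(r):
    """Fisher transformation z = atanh(r), with |r| clipped to 1 - 1e-7.

    Accepts scalars or arrays. Values with |r| > 1 (beyond numerical
    round-off) are rejected.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValidationError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(arr, -1.0 + FISHER_CLIP_EPS, 1.0 - FISHER_CLIP_EPS))
    return z if arr.ndim else float(z)


@dataclass(frozen=True)
class DFCConfig:
    """Sliding-window / state-clustering parameters.

    window_tr, step_tr are in samples. The defaults (85-sample window,
    5-sample step, K = 4 states) correspond to a 61.2 s window and a 3.6 s
    step at TR = 0.72 s; the window length is ~1/f_min of the default
    bandpass.
    """

    window_tr: int = 85
    step_tr: int = 5
    n_states: int = 4
    seed: int = 0
    n_restarts: int = 10

    def __post_init__(self) -> None:
        if self.window_tr < 2:
            raise ValidationError("window_tr must be >= 2 samples")
        if self.step_tr < 1:
            raise ValidationError("step_tr must be >= 1")
        if self.n_states < 1:
            raise ValidationError("n_states must be >= 1")
        if self.n_restarts < 1:
            raise ValidationError("n_restarts must be >= 1")


@dataclass
class DynamicStates:
    """K state FC matrices sorted by window occupancy (descending).

    ``window_assignments[w]`` is the (post-sort) state index of window ``w``;
    ``counts[k]`` is the occupancy of state ``k`` and is non-increasing in k.
    """

    states: list[FCMatrix]
    counts: np.ndarray
    window_assignments: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.window_assignments = np.asarray(self.window_assignments, dtype=int)
        if np.any(np.diff(self.counts) > 0):
            raise ValidationError("state counts must be non-increasing")
        if self.counts.sum() != self.window_assignments.shape[0]:
            raise ValidationError("counts must sum to the number of windows")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_nodes(self) -> int:
        return self.states[0].n_nodes

    def state_vectors(self) -> np.ndarray:
        """(K, n_edges) array of vectorized states in occupancy order."""
        return np.stack([vectorize_upper(s).values for s in self.states])

    def occupancy_fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def _check_variance(values: np.ndarray, node_ids: Sequence[str]) -> None:
    sd = values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [node_ids[k] for k in bad[:5]]
        raise ValidationError(f"zero-variance node series: {names}")


def pearson_sfc(ts: TimeSeriesMatrix) -> FCMatrix:
    """Full-run Pearson correlation, Fisher-z, zero diagonal."""
    if ts.n_timepoints < 3:
        raise ValidationError("Pearson sFC needs at least 3 time points")
    _check_variance(ts.values, ts.node_ids)
    r = np.corrcoef(ts.values, rowvar=False)
    r = (r + r.T) / 2.0  # enforce exact symmetry against round-off
    z = fisher_z(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(z, 0.0)
    return FCMatrix(values=z, method_tag="pearson_sfc", node_ids=list(ts.node_ids))


def partial_sfc(ts: TimeSeriesMatrix, *, ridge: float = 0.0,
                max_condition: float = 1e12) -> FCMatrix:
    """Partial correlation from the inverse sample covariance.

    With ``P`` the precision (inverse covariance) matrix, the partial
    correlation between nodes i and j given all others is
    ``-P_ij / sqrt(P_ii P_jj)``. An optional ridge term (``ridge * mean
    diagonal`` added to the covariance diagonal) is available for
    ill-conditioned inputs and defaults to 0.
    """
    t, n = ts.values.shape
    if t <= n:
        raise ValidationError(
            f"partial correlation needs more time points than nodes "
            f"(T={t}, n={n}); use a longer series or fewer nodes"
        )
    _check_variance(ts.values, ts.node_ids)
    cov = np.cov(ts.values, rowvar=False, ddof=1)
    if ridge > 0:
        cov = cov + ridge * np.mean(np.diag(cov)) * np.eye(n)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > max_condition:
        raise ValidationError(
            f"sample covariance is ill-conditioned (cond={cond:.3g}); "
            "use a longer series, fewer nodes, or a ridge term"
        )
    p = np.linalg.inv(cov)
    d = np.sqrt(np.diag(p))
    r = -p / np.outer(d, d)
    r = (r + r.T) / 2.0
    z = fisher_z(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(z, 0.0)
    return FCMatrix(values=z, method_tag="partial_sfc", node_ids=list(ts.node_ids))


def window_count(t: int, window_tr: int, step_tr: int) -> int:
    """Number of full windows: floor((T - window)/step) + 1."""
    if window_tr > t:
        raise ValidationError(f"window ({window_tr}) exceeds series length ({t})")
    return (t - window_tr) // step_tr + 1


def sliding_windows(ts: TimeSeriesMatrix, cfg: DFCConfig) -> list[FCVector]:
    """Windowed Pearson FC: one Fisher-z FCVector per fully-fitting window.

    Windows start at samples 0, step, 2*step, ...; a window is used only if
    it fits entirely within the run.
    """
    t = ts.n_timepoints
    n_win = window_count(t, cfg.window_tr, cfg.step_tr)
    # per-run z-scoring: Pearson within each window is invariant to it,
    # it only improves numerical conditioning
    x = (ts.values - ts.values.mean(axis=0)) / ts.values.std(axis=0, ddof=1)
    iu = np.triu_indices(ts.n_nodes, k=1)
    out: list[FCVector] = []
    for w in range(n_win):
        start = w * cfg.step_tr
        seg = x[start:start + cfg.window_tr]
        _check_variance(seg, ts.node_ids)
        r = np.corrcoef(seg, rowvar=False)
        z = fisher_z(np.clip(r[iu], -1.0, 1.0))
        out.append(FCVector(values=z, n_nodes=ts.n_nodes))
    return out


def cluster_states(windows: Sequence[FCVector], cfg: DFCConfig,
                   node_ids: list[str] | None = None) -> DynamicStates:
    """K-means over window vectors; centroids become state FC matrices.

    Squared-Euclidean K-means, ``cfg.n_restarts`` seeded restarts, best run
    by within-cluster sum of squares (empty clusters are re-seeded at the
    farthest points). States are sorted by occupancy, descending; occupancy
    ties are broken by the first window index assigned to the state.
    """
    if len(windows) == 0:
        raise ValidationError("no windows to cluster")
    if cfg.n_states > len(windows):
        raise ValidationError(
            f"K={cfg.n_states} exceeds the number of windows ({len(windows)})"
        )
    x = np.stack([w.values for w in windows])
    if cfg.n_states == 1 or len(windows) == 1:
        centroids = x.mean(axis=0, keepdims=True)
        labels = np.zeros(len(windows), dtype=int)
    else:
        km = KMeans(
            n_clusters=cfg.n_states, n_init=cfg.n_restarts, max_iter=300,
            tol=1e-6, random_state=cfg.seed, algorithm="lloyd",
        ).fit(x)
        centroids, labels = km.cluster_centers_, km.labels_
    counts = np.bincount(labels, minlength=centroids.shape[0])
    first_idx = np.array([
        int(np.flatnonzero(labels == k)[0]) if counts[k] else len(windows)
        for k in range(centroids.shape[0])
    ])
    order = sorted(range(centroids.shape[0]), key=lambda k: (-counts[k], first_idx[k]))
    remap = {old: new for new, old in enumerate(order)}
    states = [
        devectorize(centroids[k], method_tag="dfc_state", node_ids=node_ids)
        for k in order
    ]
    return DynamicStates(
        states=states,
        counts=counts[order],
        window_assignments=np.array([remap[l] for l in labels]),
    )


def dfc_for_run(runs: TimeSeriesMatrix | Sequence[TimeSeriesMatrix],
                cfg: DFCConfig) -> DynamicStates:
    """Sliding windows -> one K-means clustering.

    When several runs of one session are given, their window vectors are
    pooled before a single clustering (averaging centroid *sets* across
    runs is ill-defined, pooling windows is not).
    """
    if isinstance(runs, TimeSeriesMatrix):
        runs = [runs]
    if not runs:
        raise ValidationError("no runs supplied")
    node_ids = list(runs[0].node_ids)
    windows: list[FCVector] = []
    for ts in runs:
        if list(ts.node_ids) != node_ids:
            raise ValidationError("node id mismatch between pooled runs")
        windows.extend(sliding_windows(ts, cfg))
    return cluster_states(windows, cfg, node_ids=node_ids)
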