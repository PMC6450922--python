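"""Edge-level statistics: consistency, variability, differential power, and
resting-state-network contribution summaries.

* Edge consistency selects edges whose strength standard deviation across
  subjects falls in the bottom percentile tail (edges shared by everyone —
  useless for telling subjects apart); edge variability selects the top
  tail (edges that differ between people).
* The differential power DP(e) of an edge is the empirical probability,
  averaged over subjects, that the within-subject cross-session edge
  product exceeds the corresponding between-subject products.  With
  ``X_i^{S1}, X_i^{S2}`` the (vectorized) session fingerprints and

      phi_ij(e) = X_i^S1(e) * X_j^S2(e) / (||X_i^S1|| ||X_j^S2||),

  subject i's score at edge e is

      P_i(e) = [ #{j != i : phi_ii(e) > phi_ij(e)}
               + #{j != i : phi_ii(e) > phi_ji(e)} ] / (2 (N - 1)),

  and DP(e) = mean_i P_i(e) in [0, 1].  This is the mean-based variant of
  the original logarithmic differential power, which avoids undefined
  values when an empirical probability is zero.  Comparisons are strict, so
  a cohort of identical fingerprints yields DP = 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import EdgeIndexMap, FCVector, NetworkAtlas, ValidationError

__all__ = [
    "EdgeReport",
    "NetworkContribution",
    "edge_std",
    "threshold_edges",
    "differential_power",
    "group_differential_power",
    "network_contribution",
    "build_edge_report",
]


def _stack_vectors(vectors: Sequence) -> np.ndarray:
    rows = [v.values if isinstance(v, FCVector) else np.asarray(v, float)
            for v in vectors]
    arr = np.stack(rows)
    if arr.ndim != 2:
        raise ValidationError("expected one 1-D FC vector per subject")
    return arr


def edge_std(vectors: Sequence) -> np.ndarray:
    """Per-edge standard deviation of edge strength across subjects
    (unbiased, N-1 denominator)."""
    x = _stack_vectors(vectors)
    if x.shape[0] < 2:
        raise ValidationError("edge std needs at least 2 subjects")
    return x.std(axis=0, ddof=1)


def threshold_edges(stds: np.ndarray, percentile: float, mode: str) -> np.ndarray:
    """Boolean mask of the percentile tail of the edge-std distribution.

    ``consistency``: std <= P_q (low-variance tail); ``variability``:
    std >= P_q (high-variance tail). Percentiles use linear interpolation
    between order statistics; comparisons are inclusive at the threshold.
    """
    stds = np.asarray(stds, dtype=float)
    if stds.size == 0:
        raise ValidationError("empty std vector")
    if not (0.0 < percentile < 100.0):
        raise ValidationError("percentile must lie in (0, 100)")
    q = np.percentile(stds, percentile, method="linear")
    if mode == "consistency":
        return stds <= q
    if mode == "variability":
        return stds >= q
    raise ValidationError(f"mode must be 'consistency' or 'variability', got {mode!r}")


def _phi_scores(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Per-unit P_i(e) matrix, shape (N, E), from stacked session vectors."""
    n = s1.shape[0]
    n1 = np.linalg.norm(s1, axis=1)
    n2 = np.linalg.norm(s2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValidationError("zero-norm FC vector")
    a = s1 / n1[:, None]                    # rows X_i^S1 / ||X_i^S1||
    b = s2 / n2[:, None]
    diag = a * b                            # phi_ii(e), shape (N, E)
    # phi_ij(e) = a[i, e] * b[j, e]; compare against phi_ii(e) over j != i
    phi = a[:, None, :] * b[None, :, :]     # (i, j, e)
    gt_ij = (diag[:, None, :] > phi).sum(axis=1)                  # counts incl. j=i (never true)
    gt_ji = (diag[:, None, :] > np.swapaxes(phi, 0, 1)).sum(axis=1)
    return (gt_ij + gt_ji) / (2.0 * (n - 1))


def differential_power(s1_vectors: Sequence, s2_vectors: Sequence) -> np.ndarray:
    """Modified differential power DP(e) per edge, in [0, 1].

    ``s1_vectors[i]`` and ``s2_vectors[i]`` are subject i's session-1 and
    session-2 fingerprints.
    """
    s1 = _stack_vectors(s1_vectors)
    s2 = _stack_vectors(s2_vectors)
    if s1.shape != s2.shape:
        raise ValidationError("session-1 and session-2 stacks differ in shape")
    if s1.shape[0] < 2:
        raise ValidationError("differential power needs at least 2 subjects")
    return _phi_scores(s1, s2).mean(axis=0)


def group_differential_power(male_s1, male_s2, female_s1, female_s2
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Differential power with the two sexes as the two units (N = 2).

    The inputs are the four group-average fingerprints. Returns
    ``(P_male(e), P_female(e))``, each with values in {0, 0.5, 1}.
    """
    s1 = _stack_vectors([male_s1, female_s1])
    s2 = _stack_vectors([male_s2, female_s2])
    p = _phi_scores(s1, s2)
    return p[0], p[1]


@dataclass
class NetworkContribution:
    """Percentage contribution of each network to a set of selected edges.

    A within-network edge credits 1 to its network; a between-network edge
    credits 0.5 to each endpoint network, so per-network percentages sum to
    100. ``blocks`` is the networks x networks grid of selected-edge
    percentages (symmetric; within-network on the diagonal), whose unique
    blocks also sum to 100.
    """

    per_network: pd.Series
    blocks: pd.DataFrame
    n_selected: int


def network_contribution(selected: np.ndarray, edge_map: EdgeIndexMap
                         ) -> NetworkContribution:
    """Summarize which networks a selected edge set lives in."""
    if edge_map.atlas is None:
        raise ValidationError("edge map needs an atlas for network contributions")
    selected = np.asarray(selected)
    if selected.dtype == bool:
        idx = np.flatnonzero(selected)
    else:
        idx = selected.astype(int)
    if idx.size == 0:
        raise ValidationError("no edges selected")
    networks = edge_map.atlas.networks
    k = len(networks)
    credit = np.zeros(k)
    block = np.zeros((k, k))
    ni = edge_map.network_i[idx]
    nj = edge_map.network_j[idx]
    for a, b in zip(ni, nj):
        if a == b:
            credit[a] += 1.0
            block[a, a] += 1.0
        else:
            credit[a] += 0.5
            credit[b] += 0.5
            block[a, b] += 1.0
            block[b, a] += 1.0
    total = idx.size
    per_network = pd.Series(100.0 * credit / total, index=networks)
    # percentages are of total selected edges; the symmetric off-diagonal
    # mirror repeats the same block, so unique blocks sum to 100
    block_pct = 100.0 * block / total
    blocks = pd.DataFrame(block_pct, index=networks, columns=networks)
    return NetworkContribution(per_network=per_network, blocks=blocks,
                               n_selected=int(total))


@dataclass
class EdgeReport:
    """Per-edge statistics for a cohort and one FC method."""

    edge_std: np.ndarray
    consistency_mask: np.ndarray
    variability_mask: np.ndarray
    dp: np.ndarray | None
    consistency_percentile: float
    variability_percentile: float

    def as_frame(self, edge_map: EdgeIndexMap) -> pd.DataFrame:
        df = pd.DataFrame({
            "edge": np.arange(edge_map.n_edges),
            "node_i": edge_map.i_idx,
            "node_j": edge_map.j_idx,
            "std": self.edge_std,
            "consistency": self.consistency_mask,
            "variability": self.variability_mask,
        })
        if self.dp is not None:
            df["dp"] = self.dp
        return df


def build_edge_report(s1_vectors: Sequence, s2_vectors: Sequence | None = None,
                      consistency_percentile: float = 5.0,
                      variability_percentile: float = 95.0,
                      with_dp: bool = True) -> EdgeReport:
    """Edge std + tail masks from session-1 fingerprints, and DP when the
    session-2 fingerprints are supplied."""
    stds = edge_std(s1_vectors)
    dp = None
    if with_dp:
        if s2_vectors is None:
            raise ValidationError("differential power needs session-2 vectors")
        dp = differential_power(s1_vectors, s2_vectors)
    return EdgeReport(
        edge_std=stds,
        consistency_mask=threshold_edges(stds, consistency_percentile, "consistency"),
        variability_mask=threshold_edges(stds, variability_percentile, "variability"),
        dp=dp,
        consistency_percentile=consistency_percentile,
        variability_percentile=variability_percentile,
    )
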