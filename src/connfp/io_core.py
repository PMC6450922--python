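"""Core data containers and file round-trips for connectivity analysis.

The conventions frozen here are used everywhere downstream:

* A functional-connectivity (FC) matrix is a symmetric ``n x n`` matrix of
  Fisher-z values with an exactly zero diagonal.
* Its vector form concatenates the ``n(n-1)/2`` strictly-upper-triangular
  entries in row-major order over pairs ``(i, j)`` with ``i < j``.  All
  downstream statistics (cosine similarity, differential power) are invariant
  to the ordering, but a single fixed order is required for file round-trips
  and per-edge reporting.
* Time-series files are delimited text with a header row of node ids, rows =
  time points, columns = nodes.  Node identity is matched by id, never by
  position, when an atlas is present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesMatrix",
    "NetworkAtlas",
    "FCMatrix",
    "FCVector",
    "EdgeIndexMap",
    "ValidationError",
    "vectorize_upper",
    "devectorize",
    "read_timeseries",
    "write_timeseries",
    "read_atlas",
    "write_atlas",
    "read_fc",
    "write_fc",
]

#: method tags recognised on FCMatrix
METHOD_TAGS = ("pearson_sfc", "partial_sfc", "dfc_state")


class ValidationError(ValueError):
    """Raised when a container invariant or file contract is violated."""


@dataclass
class TimeSeriesMatrix:
    """One run's node time series: ``values[t, k]`` is node ``k`` at time ``t``.

    Parameters
    ----------
    values : (T, n) float array, T >= 2, n >= 2, finite.
    tr_seconds : sampling interval (the fMRI repetition time), > 0.
    node_ids : n unique node identifiers, column order.
    subject_id, session_id, run_id : opaque provenance labels.
    """

    values: np.ndarray
    tr_seconds: float
    node_ids: list[str]
    subject_id: str = ""
    session_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("time series must be a 2-D array (T x n)")
        t, n = self.values.shape
        if t < 2:
            raise ValidationError(f"need at least 2 time points, got T={t}")
        if n < 2:
            raise ValidationError(f"need at least 2 nodes, got n={n}")
        if not np.isfinite(self.values).all():
            raise ValidationError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        self.node_ids = [str(x) for x in self.node_ids]
        if len(self.node_ids) != n:
            raise ValidationError("node_ids length does not match column count")
        if len(set(self.node_ids)) != n:
            raise ValidationError("node_ids must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class NetworkAtlas:
    """Node -> network assignment; networks keep first-appearance order."""

    node_ids: list[str]
    network_of: Mapping[str, str]
    networks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_ids = [str(x) for x in self.node_ids]
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("atlas node ids must be unique")
        missing = [n for n in self.node_ids if n not in self.network_of]
        if missing:
            raise ValidationError(f"nodes without a network assignment: {missing[:5]}")
        if not self.networks:
            seen: dict[str, None] = {}
            for n in self.node_ids:
                seen.setdefault(self.network_of[n], None)
            self.networks = list(seen)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def network_index_of(self, node_id: str) -> int:
        return self.networks.index(self.network_of[node_id])


@dataclass
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix with an exactly-zero diagonal."""

    values: np.ndarray
    method_tag: str
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("FC matrix must be square")
        if self.values.shape[0] < 2:
            raise ValidationError("FC matrix needs at least 2 nodes")
        if not np.isfinite(self.values).all():
            raise ValidationError("FC matrix contains non-finite values")
        if not np.array_equal(self.values, self.values.T):
            raise ValidationError("FC matrix must be exactly symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValidationError("FC matrix diagonal must be exactly zero")
        if self.method_tag not in METHOD_TAGS:
            raise ValidationError(
                f"unknown method_tag {self.method_tag!r}; expected one of {METHOD_TAGS}"
            )
        if self.node_ids is not None:
            self.node_ids = [str(x) for x in self.node_ids]
            if len(self.node_ids) != self.values.shape[0]:
                raise ValidationError("node_ids length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class FCVector:
    """Upper-triangle vectorization of an FCMatrix (row-major over i < j)."""

    values: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("FC vector must be 1-D")
        expected = self.n_nodes * (self.n_nodes - 1) // 2
        if self.values.shape[0] != expected:
            raise ValidationError(
                f"FC vector for n={self.n_nodes} must have length {expected}, "
                f"got {self.values.shape[0]}"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs, n(n-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def _n_from_triangular(length: int) -> int:
    """Invert m(m-1)/2 = length; raise if length is not triangular."""
    m = int((1 + math.isqrt(1 + 8 * length)) // 2)
    if m < 2 or m * (m - 1) // 2 != length:
        raise ValidationError(f"length {length} is not n(n-1)/2 for any integer n >= 2")
    return m


class EdgeIndexMap:
    """Bijection between edge index ``e`` and node pair ``(i, j)``, ``i < j``.

    With an atlas attached, each edge is classified as within-network
    (both endpoints share a network) or between-network.
    """

    def __init__(self, n_nodes: int, atlas: NetworkAtlas | None = None):
        if n_nodes < 2:
            raise ValidationError("need at least 2 nodes")
        if atlas is not None and atlas.n_nodes != n_nodes:
            raise ValidationError("atlas size does not match n_nodes")
        self.n_nodes = n_nodes
        self.i_idx, self.j_idx = np.triu_indices(n_nodes, k=1)  # row-major
        self.atlas = atlas
        if atlas is not None:
            net = np.array([atlas.network_index_of(nid) for nid in atlas.node_ids])
            self.network_i = net[self.i_idx]
            self.network_j = net[self.j_idx]
            self.within = self.network_i == self.network_j
        else:
            self.network_i = self.network_j = self.within = None

    @property
    def n_edges(self) -> int:
        return self.i_idx.shape[0]

    def pair_of(self, e: int) -> tuple[int, int]:
        return int(self.i_idx[e]), int(self.j_idx[e])

    def edge_of(self, i: int, j: int) -> int:
        if i == j:
            raise ValidationError("diagonal entries are not edges")
        if i > j:
            i, j = j, i
        # row-major offset of pair (i, j) in the strict upper triangle
        n = self.n_nodes
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    def classification(self, e: int) -> tuple[str, ...]:
        """('within', net) or ('between', net_a, net_b) for edge ``e``."""
        if self.atlas is None:
            raise ValidationError("no atlas attached to this edge map")
        a = self.atlas.networks[self.network_i[e]]
        b = self.atlas.networks[self.network_j[e]]
        return ("within", a) if a == b else ("between", a, b)


def vectorize_upper(fc: FCMatrix) -> FCVector:
    """Concatenate the n(n-1)/2 upper-triangular entries of ``fc``."""
    iu = np.triu_indices(fc.n_nodes, k=1)
    return FCVector(values=fc.values[iu].copy(), n_nodes=fc.n_nodes)


def devectorize(v: FCVector | np.ndarray, method_tag: str = "pearson_sfc",
                node_ids: list[str] | None = None) -> FCMatrix:
    """Rebuild the symmetric zero-diagonal matrix from its upper triangle."""
    vals = v.values if isinstance(v, FCVector) else np.asarray(v, dtype=float)
    n = _n_from_triangular(vals.shape[0])
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = vals
    m = m + m.T
    return FCMatrix(values=m, method_tag=method_tag, node_ids=node_ids)


# ---------------------------------------------------------------------------
# file round-trips (delimited text, full double precision)
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(path: str | Path, tr_seconds: float, *, subject_id: str = "",
                    session_id: str = "", run_id: str = "") -> TimeSeriesMatrix:
    """Read a delimited time-series file (header of node ids, numeric body)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValidationError(f"{path}: empty file")
        node_ids = header.split(sep)
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(sep)
            if len(cells) != len(node_ids):
                raise ValidationError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected {len(node_ids)}"
                )
            parsed = []
            for col, cell in enumerate(cells):
                try:
                    x = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric cell at row {lineno}, column "
                        f"{col + 1} ({node_ids[col]!r}): {cell!r}"
                    ) from None
                if not math.isfinite(x):
                    raise ValidationError(
                        f"{path}: non-finite cell at row {lineno}, column {col + 1}"
                    )
                parsed.append(x)
            rows.append(parsed)
    if len(rows) < 2:
        raise ValidationError(f"{path}: need at least 2 time points, got {len(rows)}")
    return TimeSeriesMatrix(
        values=np.array(rows), tr_seconds=tr_seconds, node_ids=node_ids,
        subject_id=subject_id, session_id=session_id, run_id=run_id,
    )


def write_timeseries(path: str | Path, ts: TimeSeriesMatrix) -> None:
    path = Path(path)
    df = pd.DataFrame(ts.values, columns=ts.node_ids)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_atlas(path: str | Path) -> NetworkAtlas:
    """Read a two-column (node_id, network) delimited table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: atlas needs two columns (node_id, network)")
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: empty atlas")
    node_ids = df.iloc[:, 0].tolist()
    if len(set(node_ids)) != len(node_ids):
        raise ValidationError(f"{path}: duplicate node ids in atlas")
    network_of = dict(zip(node_ids, df.iloc[:, 1].tolist()))
    return NetworkAtlas(node_ids=node_ids, network_of=network_of)


def write_atlas(path: str | Path, atlas: NetworkAtlas) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"node_id": atlas.node_ids,
         "network": [atlas.network_of[n] for n in atlas.node_ids]}
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_fc(path: str | Path, fc: FCMatrix) -> None:
    """Write an FC matrix as TSV with a one-line metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#method_tag={fc.method_tag}\tn={fc.n_nodes}\n")
        if fc.node_ids is not None:
            fh.write("\t".join(fc.node_ids) + "\n")
        else:
            fh.write("\t".join(f"node{k}" for k in range(fc.n_nodes)) + "\n")
        np.savetxt(fh, fc.values, delimiter="\t", fmt="%.17g")


def read_fc(path: str | Path) -> FCMatrix:
    path = Path(path)
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("#method_tag="):
            raise ValidationError(f"{path}: missing metadata header")
        fields = dict(kv.split("=", 1) for kv in meta.lstrip("#").split("\t"))
        method_tag = fields["method_tag"]
        n = int(fields["n"])
        node_ids = fh.readline().strip().split("\t")
        body = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if body.shape != (n, n):
        raise ValidationError(
            f"{path}: expected a {n}x{n} matrix, got {body.shape[0]}x{body.shape[1]}"
        )
    return FCMatrix(values=body, method_tag=method_tag, node_ids=node_ids)
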