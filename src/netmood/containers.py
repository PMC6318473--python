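"""Core data containers shared across the pipeline.

The analysis joins two blocks of session-wise observations — a
sessions × edges functional-connectivity matrix ``X`` and a
sessions × scales mood matrix ``Y`` — plus a fixed node → community
partition used by all network-level statistics.  These containers pin
down the contracts the rest of the package relies on: a frozen edge
ordering (row-major upper triangle, ``i < j``), symmetric unit-diagonal
FC matrices, and session alignment between the two blocks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FCMatrix",
    "EdgeDataset",
    "MoodTable",
    "Partition",
    "PANAS_X_SCALES",
    "edge_index_for",
    "align_sessions",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_mood_tsv",
    "write_mood_tsv",
    "read_partition_tsv",
    "write_partition_tsv",
    "read_edge_dataset",
    "write_edge_dataset",
]

#: The 13 PANAS-X scales: 2 general dimensions plus 11 specific scales.
PANAS_X_SCALES = [
    "negative_affect",
    "positive_affect",
    "fear",
    "hostility",
    "guilt",
    "sadness",
    "joviality",
    "self_assurance",
    "attentiveness",
    "shyness",
    "fatigue",
    "serenity",
    "surprise",
]


def edge_index_for(n_nodes: int) -> np.ndarray:
    """Canonical edge ordering for ``n_nodes``: upper triangle, row-major.

    Returns an ``(n_edges, 2)`` integer array of ``(i, j)`` pairs with
    ``i < j``, sorted lexicographically.  This ordering is a frozen
    contract: every edge vector in the package follows it.
    """
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


@dataclass
class FCMatrix:
    """A single session's functional-connectivity matrix.

    Entries are zero-lag Pearson correlations between regional time
    series; the matrix is symmetric with unit diagonal.
    """

    values: np.ndarray
    node_ids: list[str]
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.values.shape[0]
        if self.values.shape != (k, k):
            raise ValueError(f"FC matrix must be square, got {self.values.shape}")
        if len(self.node_ids) != k:
            raise ValueError("node_ids length does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("FC matrix is not symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("FC matrix diagonal must be 1")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("FC entries must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def node_index(self, node: str) -> int:
        try:
            return self.node_ids.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None


@dataclass
class EdgeDataset:
    """Sessions × edges design matrix — the left PLS block.

    For ``k`` nodes there are ``k(k-1)/2`` unique connections; row ``s``
    holds the vectorized upper triangle of session ``s``'s FC matrix in
    the canonical edge order.
    """

    X: np.ndarray
    node_ids: list[str]
    session_ids: list[str]
    edge_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        k = len(self.node_ids)
        if self.edge_index is None:
            self.edge_index = edge_index_for(k)
        self.edge_index = np.asarray(self.edge_index, dtype=int)
        p = k * (k - 1) // 2
        if self.X.shape[1] != p:
            raise ValueError(
                f"expected {p} edges for {k} nodes, got {self.X.shape[1]} columns"
            )
        if self.edge_index.shape != (p, 2):
            raise ValueError("edge_index shape does not match edge count")
        # edge ordering is a frozen contract
        if not np.array_equal(self.edge_index, edge_index_for(k)):
            raise ValueError("edge_index must be the row-major upper triangle order")
        if len(self.session_ids) != self.X.shape[0]:
            raise ValueError("session_ids length does not match number of rows")

    @property
    def n_sessions(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]


@dataclass
class MoodTable:
    """Sessions × mood-scale matrix — the right PLS block."""

    Y: np.ndarray
    scale_names: list[str]
    session_ids: list[str]

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.shape[1] != len(self.scale_names):
            raise ValueError("scale_names length does not match number of columns")
        if len(self.session_ids) != self.Y.shape[0]:
            raise ValueError("session_ids length does not match number of rows")

    @property
    def n_sessions(self) -> int:
        return self.Y.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Y, index=self.session_ids, columns=self.scale_names)


@dataclass
class Partition:
    """Node → community assignment (e.g. resting-state network labels).

    ``labels`` holds one integer community index per node; index ``c``
    refers to ``community_names[c]``.
    """

    labels: np.ndarray
    community_names: list[str]
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n_comm = len(self.community_names)
        if self.labels.min(initial=0) < 0 or (
            self.labels.size and self.labels.max() >= n_comm
        ):
            raise ValueError("labels reference communities outside community_names")
        present = np.unique(self.labels)
        if len(present) != n_comm:
            raise ValueError("every community must be non-empty")
        if self.node_ids is not None and len(self.node_ids) != self.labels.size:
            raise ValueError("node_ids length does not match labels")

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def n_communities(self) -> int:
        return len(self.community_names)

    def members(self, community: int | str) -> np.ndarray:
        """Node indices belonging to a community (by index or name)."""
        if isinstance(community, str):
            community = self.community_names.index(community)
        return np.flatnonzero(self.labels == community)

    def relabeled(self, labels: np.ndarray) -> "Partition":
        """Same communities, different node assignment (used by nulls)."""
        return Partition(labels, list(self.community_names), self.node_ids)

    def within_edge_mask(self, edge_index: np.ndarray) -> np.ndarray:
        """Boolean mask over edges: True where both endpoints share a community."""
        return self.labels[edge_index[:, 0]] == self.labels[edge_index[:, 1]]


def align_sessions(edges: EdgeDataset, mood: MoodTable) -> tuple[EdgeDataset, MoodTable]:
    """Restrict both blocks to sessions present in each, preserving X's order.

    Only sessions with both a connectivity row and a mood row are
    analyzed; anything else is dropped with a warning.
    """
    common = [s for s in edges.session_ids if s in set(mood.session_ids)]
    if not common:
        raise ValueError(
            "no overlapping sessions between connectivity and mood tables; "
            f"connectivity has {edges.session_ids[:3]}..., mood has "
            f"{mood.session_ids[:3]}..."
        )
    dropped = (len(edges.session_ids) - len(common)) + (len(mood.session_ids) - len(common))
    if dropped:
        warnings.warn(f"dropping {dropped} session(s) without a match in both blocks")
    xi = [edges.session_ids.index(s) for s in common]
    yi = [mood.session_ids.index(s) for s in common]
    new_edges = EdgeDataset(edges.X[xi], edges.node_ids, common, edges.edge_index)
    new_mood = MoodTable(mood.Y[yi], mood.scale_names, common)
    return new_edges, new_mood


# ---------------------------------------------------------------------------
# Plain-text readers/writers (TSV + JSON sidecars)

def write_timeseries_tsv(path: str | Path, ts: np.ndarray, node_ids: Sequence[str]) -> None:
    pd.DataFrame(ts, columns=list(node_ids)).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_mood_tsv(path: str | Path, mood: MoodTable) -> None:
    df = mood.to_frame()
    df.index.name = "session_id"
    df.to_csv(path, sep="\t")


def read_mood_tsv(path: str | Path) -> MoodTable:
    df = pd.read_csv(path, sep="\t", index_col="session_id")
    return MoodTable(df.to_numpy(dtype=float), list(df.columns), [str(s) for s in df.index])


def write_partition_tsv(path: str | Path, partition: Partition) -> None:
    node_ids = partition.node_ids or [f"n{i:04d}" for i in range(partition.n_nodes)]
    df = pd.DataFrame(
        {
            "node_id": node_ids,
            "community": [partition.community_names[c] for c in partition.labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition_tsv(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t")
    names = sorted(df["community"].astype(str).unique())
    idx = {name: i for i, name in enumerate(names)}
    labels = np.array([idx[str(c)] for c in df["community"]])
    return Partition(labels, names, [str(n) for n in df["node_id"]])


def write_edge_dataset(path_prefix: str | Path, ds: EdgeDataset) -> None:
    """Write X as TSV plus a JSON sidecar holding node ids and edge index."""
    prefix = Path(path_prefix)
    cols = [f"e{i}_{j}" for i, j in ds.edge_index]
    df = pd.DataFrame(ds.X, index=ds.session_ids, columns=cols)
    df.index.name = "session_id"
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t")
    sidecar = {
        "node_ids": ds.node_ids,
        "edge_index": ds.edge_index.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_edge_dataset(path_prefix: str | Path) -> EdgeDataset:
    prefix = Path(path_prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="session_id")
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return EdgeDataset(
        df.to_numpy(dtype=float),
        sidecar["node_ids"],
        [str(s) for s in df.index],
        np.asarray(sidecar["edge_index"]),
    )
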