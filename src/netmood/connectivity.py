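"""Functional connectivity from parceled time series.

FC is the zero-lag Pearson correlation between regional time series
within one session.  The upper triangle of each session's FC matrix
(row-major, ``i < j``) becomes one row of the sessions × edges design
matrix submitted to PLS.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EdgeDataset, FCMatrix, Partition, edge_index_for

__all__ = [
    "fc_matrix",
    "vectorize_upper",
    "devectorize_upper",
    "build_edge_dataset",
    "node_strength",
    "seed_to_community_fc",
]


class ZeroVarianceError(ValueError):
    """A time series (or data column) is constant, so correlation is undefined."""


def fc_matrix(
    ts: np.ndarray,
    node_ids: Sequence[str] | None = None,
    session_id: str | None = None,
) -> FCMatrix:
    """Pairwise Pearson correlation of a time × node matrix.

    Raises :class:`ZeroVarianceError` naming the offending node if any
    column is constant.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("time series must be 2-D with at least 3 time points")
    k = ts.shape[1]
    if node_ids is None:
        node_ids = [f"n{i:04d}" for i in range(k)]
    sds = ts.std(axis=0)
    if np.any(sds == 0):
        bad = [node_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ZeroVarianceError(f"constant time series for node(s): {bad}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, list(node_ids), session_id)


def vectorize_upper(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Upper triangle of an FC matrix in the canonical edge order."""
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc)
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def devectorize_upper(vec: np.ndarray, n_nodes: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (diagonal filled with ``diagonal``)."""
    vec = np.asarray(vec, dtype=float)
    expected = n_nodes * (n_nodes - 1) // 2
    if vec.size != expected:
        raise ValueError(f"expected {expected} edges for {n_nodes} nodes, got {vec.size}")
    mat = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    mat[iu] = vec
    mat = mat + mat.T
    np.fill_diagonal(mat, diagonal)
    return mat


def build_edge_dataset(
    series: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    node_ids: Sequence[str] | None = None,
) -> EdgeDataset:
    """Stack vectorized session FC matrices into a sessions × edges matrix.

    ``series`` is either a mapping of session id → time × node array or a
    plain sequence (session ids are then generated).  All sessions must
    share the node count; session order is preserved.
    """
    if isinstance(series, Mapping):
        ids = [str(s) for s in series]
        arrays = [np.asarray(series[s]) for s in series]
    else:
        arrays = [np.asarray(a) for a in series]
        ids = [f"ses-{s + 1:03d}" for s in range(len(arrays))]
    if not arrays:
        raise ValueError("no sessions supplied")
    k = arrays[0].shape[1]
    bad = [ids[i] for i, a in enumerate(arrays) if a.shape[1] != k]
    if bad:
        raise ValueError(f"inconsistent node count in session(s): {bad}")
    if node_ids is None:
        node_ids = [f"n{i:04d}" for i in range(k)]
    rows = [vectorize_upper(fc_matrix(a, node_ids, sid)) for sid, a in zip(ids, arrays)]
    return EdgeDataset(np.vstack(rows), list(node_ids), ids, edge_index_for(k))


def node_strength(fc: FCMatrix, node: str) -> float:
    """Mean correlation of a node with all other nodes (diagonal excluded).

    Signed raw correlations are averaged — no absolute value, no Fisher
    transform.
    """
    i = fc.node_index(node)
    row = np.delete(fc.values[i], i)
    return float(row.mean())


def seed_to_community_fc(
    fc: FCMatrix, seed: str, partition: Partition
) -> pd.Series:
    """Mean FC between a seed node and each community.

    The seed is excluded from its own community's average.  A community
    containing only the seed yields NaN (flagged, never silently zero).
    """
    if partition.n_nodes != fc.n_nodes:
        raise ValueError("partition does not cover the FC matrix's nodes")
    si = fc.node_index(seed)
    out = {}
    for c, name in enumerate(partition.community_names):
        members = partition.members(c)
        members = members[members != si]
        out[name] = float(fc.values[si, members].mean()) if members.size else np.nan
    return pd.Series(out, name=seed)
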