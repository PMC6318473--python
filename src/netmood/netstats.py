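"""Network-level statistics: regional contributions, community-block
summaries with label-permuting nulls, and per-session
segregation–integration measures.

Modularity follows the Newman–Girvan weighted form with the
configuration-model null, computed on the positive-weight subgraph:

    Q = (1 / 2m) Σ_ij [w_ij − s_i s_j / 2m] δ(c_i, c_j)

(the 1/2m normalization can be dropped via ``normalized=False`` to
obtain the raw sum).  System segregation is the normalized difference of
mean within- and between-community connectivity, S = (Z_w − Z_b) / Z_w,
computed on raw signed weights, as are within/between densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EdgeDataset, FCMatrix, Partition

__all__ = [
    "BlockSummary",
    "edge_vector_to_matrix",
    "regional_mean_bsr",
    "top_fraction_nodes",
    "rsn_block_means",
    "label_permutation_null",
    "within_between_density",
    "modularity",
    "system_segregation",
    "session_network_measures",
    "measure_behavior_correlation",
    "session_consistent_label_null",
    "seed_fingerprint_analysis",
]

MEASURE_NAMES = ["within_density", "between_density", "modularity", "segregation"]


@dataclass
class BlockSummary:
    """Per community-pair mean statistic (symmetric; NaN = undefined block)."""

    means: np.ndarray   # n_comm × n_comm
    counts: np.ndarray  # qualifying edges per block
    community_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.means, index=self.community_names, columns=self.community_names
        )


def edge_vector_to_matrix(values: np.ndarray, edge_index: np.ndarray) -> np.ndarray:
    """Symmetric node × node matrix from an edge vector (zero diagonal)."""
    values = np.asarray(values, dtype=float)
    edge_index = np.asarray(edge_index, dtype=int)
    if values.size != edge_index.shape[0]:
        raise ValueError(
            f"edge vector length {values.size} does not match "
            f"edge_index with {edge_index.shape[0]} entries"
        )
    k = int(edge_index.max()) + 1 if edge_index.size else 0
    mat = np.zeros((k, k))
    mat[edge_index[:, 0], edge_index[:, 1]] = values
    mat[edge_index[:, 1], edge_index[:, 0]] = values
    return mat


def regional_mean_bsr(mat: np.ndarray) -> np.ndarray:
    """Per-node mean of the k−1 incident edge values (diagonal excluded)."""
    mat = np.asarray(mat, dtype=float)
    k = mat.shape[0]
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    return (mat.sum(axis=1) - np.diag(mat)) / (k - 1)


def top_fraction_nodes(
    values: np.ndarray, fraction: float, mode: str = "positive"
) -> np.ndarray:
    """Indices of the top ⌈fraction · k⌉ nodes by the chosen ranking.

    ``positive``/``absolute`` rank descending (by value / |value|),
    ``negative`` ranks ascending.  Ties are broken by node index.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    k = values.size
    n_top = int(np.ceil(fraction * k))
    if mode == "positive":
        key = -values
    elif mode == "negative":
        key = values
    elif mode == "absolute":
        key = -np.abs(values)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    order = np.lexsort((np.arange(k), key))  # stable: ties by node index
    return order[:n_top]


def _block_masks(partition: Partition) -> np.ndarray:
    """Boolean node masks per community, stacked (n_comm × k)."""
    return np.stack(
        [partition.labels == c for c in range(partition.n_communities)]
    )


def rsn_block_means(
    mat: np.ndarray, partition: Partition, sign: str = "positive"
) -> BlockSummary:
    """Mean sign-restricted edge value within and between communities.

    ``sign="positive"`` averages only entries > 0; ``"negative"`` averages
    only entries < 0 and reports magnitudes.  Blocks with no qualifying
    edge are NaN.  ``sign="signed"`` averages raw values.
    """
    if partition.n_communities < 2:
        raise ValueError("block statistics require at least 2 communities")
    mat = np.asarray(mat, dtype=float)
    k = mat.shape[0]
    if sign == "positive":
        qual = mat > 0
        vals = mat
    elif sign == "negative":
        qual = mat < 0
        vals = -mat
    elif sign == "signed":
        qual = np.ones_like(mat, dtype=bool)
        vals = mat
    else:
        raise ValueError(f"unknown sign {sign!r}")
    offdiag = ~np.eye(k, dtype=bool)
    qual = qual & offdiag

    masks = _block_masks(partition)
    C = partition.n_communities
    means = np.full((C, C), np.nan)
    counts = np.zeros((C, C), dtype=int)
    for a in range(C):
        for b in range(a, C):
            block = qual[np.ix_(masks[a], masks[b])]
            n = int(block.sum())
            if a == b:
                n //= 2  # diagonal blocks double-count ordered pairs
            counts[a, b] = counts[b, a] = n
            if n:
                m = vals[np.ix_(masks[a], masks[b])][block].mean()
                means[a, b] = means[b, a] = m
    return BlockSummary(means, counts, list(partition.community_names))


def label_permutation_null(
    statistic_fn: Callable[[Partition], np.ndarray],
    partition: Partition,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Node-label permutation null for any partition-valued statistic.

    ``statistic_fn`` maps a partition to an array of statistics (e.g. the
    block-mean matrix).  Labels are permuted uniformly per replicate and
    the statistic recomputed; returns observed values, null mean/sd,
    z-scores and two-sided p-values (+1 convention).  Entries with zero
    null sd get NaN z and a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    observed = np.asarray(statistic_fn(partition), dtype=float)
    null = np.empty((n_perm,) + observed.shape)
    for b in range(n_perm):
        null[b] = statistic_fn(partition.relabeled(rng.permutation(partition.labels)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices allowed
        null_mean = np.nanmean(null, axis=0)
        null_sd = np.nanstd(null, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
    if np.any(null_sd == 0):
        warnings.warn("zero null standard deviation: z undefined for some entries")
    dev = np.abs(null - null_mean)
    p = (np.nansum(dev >= np.abs(observed - null_mean), axis=0) + 1) / (n_perm + 1)
    return {
        "observed": observed,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "z": z,
        "p": p,
        "null": null,
    }


def within_between_density(mat: np.ndarray, partition: Partition) -> tuple[float, float]:
    """Mean signed FC over within-community and between-community edges."""
    if partition.n_communities < 2:
        raise ValueError("need at least 2 communities")
    mat = np.asarray(mat, dtype=float)
    k = mat.shape[0]
    iu = np.triu_indices(k, k=1)
    within = partition.labels[iu[0]] == partition.labels[iu[1]]
    vals = mat[iu]
    return float(vals[within].mean()), float(vals[~within].mean())


def modularity(mat: np.ndarray, partition: Partition, normalized: bool = True) -> float:
    """Weighted modularity of the positive subgraph under the given partition.

    Negative weights are zeroed; self-weights are ignored.  With
    ``normalized=False`` the raw (un-normalized) within-community excess
    Σ[w − ss/2m]δ is returned instead of the conventional Q.
    """
    mat = np.asarray(mat, dtype=float)
    W = np.where(mat > 0, mat, 0.0)
    np.fill_diagonal(W, 0.0)
    two_m = W.sum()
    if two_m == 0:
        raise ValueError("no positive weights: modularity undefined")
    s = W.sum(axis=1)
    same = partition.labels[:, None] == partition.labels[None, :]
    raw = (W[same]).sum() - (np.outer(s, s)[same]).sum() / two_m
    return float(raw / two_m) if normalized else float(raw)


def system_segregation(mat: np.ndarray, partition: Partition) -> float:
    """S = (Z_w − Z_b) / Z_w with Z the mean within/between edge weight."""
    zw, zb = within_between_density(mat, partition)
    if zw == 0:
        raise ValueError("mean within-community connectivity is zero: S undefined")
    return (zw - zb) / zw


# ---------------------------------------------------------------------------
# Vectorized per-session measures (shared by the session-consistent null)

def _session_measures_for_labels(
    X: np.ndarray,
    edge_index: np.ndarray,
    n_nodes: int,
    labels: np.ndarray,
    Wpos: np.ndarray,
    s_pos: np.ndarray,
    two_m: np.ndarray,
) -> np.ndarray:
    """All four measures for every session, given one label assignment.

    Returns an (n_sessions × 4) array ordered as MEASURE_NAMES.  Uses
    precomputed positive edge weights, node strengths and total weights.
    """
    within = labels[edge_index[:, 0]] == labels[edge_index[:, 1]]
    zw = X[:, within].mean(axis=1)
    zb = X[:, ~within].mean(axis=1)
    seg = (zw - zb) / zw

    n_comm = int(labels.max()) + 1
    onehot = np.zeros((n_nodes, n_comm))
    onehot[np.arange(n_nodes), labels] = 1.0
    # ordered-pair within sums: Σ_within w = 2 * Σ_{within edges} w_e;
    # Σ_within s_i s_j = Σ_c (Σ_{i∈c} s_i)²
    within_w = 2.0 * Wpos[:, within].sum(axis=1)
    S_c = s_pos @ onehot
    with np.errstate(invalid="ignore", divide="ignore"):
        Q = (within_w - (S_c**2).sum(axis=1) / two_m) / two_m
    return np.column_stack([zw, zb, Q, seg])


def _positive_precompute(X: np.ndarray, edge_index: np.ndarray, n_nodes: int):
    Wpos = np.where(X > 0, X, 0.0)
    # node strength: each edge contributes to both endpoints
    s_pos = np.zeros((X.shape[0], n_nodes))
    np.add.at(s_pos.T, edge_index[:, 0], Wpos.T)
    np.add.at(s_pos.T, edge_index[:, 1], Wpos.T)
    two_m = 2.0 * Wpos.sum(axis=1)
    return Wpos, s_pos, two_m


def session_network_measures(ds: EdgeDataset, partition: Partition) -> pd.DataFrame:
    """Within/between density, modularity Q and segregation S per session."""
    if partition.n_nodes != len(ds.node_ids):
        raise ValueError("partition does not cover the dataset's nodes")
    Wpos, s_pos, two_m = _positive_precompute(ds.X, ds.edge_index, partition.n_nodes)
    vals = _session_measures_for_labels(
        ds.X, ds.edge_index, partition.n_nodes, partition.labels, Wpos, s_pos, two_m
    )
    return pd.DataFrame(vals, index=ds.session_ids, columns=MEASURE_NAMES)


def measure_behavior_correlation(
    measures: np.ndarray, behavior_scores: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation of a per-session measure with behavior scores."""
    measures = np.asarray(measures, dtype=float)
    behavior_scores = np.asarray(behavior_scores, dtype=float)
    if measures.size < 8:
        raise ValueError("need at least 8 sessions")
    if np.std(measures) == 0 or np.std(behavior_scores) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(measures, behavior_scores)
    return float(rho), float(p)


def session_consistent_label_null(
    ds: EdgeDataset,
    partition: Partition,
    behavior_scores: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Are measure–behavior correlations module-specific or density-driven?

    One label permutation per replicate, applied identically to every
    session; all four network measures and their Spearman correlations
    with the behavior scores are recomputed.  p per measure is the
    fraction of null |ρ| reaching the observed |ρ| (+1 convention) — the
    null hypothesis that unspecific density fluctuations, not module
    assignment, drive the correlation.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    behavior_scores = np.asarray(behavior_scores, dtype=float)
    k = partition.n_nodes
    Wpos, s_pos, two_m = _positive_precompute(ds.X, ds.edge_index, k)
    b_rank = stats.rankdata(behavior_scores)

    def correlations(labels: np.ndarray) -> np.ndarray:
        vals = _session_measures_for_labels(
            ds.X, ds.edge_index, k, labels, Wpos, s_pos, two_m
        )
        ranks = np.apply_along_axis(stats.rankdata, 0, vals)
        rc = ranks - ranks.mean(axis=0)
        bc = b_rank - b_rank.mean()
        denom = np.sqrt((rc**2).sum(axis=0) * (bc**2).sum())
        return (rc.T @ bc) / denom

    observed = correlations(partition.labels)
    null = np.empty((n_perm, 4))
    for b in range(n_perm):
        null[b] = correlations(rng.permutation(partition.labels))
    p = (np.sum(np.abs(null) >= np.abs(observed), axis=0) + 1) / (n_perm + 1)
    return pd.DataFrame(
        {"observed_rho": observed, "p_value": p}, index=MEASURE_NAMES
    )


def seed_fingerprint_analysis(
    fcs: Sequence[FCMatrix] | np.ndarray,
    seed_node: str | int,
    partition: Partition,
    positive_mood: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Seed → community connectivity fingerprint against mood.

    For each community, the across-session correlation between mean
    seed-to-community FC and positive mood is compared with a null built
    by permuting community labels over the non-seed nodes (the seed's
    own label is never permuted, and the seed is excluded from every
    community average).  Null correlations from all communities and
    replicates are pooled into a single distribution; z and two-sided p
    are reported per community.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    positive_mood = np.asarray(positive_mood, dtype=float)
    if positive_mood.std() == 0:
        raise ValueError("constant mood vector: correlation undefined")
    if isinstance(fcs, np.ndarray):
        stack = fcs
        si = int(seed_node)
    else:
        stack = np.stack([f.values for f in fcs])
        si = fcs[0].node_index(seed_node) if isinstance(seed_node, str) else int(seed_node)
    n_sessions, k, _ = stack.shape
    if positive_mood.size != n_sessions:
        raise ValueError("mood vector length does not match session count")

    seed_rows = stack[:, si, :]  # n_sessions × k
    others = np.delete(np.arange(k), si)
    other_labels = partition.labels[others]
    seed_fc = seed_rows[:, others]  # seed excluded from every average
    mc = positive_mood - positive_mood.mean()
    mnorm = np.sqrt((mc**2).sum())

    def comm_corrs(labels_of_others: np.ndarray) -> np.ndarray:
        out = np.full(partition.n_communities, np.nan)
        for c in range(partition.n_communities):
            cols = labels_of_others == c
            if not cols.any():
                continue
            prof = seed_fc[:, cols].mean(axis=1)
            pc = prof - prof.mean()
            denom = np.sqrt((pc**2).sum()) * mnorm
            if denom > 0:
                out[c] = (pc @ mc) / denom
        return out

    observed = comm_corrs(other_labels)
    rng = np.random.default_rng(seed)
    pooled = np.empty((n_perm, partition.n_communities))
    for b in range(n_perm):
        pooled[b] = comm_corrs(rng.permutation(other_labels))
    flat = pooled[np.isfinite(pooled)]
    mu, sd = flat.mean(), flat.std(ddof=1)
    z = (observed - mu) / sd
    p = np.array(
        [(np.sum(np.abs(flat) >= abs(r)) + 1) / (flat.size + 1) for r in observed]
    )
    return pd.DataFrame(
        {"observed_r": observed, "z": z, "p_value": p},
        index=partition.community_names,
    )
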