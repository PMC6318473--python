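"""Synthetic multi-session connectivity + mood data with planted structure.

Two generators are provided.  The *edge-level* generator plants a
rank-1 cross-covariance directly in the sessions × edges and
sessions × scales blocks,

    X = d · t u*ᵀ + E,     Y = d · t v*ᵀ + F,

with a per-session latent score ``t_s ~ N(0, 1)``, unit-norm patterns
``u*`` (edges) and ``v*`` (scales), signal strength ``d`` and i.i.d.
standard-normal noise — the latent-variable structure the PLS
decomposition is designed to recover.  The *time-series* generator
produces per-session regional series with modular correlation structure
and AR(1) temporal autocorrelation; the session latent modulates the
between-community coupling, so that high-latent ("positive mood")
sessions have a more integrated network.  Ground truth is returned
alongside the data so every downstream stage can be tested against a
known answer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    PANAS_X_SCALES,
    EdgeDataset,
    MoodTable,
    Partition,
    edge_index_for,
)

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "generate_partition",
    "generate_edge_dataset",
    "generate_session_timeseries",
    "generate_timeseries_dataset",
    "generate_covariates",
    "write_truth_json",
]

#: Lifestyle covariates recorded alongside each session (subjective
#: evening measures, weather, and sleep-staging summaries).
LIFESTYLE_COLUMNS = [
    "alcohol",
    "gut_health",
    "stress",
    "time_outdoors",
    "precipitation",
    "temp_low",
    "temp_high",
    "sleep_total",
    "sleep_light",
    "sleep_deep",
    "sleep_rem",
]

# negative eigenvalues of the ideal block target are clipped here and the
# matrix renormalized to unit diagonal, guaranteeing a valid correlation
_EIG_CLIP = 1e-8


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generators.

    Defaults mirror the sampling design being emulated: 73 complete
    sessions, 13 mood scales, 518 time points per scan.  Node count is
    configurable (60 by default for desk-scale runs).  ``ar_coefficient``
    is the lag-1 temporal autocorrelation of the regional series;
    ``within_coupling``/``between_coupling`` set the modular FC target;
    ``latent_gain`` scales how strongly the session latent raises
    between-community coupling; ``signal_strength`` (d) scales the
    planted rank-1 cross-covariance in the edge-level generator.
    """

    n_sessions: int = 73
    n_nodes: int = 60
    n_scales: int = 13
    n_timepoints: int = 518
    ar_coefficient: float = 0.4
    signal_strength: float = 2.0
    within_coupling: float = 0.35
    between_coupling: float = 0.10
    latent_gain: float = 0.10
    u_support_fraction: float = 1.0
    session_score_ar: float = 0.0  # optional AR(1) on session latents, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")
        if self.n_sessions < 8:
            raise ValueError("n_sessions must be >= 8")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be nonnegative")
        for name in ("within_coupling", "between_coupling"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"|{name}| must be < 1")
        if not 0 <= self.session_score_ar < 1:
            raise ValueError("session_score_ar must lie in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth behind a synthetic dataset."""

    u_star: np.ndarray
    v_star: np.ndarray
    latent_scores: np.ndarray
    signal_strength: float
    partition: Partition

    def __post_init__(self) -> None:
        self.u_star = np.asarray(self.u_star, dtype=float)
        self.v_star = np.asarray(self.v_star, dtype=float)
        self.latent_scores = np.asarray(self.latent_scores, dtype=float)
        for name, vec in (("u_star", self.u_star), ("v_star", self.v_star)):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be unit-norm within 1e-12")


def _default_scale_names(q: int) -> list[str]:
    if q == len(PANAS_X_SCALES):
        return list(PANAS_X_SCALES)
    return [f"scale_{i + 1:02d}" for i in range(q)]


#: Valence of each PANAS-X scale: +1 positive, −1 negative, 0 ambiguous.
_SCALE_VALENCE = {
    "negative_affect": -1,
    "positive_affect": 1,
    "fear": -1,
    "hostility": -1,
    "guilt": -1,
    "sadness": -1,
    "joviality": 1,
    "self_assurance": 1,
    "attentiveness": 1,
    "shyness": -1,
    "fatigue": -1,
    "serenity": 1,
    "surprise": 0,
}


def _default_v_star(q: int) -> np.ndarray:
    """Planted scale pattern: a bipolar valence contrast.

    Positive-mood scales weigh +1, negative-mood scales −1 (surprise,
    valence-ambiguous, weighs 0); for non-PANAS scale counts the signs
    simply alternate.  Equal magnitudes mean column standardization
    rescales every signal-carrying scale identically, so the planted
    direction is preserved exactly in the standardized blocks.
    """
    if q == len(PANAS_X_SCALES):
        v = np.array([_SCALE_VALENCE[s] for s in PANAS_X_SCALES], dtype=float)
    else:
        v = np.where(np.arange(q) % 2 == 0, 1.0, -1.0)
    return v / np.linalg.norm(v)


def generate_partition(n_nodes: int, n_communities: int, seed: int) -> Partition:
    """Random balanced node → community assignment.

    Community sizes differ by at most one; which nodes land in which
    community is a deterministic function of the seed.
    """
    if n_communities > n_nodes:
        raise ValueError(
            f"n_communities ({n_communities}) cannot exceed n_nodes ({n_nodes})"
        )
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    rng = np.random.default_rng(seed)
    base = np.arange(n_nodes) % n_communities  # balanced by construction
    labels = base[rng.permutation(n_nodes)]
    names = [f"net{c + 1}" for c in range(n_communities)]
    return Partition(labels, names, [f"n{i:04d}" for i in range(n_nodes)])


def _latent_scores(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    t = rng.standard_normal(cfg.n_sessions)
    if cfg.session_score_ar > 0:
        phi = cfg.session_score_ar
        out = np.empty_like(t)
        out[0] = t[0]
        for s in range(1, cfg.n_sessions):
            out[s] = phi * out[s - 1] + np.sqrt(1 - phi**2) * t[s]
        return out
    return t


def generate_edge_dataset(
    cfg: SimConfig,
    u_star: np.ndarray | None = None,
    v_star: np.ndarray | None = None,
    n_communities: int | None = None,
) -> tuple[EdgeDataset, MoodTable, PlantedTruth]:
    """Plant a rank-1 edge × scale cross-covariance directly in X and Y.

    ``u_star``/``v_star`` may be supplied (they are normalized in place).
    By default ``u_star`` is dense Gaussian (set ``u_support_fraction``
    below 1 for a sparse pattern with testable on/off-support contrasts)
    and ``v_star`` is the bipolar valence contrast across scales.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_nodes
    p = k * (k - 1) // 2
    q = cfg.n_scales
    if n_communities is None:
        n_communities = max(2, min(8, k // 4))
    partition = generate_partition(k, n_communities, seed=cfg.seed)

    if u_star is None:
        u_star = np.zeros(p)
        n_support = max(1, int(np.ceil(cfg.u_support_fraction * p)))
        support = (
            np.arange(p)
            if n_support >= p
            else rng.choice(p, size=n_support, replace=False)
        )
        u_star[support] = rng.standard_normal(support.size)
    u_star = np.asarray(u_star, dtype=float)
    u_star = u_star / np.linalg.norm(u_star)

    if v_star is None:
        v_star = _default_v_star(q)
    v_star = np.asarray(v_star, dtype=float)
    v_star = v_star / np.linalg.norm(v_star)

    t = _latent_scores(cfg, rng)
    d = cfg.signal_strength
    X = d * np.outer(t, u_star) + rng.standard_normal((cfg.n_sessions, p))
    Y = d * np.outer(t, v_star) + rng.standard_normal((cfg.n_sessions, q))

    session_ids = [f"ses-{s + 1:03d}" for s in range(cfg.n_sessions)]
    node_ids = [f"n{i:04d}" for i in range(k)]
    edges = EdgeDataset(X, node_ids, session_ids, edge_index_for(k))
    mood = MoodTable(Y, _default_scale_names(q), session_ids)
    truth = PlantedTruth(u_star, v_star, t, d, partition)
    return edges, mood, truth


def _block_correlation_target(
    cfg: SimConfig, partition: Partition, session_latent: float
) -> np.ndarray:
    """Community-structured correlation target for one session.

    Within-community pairs get ``within_coupling``; between-community
    pairs get ``between_coupling + latent_gain * session_latent`` — the
    planted encoding of "integration tracks positive mood".  Coupling
    magnitudes ≥ 1 (the modulated value included) are invalid; any
    negative eigenvalues of the ideal target are clipped and the matrix
    renormalized to unit diagonal, so extreme latents saturate rather
    than break the simulation.
    """
    w = cfg.within_coupling
    b = cfg.between_coupling + cfg.latent_gain * session_latent
    if abs(w) >= 1 or abs(b) >= 1:
        raise ValueError(
            f"coupling out of range: within={w:.3f}, modulated between={b:.3f}"
        )
    same = partition.labels[:, None] == partition.labels[None, :]
    C = np.where(same, w, b)
    np.fill_diagonal(C, 1.0)
    eigval, eigvec = np.linalg.eigh(C)
    if eigval.min() < _EIG_CLIP:
        eigval = np.clip(eigval, _EIG_CLIP, None)
        C = (eigvec * eigval) @ eigvec.T
        dinv = 1.0 / np.sqrt(np.diag(C))
        C = C * np.outer(dinv, dinv)
        np.fill_diagonal(C, 1.0)
    return C


def generate_session_timeseries(
    cfg: SimConfig,
    partition: Partition,
    session_latent: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one session's time × node series.

    The series is a stationary vector AR(1): ``x_t = φ x_{t−1} +
    √(1−φ²) L z_t`` with ``L Lᵀ`` the session's target correlation, so
    the stationary spatial correlation equals the target and the lag-1
    temporal autocorrelation equals ``φ = ar_coefficient``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed if seed is None else seed
    )
    C = _block_correlation_target(cfg, partition, session_latent)
    L = np.linalg.cholesky(C)
    phi = cfg.ar_coefficient
    z = rng.standard_normal((cfg.n_timepoints, partition.n_nodes)) @ L.T
    x = np.empty_like(z)
    x[0] = z[0]  # start at the stationary distribution
    scale = np.sqrt(1 - phi**2)
    for tt in range(1, cfg.n_timepoints):
        x[tt] = phi * x[tt - 1] + scale * z[tt]
    return x


def generate_timeseries_dataset(
    cfg: SimConfig, n_communities: int = 5, v_star: np.ndarray | None = None
) -> tuple[dict[str, np.ndarray], MoodTable, PlantedTruth]:
    """Full multi-session time-series bundle driven by one latent.

    Each session's between-community coupling is modulated by its latent
    score; the mood block is generated from the same latent via the
    rank-1 model.  Returns ``{session_id: T × N array}``, the mood
    table, and the planted truth (``u_star`` is the normalized indicator
    of between-community edges — the edge set whose FC the latent
    drives).
    """
    rng = np.random.default_rng(cfg.seed)
    partition = generate_partition(cfg.n_nodes, n_communities, seed=cfg.seed)
    t = _latent_scores(cfg, rng)

    if v_star is None:
        v_star = _default_v_star(cfg.n_scales)
    v_star = np.asarray(v_star, dtype=float)
    v_star = v_star / np.linalg.norm(v_star)
    Y = cfg.signal_strength * np.outer(t, v_star) + rng.standard_normal(
        (cfg.n_sessions, cfg.n_scales)
    )

    series: dict[str, np.ndarray] = {}
    for s in range(cfg.n_sessions):
        sid = f"ses-{s + 1:03d}"
        series[sid] = generate_session_timeseries(cfg, partition, t[s], seed=rng)

    between = ~partition.within_edge_mask(edge_index_for(cfg.n_nodes))
    u_star = between.astype(float)
    u_star /= np.linalg.norm(u_star)

    mood = MoodTable(Y, _default_scale_names(cfg.n_scales), list(series))
    truth = PlantedTruth(u_star, v_star, t, cfg.latent_gain, partition)
    return series, mood, truth


def generate_covariates(n_sessions: int, seed: int) -> pd.DataFrame:
    """Session covariate table: alternating fasting flag + lifestyle columns.

    The fasting indicator strictly alternates (split sizes differ by at
    most one).  Lifestyle columns are standard-normal draws independent
    of everything else in the study — the null ground truth for the
    covariate regressions.
    """
    if n_sessions < 2:
        raise ValueError("n_sessions must be >= 2")
    rng = np.random.default_rng(seed)
    fasting = (np.arange(n_sessions) % 2 == 0).astype(int)
    data = {"fasting": fasting}
    for col in LIFESTYLE_COLUMNS:
        data[col] = rng.standard_normal(n_sessions)
    df = pd.DataFrame(data, index=[f"ses-{s + 1:03d}" for s in range(n_sessions)])
    df.index.name = "session_id"
    return df


def write_truth_json(path: str | Path, truth: PlantedTruth) -> None:
    payload = {
        "u_star": truth.u_star.tolist(),
        "v_star": truth.v_star.tolist(),
        "latent_scores": truth.latent_scores.tolist(),
        "signal_strength": truth.signal_strength,
        "partition_labels": truth.partition.labels.tolist(),
        "community_names": truth.partition.community_names,
    }
    Path(path).write_text(json.dumps(payload))
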