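"""Behavioral partial least squares: SVD of the cross-correlation matrix.

Both blocks are standardized column-wise and the p × q correlation
matrix ``R = Xzᵀ Yz / (n − 1)`` is decomposed as ``R = U S Vᵀ``.  Each
latent variable pairs an edge-weight pattern (column of U) with a
scale-weight pattern (column of V); its squared singular value as a
fraction of the total is the effect size η, and per-session scores are
the projections ``Xz u`` and ``Yz v``.  Scale loadings are the Pearson
correlations of each raw mood scale with the session network scores.

Sign convention (SVD signs are arbitrary): each (u, v) pair is flipped
jointly so that the summed v weight over an anchor set of scales —
by default the general positive-affect scale — is nonnegative, making
"positive weights ↔ positive mood" reproducible across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EdgeDataset, MoodTable

__all__ = [
    "LatentVariable",
    "PLSModel",
    "standardize_columns",
    "cross_correlation",
    "pls_svd",
    "effect_size",
    "session_scores",
    "scale_loadings",
    "score_scales",
    "fit_pls",
]

DEFAULT_ANCHOR_SCALE = "positive_affect"


@dataclass
class LatentVariable:
    """One (u, v, σ) triple from the decomposition, with derived statistics."""

    index: int
    u: np.ndarray
    v: np.ndarray
    sigma: float
    eta: float | None = None
    x_scores: np.ndarray | None = None
    y_scores: np.ndarray | None = None
    loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.sigma < 0:
            raise ValueError("singular value must be nonnegative")
        for name, vec in (("u", self.u), ("v", self.v)):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-10:
                raise ValueError(f"{name} must be unit-norm within 1e-10")

    @property
    def score_correlation(self) -> float:
        """Pearson correlation of network and mood session scores."""
        if self.x_scores is None or self.y_scores is None:
            raise ValueError("scores have not been computed for this LV")
        return float(np.corrcoef(self.x_scores, self.y_scores)[0, 1])


@dataclass
class PLSModel:
    """Fitted decomposition plus the standardization needed to project new data."""

    latent_variables: list[LatentVariable]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    n_sessions: int
    scale_names: list[str] | None = None

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([lv.sigma for lv in self.latent_variables])

    @property
    def etas(self) -> np.ndarray:
        return np.array([lv.eta for lv in self.latent_variables])

    def project(
        self, X_new: np.ndarray, Y_new: np.ndarray, lv_index: int = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Score new sessions using the training standardization (no leakage)."""
        lv = self.latent_variables[lv_index]
        Xz = (np.atleast_2d(X_new) - self.x_mean) / self.x_sd
        Yz = (np.atleast_2d(Y_new) - self.y_mean) / self.y_sd
        return Xz @ lv.u, Yz @ lv.v

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_sessions": self.n_sessions,
            "scale_names": self.scale_names,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_sd": self.y_sd.tolist(),
            "latent_variables": [
                {
                    "index": lv.index,
                    "sigma": lv.sigma,
                    "eta": lv.eta,
                    "u": lv.u.tolist(),
                    "v": lv.v.tolist(),
                    "x_scores": None if lv.x_scores is None else lv.x_scores.tolist(),
                    "y_scores": None if lv.y_scores is None else lv.y_scores.tolist(),
                    "loadings": None if lv.loadings is None else lv.loadings.tolist(),
                }
                for lv in self.latent_variables
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        lvs = [
            LatentVariable(
                index=e["index"],
                u=np.asarray(e["u"]),
                v=np.asarray(e["v"]),
                sigma=e["sigma"],
                eta=e["eta"],
                x_scores=None if e["x_scores"] is None else np.asarray(e["x_scores"]),
                y_scores=None if e["y_scores"] is None else np.asarray(e["y_scores"]),
                loadings=None if e["loadings"] is None else np.asarray(e["loadings"]),
            )
            for e in d["latent_variables"]
        ]
        return cls(
            lvs,
            np.asarray(d["x_mean"]),
            np.asarray(d["x_sd"]),
            np.asarray(d["y_mean"]),
            np.asarray(d["y_sd"]),
            d["n_sessions"],
            d["scale_names"],
        )


def standardize_columns(
    M: np.ndarray, names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring (mean 0, sd 1 with the n−1 denominator).

    Returns ``(Z, means, sds)``.  A zero-variance column is a hard
    error naming the column — never a silent drop.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 3:
        raise ValueError("matrix must be 2-D with at least 3 rows")
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    if np.any(sds == 0):
        idx = np.flatnonzero(sds == 0)
        labels = [names[i] for i in idx] if names is not None else idx.tolist()
        raise ValueError(f"zero-variance column(s): {labels}")
    return (M - means) / sds, means, sds


def cross_correlation(Xz: np.ndarray, Yz: np.ndarray) -> np.ndarray:
    """R = Xzᵀ Yz / (n − 1); entries are Pearson correlations for z-scored blocks."""
    Xz = np.asarray(Xz, dtype=float)
    Yz = np.asarray(Yz, dtype=float)
    if Xz.shape[0] != Yz.shape[0]:
        raise ValueError(
            f"row-count mismatch: X has {Xz.shape[0]} sessions, Y has {Yz.shape[0]}"
        )
    return Xz.T @ Yz / (Xz.shape[0] - 1)


def pls_svd(
    R: np.ndarray, anchor: Sequence[int] | None = None
) -> list[LatentVariable]:
    """SVD of the cross-correlation matrix, with the package sign convention.

    Returns min(p, q) latent variables ordered by non-increasing singular
    value, with effect sizes filled in.  ``anchor`` gives the v-column
    indices whose summed weight is made nonnegative per LV; without an
    anchor, the largest-magnitude v entry is made positive.
    """
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("cross-correlation matrix contains non-finite entries")
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for i in range(S.size):
        v = V[:, i]
        ref = v[anchor].sum() if anchor is not None else v[np.argmax(np.abs(v))]
        if ref < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    etas = effect_size(S)
    return [
        LatentVariable(index=i, u=U[:, i], v=V[:, i], sigma=float(S[i]), eta=float(etas[i]))
        for i in range(S.size)
    ]


def effect_size(sigmas: np.ndarray) -> np.ndarray:
    """η_i = σ_i² / Σ_j σ_j² — covariance fraction per latent variable."""
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas < 0):
        raise ValueError("singular values must be nonnegative")
    total = np.sum(sigmas**2)
    if total == 0:
        raise ValueError("all singular values are zero; effect size undefined")
    return sigmas**2 / total


def session_scores(
    Xz: np.ndarray, Yz: np.ndarray, lv: LatentVariable
) -> tuple[np.ndarray, np.ndarray]:
    """Project standardized session rows onto the singular vectors."""
    Xz = np.asarray(Xz, dtype=float)
    Yz = np.asarray(Yz, dtype=float)
    if Xz.shape[1] != lv.u.size or Yz.shape[1] != lv.v.size:
        raise ValueError("block widths do not match singular-vector lengths")
    return Xz @ lv.u, Yz @ lv.v


def scale_loadings(Y_raw: np.ndarray, x_scores: np.ndarray) -> np.ndarray:
    """Pearson r of each raw mood scale with the session network scores.

    Constant scale columns yield NaN (flagged as undefined).
    """
    Y_raw = np.atleast_2d(np.asarray(Y_raw, dtype=float))
    x_scores = np.asarray(x_scores, dtype=float)
    if Y_raw.shape[0] < 4:
        raise ValueError("need at least 4 sessions for loadings")
    out = np.empty(Y_raw.shape[1])
    for j in range(Y_raw.shape[1]):
        col = Y_raw[:, j]
        if col.std() == 0 or x_scores.std() == 0:
            out[j] = np.nan
        else:
            out[j] = stats.pearsonr(col, x_scores)[0]
    return out


def score_scales(
    item_table: pd.DataFrame,
    item_to_scale: Mapping[str, Sequence[str]],
    value_range: tuple[float, float] = (0.0, 5.0),
) -> MoodTable:
    """Aggregate item-level ratings into scale scores (mean of items).

    ``item_to_scale`` maps each scale name to its item columns; every
    mapped item must be present and every rating must lie within
    ``value_range`` (the schedule's 0–5 Likert range by default).
    """
    lo, hi = value_range
    for scale, items in item_to_scale.items():
        missing = [it for it in items if it not in item_table.columns]
        if missing:
            raise KeyError(f"scale {scale!r} references missing item(s): {missing}")
    vals = item_table.to_numpy(dtype=float)
    if np.any(vals < lo) or np.any(vals > hi):
        raise ValueError(f"item ratings outside declared range [{lo}, {hi}]")
    scale_names = list(item_to_scale)
    Y = np.column_stack(
        [item_table[list(item_to_scale[s])].mean(axis=1).to_numpy() for s in scale_names]
    )
    return MoodTable(Y, scale_names, [str(s) for s in item_table.index])


def fit_pls(
    edges: EdgeDataset | np.ndarray,
    mood: MoodTable | np.ndarray,
    anchor_scale: str | None = DEFAULT_ANCHOR_SCALE,
) -> PLSModel:
    """Full decomposition: standardize, cross-correlate, SVD, scores, loadings.

    When ``mood`` carries scale names and ``anchor_scale`` is among them,
    the sign convention anchors on that scale.
    """
    X = edges.X if isinstance(edges, EdgeDataset) else np.asarray(edges, dtype=float)
    if isinstance(mood, MoodTable):
        Y, scale_names = mood.Y, list(mood.scale_names)
    else:
        Y, scale_names = np.asarray(mood, dtype=float), None
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of sessions")

    Xz, x_mean, x_sd = standardize_columns(X)
    Yz, y_mean, y_sd = standardize_columns(Y, scale_names)
    R = cross_correlation(Xz, Yz)

    anchor = None
    if scale_names is not None and anchor_scale in (scale_names or []):
        anchor = [scale_names.index(anchor_scale)]
    lvs = pls_svd(R, anchor=anchor)
    for lv in lvs:
        lv.x_scores, lv.y_scores = session_scores(Xz, Yz, lv)
        lv.loadings = scale_loadings(Y, lv.x_scores)
    return PLSModel(lvs, x_mean, x_sd, y_mean, y_sd, X.shape[0], scale_names)
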