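"""Resampling inference around the PLS decomposition.

Four procedures: permutation tests for pattern significance, bootstrap
resampling for edge/scale reliability (bootstrap ratios), split-half
resampling for pattern stability, and randomized train/test splits for
the out-of-sample score correlation.

All p-values use the (count + 1) / (n + 1) convention — valid at finite
sample sizes and never exactly zero, so an overwhelmingly significant
pattern is reported at the achievable floor 1 / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pls import cross_correlation, pls_svd, standardize_columns

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "StabilityResult",
    "CVResult",
    "bootstrap_ratio",
    "permutation_test",
    "bootstrap",
    "split_half_stability",
    "out_of_sample_cv",
]


def bootstrap_ratio(weight: float | np.ndarray, se: float | np.ndarray):
    """b = w / SE(w); NaN where the bootstrap SE is zero, 0 where w is 0."""
    weight = np.asarray(weight, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(weight == 0, 0.0, np.where(se > 0, weight / se, np.nan))
    return float(out) if out.ndim == 0 else out


def _standardized(M: np.ndarray) -> np.ndarray:
    Z, _, _ = standardize_columns(M)
    return Z


def _svd_uv(X: np.ndarray, Y: np.ndarray, restandardize: bool = True):
    Xz = _standardized(X) if restandardize else X
    Yz = _standardized(Y) if restandardize else Y
    R = cross_correlation(Xz, Yz)
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    return U, S, Vt.T


@dataclass
class PermutationResult:
    observed_sigmas: np.ndarray
    null_sigmas: np.ndarray  # n_perm × n_lv
    p_values: np.ndarray
    n_perm: int
    seed: int


@dataclass
class BootstrapResult:
    u_bsr: np.ndarray          # per-edge bootstrap ratio for the chosen LV
    v_bsr: np.ndarray          # per-scale bootstrap ratio
    loading_ci: np.ndarray     # 2 × q percentile interval (2.5, 97.5)
    u_se: np.ndarray
    v_se: np.ndarray
    n_boot: int
    n_discarded: int
    seed: int
    lv_index: int


@dataclass
class StabilityResult:
    mean_u_corr: np.ndarray    # per retained LV
    mean_v_corr: np.ndarray
    u_ci: np.ndarray           # 2 × n_lv percentile interval
    v_ci: np.ndarray
    u_corrs: np.ndarray        # n_splits × n_lv
    v_corrs: np.ndarray
    kept_lvs: np.ndarray
    n_splits: int
    seed: int


@dataclass
class CVResult:
    split_correlations: np.ndarray
    mean_r: float
    p_value: float | None
    null_mean_rs: np.ndarray | None
    n_splits: int
    n_test: int
    test_fraction: float
    seed: int


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    restandardize: bool = True,
) -> PermutationResult:
    """Row-permutation null for the singular values.

    The rows of X are permuted independently of Y in each replicate, the
    cross-correlation recomputed and decomposed, and the i-th observed
    singular value compared with the i-th null singular value per
    replicate:  p_i = (#{null σ_i ≥ observed σ_i} + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    _, obs, _ = _svd_uv(X, Y)
    n = X.shape[0]
    null = np.empty((n_perm, obs.size))
    Yz = _standardized(Y)
    for b in range(n_perm):
        perm = rng.permutation(n)
        # note: row permutation leaves column means/sds unchanged, so
        # re-standardizing here only matters if restandardize=False was
        # paired with pre-standardized inputs
        _, s, _ = _svd_uv(X[perm], Y, restandardize=restandardize)
        null[b] = s
    p = (np.sum(null >= obs, axis=0) + 1) / (n_perm + 1)
    return PermutationResult(obs, null, p, n_perm, seed)


def bootstrap(
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    lv_index: int = 0,
    numerator: str = "original",
    restandardize: bool = True,
) -> BootstrapResult:
    """Bootstrap ratios: weight / bootstrap-estimated standard error.

    Sessions (rows of X and Y, jointly) are resampled with replacement;
    each replicate's singular vectors are sign-aligned to the original
    via the dot-product flip before accumulating.  The ratio's numerator
    is the original-sample weight by default (``numerator="original"``);
    ``"boot_mean"`` uses the bootstrap mean instead.  Loading intervals
    are percentile 2.5/97.5 of the replicate loadings.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 sessions to bootstrap")
    rng = np.random.default_rng(seed)

    U0, S0, V0 = _svd_uv(X, Y)
    u0, v0 = U0[:, lv_index], V0[:, lv_index]
    Xz0 = _standardized(X)

    u_reps = np.empty((n_boot, u0.size))
    v_reps = np.empty((n_boot, v0.size))
    load_reps = np.empty((n_boot, Y.shape[1]))
    n_discarded = 0
    b = 0
    attempts = 0
    max_attempts = 2 * n_boot
    while b < n_boot and attempts < max_attempts:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        if np.unique(idx).size < 2:
            n_discarded += 1
            continue
        Xb, Yb = X[idx], Y[idx]
        try:
            Ub, Sb, Vb = _svd_uv(Xb, Yb, restandardize=restandardize)
        except ValueError:
            n_discarded += 1  # zero-variance column in a degenerate resample
            continue
        ub, vb = Ub[:, lv_index], Vb[:, lv_index]
        if ub @ u0 < 0:
            ub, vb = -ub, -vb
        u_reps[b] = ub
        v_reps[b] = vb
        xb_scores = _standardized(Xb) @ ub if restandardize else Xb @ ub
        # replicate loadings: raw resampled scales vs replicate scores
        Yc = Yb - Yb.mean(axis=0)
        xc = xb_scores - xb_scores.mean()
        denom = np.sqrt((Yc**2).sum(axis=0) * (xc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            load_reps[b] = (Yc.T @ xc) / denom
        b += 1
    if b < n_boot:
        raise RuntimeError("too many degenerate bootstrap resamples")
    if n_discarded > 0.01 * n_boot:
        warnings.warn(f"{n_discarded} degenerate bootstrap resample(s) discarded")

    u_se = u_reps.std(axis=0, ddof=1)
    v_se = v_reps.std(axis=0, ddof=1)
    u_num = u0 if numerator == "original" else u_reps.mean(axis=0)
    v_num = v0 if numerator == "original" else v_reps.mean(axis=0)
    u_bsr = bootstrap_ratio(u_num, u_se)
    v_bsr = bootstrap_ratio(v_num, v_se)
    loading_ci = np.nanpercentile(load_reps, [2.5, 97.5], axis=0)
    return BootstrapResult(
        u_bsr, v_bsr, loading_ci, u_se, v_se, n_boot, n_discarded, seed, lv_index
    )


def split_half_projections(
    X1: np.ndarray,
    Y1: np.ndarray,
    X2: np.ndarray,
    Y2: np.ndarray,
    U: np.ndarray,
    S: np.ndarray,
    V: np.ndarray,
    restandardize: bool = True,
    sigma_tol: float = 1e-10,
):
    """Project two half-samples onto full-sample singular vectors.

    For each half h, with R_h the half's cross-correlation matrix,
    ``U_h = R_h V S⁻¹`` and ``V_h = R_hᵀ U S⁻¹``.  LVs whose singular
    value is numerically zero are excluded.  Returns (U1, U2, V1, V2,
    kept LV indices).
    """
    keep = np.flatnonzero(S > sigma_tol * max(S.max(), 1.0))
    Sinv = 1.0 / S[keep]
    R1 = cross_correlation(
        _standardized(X1) if restandardize else X1,
        _standardized(Y1) if restandardize else Y1,
    )
    R2 = cross_correlation(
        _standardized(X2) if restandardize else X2,
        _standardized(Y2) if restandardize else Y2,
    )
    U1 = R1 @ V[:, keep] * Sinv
    U2 = R2 @ V[:, keep] * Sinv
    V1 = R1.T @ U[:, keep] * Sinv
    V2 = R2.T @ U[:, keep] * Sinv
    return U1, U2, V1, V2, keep


def _colwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    denom = np.sqrt((Ac**2).sum(axis=0) * (Bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Ac * Bc).sum(axis=0) / denom


def split_half_stability(
    X: np.ndarray,
    Y: np.ndarray,
    n_splits: int = 1000,
    seed: int = 0,
    restandardize: bool = True,
) -> StabilityResult:
    """Split-half stability of the edge and scale patterns.

    Sessions are split into halves (⌈n/2⌉ and ⌊n/2⌋); each half's
    cross-correlation matrix is projected onto the full-sample singular
    vectors and the per-LV correlation between the two halves' projected
    patterns is recorded.  High mean correlation means the pattern is
    stable under halving the sample.
    """
    if n_splits < 100:
        raise ValueError("n_splits must be >= 100")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 8:
        raise ValueError("need at least 8 sessions for split-half resampling")
    rng = np.random.default_rng(seed)
    U, S, V = _svd_uv(X, Y)
    n_half = (n + 1) // 2

    u_corrs = []
    v_corrs = []
    kept = None
    for _ in range(n_splits):
        perm = rng.permutation(n)
        h1, h2 = perm[:n_half], perm[n_half:]
        U1, U2, V1, V2, keep = split_half_projections(
            X[h1], Y[h1], X[h2], Y[h2], U, S, V, restandardize=restandardize
        )
        kept = keep
        u_corrs.append(_colwise_corr(U1, U2))
        v_corrs.append(_colwise_corr(V1, V2))
    u_corrs = np.asarray(u_corrs)
    v_corrs = np.asarray(v_corrs)
    return StabilityResult(
        mean_u_corr=u_corrs.mean(axis=0),
        mean_v_corr=v_corrs.mean(axis=0),
        u_ci=np.percentile(u_corrs, [2.5, 97.5], axis=0),
        v_ci=np.percentile(v_corrs, [2.5, 97.5], axis=0),
        u_corrs=u_corrs,
        v_corrs=v_corrs,
        kept_lvs=kept,
        n_splits=n_splits,
        seed=seed,
    )


def cv_split_correlation(
    X: np.ndarray, Y: np.ndarray, train: np.ndarray, test: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fit on training rows only, project held-out rows, correlate scores.

    Standardization parameters and the decomposition come exclusively
    from the training rows, so corrupting test rows cannot change the
    fitted model.  Returns (test score correlation, u₁, v₁).
    """
    Xz, xm, xs = standardize_columns(X[train])
    Yz, ym, ys = standardize_columns(Y[train])
    U, S, Vt = np.linalg.svd(cross_correlation(Xz, Yz), full_matrices=False)
    u1, v1 = U[:, 0], Vt[0]
    xte = ((X[test] - xm) / xs) @ u1
    yte = ((Y[test] - ym) / ys) @ v1
    return float(np.corrcoef(xte, yte)[0, 1]), u1, v1


def _cv_mean_r(
    X: np.ndarray,
    Y: np.ndarray,
    n_splits: int,
    n_test: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Out-of-sample score correlations over randomized splits."""
    n = X.shape[0]
    rs = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(n)
        rs[s], _, _ = cv_split_correlation(X, Y, perm[n_test:], perm[:n_test])
    return rs


def out_of_sample_cv(
    X: np.ndarray,
    Y: np.ndarray,
    n_splits: int = 100,
    test_fraction: float = 0.25,
    seed: int = 0,
    n_perm: int | None = 1000,
) -> CVResult:
    """Out-of-sample correlation between connectivity and mood scores.

    Per split, the decomposition is fit on the training rows only
    (training-set standardization), held-out rows of both blocks are
    projected onto the first pair of singular vectors, and the test
    scores are correlated.  Test-set size is ⌈test_fraction · n⌉.
    Significance: rows of X are permuted and the whole procedure
    repeated; p is the fraction of null mean correlations that reach the
    observed one (with the +1 convention).
    """
    if not 0 < test_fraction < 0.5:
        raise ValueError("test_fraction must lie in (0, 0.5)")
    if n_splits < 10:
        raise ValueError("n_splits must be >= 10")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    n_test = int(np.ceil(test_fraction * n))
    if n_test < 3:
        raise ValueError("test sets would have fewer than 3 sessions")
    rng = np.random.default_rng(seed)
    rs = _cv_mean_r(X, Y, n_splits, n_test, rng)
    mean_r = float(rs.mean())

    p_value = None
    null_means = None
    if n_perm:
        null_means = np.empty(n_perm)
        for b in range(n_perm):
            Xp = X[rng.permutation(n)]
            null_means[b] = _cv_mean_r(Xp, Y, n_splits, n_test, rng).mean()
        p_value = float((np.sum(null_means >= mean_r) + 1) / (n_perm + 1))
    return CVResult(rs, mean_r, p_value, null_means, n_splits, n_test, test_fraction, seed)
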