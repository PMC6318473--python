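"""End-to-end orchestration: FC → PLS → inference → network stats → covariates.

`analyze` runs the full analysis on in-memory containers and returns a
JSON-serializable summary; `run_pipeline` wraps it with file input and
output.  All stage seeds are derived from the single configured seed via
`numpy.random.SeedSequence` spawning, so identical (inputs, config,
seed) give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, covariates as cov_mod, netstats, pls, resampling
from .containers import (
    EdgeDataset,
    MoodTable,
    Partition,
    align_sessions,
    read_edge_dataset,
    read_mood_tsv,
    read_partition_tsv,
    read_timeseries_tsv,
)

logger = logging.getLogger("netmood")

__all__ = ["RunConfig", "analyze", "run_pipeline", "stage_seeds"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``timeseries_dir`` / ``edge_dataset_prefix`` selects
    the connectivity input mode.  Resampling counts default to the
    full-scale analysis (10 000 permutations and bootstraps, 1000
    split-half samples, 100 CV splits with 25% test sets); ``fast=True``
    scales each down 10×.
    """

    mood_path: str
    partition_path: str | None = None
    timeseries_dir: str | None = None
    edge_dataset_prefix: str | None = None
    covariates_path: str | None = None
    output_dir: str = "netmood_results"
    n_perm: int = 10_000
    n_boot: int = 10_000
    n_splits: int = 1000
    n_cv_splits: int = 100
    cv_n_perm: int = 1000
    test_fraction: float = 0.25
    seed: int = 0
    fast: bool = False
    run_inference: bool = True
    run_netstats: bool = True
    run_covariates: bool = True

    def __post_init__(self) -> None:
        modes = [self.timeseries_dir, self.edge_dataset_prefix]
        if sum(m is not None for m in modes) != 1:
            raise ValueError(
                "exactly one of timeseries_dir / edge_dataset_prefix must be set"
            )
        if self.fast:
            self.n_perm = max(100, self.n_perm // 10)
            self.n_boot = max(100, self.n_boot // 10)
            self.n_splits = max(100, self.n_splits // 10)
            self.cv_n_perm = max(100, self.cv_n_perm // 10)
        for name in ("n_perm", "n_boot"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100")
        if not 0 < self.test_fraction < 0.5:
            raise ValueError("test_fraction must lie in (0, 0.5)")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def analyze(
    edges: EdgeDataset,
    mood: MoodTable,
    partition: Partition | None = None,
    covariate_table: pd.DataFrame | None = None,
    *,
    n_perm: int = 1000,
    n_boot: int = 1000,
    n_splits: int = 200,
    n_cv_splits: int = 100,
    cv_n_perm: int = 200,
    test_fraction: float = 0.25,
    seed: int = 0,
    run_inference: bool = True,
    run_netstats: bool = True,
) -> dict:
    """Run the full analysis on aligned in-memory blocks; return a summary dict."""
    edges, mood = align_sessions(edges, mood)
    seeds = stage_seeds(seed)
    t0 = time.time()

    model = pls.fit_pls(edges, mood)
    lv1 = model.latent_variables[0]
    summary: dict = {
        "n_sessions": edges.n_sessions,
        "n_edges": edges.n_edges,
        "n_scales": len(mood.scale_names),
        "effect_sizes": model.etas.tolist(),
        "singular_values": model.sigmas.tolist(),
        "lv1_score_correlation": lv1.score_correlation,
        "lv1_loadings": dict(zip(mood.scale_names, lv1.loadings.tolist())),
        "seed": seed,
    }
    logger.info("pls fitted in %.2fs (eta1=%.3f)", time.time() - t0, model.etas[0])

    bsr = None
    if run_inference:
        t0 = time.time()
        perm = resampling.permutation_test(edges.X, mood.Y, n_perm=n_perm, seed=seeds[0])
        boot = resampling.bootstrap(edges.X, mood.Y, n_boot=n_boot, seed=seeds[1])
        stab = resampling.split_half_stability(
            edges.X, mood.Y, n_splits=n_splits, seed=seeds[2]
        )
        cv = resampling.out_of_sample_cv(
            edges.X,
            mood.Y,
            n_splits=n_cv_splits,
            test_fraction=test_fraction,
            seed=seeds[3],
            n_perm=cv_n_perm,
        )
        bsr = boot.u_bsr
        summary.update(
            {
                "permutation_p": perm.p_values.tolist(),
                "split_half_mean_u_corr": float(stab.mean_u_corr[0]),
                "split_half_mean_v_corr": float(stab.mean_v_corr[0]),
                "cv_mean_r": cv.mean_r,
                "cv_p": cv.p_value,
                "bootstrap_discarded": boot.n_discarded,
            }
        )
        logger.info("inference done in %.2fs", time.time() - t0)

    if run_netstats and partition is not None:
        t0 = time.time()
        measures = netstats.session_network_measures(edges, partition)
        behavior = lv1.y_scores
        corrs = {
            m: netstats.measure_behavior_correlation(measures[m].to_numpy(), behavior)
            for m in netstats.MEASURE_NAMES
        }
        null = netstats.session_consistent_label_null(
            edges, partition, behavior, n_perm=max(100, n_perm), seed=seeds[4]
        )
        summary["network_measures"] = {
            m: {"spearman_r": corrs[m][0], "p": corrs[m][1],
                "label_null_p": float(null.loc[m, "p_value"])}
            for m in netstats.MEASURE_NAMES
        }
        if bsr is not None:
            bsr_mat = netstats.edge_vector_to_matrix(bsr, edges.edge_index)
            blocks = netstats.label_permutation_null(
                lambda part: netstats.rsn_block_means(bsr_mat, part, "positive").means,
                partition,
                n_perm=max(100, n_perm),
                seed=seeds[5],
            )
            summary["positive_bsr_block_z"] = np.where(
                np.isfinite(blocks["z"]), blocks["z"], None
            ).tolist()
        logger.info("network stats done in %.2fs", time.time() - t0)

    if covariate_table is not None:
        cov = covariate_table.loc[[s for s in edges.session_ids]]
        if "fasting" in cov.columns:
            fasting = cov["fasting"].to_numpy().astype(bool)
            tx = cov_mod.group_compare_scores(lv1.x_scores, fasting)
            ty = cov_mod.group_compare_scores(lv1.y_scores, fasting)
            fisher = cov_mod.per_group_score_correlation(
                lv1.x_scores, lv1.y_scores, fasting
            )
            summary["fasting"] = {
                "network_t": tx.t_statistic,
                "network_df": tx.degrees_of_freedom,
                "network_p": tx.p_value,
                "mood_t": ty.t_statistic,
                "mood_p": ty.p_value,
                "fisher_z": fisher.fisher_z,
                "fisher_p": fisher.p_value,
                "r_fasting": fisher.r1,
                "r_nonfasting": fisher.r2,
            }
        lifestyle = cov.drop(columns=["fasting"], errors="ignore")
        if not lifestyle.empty:
            reg = cov_mod.lifestyle_regression(
                {"network": lv1.x_scores, "mood": lv1.y_scores}, lifestyle
            )
            summary["lifestyle_min_q"] = float(reg["q_value"].min())
            summary["lifestyle_n_tests"] = int(len(reg))
    return summary


def _load_edges(config: RunConfig) -> EdgeDataset:
    if config.edge_dataset_prefix is not None:
        return read_edge_dataset(config.edge_dataset_prefix)
    ts_dir = Path(config.timeseries_dir)
    files = sorted(ts_dir.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .tsv time series found in {ts_dir}")
    series = {}
    node_ids = None
    for f in files:
        ts, nodes = read_timeseries_tsv(f)
        if node_ids is None:
            node_ids = nodes
        elif nodes != node_ids:
            raise ValueError(f"node set in {f.name} differs from the first session")
        series[f.stem] = ts
    return connectivity.build_edge_dataset(series, node_ids)


def run_pipeline(config: RunConfig) -> dict:
    """Load inputs per config, run every enabled stage, write artifacts.

    Writes ``summary.json`` (with config hash and seed) plus TSV
    artifacts into ``config.output_dir`` and returns the summary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = _load_edges(config)
    mood = read_mood_tsv(config.mood_path)
    partition = (
        read_partition_tsv(config.partition_path) if config.partition_path else None
    )
    covariate_table = (
        pd.read_csv(config.covariates_path, sep="\t", index_col="session_id")
        if config.covariates_path
        else None
    )
    summary = analyze(
        edges,
        mood,
        partition,
        covariate_table if config.run_covariates else None,
        n_perm=config.n_perm,
        n_boot=config.n_boot,
        n_splits=config.n_splits,
        n_cv_splits=config.n_cv_splits,
        cv_n_perm=config.cv_n_perm,
        test_fraction=config.test_fraction,
        seed=config.seed,
        run_inference=config.run_inference,
        run_netstats=config.run_netstats,
    )
    summary["config_hash"] = config.config_hash()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
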