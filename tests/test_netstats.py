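"""Tests of network statistics: block summaries, modularity, segregation,
and their label-permuting null models."""

import numpy as np
import pandas as pd
import pytest

import netmood as nm
from netmood.containers import edge_index_for
from netmood.netstats import session_network_measures, MEASURE_NAMES


def symmetric_random(rng, k, scale=1.0):
    m = rng.standard_normal((k, k)) * scale
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def two_block_matrix(k, within, between, labels):
    same = labels[:, None] == labels[None, :]
    m = np.where(same, within, between).astype(float)
    np.fill_diagonal(m, 0.0)
    return m


class TestEdgeVectorToMatrix:
    def test_roundtrip(self, rng):
        k = 9
        vec = rng.standard_normal(k * (k - 1) // 2)
        mat = nm.edge_vector_to_matrix(vec, edge_index_for(k))
        from netmood.connectivity import vectorize_upper

        assert np.array_equal(vectorize_upper(mat), vec)
        assert np.all(np.diag(mat) == 0)

    def test_single_edge(self):
        vec = np.zeros(6)
        vec[1] = 2.5  # edge (0, 2) for 4 nodes
        mat = nm.edge_vector_to_matrix(vec, edge_index_for(4))
        assert mat[0, 2] == mat[2, 0] == 2.5
        assert np.count_nonzero(mat) == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            nm.edge_vector_to_matrix(np.zeros(5), edge_index_for(4))


class TestRegionalMeanBsr:
    def test_star_node(self):
        mat = np.zeros((4, 4))
        mat[0, 1:] = mat[1:, 0] = 2.0
        means = nm.regional_mean_bsr(mat)
        assert means[0] == pytest.approx(2.0)
        assert means[1] == pytest.approx(2 / 3)

    def test_matches_brute_force(self, rng):
        mat = symmetric_random(rng, 8)
        means = nm.regional_mean_bsr(mat)
        for i in range(8):
            expected = np.mean([mat[i, j] for j in range(8) if j != i])
            assert means[i] == pytest.approx(expected)


class TestTopFractionNodes:
    def test_ceiling_counts(self):
        assert nm.top_fraction_nodes(np.arange(630.0), 0.05).size == 32
        assert nm.top_fraction_nodes(np.arange(20.0), 0.05).size == 1

    def test_modes_and_ordering(self):
        vals = np.array([0.1, -3.0, 2.0, -0.5, 2.0])
        assert list(nm.top_fraction_nodes(vals, 0.4, "positive")) == [2, 4]
        assert list(nm.top_fraction_nodes(vals, 0.4, "negative")) == [1, 3]
        assert list(nm.top_fraction_nodes(vals, 0.4, "absolute")) == [1, 2]

    def test_increasing_values_pick_highest_indices(self):
        out = nm.top_fraction_nodes(np.arange(10.0), 0.2, "positive")
        assert set(out) == {8, 9}


class TestRsnBlockMeans:
    def test_sign_masked_blocks(self):
        labels = np.array([0, 0, 1, 1])
        part = nm.Partition(labels, ["A", "B"])
        mat = two_block_matrix(4, 2.0, -1.0, labels)
        pos = nm.rsn_block_means(mat, part, "positive")
        assert pos.means[0, 0] == pytest.approx(2.0)
        assert np.isnan(pos.means[0, 1])
        neg = nm.rsn_block_means(mat, part, "negative")
        assert np.isnan(neg.means[0, 0])
        assert neg.means[0, 1] == pytest.approx(1.0)  # reported as magnitude

    def test_matches_brute_force(self, rng):
        k = 10
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
        part = nm.Partition(labels, ["A", "B", "C"])
        mat = symmetric_random(rng, k)
        out = nm.rsn_block_means(mat, part, "positive")
        for a in range(3):
            for b in range(3):
                vals = [
                    mat[i, j]
                    for i in range(k)
                    for j in range(k)
                    if i != j and labels[i] == a and labels[j] == b and mat[i, j] > 0
                ]
                if vals:
                    assert out.means[a, b] == pytest.approx(np.mean(vals))
                else:
                    assert np.isnan(out.means[a, b])


class TestLabelPermutationNull:
    def test_planted_block_elevation_detected(self, rng):
        labels = np.repeat(np.arange(4), 5)
        part = nm.Partition(labels, list("ABCD"))
        detections = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            mat = symmetric_random(r, 20, scale=1.0)
            block0 = np.ix_(labels == 0, labels == 0)
            mat[block0] += 3.0
            np.fill_diagonal(mat, 0.0)
            out = nm.label_permutation_null(
                lambda p: nm.rsn_block_means(mat, p, "signed").means,
                part,
                n_perm=200,
                seed=rep,
            )
            detections += out["z"][0, 0] > 2
        assert detections >= 19

    def test_constant_matrix_flagged(self):
        labels = np.array([0, 0, 1, 1])
        part = nm.Partition(labels, ["A", "B"])
        mat = np.full((4, 4), 0.5)
        np.fill_diagonal(mat, 0.0)
        with pytest.warns(UserWarning, match="zero null standard deviation"):
            out = nm.label_permutation_null(
                lambda p: nm.rsn_block_means(mat, p, "signed").means,
                part,
                n_perm=100,
                seed=0,
            )
        assert np.all(np.isnan(out["z"]))


class TestDensityModularitySegregation:
    def test_two_block_densities(self):
        labels = np.array([0, 0, 1, 1])
        part = nm.Partition(labels, ["A", "B"])
        mat = two_block_matrix(4, 0.8, 0.2, labels)
        assert nm.within_between_density(mat, part) == (0.8, 0.2)

    def test_density_brute_force(self, rng):
        labels = np.array([0, 1, 0, 1, 2, 2, 0])
        part = nm.Partition(labels, ["A", "B", "C"])
        mat = symmetric_random(rng, 7)
        w, b = nm.within_between_density(mat, part)
        wv, bv = [], []
        for i in range(7):
            for j in range(i + 1, 7):
                (wv if labels[i] == labels[j] else bv).append(mat[i, j])
        assert w == pytest.approx(np.mean(wv))
        assert b == pytest.approx(np.mean(bv))

    def test_modularity_disjoint_dyads(self):
        mat = np.zeros((4, 4))
        mat[0, 1] = mat[1, 0] = 1.0
        mat[2, 3] = mat[3, 2] = 1.0
        part = nm.Partition(np.array([0, 0, 1, 1]), ["A", "B"])
        assert nm.modularity(mat, part) == pytest.approx(0.5)

    def test_modularity_single_community_is_zero(self):
        mat = np.zeros((4, 4))
        mat[0, 1] = mat[1, 0] = 1.0
        mat[2, 3] = mat[3, 2] = 1.0
        part = nm.Partition(np.zeros(4, dtype=int), ["all"])
        assert nm.modularity(mat, part) == pytest.approx(0.0)

    def test_modularity_random_partition_near_zero(self, rng):
        qs = []
        for rep in range(100):
            r = np.random.default_rng(rep)
            mat = np.abs(symmetric_random(r, 10))
            labels = r.integers(0, 2, size=10)
            if len(np.unique(labels)) < 2:
                continue
            part = nm.Partition(labels, ["A", "B"])
            qs.append(nm.modularity(mat, part))
        assert abs(np.mean(qs)) < 0.1

    def test_modularity_matches_networkx(self, rng):
        """Independent oracle: networkx's weighted modularity on the
        positive subgraph agrees with ours."""
        import networkx as nx

        mat = np.abs(symmetric_random(rng, 12))
        labels = np.array([0] * 4 + [1] * 4 + [2] * 4)
        part = nm.Partition(labels, ["A", "B", "C"])
        G = nx.from_numpy_array(mat)
        comms = [set(np.flatnonzero(labels == c)) for c in range(3)]
        expected = nx.community.modularity(G, comms, weight="weight")
        assert nm.modularity(mat, part) == pytest.approx(expected, abs=1e-10)

    def test_modularity_no_positive_weights(self):
        mat = -np.ones((4, 4))
        np.fill_diagonal(mat, 0.0)
        part = nm.Partition(np.array([0, 0, 1, 1]), ["A", "B"])
        with pytest.raises(ValueError):
            nm.modularity(mat, part)

    def test_planted_q_beats_label_permuted_q(self, rng):
        labels = np.repeat([0, 1], 6)
        part = nm.Partition(labels, ["A", "B"])
        mat = two_block_matrix(12, 0.8, 0.1, labels) + symmetric_random(rng, 12, 0.05)
        q_true = nm.modularity(mat, part)
        q_null = [
            nm.modularity(mat, part.relabeled(rng.permutation(labels)))
            for _ in range(1000)
        ]
        assert q_true > np.mean(q_null)

    @pytest.mark.parametrize(
        "zw,zb,expected", [(0.5, 0.25, 0.5), (0.4, 0.4, 0.0), (0.3, 0.0, 1.0)]
    )
    def test_segregation_closed_forms(self, zw, zb, expected):
        labels = np.array([0, 0, 1, 1])
        part = nm.Partition(labels, ["A", "B"])
        mat = two_block_matrix(4, zw, zb, labels)
        assert nm.system_segregation(mat, part) == pytest.approx(expected)

    def test_segregation_zero_within_undefined(self):
        labels = np.array([0, 0, 1, 1])
        part = nm.Partition(labels, ["A", "B"])
        mat = two_block_matrix(4, 0.0, 0.3, labels)
        with pytest.raises(ValueError):
            nm.system_segregation(mat, part)

    def test_segregation_decreasing_in_between_coupling(self):
        labels = np.repeat([0, 1, 2], 4)
        part = nm.Partition(labels, ["A", "B", "C"])
        vals = [
            nm.system_segregation(two_block_matrix(12, 0.6, b, labels), part)
            for b in (0.0, 0.1, 0.2, 0.3, 0.4)
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_relabeling_invariance(self, rng):
        labels = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        mat = np.abs(symmetric_random(rng, 8))
        part = nm.Partition(labels, ["A", "B", "C"])
        # swap community identities 0<->2 without changing the grouping
        swapped = np.array([2, 1, 0, 2, 1, 0, 2, 1])
        part2 = nm.Partition(swapped, ["A", "B", "C"])
        assert nm.modularity(mat, part) == pytest.approx(nm.modularity(mat, part2))
        assert nm.system_segregation(mat, part) == pytest.approx(
            nm.system_segregation(mat, part2)
        )


class TestSessionMeasures:
    def test_vectorized_matches_per_matrix_loops(self, rng):
        cfg = nm.SimConfig(n_sessions=10, n_nodes=12, n_timepoints=80, seed=31)
        series, _, truth = nm.generate_timeseries_dataset(cfg, n_communities=3)
        edges = nm.build_edge_dataset(series)
        df = session_network_measures(edges, truth.partition)
        for s, sid in enumerate(edges.session_ids):
            mat = nm.edge_vector_to_matrix(edges.X[s], edges.edge_index)
            w, b = nm.within_between_density(mat, truth.partition)
            assert df.loc[sid, "within_density"] == pytest.approx(w)
            assert df.loc[sid, "between_density"] == pytest.approx(b)
            assert df.loc[sid, "modularity"] == pytest.approx(
                nm.modularity(mat, truth.partition)
            )
            assert df.loc[sid, "segregation"] == pytest.approx(
                nm.system_segregation(mat, truth.partition)
            )

    def test_spearman_examples(self):
        x = np.arange(10.0)
        assert nm.measure_behavior_correlation(x, x)[0] == pytest.approx(1.0)
        assert nm.measure_behavior_correlation(x, -x)[0] == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            nm.measure_behavior_correlation(np.ones(10), x)

    def test_null_spearman_bounded(self, rng):
        hits = 0
        for _ in range(200):
            r = nm.measure_behavior_correlation(
                rng.standard_normal(73), rng.standard_normal(73)
            )[0]
            hits += abs(r) < 0.31
        assert hits / 200 >= 0.97


class TestSessionConsistentLabelNull:
    def test_reproducible(self, rng):
        cfg = nm.SimConfig(n_sessions=12, n_nodes=12, n_timepoints=60, seed=41)
        series, _, truth = nm.generate_timeseries_dataset(cfg, n_communities=3)
        edges = nm.build_edge_dataset(series)
        a = nm.session_consistent_label_null(
            edges, truth.partition, truth.latent_scores, n_perm=100, seed=1
        )
        b = nm.session_consistent_label_null(
            edges, truth.partition, truth.latent_scores, n_perm=100, seed=1
        )
        pd.testing.assert_frame_equal(a, b)

    def test_detects_planted_integration(self):
        cfg = nm.SimConfig(n_sessions=73, n_nodes=30, n_timepoints=300, seed=42)
        series, _, truth = nm.generate_timeseries_dataset(cfg, n_communities=5)
        edges = nm.build_edge_dataset(series)
        out = nm.session_consistent_label_null(
            edges, truth.partition, truth.latent_scores, n_perm=200, seed=2
        )
        assert out.loc["between_density", "observed_rho"] > 0.5
        assert out.loc["between_density", "p_value"] < 0.05


class TestSeedFingerprint:
    def _mood_modulated_fcs(self, seed, n_sessions=60, k=20, effect=-0.1):
        """Sessions where seed-to-community-A FC decreases with mood."""
        rng = np.random.default_rng(seed)
        mood = rng.standard_normal(n_sessions)
        labels = np.repeat(np.arange(4), 5)
        part = nm.Partition(labels, list("ABCD"))
        fcs = np.zeros((n_sessions, k, k))
        for s in range(n_sessions):
            m = rng.standard_normal((k, k)) * 0.3
            m = (m + m.T) / 2 + 0.2
            m[0, labels == 0] += effect * mood[s]
            m[labels == 0, 0] += effect * mood[s]
            m = np.clip(m, -0.9, 0.9)
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            fcs[s] = m
        return fcs, part, mood

    def test_planted_decoupling_detected(self):
        hits = 0
        for rep in range(10):
            fcs, part, mood = self._mood_modulated_fcs(seed=rep)
            out = nm.seed_fingerprint_analysis(fcs, 0, part, mood, n_perm=200, seed=rep)
            hits += out.loc["A", "z"] < -2
        assert hits >= 9

    def test_no_effect_calibrated(self):
        within2 = total = 0
        for rep in range(20):
            fcs, part, mood = self._mood_modulated_fcs(seed=100 + rep, effect=0.0)
            out = nm.seed_fingerprint_analysis(
                fcs, 0, part, mood, n_perm=150, seed=rep
            )
            within2 += int((np.abs(out["z"]) <= 2).sum())
            total += len(out)
        assert within2 / total >= 0.93

    def test_constant_mood_rejected(self):
        fcs, part, _ = self._mood_modulated_fcs(seed=0, n_sessions=20)
        with pytest.raises(ValueError, match="constant"):
            nm.seed_fingerprint_analysis(fcs, 0, part, np.ones(20), n_perm=100, seed=0)
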