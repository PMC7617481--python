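"""Graph thresholding, profiles, trend test, spatial normalization, score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lateralpred import connectivity as conn
from lateralpred.receptive_fields import GaborFit
from lateralpred.tuning import TuningProfile


def make_fit(x, y, ori=0.0):
    return GaborFit(x, y, 2.0, 1.0, ori, 0.15, 0.0, 1.0, 0.9, included=True)


def make_profile(ori=0.0, direction=0.0, osi=0.9, dsi=0.9):
    return TuningProfile(direction, ori, 0.1, 0.1, osi, dsi, 1, 0, 1, 0)


class TestThreshold:
    def test_all_equal_weights_empty_graph(self):
        W = np.full((5, 5), 0.3)
        g = conn.threshold_connections(W, np.ones(5, bool))
        assert g.adjacency.sum() == 0

    def test_edge_count_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        n = 40
        W = rng.standard_normal((n, n))
        g = conn.threshold_connections(W, np.ones(n, bool), percentile=95)
        vals = np.abs(W[~np.eye(n, dtype=bool)])
        thr = np.percentile(vals, 95)  # linear interpolation convention
        assert g.adjacency.sum() == (vals > thr).sum()

    def test_edge_fraction_near_five_percent_distinct_weights(self):
        rng = np.random.default_rng(1)
        n = 50
        W = rng.standard_normal((n, n))
        g = conn.threshold_connections(W, np.ones(n, bool), percentile=95)
        frac = g.adjacency.sum() / (n * (n - 1))
        assert frac == pytest.approx(0.05, abs=0.005)

    def test_raising_percentile_never_adds_edges(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((30, 30))
        exc = np.ones(30, bool)
        g1 = conn.threshold_connections(W, exc, percentile=92.5)
        g2 = conn.threshold_connections(W, exc, percentile=99)
        assert not np.any(g2.adjacency & ~g1.adjacency)

    def test_self_connections_excluded(self):
        W = np.eye(4) * 100.0
        g = conn.threshold_connections(W, np.ones(4, bool))
        assert g.adjacency.sum() == 0


class TestProbabilityByTuning:
    def build(self, deltas_and_edges):
        """4 units with given orientations; edge list as (post, pre)."""
        oris, edges = deltas_and_edges
        n = len(oris)
        profiles = [make_profile(ori=np.radians(o)) for o in oris]
        adjacency = np.zeros((n, n), bool)
        for post, pre in edges:
            adjacency[post, pre] = True
        g = conn.ConnectivityGraph(adjacency, adjacency.astype(float),
                                   np.ones(n, bool), np.ones(n, bool), 0.0)
        return g, profiles

    def test_worked_arithmetic(self):
        # orientations chosen so ordered pairs fall in known delta bins
        g, profiles = self.build(([0, 10, 50, 80], [(1, 0), (2, 0), (3, 0)]))
        prof = conn.probability_by_tuning_difference(g, profiles, "orientation",
                                                     "EE")
        # deltas: 0-10:10deg(bin0) both directions; 0-50:50(bin1); 0-80:80(bin2);
        # 10-50:40(bin1); 10-80:70(bin2); 50-80:30(bin1)
        np.testing.assert_array_equal(prof.candidate_counts, [2, 6, 4])
        np.testing.assert_array_equal(prof.connected_counts, [1, 1, 1])
        np.testing.assert_allclose(prof.probability, [0.5, 1 / 6, 0.25])

    def test_fully_connected_probability_one(self):
        n = 4
        adjacency = ~np.eye(n, dtype=bool)
        profiles = [make_profile(ori=np.radians(o)) for o in (0, 10, 40, 80)]
        g = conn.ConnectivityGraph(adjacency, adjacency.astype(float),
                                   np.ones(n, bool), np.ones(n, bool), 0.0)
        prof = conn.probability_by_tuning_difference(g, profiles, "orientation", "EE")
        valid = prof.candidate_counts > 0
        np.testing.assert_allclose(prof.probability[valid], 1.0)

    def test_empty_bin_reported_nan(self):
        g, profiles = self.build(([0, 5, 10, 15], [(1, 0)]))
        prof = conn.probability_by_tuning_difference(g, profiles, "orientation", "EE")
        assert prof.candidate_counts[2] == 0 and np.isnan(prof.probability[2])

    def test_direction_folding_to_180(self):
        profiles = [make_profile(direction=np.radians(d)) for d in (0, 350)]
        delta = conn.fold_direction_difference_deg(
            profiles[0].preferred_direction, profiles[1].preferred_direction)
        assert delta == pytest.approx(10.0)


class TestCochranArmitage:
    def test_equal_proportions_null(self):
        prof = conn.ConnectivityProfile(np.array([0, 1, 2, 3.0]),
                                        np.array([10, 10, 10.0]),
                                        np.array([100, 100, 100.0]))
        z, p = conn.cochran_armitage_trend(prof)
        assert abs(z) < 1e-9 and p == pytest.approx(1.0)

    def test_two_bin_equals_two_proportion_z(self):
        prof = conn.ConnectivityProfile(np.array([0, 1, 2.0]),
                                        np.array([30, 10.0]),
                                        np.array([100, 80.0]))
        z, p = conn.cochran_armitage_trend(prof)
        # pooled two-proportion z statistic
        p1, p2 = 30 / 100, 10 / 80
        pbar = 40 / 180
        se = np.sqrt(pbar * (1 - pbar) * (1 / 100 + 1 / 80))
        assert abs(abs(z) - abs((p1 - p2) / se)) < 1e-9

    def test_matches_permutation_oracle(self):
        """Small monotone table: asymptotic p within Monte-Carlo error."""
        connected = np.array([12, 6, 2.0])
        candidates = np.array([40, 40, 40.0])
        prof = conn.ConnectivityProfile(np.arange(4.0), connected, candidates)
        z, p = conn.cochran_armitage_trend(prof)
        # permutation oracle: shuffle bin labels of individual pairs
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(3), 40)
        outcomes = np.concatenate([
            np.r_[np.ones(int(c)), np.zeros(int(n - c))]
            for c, n in zip(connected, candidates)])
        def stat(lab):
            t = lab.astype(float)
            r = np.array([outcomes[lab == k].sum() for k in range(3)])
            nn = np.array([40.0, 40, 40])
            pbar = outcomes.mean()
            num = ((np.arange(3)) * (r - nn * pbar)).sum()
            var = pbar * (1 - pbar) * ((nn * np.arange(3) ** 2).sum()
                                       - (nn * np.arange(3)).sum() ** 2 / nn.sum())
            return num / np.sqrt(var)
        obs = stat(labels)
        null = np.array([stat(rng.permutation(labels)) for _ in range(10000)])
        p_perm = (np.abs(null) >= abs(obs)).mean()
        assert abs(p - p_perm) < 0.02

    def test_degenerate_margins(self):
        prof = conn.ConnectivityProfile(np.arange(3.0), np.array([0, 0.0]),
                                        np.array([10, 10.0]))
        assert conn.cochran_armitage_trend(prof)[1] == 1.0


class TestNormalizeVisualSpace:
    def test_worked_examples(self):
        # theta = pi/2: rotation is identity
        out = conn.normalize_visual_space(np.array([3.0, 5.0]),
                                          np.array([3.0, 4.0]), np.pi / 2)
        np.testing.assert_allclose(out[0], [0.0, 1.0], atol=1e-12)
        # theta = 0: (1, 0) offset maps to (0, -1)
        out = conn.normalize_visual_space(np.array([1.0, 0.0]),
                                          np.array([0.0, 0.0]), 0.0)
        np.testing.assert_allclose(out[0], [0.0, -1.0], atol=1e-12)

    def test_distances_preserved_and_invertible(self):
        rng = np.random.default_rng(0)
        pre = rng.uniform(-5, 5, size=(20, 2))
        post = np.array([1.0, 2.0])
        theta = 0.7
        out = conn.normalize_visual_space(pre, post, theta)
        d0 = np.linalg.norm(pre[:, None] - pre[None, :], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, rtol=1e-12, atol=1e-12)
        # inverse transform recovers inputs
        a = theta - np.pi / 2
        rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
        back = out @ rot.T + post
        np.testing.assert_allclose(back, pre, atol=1e-12)

    def test_sector_labels_and_axial_symmetry(self):
        coords = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.5]])
        labs = conn.sector_labels_orientation(coords)
        assert list(labs) == ["coaxial", "boundary", "coorthogonal"]
        # theta and theta + pi give identical sector labels
        pre = np.random.default_rng(1).uniform(-3, 3, (10, 2))
        post = np.zeros(2)
        l1 = conn.sector_labels_orientation(
            conn.normalize_visual_space(pre, post, 0.4))
        l2 = conn.sector_labels_orientation(
            conn.normalize_visual_space(pre, post, 0.4 + np.pi))
        assert list(l1) == list(l2)


class TestCorrelationVsConnectivity:
    def test_step_function_when_connection_follows_correlation(self):
        n = 10
        rng = np.random.default_rng(0)
        corr = np.clip(rng.uniform(-0.1, 0.6, (n, n)), -1, 1)
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        adjacency = (corr > 0.3) & ~np.eye(n, dtype=bool)
        g = conn.ConnectivityGraph(adjacency, np.ones((n, n)),
                                   np.ones(n, bool), np.ones(n, bool), 0.0)
        out = conn.correlation_vs_connectivity(corr, g,
                                               bins=np.array([-0.1, 0.3, 0.6]))
        assert out.p_connected.iloc[0] == 0.0
        assert out.p_connected.iloc[1] == 1.0
        assert out.mean_strength.iloc[1] == 1.0

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(3)
        n = 10
        corr = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (n, n))), -1, 1)
        np.fill_diagonal(corr, 1.0)
        W = rng.standard_normal((n, n))
        g = conn.threshold_connections(W, np.ones(n, bool), percentile=80)
        bins = np.array([-1.0, 0.0, 1.0])
        out = conn.correlation_vs_connectivity(corr, g, bins=bins)
        # brute-force enumeration
        for k, (lo, hi) in enumerate(zip(bins[:-1], bins[1:])):
            n_cand = n_conn = 0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    c = corr[i, j]
                    inside = (lo <= c < hi) if k == 0 else (lo <= c <= hi)
                    if inside:
                        n_cand += 1
                        n_conn += bool(g.adjacency[i, j])
            assert out.n_candidates.iloc[k] == n_cand
            assert out.n_connected.iloc[k] == n_conn


class TestShuffle:
    def test_weight_multiset_preserved(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((8, 8))
        subset = np.arange(6)
        def op(w):
            return [w[np.ix_(subset, subset)].sum()]
        res = conn.shuffle_control(W, subset, op, n_shuffles=5, seed=1)
        target = W[np.ix_(subset, subset)].sum()
        np.testing.assert_allclose(res["samples"][:, 0], target, atol=1e-9)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((6, 6))
        op = lambda w: [w[0, 1]]
        a = conn.shuffle_control(W, np.arange(6), op, n_shuffles=4, seed=9)
        b = conn.shuffle_control(W, np.arange(6), op, n_shuffles=4, seed=9)
        np.testing.assert_array_equal(a["samples"], b["samples"])

    def test_null_probability_equals_overall_rate(self):
        """Mean per-bin connection probability over shuffles approaches the
        subset's overall connection rate."""
        rng = np.random.default_rng(2)
        n = 30
        W = rng.standard_normal((n, n))
        oris = rng.uniform(0, np.pi, n)
        profiles = [make_profile(ori=o) for o in oris]
        exc = np.ones(n, bool)
        subset = np.arange(n)
        def op(w):
            g = conn.threshold_connections(w, exc, percentile=90)
            return conn.probability_by_tuning_difference(
                g, profiles, "orientation", "EE").probability
        res = conn.shuffle_control(W, subset, op, n_shuffles=300, seed=3)
        overall = 0.10 * n * (n - 1) / (n * (n - 1))
        np.testing.assert_allclose(res["mean"], overall, atol=0.02)

    def test_type_one_error_calibration(self):
        """Trend test rejects at about the nominal 5% rate under the null."""
        rng = np.random.default_rng(4)
        n = 40
        W = rng.standard_normal((n, n))
        oris = rng.uniform(0, np.pi, n)
        profiles = [make_profile(ori=o) for o in oris]
        exc = np.ones(n, bool)
        def op(w):
            g = conn.threshold_connections(w, exc, percentile=90)
            prof = conn.probability_by_tuning_difference(
                g, profiles, "orientation", "EE")
            return [conn.cochran_armitage_trend(prof)[1]]
        res = conn.shuffle_control(W, np.arange(n), op, n_shuffles=1000, seed=5)
        rate = (res["samples"][:, 0] < 0.05).mean()
        assert 0.02 <= rate <= 0.09


class TestConnectivityScore:
    def test_identity_and_negation(self):
        profs = [np.array([0.5, 0.3, 0.1]), np.array([0.4, 0.2, 0.3])]
        assert conn.connectivity_score(profs, profs) == pytest.approx(1.0)
        neg = [-p + np.mean(p) * 2 for p in profs]
        assert conn.connectivity_score(profs, neg) == pytest.approx(-1.0)

    def test_mean_of_individual_rs(self):
        rng = np.random.default_rng(0)
        model = [rng.standard_normal(5) for _ in range(3)]
        ref = [rng.standard_normal(5) for _ in range(3)]
        expected = np.mean([stats.pearsonr(m, r)[0] for m, r in zip(model, ref)])
        assert conn.connectivity_score(model, ref) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conn.connectivity_score([np.ones(3)], [np.ones(4)])
        with pytest.raises(ValueError):
            conn.connectivity_score([np.ones(3)], [np.ones(3), np.ones(3)])


class TestReferenceProfiles:
    def test_synthetic_references_roundtrip_csv(self, tmp_path):
        import pandas as pd
        refs = conn.synthetic_reference_profiles()
        rows = [{"label": k, "bin_index": i, "value": v}
                for k, arr in refs.items() for i, v in enumerate(arr)]
        path = tmp_path / "refs.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        loaded = conn.load_reference_profiles(path)
        assert set(loaded) == set(refs)
        for k in refs:
            np.testing.assert_allclose(loaded[k], refs[k])

    def test_score_against_synthetic_references(self):
        refs = conn.synthetic_reference_profiles()
        model_profiles = [refs["EE_orientation_short"],
                          refs["coaxial"]]
        reference = [refs["EE_orientation_short"], refs["coaxial"]]
        assert conn.connectivity_score(model_profiles, reference) == 1.0
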