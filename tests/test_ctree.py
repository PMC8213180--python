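import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forestmort.ctree import (CovariateSchema, CTreeControl, CTreeModel,
                              SplitNode, TerminalNode, best_split, grow,
                              linear_statistic, predict_rate, select_variable)
from forestmort.ctree import test_pvalue as pvalue_of  # avoid collection

from conftest import make_planted_table


def exhaustive_moments(g: np.ndarray, h: np.ndarray):
    """Oracle: mean/covariance of T = sum g_i h_{pi(i)} over all n! perms."""
    n = len(h)
    Ts = np.array([g.T @ h[list(p)]
                   for p in itertools.permutations(range(n))])
    mean = Ts.mean(axis=0)
    centred = Ts - mean
    cov = centred.T @ centred / len(Ts)
    return mean, cov


class TestLinearStatistic:
    def test_scalar_moments_match_enumeration(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=6)
        y = rng.integers(0, 2, size=6).astype(float)
        T, mu, sigma = linear_statistic(x.reshape(-1, 1), y)
        mean_o, cov_o = exhaustive_moments(x.reshape(-1, 1), y)
        np.testing.assert_allclose(mu, mean_o, atol=1e-10)
        np.testing.assert_allclose(sigma, cov_o, atol=1e-10)

    def test_constant_response_zero_covariance(self):
        x = np.arange(5.0).reshape(-1, 1)
        T, mu, sigma = linear_statistic(x, np.ones(5))
        np.testing.assert_allclose(sigma, 0.0, atol=1e-14)
        p, _ = pvalue_of(T, mu, sigma)
        assert p == 1.0

    def test_permutation_symmetry_of_inputs(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=8).reshape(-1, 1)
        y = rng.integers(0, 2, 8).astype(float)
        T1, m1, s1 = linear_statistic(x, y)
        perm = rng.permutation(8)
        T2, m2, s2 = linear_statistic(x[perm], y[perm])
        np.testing.assert_allclose(T1, T2, atol=1e-12)
        np.testing.assert_allclose(m1, m2, atol=1e-12)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_case_weights_equal_replication(self):
        x = np.array([1.0, 2.0, 3.0]).reshape(-1, 1)
        y = np.array([0.0, 1.0, 1.0])
        w = np.array([2.0, 1.0, 3.0])
        xr = np.repeat(x, [2, 1, 3], axis=0)
        yr = np.repeat(y, [2, 1, 3])
        Tw, mw, sw = linear_statistic(x, y, weights=w)
        Tr, mr, sr = linear_statistic(xr, yr)
        np.testing.assert_allclose(Tw, Tr, atol=1e-12)
        np.testing.assert_allclose(mw, mr, atol=1e-12)
        np.testing.assert_allclose(sw, sr, atol=1e-12)


class TestTestPvalue:
    def test_statistic_at_mean_gives_p_one(self):
        sigma = np.array([[2.0]])
        p, c = pvalue_of(np.array([3.0]), np.array([3.0]), sigma)
        assert p == pytest.approx(1.0)
        assert c == pytest.approx(0.0)

    def test_scalar_quadratic_equals_chi2_of_squared_z(self):
        # chi-squared(1) identity: quadratic p == two-sided normal p
        for z in (0.5, 1.96, 3.2):
            p, _ = pvalue_of(np.array([z]), np.array([0.0]),
                               np.array([[1.0]]))
            assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-10)

    def test_perfect_separation_tiny_p(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        y = np.repeat([0.0, 1.0], 500)
        T, mu, sigma = linear_statistic(x.reshape(-1, 1), y)
        p, _ = pvalue_of(T, mu, sigma)
        assert p < 1e-6

    def test_maximum_type_bonferroni(self):
        T = np.array([2.0, 0.0])
        mu = np.zeros(2)
        sigma = np.eye(2)
        p, c = pvalue_of(T, mu, sigma, test_stat="maximum")
        assert c == pytest.approx(2.0)
        assert p == pytest.approx(min(1.0, 2 * 2 * stats.norm.sf(2.0)))


class TestSelectVariable:
    def test_single_candidate_adjusted_equals_raw(self):
        df = make_planted_table(400, seed=2)
        schema = CovariateSchema.from_dataframe(df, ["gdd"])
        h = (df["outcome"] == 0).to_numpy(float)
        sel = select_variable({"gdd": df["gdd"].to_numpy()}, h, schema,
                              CTreeControl())
        assert sel is not None
        name, adj, raw = sel
        assert adj == pytest.approx(raw)

    def test_planted_signal_selected_among_noise(self):
        df = make_planted_table(4000, seed=3)
        schema = CovariateSchema.from_dataframe(
            df, ["gdd", "pcp", "slp", "species"], ["species"])
        h = (df["outcome"] == 0).to_numpy(float)
        X = {n: (df[n].astype(str).to_numpy()
                 if schema.kinds[n] == "nominal"
                 else df[n].to_numpy(float)) for n in schema.names}
        sel = select_variable(X, h, schema, CTreeControl())
        assert sel is not None and sel[0] == "gdd"

    def test_adjusted_at_least_raw(self):
        df = make_planted_table(300, seed=5)
        schema = CovariateSchema.from_dataframe(df, ["gdd", "pcp", "slp"])
        h = (df["outcome"] == 0).to_numpy(float)
        X = {n: df[n].to_numpy(float) for n in schema.names}
        sel = select_variable(X, h, schema, CTreeControl(alpha=0.9999))
        if sel is not None:
            _, adj, raw = sel
            assert raw <= adj <= 1.0


class TestBestSplit:
    def test_step_threshold_between_straddling_values(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 15.0, 16.0, 17.0, 18.0])
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        ctrl = CTreeControl(min_split=4, min_bucket=2)
        thr = best_split(x, y, "ordered", None, ctrl)
        assert thr == pytest.approx((4.0 + 15.0) / 2)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        ctrl = CTreeControl(min_split=10, min_bucket=5)
        for _ in range(10):
            x = rng.normal(size=60)
            y = (rng.random(60) < 0.3).astype(float)
            thr = best_split(x, y, "ordered", None, ctrl)
            # oracle: evaluate standardised statistic at every midpoint
            xs = np.sort(np.unique(x))
            n, hbar = len(y), y.mean()
            vh = y.var()
            best_z, best_thr = -1, None
            for lo, hi in zip(xs[:-1], xs[1:]):
                cut = (lo + hi) / 2
                left = x <= cut
                nl = left.sum()
                if nl < 5 or n - nl < 5:
                    continue
                var = vh * nl * (n - nl) / (n - 1)
                z = abs(y[left].sum() - nl * hbar) / np.sqrt(var)
                if z > best_z:
                    best_z, best_thr = z, cut
            if best_thr is None:
                assert thr is None
            else:
                assert thr == pytest.approx(best_thr)

    def test_two_level_nominal_is_the_only_split(self):
        x = np.array(["a", "b"] * 10)
        y = np.array([0.0, 1.0] * 10)
        ctrl = CTreeControl(min_split=4, min_bucket=2)
        split = best_split(x, y, "nominal", ("a", "b"), ctrl)
        assert split in (("a",), ("b",))

    def test_min_bucket_blocks_split(self):
        x = np.arange(10.0)
        y = np.array([0.0] * 5 + [1.0] * 5)
        ctrl = CTreeControl(min_split=10, min_bucket=5)
        # admissible, balanced
        assert best_split(x, y, "ordered", None, ctrl) is not None
        ctrl2 = CTreeControl(min_split=12, min_bucket=6)
        assert best_split(x, y, "ordered", None, ctrl2) is None

    def test_exhaustive_and_ordering_scan_agree_binary_response(self):
        # for a binary response the mean-response-ordering reduction finds
        # the same optimum as exhaustive subset search
        rng = np.random.default_rng(21)
        levels = tuple("abcdefg")
        x = rng.choice(levels, size=400)
        rates = dict(zip(levels, rng.uniform(0.05, 0.5, len(levels))))
        y = np.array([float(rng.random() < rates[v]) for v in x])
        exhaustive = best_split(x, y, "nominal", levels,
                                CTreeControl(nominal_exhaustive_max_levels=10))
        scanned = best_split(x, y, "nominal", levels,
                             CTreeControl(nominal_exhaustive_max_levels=2))
        assert exhaustive is not None and scanned is not None
        # same partition up to complement
        a, b = set(exhaustive), set(scanned)
        assert a == b or a == set(levels) - b


class TestGrow:
    def test_constant_outcome_single_terminal(self):
        df = pd.DataFrame({"gdd": np.arange(100.0), "outcome": 1})
        schema = CovariateSchema.from_dataframe(df, ["gdd"])
        model = grow(df, schema, CTreeControl(), interval_col=None)
        assert model.n_inner == 0 and model.n_terminal == 1

    def test_noise_with_tiny_alpha_single_terminal(self):
        df = make_planted_table(500, seed=6, low=0.1, high=0.1)  # no signal
        schema = CovariateSchema.from_dataframe(df, ["gdd", "pcp", "slp"])
        model = grow(df, schema, CTreeControl(alpha=1e-12),
                     interval_col=None)
        assert model.n_inner == 0

    def test_planted_two_level_structure_recovered(self):
        # threshold on GDD, then species subset below/above
        rng = np.random.default_rng(30)
        n = 10000
        gdd = rng.normal(1500, 150, n)
        species = rng.choice(["FB", "SB", "MR", "BW"], size=n)
        hardwood = np.isin(species, ["MR", "BW"])
        p = np.where(gdd > 1500,
                     np.where(hardwood, 0.30, 0.12),
                     np.where(hardwood, 0.10, 0.02))
        df = pd.DataFrame({"gdd": gdd, "species": species,
                           "pcp": rng.normal(1100, 130, n),
                           "outcome": (rng.random(n) >= p).astype(int)})
        schema = CovariateSchema.from_dataframe(
            df, ["gdd", "species", "pcp"], ["species"])
        model = grow(df, schema, CTreeControl(min_split=200, min_bucket=100),
                     interval_col=None)
        # top two levels recover the planted gdd-threshold x species-group
        # structure (both signals are strong; either may take the root)
        root = model.nodes[model.root_id]
        assert isinstance(root, SplitNode) and root.var in ("gdd", "species")
        other = "species" if root.var == "gdd" else "gdd"
        for child_id in (root.left_id, root.right_id):
            child = model.nodes[child_id]
            assert isinstance(child, SplitNode) and child.var == other
        for node in [root] + [model.nodes[c]
                              for c in (root.left_id, root.right_id)]:
            if node.var == "gdd":
                assert abs(node.threshold - 1500) < 30
            else:
                assert set(node.left_levels) in ({"MR", "BW"}, {"FB", "SB"})

    def test_row_order_invariance(self):
        df = make_planted_table(2000, seed=7)
        schema = CovariateSchema.from_dataframe(
            df, ["gdd", "pcp", "slp", "species"], ["species"])
        m1 = grow(df, schema, CTreeControl(), interval_col=None)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        m2 = grow(shuffled, schema, CTreeControl(), interval_col=None)
        assert m1.n_inner == m2.n_inner
        r1, r2 = m1.nodes[m1.root_id], m2.nodes[m2.root_id]
        assert isinstance(r1, SplitNode) and r1.var == r2.var
        assert r1.threshold == pytest.approx(r2.threshold)

    def test_monotone_transform_invariance_with_rank_scores(self):
        df = make_planted_table(2000, seed=8)
        schema = CovariateSchema.from_dataframe(df, ["gdd", "pcp"])
        ctrl = CTreeControl(score="rank")
        m1 = grow(df, schema, ctrl, interval_col=None)
        df2 = df.copy()
        df2["gdd"] = np.exp(df2["gdd"] / 300.0)   # strictly monotone
        m2 = grow(df2, schema, ctrl, interval_col=None)
        # identical record partition: same terminal sizes in same structure
        from forestmort.ctree import predict_node
        np.testing.assert_array_equal(
            pd.factorize(predict_node(m1, df))[0],
            pd.factorize(predict_node(m2, df2))[0])

    def test_terminal_proportions_are_exact_count_ratios(self):
        df = make_planted_table(3000, seed=9)
        schema = CovariateSchema.from_dataframe(df, ["gdd", "pcp"])
        model = grow(df, schema, CTreeControl(), interval_col=None)
        for node in model.terminal_nodes:
            assert node.proportion == node.n_dead / node.n_records

    def test_training_predictions_conserve_global_death_rate(self):
        df = make_planted_table(3000, seed=10)
        schema = CovariateSchema.from_dataframe(df, ["gdd", "pcp"])
        model = grow(df, schema, CTreeControl(), interval_col=None)
        preds = predict_rate(model, df)
        assert preds.mean() == pytest.approx((df["outcome"] == 0).mean(),
                                             abs=1e-12)

    def test_empty_table_raises(self):
        df = pd.DataFrame({"gdd": [], "outcome": []})
        schema = CovariateSchema(names=("gdd",), kinds={"gdd": "ordered"},
                                 levels={})
        with pytest.raises(ValueError):
            grow(df, schema, CTreeControl(), interval_col=None)

    def test_missing_covariate_raises(self):
        df = pd.DataFrame({"gdd": [1.0, np.nan] * 20,
                           "outcome": [0, 1] * 20})
        schema = CovariateSchema(names=("gdd",), kinds={"gdd": "ordered"},
                                 levels={})
        with pytest.raises(ValueError, match="missing"):
            grow(df, schema, CTreeControl(), interval_col=None)


class TestPredictAndSerialise:
    def _fitted(self):
        df = make_planted_table(4000, seed=11)
        schema = CovariateSchema.from_dataframe(
            df, ["gdd", "species"], ["species"])
        return df, grow(df, schema, CTreeControl(), interval_col=None)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        df, model = self._fitted()
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = CTreeModel.from_json(path)
        np.testing.assert_allclose(predict_rate(restored, df),
                                   predict_rate(model, df))
        assert restored.n_inner == model.n_inner

    def test_unseen_level_routed_to_majority_child_and_logged(self):
        rng = np.random.default_rng(14)
        n = 2000
        species = rng.choice(["FB", "MR"], size=n)
        p = np.where(species == "MR", 0.4, 0.05)
        df = pd.DataFrame({"species": species, "gdd": rng.normal(size=n),
                           "outcome": (rng.random(n) >= p).astype(int)})
        schema = CovariateSchema.from_dataframe(
            df, ["species", "gdd"], ["species"])
        model = grow(df, schema, CTreeControl(), interval_col=None)
        assert model.n_inner >= 1
        new = pd.DataFrame({"species": ["ZZ"], "gdd": [0.0]})
        preds = predict_rate(model, new)
        assert np.isfinite(preds).all()
        assert model.unseen_level_log
        assert model.unseen_level_log[0]["level"] == "ZZ"

    def test_missing_value_at_prediction_raises(self):
        df, model = self._fitted()
        bad = df.head(1).copy()
        bad["gdd"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            predict_rate(model, bad)

    def test_single_node_tree_predicts_global_proportion(self):
        df = pd.DataFrame({"gdd": np.arange(50.0),
                           "outcome": [1] * 45 + [0] * 5})
        schema = CovariateSchema.from_dataframe(df, ["gdd"])
        model = grow(df, schema, CTreeControl(alpha=1e-12),
                     interval_col=None)
        np.testing.assert_allclose(predict_rate(model, df), 0.1)

    def test_render_mentions_nodes(self):
        _, model = self._fitted()
        text = model.render()
        assert "[N1]" in text and "terminal" in text


def test_control_validation():
    with pytest.raises(ValueError):
        CTreeControl(alpha=0.0)
    with pytest.raises(ValueError):
        CTreeControl(min_split=5, min_bucket=10)
    with pytest.raises(ValueError):
        CTreeControl(test_stat="bogus")
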