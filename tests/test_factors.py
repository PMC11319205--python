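"""NMF fitting and factor-level summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import fibroniche as fn
from fibroniche.factors import FactorModel


def random_nonneg(n, m, seed):
    return pd.DataFrame(
        np.random.default_rng(seed).gamma(2.0, 1.0, size=(n, m)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"g{j}" for j in range(m)],
    )


class TestFitNMF:
    def test_rank_one_input_recovered_exactly(self):
        rng = np.random.default_rng(0)
        u = rng.gamma(2, 1, size=30)
        v = rng.gamma(2, 1, size=20)
        x = pd.DataFrame(np.outer(u, v))
        model = fn.fit_nmf(x, k=1, seed=0)
        rel_err = model.objective_trace[-1] / np.linalg.norm(x.to_numpy())
        assert rel_err < 1e-6

    def test_objective_trace_non_increasing(self):
        x = random_nonneg(40, 25, 1)
        model = fn.fit_nmf(x, k=4, seed=0, max_iter=100)
        tr = model.objective_trace
        assert (np.diff(tr) <= 1e-10 * tr[0]).all()

    def test_deterministic(self):
        x = random_nonneg(30, 20, 2)
        a = fn.fit_nmf(x, k=3, seed=0)
        b = fn.fit_nmf(x, k=3, seed=0)
        assert np.array_equal(a.activities.to_numpy(), b.activities.to_numpy())
        assert np.array_equal(a.loadings.to_numpy(), b.loadings.to_numpy())

    def test_outputs_nonnegative(self):
        x = random_nonneg(30, 20, 3)
        model = fn.fit_nmf(x, k=3, seed=0)
        assert (model.activities.to_numpy() >= 0).all()
        assert (model.loadings.to_numpy() >= 0).all()

    def test_capacity_monotone_in_k(self):
        x = random_nonneg(40, 30, 4)
        errs = [fn.fit_nmf(x, k=k, seed=0, max_iter=300).objective_trace[-1]
                for k in (2, 3, 4)]
        assert errs[1] <= errs[0] + 1e-9 and errs[2] <= errs[1] + 1e-9

    def test_matches_sklearn_fit_quality(self):
        """Cross-check: our reconstruction error is comparable to sklearn's
        NMF on the same data and K (independent optimizer, same loss)."""
        from sklearn.decomposition import NMF

        x = random_nonneg(50, 30, 5)
        ours = fn.fit_nmf(x, k=4, seed=0, max_iter=500).objective_trace[-1]
        sk = NMF(n_components=4, init="nndsvda", solver="mu", max_iter=500,
                 random_state=0, tol=1e-6).fit(x.to_numpy())
        theirs = np.linalg.norm(
            x.to_numpy() - sk.transform(x.to_numpy()) @ sk.components_
        )
        assert ours <= 1.05 * theirs

    def test_negative_input_raises(self):
        x = random_nonneg(10, 5, 6)
        x.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            fn.fit_nmf(x, k=2)

    def test_k_exceeding_dims_raises(self):
        with pytest.raises(ValueError, match="k must be"):
            fn.fit_nmf(random_nonneg(5, 4, 7), k=6)


def make_model(weights_by_factor, activities=None):
    loadings = pd.DataFrame(weights_by_factor)
    loadings.index = [f"g{i}" for i in range(len(loadings))]
    if activities is None:
        activities = pd.DataFrame(
            np.ones((3, loadings.shape[1])), columns=loadings.columns,
            index=["s0", "s1", "s2"],
        )
    return FactorModel(activities=activities, loadings=loadings,
                       k=loadings.shape[1], objective_trace=np.array([0.0]),
                       seed=0, n_iter=0)


class TestTopFactorGenes:
    def test_min_max_scaling(self):
        model = make_model({"F1": [4.0, 2.0, 0.0]})
        ranking = fn.top_factor_genes(model, n=3)
        assert list(ranking.per_factor["F1"]["scaled_weight"]) == [1.0, 0.5, 0.0]

    def test_all_equal_nonzero_weights_scale_to_one(self):
        model = make_model({"F1": [2.0, 2.0, 2.0]})
        ranking = fn.top_factor_genes(model, n=3)
        assert (ranking.per_factor["F1"]["scaled_weight"] == 1.0).all()

    def test_top_n_selection(self):
        model = make_model({"F1": [5.0, 3.0, 1.0]})
        ranking = fn.top_factor_genes(model, n=2)
        assert list(ranking.per_factor["F1"].index) == ["g0", "g1"]

    def test_n_clipped_with_warning(self):
        model = make_model({"F1": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="clipping"):
            ranking = fn.top_factor_genes(model, n=10)
        assert len(ranking.per_factor["F1"]) == 2

    def test_ties_broken_by_gene_id(self):
        model = make_model({"F1": [1.0, 1.0, 1.0, 0.5]})
        ranking = fn.top_factor_genes(model, n=2)
        assert list(ranking.per_factor["F1"].index) == ["g0", "g1"]


class TestSelectHighSpots:
    def make_distinct(self, n=1000):
        act = pd.DataFrame(
            {"F1": np.arange(1, n + 1, dtype=float)},
            index=[f"s{i:04d}" for i in range(n)],
        )
        return make_model({"F1": [1.0]}, activities=act)

    def test_q99_on_distinct_activities_selects_top_ten(self):
        model = self.make_distinct()
        fhi = fn.select_high_spots(model, "F1", q=99.0)
        # type-7 quantile of 1..1000 at 0.99 is 990.01: activities 991..1000
        assert set(model.activities.loc[fhi, "F1"]) == set(range(991, 1001))

    def test_constant_activity_yields_empty_set(self):
        act = pd.DataFrame({"F1": np.ones(50)}, index=[f"s{i}" for i in range(50)])
        model = make_model({"F1": [1.0]}, activities=act)
        assert len(fn.select_high_spots(model, "F1", q=99.0)) == 0

    def test_top_n_per_sample(self):
        act = pd.DataFrame({"F1": np.arange(200, dtype=float)},
                           index=[f"s{i:03d}" for i in range(200)])
        model = make_model({"F1": [1.0]}, activities=act)
        samples = pd.Series(["a"] * 100 + ["b"] * 100, index=act.index)
        fhi = fn.select_high_spots(model, "F1", mode="top_n", n=100,
                                   scope="per_sample", sample_ids=samples)
        assert len(fhi) == 200

    def test_percentile_size_bracket(self):
        for n in (100, 537, 1000):
            model = self.make_distinct(n)
            fhi = fn.select_high_spots(model, "F1", q=99.0)
            assert int(np.floor(0.01 * n)) <= len(fhi) <= int(np.ceil(0.01 * n))

    def test_unknown_factor_raises(self):
        with pytest.raises(ValueError, match="unknown factor"):
            fn.select_high_spots(self.make_distinct(), "F9")


class TestFactorRegionSummary:
    def test_planted_frequency(self):
        n = 1000
        act = np.zeros(n)
        act[:10] = np.arange(100, 110)  # the F^hi spots, all inside group A
        act[10:] = np.linspace(0.1, 0.9, n - 10)
        model = make_model(
            {"F1": [1.0]},
            activities=pd.DataFrame({"F1": act}, index=[f"s{i:04d}" for i in range(n)]),
        )
        groups = pd.Series("B", index=model.activities.index)
        groups.iloc[:50] = "A"
        summary = fn.factor_region_summary(model, groups)
        row_a = summary[(summary["factor"] == "F1") & (summary["group"] == "A")].iloc[0]
        row_b = summary[(summary["factor"] == "F1") & (summary["group"] == "B")].iloc[0]
        assert row_a["fhi_frequency"] == pytest.approx(10 / 50)
        assert row_b["fhi_frequency"] == 0.0

    def test_z_scaled_mean_over_all_spots_is_zero(self):
        rng = np.random.default_rng(0)
        act = pd.DataFrame({"F1": rng.gamma(2, 1, 200)},
                           index=[f"s{i:03d}" for i in range(200)])
        model = make_model({"F1": [1.0]}, activities=act)
        groups = pd.Series("all", index=act.index)
        summary = fn.factor_region_summary(model, groups)
        assert summary["mean_z_activity"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_uniform_activities_frequency_near_one_percent(self):
        """With uniform random activities, every group's F^hi frequency is
        ~1% (binomial expectation over 100 seeds)."""
        freqs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            act = pd.DataFrame({"F1": rng.random(400)},
                               index=[f"s{i:03d}" for i in range(400)])
            model = make_model({"F1": [1.0]}, activities=act)
            groups = pd.Series(["A"] * 200 + ["B"] * 200, index=act.index)
            summary = fn.factor_region_summary(model, groups)
            freqs.append(summary.set_index("group")["fhi_frequency"])
        mean_freq = pd.concat(freqs, axis=1).mean(axis=1)
        se = np.sqrt(0.01 * 0.99 / (200 * 100))
        assert (np.abs(mean_freq - 0.01) < 4 * se).all()


class TestSubcluster:
    def blobs(self, n_per, centers, seed, spread=0.1):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for ci, c in enumerate(centers):
            rows.append(rng.normal(c, spread, size=(n_per, len(c))))
            labels += [ci] * n_per
        x = np.vstack(rows)
        df = pd.DataFrame(np.abs(x), index=[f"s{i:03d}" for i in range(len(x))])
        df.columns = [f"f{j}" for j in range(df.shape[1])]
        return df, np.array(labels)

    def test_two_blobs_recovered(self):
        df, truth = self.blobs(40, [(0, 0, 0, 5), (5, 5, 5, 0)], seed=0)
        labels = fn.subcluster_spots(df, n_pcs=3, resolution=0.4, n_neighbors=20, seed=0)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_three_blobs_ari_across_seeds(self):
        hits = 0
        for seed in range(20):
            df, truth = self.blobs(30, [(0, 0, 0), (6, 0, 0), (0, 6, 0)], seed=seed)
            labels = fn.subcluster_spots(df, n_pcs=3, resolution=0.4,
                                         n_neighbors=15, seed=seed)
            if adjusted_rand_score(truth, labels.to_numpy()) >= 0.9:
                hits += 1
        assert hits == 20

    def test_deterministic_under_seed(self):
        df, _ = self.blobs(30, [(0, 0, 0), (4, 4, 4)], seed=1)
        a = fn.subcluster_spots(df, n_pcs=3, n_neighbors=10, seed=7)
        b = fn.subcluster_spots(df, n_pcs=3, n_neighbors=10, seed=7)
        assert a.equals(b)

    def test_resolution_zero_gives_single_cluster(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(60, 5)))
        df.index = [f"s{i}" for i in range(60)]
        labels = fn.subcluster_spots(df, n_pcs=3, resolution=1e-9,
                                     n_neighbors=15, seed=0)
        assert labels.nunique() == 1

    def test_too_small_subset_raises(self):
        df = pd.DataFrame(np.ones((5, 3)), index=list("abcde"))
        with pytest.raises(ValueError, match="n_neighbors"):
            fn.subcluster_spots(df, n_neighbors=20)


def test_spotnmf_estimator_interface():
    x = random_nonneg(30, 20, 8)
    est = fn.SpotNMF(k=3, seed=0).fit(x)
    assert est.components_.shape == (3, 20)
    w = est.transform(x)
    assert w.shape == (30, 3) and (w >= 0).all()
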