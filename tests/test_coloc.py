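"""Factor–cell-type correlation, compartments and cross-species Jaccard."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import fibroniche as fn
from fibroniche.factors import FactorModel


def model_from_activities(act: pd.DataFrame) -> FactorModel:
    return FactorModel(activities=act, loadings=pd.DataFrame(columns=act.columns),
                       k=act.shape[1], objective_trace=np.array([0.0]), seed=0, n_iter=0)


class TestFactorCelltypeCorrelation:
    def setup_method(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i:03d}" for i in range(100)]
        self.act = pd.DataFrame({"F1": rng.gamma(2, 1, 100)}, index=idx)
        self.model = model_from_activities(self.act)

    def test_identical_column_correlates_perfectly(self):
        dens = pd.DataFrame({"ct": self.act["F1"]})
        r = fn.factor_celltype_correlation(self.model, dens)
        assert r.loc["F1", "ct"] == pytest.approx(1.0)

    def test_anticorrelated_column(self):
        shift = self.act["F1"].max() + 1.0
        dens = pd.DataFrame({"ct": shift - self.act["F1"]})
        r = fn.factor_celltype_correlation(self.model, dens)
        assert r.loc["F1", "ct"] == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        dens = pd.DataFrame({"ct": rng.gamma(2, 1, 100)}, index=self.act.index)
        r1 = fn.factor_celltype_correlation(self.model, dens)
        r2 = fn.factor_celltype_correlation(self.model, dens * 3.5 + 2.0)
        assert r1.loc["F1", "ct"] == pytest.approx(r2.loc["F1", "ct"], abs=1e-12)

    def test_independent_columns_near_zero(self):
        """|r| of independent noise columns stays below 0.1 at n=1000 in
        the vast majority of seeds (null sampling distribution of r)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            idx = [f"s{i:04d}" for i in range(1000)]
            model = model_from_activities(
                pd.DataFrame({"F1": rng.gamma(2, 1, 1000)}, index=idx))
            dens = pd.DataFrame({"ct": rng.gamma(2, 1, 1000)}, index=idx)
            r = fn.factor_celltype_correlation(model, dens)
            hits += abs(r.loc["F1", "ct"]) < 0.1
        assert hits >= 95

    def test_constant_column_flagged_missing(self):
        dens = pd.DataFrame({"ct": np.ones(100)}, index=self.act.index)
        r = fn.factor_celltype_correlation(self.model, dens)
        assert np.isnan(r.loc["F1", "ct"])

    def test_disjoint_spots_raise(self):
        dens = pd.DataFrame({"ct": [1.0]}, index=["elsewhere"])
        with pytest.raises(ValueError, match="no spots"):
            fn.factor_celltype_correlation(self.model, dens)

    def test_grouped_output(self):
        rng = np.random.default_rng(2)
        dens = pd.DataFrame({"ct": rng.gamma(2, 1, 100)}, index=self.act.index)
        groups = pd.Series(["a"] * 50 + ["b"] * 50, index=self.act.index)
        out = fn.factor_celltype_correlation(self.model, dens, group_by=groups)
        assert set(out) == {"a", "b"}


class TestCompartments:
    def test_single_cell_type_single_compartment(self):
        dens = pd.DataFrame({"ct": np.arange(10, dtype=float)})
        part = fn.celltype_compartments(dens)
        assert list(part.assignments) == ["A"]

    def test_hand_computed_two_block_dendrogram(self):
        """4 types, within-block r ≈ 0.9 (distance 0.1), across ≈ −0.8
        (distance 1.8): complete linkage merges blocks at ~1.8 > 1.5, so
        the cut yields exactly the two planted blocks."""
        rng = np.random.default_rng(0)
        n = 2000
        z = rng.normal(size=n)
        # corr(a1,a2) = 1/(1+eps^2) etc.; eps chosen for within r≈0.9
        eps = np.sqrt(1 / 0.9 - 1)
        a1 = z + eps * rng.normal(size=n)
        a2 = z + eps * rng.normal(size=n)
        b1 = -z + eps * rng.normal(size=n)
        b2 = -z + eps * rng.normal(size=n)
        dens = pd.DataFrame({"a1": a1, "a2": a2, "b1": b1, "b2": b2})
        dens -= dens.min().min()  # shift non-negative, correlation unchanged
        part = fn.celltype_compartments(dens, h=1.5, linkage_method="complete")
        assert part.assignments["a1"] == part.assignments["a2"]
        assert part.assignments["b1"] == part.assignments["b2"]
        assert part.assignments["a1"] != part.assignments["b1"]

    def test_cut_above_root_single_compartment(self):
        dens, _ = fn.simulate_density_blocks(n_spots=300, seed=1)
        part = fn.celltype_compartments(dens, h=10.0)
        assert part.assignments.nunique() == 1

    def test_excluded_patterns_dropped(self):
        dens, _ = fn.simulate_density_blocks(n_spots=200, seed=2)
        dens["low.quality.cells"] = np.random.default_rng(0).random(200)
        part = fn.celltype_compartments(dens)
        assert "low.quality.cells" in part.dropped
        assert "low.quality.cells" not in part.assignments.index

    def test_constant_column_dropped_with_warning(self):
        dens, _ = fn.simulate_density_blocks(n_spots=200, seed=3)
        dens["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            part = fn.celltype_compartments(dens)
        assert "flat" in part.dropped

    def test_planted_blocks_recovered(self):
        recovered = 0
        for seed in range(20):
            dens, blocks = fn.simulate_density_blocks(n_spots=600, seed=seed)
            part = fn.celltype_compartments(dens, h=1.5)
            ari = adjusted_rand_score(
                blocks.reindex(part.assignments.index), part.assignments
            )
            recovered += ari == 1.0
        assert recovered >= 19


class TestCompartmentScores:
    def test_summation(self):
        dens = pd.DataFrame({"A": [0.5], "B": [1.5], "C": [2.0]}, index=["s0"])
        part = fn.celltype_compartments(
            pd.concat([dens] * 5, ignore_index=True)
            + np.random.default_rng(0).random((5, 3)),
            h=10.0,
        )
        # force a known partition for the arithmetic check
        part.assignments[:] = ["X", "X", "Y"]
        scores = fn.compartment_scores(dens, part)
        assert scores.loc["s0", "X"] == pytest.approx(2.0)
        assert scores.loc["s0", "Y"] == pytest.approx(2.0)

    def test_row_sum_conservation(self):
        for seed in range(50):
            dens, _ = fn.simulate_density_blocks(n_spots=50, seed=seed)
            part = fn.celltype_compartments(dens, h=1.5)
            scores = fn.compartment_scores(dens, part)
            assert np.allclose(scores.sum(axis=1), dens.sum(axis=1))

    def test_singleton_compartment_equals_density_column(self):
        dens, _ = fn.simulate_density_blocks(n_spots=200, types_per_block=1, seed=4)
        part = fn.celltype_compartments(dens, h=1.5)
        scores = fn.compartment_scores(dens, part)
        for ct, comp in part.assignments.items():
            if (part.assignments == comp).sum() == 1:
                assert np.allclose(scores[comp], dens[ct])


def ranking_from_sets(sets: dict, n: int) -> fn.FactorGeneRanking:
    per_factor = {
        f: pd.DataFrame(
            {"weight": np.linspace(1, 0.5, len(genes)), "scaled_weight": 1.0},
            index=pd.Index(sorted(genes)),
        )
        for f, genes in sets.items()
    }
    return fn.FactorGeneRanking(per_factor=per_factor, n=n)


class TestCrossFactorJaccard:
    def test_identical_sets(self):
        genes = {f"g{i}" for i in range(100)}
        a = ranking_from_sets({"F1": genes}, 100)
        out = fn.cross_factor_jaccard(a, a)
        assert out["jaccard"].iloc[0] == 1.0

    def test_disjoint_sets(self):
        a = ranking_from_sets({"F1": {"g1", "g2"}}, 2)
        b = ranking_from_sets({"F1": {"h1", "h2"}}, 2)
        assert fn.cross_factor_jaccard(a, b)["jaccard"].iloc[0] == 0.0

    def test_twenty_of_hundred_passes_filter(self):
        shared = {f"s{i}" for i in range(20)}
        a = ranking_from_sets({"F1": shared | {f"a{i}" for i in range(80)}}, 100)
        b = ranking_from_sets({"F1": shared | {f"b{i}" for i in range(80)}}, 100)
        out = fn.cross_factor_jaccard(a, b, min_jaccard=0.1)
        assert out["jaccard"].iloc[0] == pytest.approx(20 / 180)
        assert bool(out["major_overlap"].iloc[0])

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(50)]
        a = ranking_from_sets({"F1": set(rng.choice(pool, 20, replace=False))}, 20)
        b = ranking_from_sets({"F1": set(rng.choice(pool, 20, replace=False))}, 20)
        ab = fn.cross_factor_jaccard(a, b)["jaccard"].iloc[0]
        ba = fn.cross_factor_jaccard(b, a)["jaccard"].iloc[0]
        assert ab == pytest.approx(ba)

    def test_unmapped_genes_in_union_never_intersection(self):
        a = ranking_from_sets({"F1": {"G1", "G2"}}, 2)
        b = ranking_from_sets({"F1": {"m1", "m2"}}, 2)
        amap = pd.DataFrame({"gene_a": ["G1"], "gene_b": ["m1"]})
        out = fn.cross_factor_jaccard(a, b, ortholog_map=amap)
        # mapped: m1→G1 (intersect 1); m2 unmapped stays in union
        assert out["intersection"].iloc[0] == 1
        assert out["union"].iloc[0] == 3
        assert out["jaccard"].iloc[0] == pytest.approx(1 / 3)

    def test_one_to_many_uses_first_listed(self):
        amap = pd.DataFrame({"gene_a": ["Gb", "Ga"], "gene_b": ["m1", "m1"]})
        with pytest.warns(UserWarning, match="multiple"):
            from fibroniche.coloc import resolve_ortholog_map

            mapping = resolve_ortholog_map(amap)
        assert mapping == {"m1": "Ga"}

    def test_mismatched_n_raises(self):
        a = ranking_from_sets({"F1": {"g1"}}, 1)
        b = ranking_from_sets({"F1": {"g1", "g2"}}, 2)
        with pytest.raises(ValueError, match="same n"):
            fn.cross_factor_jaccard(a, b)
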