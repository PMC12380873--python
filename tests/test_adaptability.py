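import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from agroniche import adaptability as ad
from agroniche import simulate
from agroniche.grids import Grid, Stack

from tests.conftest import make_raster


def profile_frame(rng, n_regions=6, n_feat=5, suit=None):
    data = {"mean_suitability": suit if suit is not None else rng.random(n_regions)}
    data["median_suitability"] = data["mean_suitability"]
    for j in range(n_feat):
        data[f"env_f{j}"] = rng.normal(size=n_regions)
    data["suitable_area_km2"] = rng.random(n_regions) * 1e4
    return pd.DataFrame(data, index=[f"SP{i+1:02d}" for i in range(n_regions)])


class TestRegionProfiles:
    def test_constant_suitability(self):
        suit = make_raster(np.full((4, 4), 0.6))
        stack = Stack(suit.grid, {"a": np.ones((4, 4)), "b": np.zeros((4, 4))})
        regions = simulate.generate_regions((0.0, 4.0, 0.0, 4.0), 2, 2)
        prof = ad.region_profiles(suit, stack, regions)
        assert np.allclose(prof["mean_suitability"], 0.6)

    def test_one_cell_region(self):
        vals = np.arange(16, dtype=float).reshape(4, 4) / 16.0
        suit = make_raster(vals)
        stack = Stack(suit.grid, {"a": vals * 2})
        regions = simulate.generate_regions((0.0, 1.0, 0.0, 1.0), 1, 1)
        prof = ad.region_profiles(suit, stack, regions)
        # the 1x1-degree region contains only the cell at row 3, col 0
        assert prof.loc["SP01", "mean_suitability"] == pytest.approx(vals[3, 0])
        assert prof.loc["SP01", "env_a"] == pytest.approx(vals[3, 0] * 2)

    def test_means_match_enumeration(self, rng):
        vals = rng.random((4, 4))
        suit = make_raster(vals)
        stack = Stack(suit.grid, {"a": rng.random((4, 4))})
        regions = simulate.generate_regions((0.0, 4.0, 0.0, 4.0), 2, 2)
        prof = ad.region_profiles(suit, stack, regions)
        # region SP01 is the SW quadrant: rows 2-3, cols 0-1
        assert prof.loc["SP01", "mean_suitability"] == pytest.approx(
            vals[2:4, 0:2].mean())

    def test_empty_region_dropped_with_warning(self):
        suit = make_raster(np.ones((2, 2)))
        stack = Stack(suit.grid, {"a": np.ones((2, 2))})
        regions = simulate.generate_regions((0.0, 4.0, 0.0, 2.0), 1, 2)
        with pytest.warns(UserWarning, match="SP02"):
            prof = ad.region_profiles(suit, stack, regions)
        assert list(prof.index) == ["SP01"]

    def test_empty_region_set_error(self):
        suit = make_raster(np.ones((2, 2)))
        stack = Stack(suit.grid, {"a": np.ones((2, 2))})
        from agroniche.grids import RegionSet
        with pytest.raises(ValueError):
            ad.region_profiles(suit, stack, RegionSet([], []))


class TestOptimalDissimilarity:
    def test_single_candidate_returned(self, rng):
        prof = profile_frame(rng)
        best, scores = ad.optimal_dissimilarity(prof, candidates=("manhattan",))
        assert best == "manhattan"

    def test_tie_broken_by_candidate_order(self, rng):
        # one feature equal to suitability: every candidate is perfectly
        # rank-correlated, so the first one wins
        suit = rng.random(6)
        prof = pd.DataFrame({
            "mean_suitability": suit,
            "env_x": suit,
            "suitable_area_km2": np.ones(6),
        }, index=[f"SP{i:02d}" for i in range(6)])
        best, scores = ad.optimal_dissimilarity(prof)
        assert scores.max() == pytest.approx(scores["euclidean"])
        assert best == "euclidean"

    def test_gower_beats_scale_dominated_euclidean(self, rng):
        n = 12
        suit = np.linspace(0.1, 0.9, n)
        rng.shuffle(suit)
        # informative feature on a tiny scale; huge-scale nuisance feature
        prof = pd.DataFrame({
            "mean_suitability": suit,
            "env_signal": suit * 1e-3,
            "env_noise": rng.normal(scale=1e3, size=n),
            "suitable_area_km2": np.ones(n),
        }, index=[f"SP{i:02d}" for i in range(n)])
        best, scores = ad.optimal_dissimilarity(prof)
        assert scores["gower"] >= scores["euclidean"]

    def test_constant_profiles_error(self):
        prof = pd.DataFrame({
            "mean_suitability": [0.5] * 5,
            "env_a": [1.0] * 5,
            "suitable_area_km2": [1.0] * 5,
        }, index=[f"SP{i:02d}" for i in range(5)])
        with pytest.raises(ValueError):
            ad.optimal_dissimilarity(prof)


class TestMantel:
    @staticmethod
    def _dist(rng, n):
        from scipy.spatial.distance import pdist, squareform
        return squareform(pdist(rng.normal(size=(n, 3))))

    def test_self_test_r_one_min_p(self, rng):
        D = self._dist(rng, 5)
        res = ad.mantel(D, D, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.exact
        # p is the minimum attainable for this matrix's tie structure
        assert res.p_value <= 0.05

    def test_exact_matches_independent_enumeration(self, rng):
        n = 4
        D1, D2 = self._dist(rng, n), self._dist(rng, n)
        res = ad.mantel(D1, D2, method="spearman")
        iu = np.triu_indices(n, 1)
        obs = spearmanr(D1[iu], D2[iu]).statistic
        count = 0
        for perm in itertools.permutations(range(n)):
            Dp = D2[np.ix_(perm, perm)]
            if spearmanr(D1[iu], Dp[iu]).statistic >= obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / 24)
        assert res.permutations == 24

    def test_sampled_close_to_exact(self, rng):
        n = 5
        D1, D2 = self._dist(rng, n), self._dist(rng, n)
        exact = ad.mantel(D1, D2).p_value
        ps = [ad.mantel(D1, D2, permutations=999, seed=s, exact=False).p_value
              for s in range(10)]
        se = np.sqrt(exact * (1 - exact) / 999) + 1e-6
        assert abs(np.mean(ps) - exact) < 3 * se + 2 / 999

    def test_asymmetric_rejected(self, rng):
        D = self._dist(rng, 4)
        D[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            ad.mantel(D, self._dist(rng, 4))

    def test_null_p_spread_over_seeds(self, rng):
        # unrelated matrices, sampled p over seeds is not degenerate
        D1 = self._dist(rng, 8)
        ps = []
        for s in range(10):
            D2 = self._dist(np.random.default_rng(100 + s), 8)
            ps.append(ad.mantel(D1, D2, permutations=199, seed=s).p_value)
        assert np.std(ps) > 0.05


class TestAdaptabilityMatrix:
    def test_maximal_case(self, rng):
        prof = profile_frame(rng, n_regions=5)
        prof.loc["SP01", "mean_suitability"] = 1.0
        trial = prof.loc["SP01", [c for c in prof.columns if c.startswith("env_")]]
        membership = pd.Series({"G1": 1.0, "G2": 0.4})
        res = ad.adaptability_matrix(membership, prof, trial, permutations=49, seed=0)
        row = res.matrix.set_index(["germplasm_id", "region_id"])
        assert row.loc[("G1", "SP01"), "score"] == pytest.approx(1.0)

    def test_zero_suitability_gates_to_zero(self, rng):
        prof = profile_frame(rng, n_regions=5)
        prof["mean_suitability"] = 0.0
        prof.loc["SP02", "mean_suitability"] = 0.5
        trial = prof.iloc[0][[c for c in prof.columns if c.startswith("env_")]]
        membership = pd.Series({"G1": 0.9})
        res = ad.adaptability_matrix(membership, prof, trial, permutations=49, seed=0)
        sub = res.matrix[res.matrix["region_id"] != "SP02"]
        assert (sub["score"] == 0.0).all()

    def test_monotone_in_membership(self, rng):
        prof = profile_frame(rng, n_regions=6)
        trial = prof.iloc[0][[c for c in prof.columns if c.startswith("env_")]]
        membership = pd.Series({"lo": 0.2, "hi": 0.8})
        res = ad.adaptability_matrix(membership, prof, trial, permutations=49, seed=1)
        piv = res.matrix.pivot(index="region_id", columns="germplasm_id",
                               values="score")
        assert (piv["hi"] >= piv["lo"] - 1e-12).all()

    def test_engineered_region_wins(self, rng):
        prof = profile_frame(rng, n_regions=8)
        prof["mean_suitability"] = 0.5
        feats = [c for c in prof.columns if c.startswith("env_")]
        trial = pd.Series(rng.normal(size=len(feats)), index=feats)
        prof.loc["SP03", feats] = trial.to_numpy()  # identical env profile
        prof.loc["SP03", "mean_suitability"] = 0.6
        membership = pd.Series({"G1": 0.9})
        res = ad.adaptability_matrix(membership, prof, trial, permutations=49, seed=2)
        top = res.matrix.loc[res.matrix["score"].idxmax()]
        assert top["region_id"] == "SP03"

    def test_region_relabel_equivariance(self, rng):
        prof = profile_frame(rng, n_regions=6)
        trial = prof.iloc[0][[c for c in prof.columns if c.startswith("env_")]]
        membership = pd.Series({"G1": 0.7, "G2": 0.3})
        res1 = ad.adaptability_matrix(membership, prof, trial, permutations=49, seed=3)
        shuffled = prof.iloc[::-1]
        res2 = ad.adaptability_matrix(membership, shuffled, trial,
                                      permutations=49, seed=3)
        m1 = res1.matrix.set_index(["germplasm_id", "region_id"])["score"]
        m2 = res2.matrix.set_index(["germplasm_id", "region_id"])["score"]
        pd.testing.assert_series_equal(m1.sort_index(), m2.sort_index())

    def test_feature_mismatch_rejected(self, rng):
        prof = profile_frame(rng)
        trial = pd.Series({"env_other": 1.0})
        with pytest.raises(ValueError):
            ad.adaptability_matrix(pd.Series({"G1": 0.5}), prof, trial)

    def test_suitable_area_accounting(self, rng):
        prof = profile_frame(rng, n_regions=6)
        trial = prof.iloc[0][[c for c in prof.columns if c.startswith("env_")]]
        membership = pd.Series({"G1": 0.9})
        res = ad.adaptability_matrix(membership, prof, trial, permutations=49, seed=4)
        sub = res.matrix[(res.matrix["germplasm_id"] == "G1")
                         & (res.matrix["class"] != "none")]
        expected = prof["suitable_area_km2"].reindex(sub["region_id"]).sum()
        assert res.suitable_area["G1"] == pytest.approx(expected)


class TestRegionSimilarity:
    def test_identical_profiles_correlate_one(self, rng):
        prof = profile_frame(rng, n_regions=5)
        feats = [c for c in prof.columns if c.startswith("env_")]
        prof.loc["SP02", feats] = prof.loc["SP01", feats].to_numpy()
        sim = ad.region_similarity_matrix(prof)
        assert sim.loc["SP01", "SP02"] == pytest.approx(1.0)
        assert np.allclose(np.diag(sim), 1.0)
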