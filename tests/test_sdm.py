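import numpy as np
import pandas as pd
import pytest

from agroniche import sdm, simulate
from agroniche.grids import Grid, Stack

from tests.conftest import make_raster


def gradient_stack(n=20):
    """Stack whose first layer increases west->east; 3 layers total."""
    grid = Grid(ncols=n, nrows=n, xllcorner=0.0, yllcorner=0.0, cellsize=1.0)
    lon, lat = grid.center_mesh()
    rng = np.random.default_rng(0)
    return Stack(grid, {
        "g": (lon - lon.mean()) / lon.std(),
        "h": (lat - lat.mean()) / lat.std(),
        "noise": rng.normal(size=lon.shape),
    })


class TestCleanOccurrences:
    def test_zero_zero_rule(self):
        raw = pd.DataFrame({"lon": [0.0, 10.0], "lat": [0.0, 10.0]})
        cleaned, report = sdm.clean_occurrences(raw)
        assert len(cleaned) == 1
        assert report["zero_zero"] == 1

    def test_duplicates_removed(self):
        raw = pd.DataFrame({"lon": [5.0, 5.0, 6.0], "lat": [1.0, 1.0, 1.0]})
        cleaned, report = sdm.clean_occurrences(raw)
        assert len(cleaned) == 2
        assert report["duplicates"] == 1

    def test_out_of_extent_counted(self, rng):
        inside = pd.DataFrame({"lon": rng.uniform(1, 9, 7), "lat": rng.uniform(1, 9, 7)})
        outside = pd.DataFrame({"lon": [20.0, 30.0, -5.0], "lat": [1.0, 2.0, 3.0]})
        cleaned, report = sdm.clean_occurrences(
            pd.concat([inside, outside]), extent=(0, 10, 0, 10)
        )
        assert len(cleaned) == 7
        assert report["out_of_extent"] == 3

    def test_non_finite_and_range(self):
        raw = pd.DataFrame({"lon": [np.nan, 200.0, 3.0], "lat": [1.0, 1.0, 1.0]})
        cleaned, report = sdm.clean_occurrences(raw)
        assert report["non_finite"] == 1 and report["out_of_range"] == 1
        assert len(cleaned) == 1

    def test_empty_result_is_error(self):
        with pytest.raises(ValueError):
            sdm.clean_occurrences(pd.DataFrame({"lon": [0.0], "lat": [0.0]}))


class TestRarefy:
    def test_all_in_one_cell(self):
        pts = pd.DataFrame({"lon": [1.1, 1.2, 1.3], "lat": [2.1, 2.2, 2.3]})
        assert len(sdm.rarefy(pts, 5.0, seed=1)) == 1

    def test_already_thin_identity(self):
        pts = pd.DataFrame({"lon": [0.5, 10.5, 20.5], "lat": [0.5, 10.5, 20.5]})
        out = sdm.rarefy(pts, 1.0, seed=2)
        assert len(out) == 3

    def test_retained_equals_occupied_cells(self, rng):
        pts = pd.DataFrame({"lon": rng.uniform(0, 5, 100), "lat": rng.uniform(0, 5, 100)})
        out = sdm.rarefy(pts, 1.0, seed=3)
        cx = np.floor((pts["lon"] - pts["lon"].min()) / 1.0).astype(int)
        cy = np.floor((pts["lat"] - pts["lat"].min()) / 1.0).astype(int)
        assert len(out) == len(set(zip(cx, cy)))

    def test_seeded_determinism(self, rng):
        pts = pd.DataFrame({"lon": rng.uniform(0, 3, 50), "lat": rng.uniform(0, 3, 50)})
        pd.testing.assert_frame_equal(sdm.rarefy(pts, 1.0, seed=9),
                                      sdm.rarefy(pts, 1.0, seed=9))


class TestCollinearityFilter:
    def test_identical_layers_one_dropped(self):
        grid = Grid(4, 4, 0.0, 0.0, 1.0)
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 4))
        stack = Stack(grid, {"a": a, "b": a.copy(), "c": rng.normal(size=(4, 4))})
        out, dropped = sdm.collinearity_filter(stack)
        assert len(dropped) == 1
        assert dropped[0] in ("a", "b")
        assert len(out) == 2

    def test_independent_layers_all_retained(self):
        grid = Grid(30, 30, 0.0, 0.0, 1.0)
        rng = np.random.default_rng(2)
        stack = Stack(grid, {f"l{i}": rng.normal(size=(30, 30)) for i in range(5)})
        out, dropped = sdm.collinearity_filter(stack)
        assert dropped == []
        assert len(out) == 5

    def test_filtered_stack_satisfies_threshold(self, small_landscape):
        stack, _ = small_landscape
        out, _ = sdm.collinearity_filter(stack, threshold=0.5)
        M = out.matrix()
        corr = np.corrcoef(M, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() < 0.5


class TestPseudoAbsences:
    def test_balanced_default(self, small_landscape):
        stack, truth = small_landscape
        pres = simulate.generate_occurrences(truth, 50, seed=1)
        bg = sdm.pseudo_absences(stack, pres, seed=1)
        assert len(bg) == len(pres)

    def test_seeded_repeat_identical(self, small_landscape):
        stack, truth = small_landscape
        pres = simulate.generate_occurrences(truth, 30, seed=2)
        pd.testing.assert_frame_equal(sdm.pseudo_absences(stack, pres, seed=5),
                                      sdm.pseudo_absences(stack, pres, seed=5))

    def test_disjoint_from_presence_cells(self, small_landscape):
        stack, truth = small_landscape
        pres = simulate.generate_occurrences(truth, 80, seed=3)
        bg = sdm.pseudo_absences(stack, pres, seed=3)
        grid = stack.grid
        pcells = set(zip(*grid.index_of(pres["lon"].to_numpy(), pres["lat"].to_numpy())))
        bcells = set(zip(*grid.index_of(bg["lon"].to_numpy(), bg["lat"].to_numpy())))
        assert pcells.isdisjoint(bcells)

    def test_insufficient_cells_error(self):
        grid = Grid(2, 2, 0.0, 0.0, 1.0)
        stack = Stack(grid, {"a": np.ones((2, 2)), "b": np.ones((2, 2)),
                             "c": np.ones((2, 2))})
        pres = pd.DataFrame({"lon": [0.5, 1.5, 0.5], "lat": [0.5, 0.5, 1.5]})
        with pytest.raises(ValueError):
            sdm.pseudo_absences(stack, pres, n=3, seed=0)


class TestEvaluateBinary:
    def test_perfect_scores(self):
        m = sdm.evaluate_binary([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.auc == 1.0 and m.tss == 1.0 and m.kappa == 1.0

    def test_reversed_scores_auc_zero(self):
        m = sdm.evaluate_binary([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert m.auc == 0.0

    def test_confusion_closed_form(self):
        # constructed so max-TSS threshold yields TP=8 FN=2 TN=7 FP=3
        scores = np.array([0.8] * 8 + [0.2] * 2 + [0.8] * 3 + [0.2] * 7)
        labels = np.array([1] * 10 + [0] * 10)
        m = sdm.evaluate_binary(scores, labels)
        assert m.tss == pytest.approx(0.8 + 0.7 - 1.0)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.7)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            sdm.evaluate_binary([0.5, 0.6], [1, 1])

    def test_rank_auc_matches_bruteforce_with_ties(self, rng):
        scores = rng.integers(0, 10, size=60) / 10.0  # force ties
        labels = rng.integers(0, 2, size=60)
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert sdm.rank_auc(scores, labels) == pytest.approx(
            wins / (len(pos) * len(neg)), abs=1e-12)


class TestEnsemble:
    def test_separable_data_every_learner_perfect(self):
        stack = gradient_stack()
        pres = pd.DataFrame({"lon": np.repeat(np.arange(15.5, 20.0), 20),
                             "lat": np.tile(np.arange(0.5, 20.0), 5)}).iloc[:90]
        bg = pd.DataFrame({"lon": np.repeat(np.arange(0.5, 5.0), 20),
                           "lat": np.tile(np.arange(0.5, 20.0), 5)}).iloc[:90]
        model = sdm.fit_ensemble(pres, bg, stack, repeats=3, seed=0)
        assert all(a == pytest.approx(1.0) for a in model.learner_auc.values())
        assert model.metrics.auc == pytest.approx(1.0)

    def test_random_labels_auc_near_half(self, rng):
        stack = gradient_stack()
        pts = pd.DataFrame({"lon": rng.uniform(0, 20, 240),
                            "lat": rng.uniform(0, 20, 240)})
        model = sdm.fit_ensemble(pts.iloc[:120], pts.iloc[120:], stack,
                                 repeats=5, auc_threshold=0.0, seed=1)
        assert abs(model.metrics.auc - 0.5) < 0.15

    def test_consensus_is_convex_combination(self, small_landscape):
        stack, truth = small_landscape
        pres = simulate.generate_occurrences(truth, 120, seed=4)
        bg = sdm.pseudo_absences(stack, pres, seed=4)
        model = sdm.fit_ensemble(pres, bg, stack, repeats=3,
                                 auc_threshold=0.0, seed=4)
        mask = stack.valid_mask()
        X = stack.matrix(mask)
        preds = np.column_stack([
            model.fitted[n].predict_proba(X)[:, 1] for n in model.weights
        ])
        consensus = model.consensus.values[mask]
        assert (consensus >= preds.min(axis=1) - 1e-9).all()
        assert (consensus <= preds.max(axis=1) + 1e-9).all()

    def test_seed_determinism(self, small_landscape):
        stack, truth = small_landscape
        pres = simulate.generate_occurrences(truth, 100, seed=5)
        bg = sdm.pseudo_absences(stack, pres, seed=5)
        m1 = sdm.fit_ensemble(pres, bg, stack, repeats=3, auc_threshold=0.0, seed=5)
        m2 = sdm.fit_ensemble(pres, bg, stack, repeats=3, auc_threshold=0.0, seed=5)
        np.testing.assert_array_equal(m1.consensus.values, m2.consensus.values)
        assert m1.learner_auc == m2.learner_auc

    def test_weights_sum_to_one(self, small_landscape):
        stack, truth = small_landscape
        pres = simulate.generate_occurrences(truth, 100, seed=6)
        bg = sdm.pseudo_absences(stack, pres, seed=6)
        model = sdm.fit_ensemble(pres, bg, stack, repeats=3,
                                 auc_threshold=0.0, seed=6)
        assert sum(model.weights.values()) == pytest.approx(1.0)

    def test_no_learner_passes_is_error(self, small_landscape):
        stack, truth = small_landscape
        pres = simulate.generate_occurrences(truth, 60, seed=7)
        bg = sdm.pseudo_absences(stack, pres, seed=7)
        with pytest.raises(ValueError, match="threshold"):
            sdm.fit_ensemble(pres, bg, stack, repeats=2, auc_threshold=1.01, seed=7)


class TestVariableImportance:
    def test_sums_to_100_and_drivers_dominate(self, small_landscape):
        stack, truth = small_landscape
        pres = simulate.generate_occurrences(truth, 150, seed=8)
        bg = sdm.pseudo_absences(stack, pres, seed=8)
        model = sdm.fit_ensemble(pres, bg, stack, repeats=3,
                                 auc_threshold=0.0, seed=8)
        imp = sdm.variable_importance(model, stack, seed=8)
        assert imp.sum() == pytest.approx(100.0)
        # truth is driven by env01/env02 only
        assert set(imp.nlargest(2).index) == {"env01", "env02"}
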