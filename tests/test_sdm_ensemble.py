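import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichedyn.occurrence_prep import OccurrenceSet
from nichedyn.predictors import SampleMatrix
from nichedyn.raster import GridTransform, RasterGrid
from nichedyn.sdm_ensemble import (
    SdmFit,
    auc_score,
    ensemble_predict,
    evaluate_scores,
    fit_and_predict,
    mss_threshold,
    pa_count,
    range_area_km2,
    sample_pseudo_absences,
)


def trapezoid_auc(scores, labels):
    """Independent oracle: trapezoid-integrated ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1]])
    tpr = [np.mean(scores[labels == 1] >= t) for t in thresholds]
    fpr = [np.mean(scores[labels == 0] >= t) for t in thresholds]
    return float(np.trapezoid(tpr, fpr))


def exhaustive_mss(scores, labels):
    """Independent oracle: argmax of sens+spec over all distinct scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best_t, best_sum = None, -np.inf
    for t in sorted(np.unique(scores)):
        sens = np.mean(scores[labels == 1] >= t)
        spec = np.mean(scores[labels == 0] < t)
        if sens + spec > best_sum + 1e-12:
            best_sum, best_t = sens + spec, t
    return best_t, best_sum


class TestPaCount:
    @pytest.mark.parametrize("n,expected", [(7291, 7291), (449, 1000), (1000, 1000), (1001, 1001)])
    def test_rule(self, n, expected):
        assert pa_count(n) == expected


class TestEvaluateScores:
    def test_separable_toy_case(self):
        scores = np.array([0.9, 0.8, 0.3, 0.4])
        labels = np.array([1, 1, 0, 0])
        ev = evaluate_scores(scores, labels)
        assert ev.auc == 1.0
        assert ev.mss_threshold == 0.8
        assert ev.tss == pytest.approx(1.0)
        assert ev.retained

    def test_uninformative_scores(self):
        scores = np.full(10, 0.5)
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        ev = evaluate_scores(scores, labels)
        assert ev.auc == 0.5
        assert ev.tss == pytest.approx(0.0)
        assert not ev.retained

    def test_partially_ranked_case(self):
        # 3 of 4 presence/absence pairs correctly ranked
        ev = evaluate_scores(np.array([0.9, 0.2, 0.8, 0.1]), np.array([1, 1, 0, 0]))
        assert ev.auc == pytest.approx(0.75)
        assert ev.auc == pytest.approx(
            trapezoid_auc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0])
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_scores(np.array([0.1, 0.2]), np.array([1, 1]))

    @given(st.integers(min_value=0, max_value=200))
    @settings(max_examples=40, deadline=None)
    def test_auc_and_mss_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = np.round(rng.random(n), 2)  # rounding induces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc_score(scores, labels) == pytest.approx(trapezoid_auc(scores, labels))
        thr, best = exhaustive_mss(scores, labels)
        got_thr, sens, spec = mss_threshold(scores, labels)
        assert sens + spec == pytest.approx(best)
        assert got_thr == pytest.approx(thr)  # smallest maximizing threshold

    def test_gate_false_positive_rate_is_low(self):
        """Random scores rarely pass the TSS/AUC retention gates."""
        rng = np.random.default_rng(0)
        retained = 0
        for _ in range(20):
            scores = rng.random(200)
            labels = rng.integers(0, 2, size=200)
            labels[0], labels[1] = 0, 1
            retained += evaluate_scores(scores, labels).retained
        assert retained <= 4


class TestPseudoAbsences:
    def test_counts_and_exclusion(self, small_stack):
        t = small_stack.transform
        coords = [t.cell_center(r, c) for r in range(5) for c in range(5)]
        df = pd.DataFrame(
            [("z", lon, lat, 0.0) for lon, lat in coords],
            columns=["taxon", "lon", "lat", "uncertainty_km"],
        )
        occ = OccurrenceSet("z", df)
        sets = sample_pseudo_absences(len(occ), small_stack, seed=3, presence=occ)
        assert len(sets) == 2 and all(len(s) == 1000 for s in sets)
        presence_cells = {t.index_of(lon, lat, small_stack.shape) for lon, lat in coords}
        for s in sets:
            for lon, lat in s.points.to_numpy():
                assert t.index_of(lon, lat, small_stack.shape) not in presence_cells

    def test_insufficient_background(self, flat_transform):
        from nichedyn.raster import PredictorStack

        stack = PredictorStack()
        stack.add("a", RasterGrid(np.zeros((3, 3)), flat_transform))
        with pytest.raises(ValueError):
            sample_pseudo_absences(2000, stack, seed=0)


def _toy_fits(values_list, tss_list, transform):
    fits = []
    for i, (vals, tss) in enumerate(zip(values_list, tss_list)):
        pred = RasterGrid(vals, transform)

        class Dummy:
            classes_ = [0, 1]

            def __init__(self, v):
                self.v = v

            def predict_proba(self, x):
                p = np.full(len(x), self.v)
                return np.column_stack([1 - p, p])

        from nichedyn.sdm_ensemble import ModelEvaluation

        ev = ModelEvaluation(f"m{i}", tss, 0.9, 0.5, 1.0, tss, True)
        fits.append(SdmFit(f"m{i}", 1, Dummy(float(vals.mean())), ev, pred, ["x"]))
    return fits


class TestEnsemble:
    def eval_points(self):
        x = pd.DataFrame({"x": np.linspace(0, 1, 10)})
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        return x, y

    def test_equal_tss_gives_arithmetic_mean(self, flat_transform):
        a = np.full((4, 4), 0.2)
        b = np.full((4, 4), 0.6)
        fits = _toy_fits([a, b], [0.8, 0.8], flat_transform)
        ens = ensemble_predict(fits, *self.eval_points())
        assert np.allclose(ens.suitability.values, 0.4)

    def test_tss_proportional_weights(self, flat_transform):
        fits = _toy_fits([np.full((4, 4), 0.2), np.full((4, 4), 0.6)], [0.9, 0.3], flat_transform)
        ens = ensemble_predict(fits, *self.eval_points())
        assert sorted(ens.weights.values()) == pytest.approx([0.25, 0.75])
        assert np.allclose(ens.suitability.values, 0.75 * 0.2 + 0.25 * 0.6)

    def test_single_member_identity(self, flat_transform):
        vals = np.random.default_rng(0).random((4, 4))
        fits = _toy_fits([vals], [0.7], flat_transform)
        ens = ensemble_predict(fits, *self.eval_points())
        np.testing.assert_allclose(ens.suitability.values, vals)

    def test_ensemble_within_member_range(self, flat_transform):
        rng = np.random.default_rng(1)
        members = [rng.random((5, 5)) for _ in range(3)]
        fits = _toy_fits(members, [0.7, 0.8, 0.9], flat_transform)
        ens = ensemble_predict(fits, *self.eval_points())
        lo = np.min(members, axis=0)
        hi = np.max(members, axis=0)
        assert np.all(ens.suitability.values >= lo - 1e-12)
        assert np.all(ens.suitability.values <= hi + 1e-12)

    def test_empty_ensemble_errors(self, flat_transform):
        fits = _toy_fits([np.full((4, 4), 0.2)], [0.7], flat_transform)
        fits[0].evaluation.retained = False
        with pytest.raises(ValueError):
            ensemble_predict(fits, *self.eval_points())


class TestFitAndPredict:
    def test_separable_data_retains_every_algorithm(self, small_stack):
        """Presences and absences split cleanly along latent axis 1, so every
        algorithm family reaches near-perfect held-out skill."""
        l1, _ = small_stack.latent
        names = [n for n in small_stack.names if not n.startswith("tmean") and n != "pet"]
        sub = small_stack.subset(names)
        m = sub.to_matrix(valid_only=False)
        pres = SampleMatrix(pd.DataFrame(m[l1.ravel() > 0.8], columns=names), "p")
        absn = SampleMatrix(pd.DataFrame(m[l1.ravel() < -0.8], columns=names), "a")
        fits = fit_and_predict(pres, [absn], sub, seed=0)
        assert len(fits) == 7
        assert all(f.evaluation.retained for f in fits)
        assert all(f.evaluation.tss > 0.6 for f in fits)

    def test_single_algorithm_ensemble_identity(self, small_stack):
        l1, _ = small_stack.latent
        names = [n for n in small_stack.names if not n.startswith("tmean") and n != "pet"]
        sub = small_stack.subset(names)
        m = sub.to_matrix(valid_only=False)
        pres = SampleMatrix(pd.DataFrame(m[l1.ravel() > 0.8], columns=names), "p")
        absn = SampleMatrix(pd.DataFrame(m[l1.ravel() < -0.8], columns=names), "a")
        fits = fit_and_predict(pres, [absn], sub, algorithms=["cta"], seed=0)
        x = pd.concat([pres.values, absn.values], ignore_index=True)
        y = np.concatenate([np.ones(len(pres), int), np.zeros(len(absn), int)])
        ens = ensemble_predict(fits, x, y)
        np.testing.assert_allclose(
            ens.suitability.values[~ens.suitability.mask],
            fits[0].prediction.values[~fits[0].prediction.mask],
        )


class TestRangeArea:
    def test_empty_map(self, flat_transform):
        grid = RasterGrid(np.zeros((5, 5)), flat_transform)
        assert range_area_km2(grid) == 0.0

    def test_counts_presence_cells_only(self):
        t = GridTransform(west=0.0, north=1.0 / 12.0, cellsize=1.0 / 12.0)
        vals = np.array([[1.0]])
        assert range_area_km2(RasterGrid(vals, t)) == pytest.approx(85.9, abs=0.2)

    def test_non_geographic_crs_rejected(self, flat_transform):
        grid = RasterGrid(np.ones((2, 2)), flat_transform, crs="EPSG:3857")
        with pytest.raises(ValueError):
            range_area_km2(grid)
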