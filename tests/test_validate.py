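"""Completeness analytics and accuracy metrics against independent oracles."""

import math

import numpy as np
import pytest

from urbanmosaic.raster import CategoricalRaster
from urbanmosaic.validate import (
    ConfusionMatrix,
    area_regression,
    completeness,
    confusion,
    kappa,
    precision,
    stratified_sample,
    urban_proportion,
)


def raster(vals):
    vals = np.asarray(vals, dtype=np.int32)
    return CategoricalRaster(values=vals, transform=(0.0, vals.shape[0] * 30.0, 30.0), crs="m")


def kappa_oracle(counts):
    """Brute-force formula evaluation with explicit loops."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p_o = sum(counts[i, i] for i in range(len(counts))) / n
    p_e = 0.0
    for i in range(len(counts)):
        row = sum(counts[i, :])
        col = sum(counts[:, i])
        p_e += row * col / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def precision_oracle(counts):
    counts = np.asarray(counts, dtype=float)
    out = []
    for i in range(len(counts)):
        row = sum(counts[i, :])
        out.append(counts[i, i] / row if row > 0 else None)
    return out


class TestKappa:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(labels=[1, 2, 3], counts=np.diag([5, 7, 9]))
        assert kappa(cm) == pytest.approx(1.0)

    def test_chance_agreement_zero(self):
        cm = ConfusionMatrix(labels=[1, 2], counts=np.array([[25, 25], [25, 25]]))
        assert kappa(cm) == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_two_class(self):
        # p_o = 0.85, p_e = 0.50 -> kappa = 0.70
        cm = ConfusionMatrix(labels=[1, 2], counts=np.array([[40, 10], [5, 45]]))
        assert kappa(cm) == pytest.approx(0.70)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            kappa(ConfusionMatrix(labels=[1], counts=np.zeros((1, 1), dtype=int)))

    def test_degenerate_single_class(self):
        cm = ConfusionMatrix(labels=[1], counts=np.array([[10]]))
        assert kappa(cm) == 1.0

    def test_random_matrices_match_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            k = rng.integers(2, 8)
            counts = rng.integers(0, 40, size=(k, k))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(labels=list(range(k)), counts=counts)
            assert kappa(cm) == pytest.approx(kappa_oracle(counts), abs=1e-12)

    def test_matches_sklearn_on_labelled_pairs(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 4, 500)
        ref = np.where(rng.random(500) < 0.7, pred, rng.integers(0, 4, 500))
        cm = confusion(list(zip(pred.tolist(), ref.tolist())), labels=[0, 1, 2, 3])
        assert kappa(cm) == pytest.approx(sklearn_metrics.cohen_kappa_score(pred, ref), abs=1e-12)

    def test_invariant_under_simultaneous_permutation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(5, 5))
        perm = rng.permutation(5)
        cm = ConfusionMatrix(labels=list(range(5)), counts=counts)
        cmp_ = ConfusionMatrix(labels=list(range(5)), counts=counts[np.ix_(perm, perm)])
        assert kappa(cm) == pytest.approx(kappa(cmp_), abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            counts = rng.integers(0, 20, size=(3, 3))
            if counts.sum() == 0:
                continue
            v = kappa(ConfusionMatrix(labels=[1, 2, 3], counts=counts))
            assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12


class TestPrecision:
    def test_diagonal_all_ones(self):
        cm = ConfusionMatrix(labels=[1, 2], counts=np.diag([4, 6]))
        assert precision(cm) == {1: 1.0, 2: 1.0}

    def test_hand_check(self):
        cm = ConfusionMatrix(labels=[1, 2], counts=np.array([[8, 2], [0, 5]]))
        assert precision(cm)[1] == pytest.approx(0.8)

    def test_never_predicted_is_missing_not_zero(self):
        cm = ConfusionMatrix(labels=[1, 2], counts=np.array([[3, 1], [0, 0]]))
        assert precision(cm)[2] is None

    def test_weighted_precision_equals_overall_accuracy(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 30, size=(4, 4))
        cm = ConfusionMatrix(labels=list(range(4)), counts=counts)
        prec = precision(cm)
        rows = counts.sum(axis=1)
        weighted = sum(prec[c] * rows[i] for i, c in enumerate(cm.labels)) / counts.sum()
        assert weighted == pytest.approx(np.trace(counts) / counts.sum(), abs=1e-12)

    def test_random_match_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 25, size=(6, 6))
        cm = ConfusionMatrix(labels=list(range(6)), counts=counts)
        got = precision(cm)
        for i, exp in enumerate(precision_oracle(counts)):
            if exp is None:
                assert got[i] is None
            else:
                assert got[i] == pytest.approx(exp, abs=1e-12)


class TestConfusion:
    def test_all_agree_diagonal(self):
        cm = confusion([(1, 1), (2, 2), (1, 1), (2, 2)])
        assert np.array_equal(cm.counts, [[2, 0], [0, 2]])

    def test_empty_zero_matrix(self):
        cm = confusion([], labels=[1, 2])
        assert cm.counts.sum() == 0

    def test_hand_tally(self):
        pairs = [(1, 1), (1, 2), (2, 2), (2, 2), (2, 1), (1, 1)]
        cm = confusion(pairs, labels=[1, 2])
        assert np.array_equal(cm.counts, [[2, 1], [1, 2]])

    def test_outside_label_set_errors(self):
        with pytest.raises(ValueError):
            confusion([(1, 9)], labels=[1, 2])


class TestCompleteness:
    def test_fully_defined(self, registry):
        osm = raster(np.full((10, 10), 1))
        glob = raster(np.full((10, 10), 1))
        assert completeness(osm, glob, registry).overall_completeness == 1.0

    @pytest.mark.parametrize("void_frac", [0.0, 0.25, 0.5, 1.0])
    def test_planted_void_fraction(self, registry, void_frac):
        vals = np.full(100, 8, dtype=np.int32)
        vals[: int(100 * void_frac)] = 0
        rep = completeness(raster(vals.reshape(10, 10)), raster(np.full((10, 10), 8)), registry)
        assert rep.overall_completeness == pytest.approx(1.0 - void_frac, abs=0)

    def test_area_diffs_match_hand_tally(self, registry):
        osm = raster([[1, 1, 8], [0, 8, 8], [12, 0, 1]])
        glob = raster([[1, 1, 1], [8, 8, 8], [12, 12, 12]])
        rep = completeness(osm, glob, registry)
        cell = 900.0
        # hand counts: osm 1:3, 8:3, 12:1; global 1:3, 8:3, 12:3
        assert rep.per_class_area_diff[1] == pytest.approx(0.0)
        assert rep.per_class_area_diff[8] == pytest.approx(0.0)
        assert rep.per_class_area_diff[12] == pytest.approx(2 * cell)

    def test_unknown_subcategory_share(self, registry):
        vals = np.full((10, 10), 8, dtype=np.int32)
        vals[:2, :] = 7
        vals[2, :5] = 17
        rep = completeness(raster(vals), raster(vals), registry)
        assert rep.unknown_subcategory_share[7] == pytest.approx(0.20)
        assert rep.unknown_subcategory_share[17] == pytest.approx(0.05)
        assert rep.unknown_subcategory_share[28] == pytest.approx(0.0)

    def test_grid_mismatch_errors(self, registry):
        with pytest.raises(ValueError):
            completeness(raster(np.zeros((3, 3))), raster(np.zeros((4, 4))), registry)


class TestUrbanProportion:
    def test_all_forest_zero(self, registry):
        assert urban_proportion(raster(np.full((5, 5), 8)), registry) == 0.0

    def test_all_buildings_one(self, registry):
        assert urban_proportion(raster(np.full((5, 5), 14)), registry) == 1.0

    def test_mixed_fraction(self, registry):
        vals = np.full(100, 8, dtype=np.int32)
        vals[:40] = 14  # 40 urban cells of 100
        assert urban_proportion(raster(vals.reshape(10, 10)), registry) == pytest.approx(0.4)

    def test_developed_unknown_counts_as_urban(self, registry):
        vals = np.full((10, 10), 8, dtype=np.int32)
        vals[0, :] = 28
        assert urban_proportion(raster(vals), registry) == pytest.approx(0.1)


class TestStratifiedSample:
    def test_exhaustion(self):
        vals = np.full((5, 5), 1, dtype=np.int32)
        vals[0, :3] = 2  # class 2 has 3 cells
        sample = stratified_sample(raster(vals), 10, seed=0)
        assert sum(1 for _, c in sample if c == 2) == 3
        assert sum(1 for _, c in sample if c == 1) == 10

    def test_deterministic_under_seed(self):
        vals = np.arange(100).reshape(10, 10) % 4 + 1
        r = raster(vals)
        assert stratified_sample(r, 5, seed=42) == stratified_sample(r, 5, seed=42)

    def test_within_class_uniformity(self):
        """Across repeated seeds every cell of a class is drawn ~equally."""
        vals = np.ones((8, 8), dtype=np.int32)
        r = raster(vals)
        hits = np.zeros((8, 8))
        n_rep = 400
        for s in range(n_rep):
            for (i, j), _ in stratified_sample(r, 16, seed=s):
                hits[i, j] += 1
        expected = n_rep * 16 / 64
        chi2 = ((hits - expected) ** 2 / expected).sum()
        # chi2 with 63 dof: 0.999 quantile ~ 103
        assert chi2 < 110

    def test_codes_are_predictions(self):
        vals = np.full((4, 4), 3, dtype=np.int32)
        for (i, j), c in stratified_sample(raster(vals), 4, seed=1):
            assert vals[i, j] == c

    def test_empty_raster_errors(self):
        with pytest.raises(ValueError):
            stratified_sample(raster(np.zeros((3, 3))), 2, seed=0)


class TestAreaRegression:
    def test_identity_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = area_regression(x, x)
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0) and r2 == pytest.approx(1.0)

    def test_constant_response(self):
        slope, intercept, r2 = area_regression(np.arange(5.0), np.full(5, 3.0))
        assert slope == 0.0 and r2 == 0.0

    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 1, 20)
        y = 0.02 + 0.96 * x + rng.normal(0, 0.01, 20)
        slope, intercept, r2 = area_regression(x, y)
        assert abs(slope - 0.96) < 0.05
        assert r2 > 0.95

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            area_regression(np.full(5, 2.0), np.arange(5.0))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            area_regression([1, 2], [1, 2])
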