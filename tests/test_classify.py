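"""Fisher LDA pipelines, feature selection, boundaries and peak ratios."""

import numpy as np
import pytest

from mrsdss.classify import (
    FisherLDA,
    FisherLDAResults,
    LabeledDataset,
    RatioRule,
    SelectionError,
    bootstrap_evaluate,
    concat_te,
    dataset_offset,
    decision_boundaries,
    default_trainer,
    evaluate_on_test,
    fisher_lda_fit,
    manual_overview,
    normalize,
    peak_height,
    ratio_classify,
    restrict_range,
    restricted_indices,
    restricted_ppm,
    sequential_forward_select,
)
from mrsdss.simulate import lorentzian_canonical
from mrsdss.spectra_io import CanonicalSpectrum, N_POINTS, PpmAxis, TeClass, ppm_axis

AXIS = PpmAxis()


def gaussian_blob_dataset(
    means_2d, n_per_class=40, sigma=1.0, noise_dims=0, seed=0
):
    """Isotropic Gaussian classes, optionally embedded among noise dimensions."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for name, mean in means_2d.items():
        pts = rng.normal(mean, sigma, size=(n_per_class, len(mean)))
        if noise_dims:
            pts = np.column_stack([pts, rng.normal(0, 1, (n_per_class, noise_dims))])
        X.append(pts)
        y += [name] * n_per_class
    X = np.vstack(X)
    return LabeledDataset(X, y, "short", ppm=np.arange(X.shape[1], dtype=float))


class TestRestrictAndConcat:
    def test_restriction_matches_brute_force_count(self):
        ppm = ppm_axis()
        expected = int(np.sum((ppm >= 0.01) & (ppm <= 4.05)))
        s = CanonicalSpectrum(np.arange(N_POINTS, dtype=float))
        assert restrict_range(s).size == expected == restricted_indices().size

    def test_every_retained_ppm_in_band_and_neighbours_outside(self):
        idx = restricted_indices()
        ppm = ppm_axis()
        assert np.all((ppm[idx] >= 0.01) & (ppm[idx] <= 4.05))
        assert np.all(np.diff(idx) == 1)  # contiguous slice
        assert not 0.01 <= ppm[idx[0] - 1] <= 4.05
        assert not 0.01 <= ppm[idx[-1] + 1] <= 4.05

    def test_all_zero_spectrum_restricts_to_zero_vector(self):
        assert not restrict_range(CanonicalSpectrum(np.zeros(N_POINTS))).any()

    def test_concat_is_short_then_long_and_splits_back(self):
        rng = np.random.default_rng(0)
        short = CanonicalSpectrum(rng.normal(size=N_POINTS), TeClass.SHORT)
        long = CanonicalSpectrum(rng.normal(size=N_POINTS), TeClass.LONG)
        vec = concat_te(short, long)
        half = restricted_indices().size
        assert vec.size == 2 * half
        assert np.array_equal(vec[:half], restrict_range(short))
        assert np.array_equal(vec[half:], restrict_range(long))

    def test_concat_column_ppm_bookkeeping(self):
        half = restricted_ppm()
        ds = LabeledDataset(
            np.zeros((1, 2 * half.size)), ["x"], "concat"
        )
        assert np.array_equal(ds.ppm[: half.size], ds.ppm[half.size:])

    def test_te_class_mismatch_rejected(self):
        s = CanonicalSpectrum(np.ones(N_POINTS), TeClass.LONG)
        l = CanonicalSpectrum(np.ones(N_POINTS), TeClass.SHORT)
        with pytest.raises(ValueError):
            concat_te(s, l)


class TestNormalize:
    def test_unit_norm(self):
        v = np.random.default_rng(0).normal(size=50)
        assert np.linalg.norm(normalize(v)) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        v = np.random.default_rng(1).normal(size=50)
        assert np.allclose(normalize(3.7 * v), normalize(v))

    def test_none_is_identity(self):
        v = np.arange(5.0)
        assert np.array_equal(normalize(v, "none"), v)

    def test_zero_vector_rejected_for_unit_norm(self):
        with pytest.raises(ValueError):
            normalize(np.zeros(10))


class TestSequentialForwardSelection:
    def test_single_separating_column_selected_first(self):
        rng = np.random.default_rng(0)
        n = 40
        X = rng.normal(0, 1, (2 * n, 5))
        X[:n, 2] += 8.0  # column 2 separates the classes
        ds = LabeledDataset(X, ["a"] * n + ["b"] * n, "short", ppm=np.arange(5.0))
        sel = sequential_forward_select(ds, max_features=1)
        # oracle: exhaustive single-column LDA training accuracy
        accs = [fisher_lda_fit(ds, [j]).training_accuracy() for j in range(5)]
        assert sel.indices[0] == int(np.argmax(accs)) == 2

    def test_duplicated_informative_column_skipped_by_correlation_rule(self):
        rng = np.random.default_rng(1)
        n = 30
        X = rng.normal(0, 1, (2 * n, 4))
        X[:n, 1] += 6.0
        X = np.column_stack([X, X[:, 1]])  # column 4 duplicates column 1 (r = 1)
        ds = LabeledDataset(X, ["a"] * n + ["b"] * n, "short", ppm=np.arange(5.0))
        sel = sequential_forward_select(ds, max_features=5)
        assert 1 in sel.indices
        assert 4 not in sel.indices
        assert 4 in sel.skipped_correlated

    def test_feature_cap_respected_with_unique_ordered_indices(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (60, 30))
        X[:20, :10] += 1.0
        X[20:40, 10:20] += 1.0
        labels = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        ds = LabeledDataset(X, labels, "short", ppm=np.arange(30.0))
        sel = sequential_forward_select(ds, max_features=13)
        assert 1 <= len(sel.indices) <= 13
        assert len(set(sel.indices)) == len(sel.indices)
        assert len(sel.criterion_trace) == len(sel.indices)
        # criterion trace is non-decreasing (greedy improvement)
        assert all(b >= a for a, b in zip(sel.criterion_trace, sel.criterion_trace[1:]))

    def test_single_class_dataset_rejected(self):
        ds = LabeledDataset(np.ones((5, 3)), ["a"] * 5, "short", ppm=np.arange(3.0))
        with pytest.raises(ValueError):
            sequential_forward_select(ds)


class TestFisherLda:
    def test_two_isotropic_classes_axis_parallel_to_mean_difference(self):
        ds = gaussian_blob_dataset(
            {"a": (0, 0), "b": (6, 2)}, n_per_class=500, sigma=1.0, seed=0
        )
        res = fisher_lda_fit(ds)
        direction = res.projection[:, 0] / np.linalg.norm(res.projection[:, 0])
        # near-isotropic scatter: discriminant axis ~ the mean difference
        mean_diff = np.array([6.0, 2.0]) / np.linalg.norm([6.0, 2.0])
        assert abs(direction @ mean_diff) > 0.99
        # exact two-class closed form: w ~ Sw^-1 (m_b - m_a)
        from mrsdss.classify import _scatter_matrices, _regularise

        sw, _, means = _scatter_matrices(ds.vectors, ds.label_indices(), 2)
        w_exact = np.linalg.solve(_regularise(sw, 1e-6), means[1] - means[0])
        w_exact /= np.linalg.norm(w_exact)
        assert abs(direction @ w_exact) > 1 - 1e-9

    def test_collinear_class_means_give_rank_one_between_scatter(self):
        ds = gaussian_blob_dataset(
            {"a": (0, 0, 0), "b": (4, 0, 0), "c": (8, 0, 0)}, sigma=1.0, seed=1
        )
        res = fisher_lda_fit(ds)
        assert res.eigenvalues[0] > 1.0
        assert res.eigenvalues[1] < 0.05 * res.eigenvalues[0]

    def test_matches_brute_force_generalized_eigensolver_on_toy_set(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (6, 3))
        ds = LabeledDataset(X, ["a", "a", "b", "b", "c", "c"], "short",
                            ppm=np.arange(3.0))
        res = fisher_lda_fit(ds)
        # independent oracle: explicit inv(Sw_reg) @ Sb eigen decomposition
        from mrsdss.classify import _scatter_matrices, _regularise

        sw, sb, _ = _scatter_matrices(X, ds.label_indices(), 3)
        w_oracle = np.linalg.eig(np.linalg.inv(_regularise(sw, 1e-6)) @ sb)
        order = np.argsort(w_oracle.eigenvalues.real)[::-1]
        ours = X @ res.projection
        theirs = X @ w_oracle.eigenvectors[:, order[:2]].real
        for j in range(2):
            r = np.corrcoef(ours[:, j], theirs[:, j])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scikit_learn_eigen_solver(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 30, 10
        X = rng.normal(0, 1, (n, p))
        labels = (["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        X[:10] += rng.normal(0, 2, p)
        X[10:20] += rng.normal(0, 2, p)
        ds = LabeledDataset(X, labels, "short", ppm=np.arange(float(p)))
        res = fisher_lda_fit(ds, shrinkage=1e-9)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        sk = LinearDiscriminantAnalysis(solver="eigen").fit(X, labels)
        ours = X @ res.projection
        theirs = X @ sk.scalings_[:, :2]
        for j in range(2):
            r = np.corrcoef(ours[:, j], theirs[:, j])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-8

    def test_single_feature_second_axis_is_plot_only_zero(self):
        ds = gaussian_blob_dataset({"a": (0,), "b": (5,)}, sigma=0.5, seed=2)
        res = fisher_lda_fit(ds)
        assert res.projection.shape == (1, 2)
        assert np.all(res.projection[:, 1] == 0.0)

    def test_fewer_than_two_classes_rejected(self):
        ds = LabeledDataset(np.ones((4, 2)), ["a"] * 4, "short", ppm=np.arange(2.0))
        with pytest.raises(ValueError):
            FisherLDA(ds)


class TestProjectPredict:
    @pytest.fixture()
    def fitted(self):
        ds = gaussian_blob_dataset(
            {"a": (0, 0), "b": (6, 0), "c": (0, 6)}, sigma=1.0, noise_dims=3, seed=4
        )
        return fisher_lda_fit(ds), ds

    def test_class_mean_input_projects_to_class_mean(self, fitted):
        res, ds = fitted
        for k, name in enumerate(res.classes):
            rows = np.array(ds.labels) == name
            mean_vec = ds.vectors[rows].mean(axis=0)
            assert np.allclose(res.project(mean_vec), res.class_means_2d[k], atol=1e-10)

    def test_projection_is_linear(self, fitted):
        res, ds = fitted
        v, w = ds.vectors[0], ds.vectors[1]
        lhs = res.project(2.0 * v + 0.5 * w)
        rhs = 2.0 * res.project(v) + 0.5 * res.project(w)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_point_at_class_mean_predicted_as_that_class(self, fitted):
        res, ds = fitted
        for k, name in enumerate(res.classes):
            rows = np.array(ds.labels) == name
            assert res.predict(ds.vectors[rows].mean(axis=0)) == name

    def test_midpoint_tie_goes_to_first_declared_class(self):
        res = FisherLDAResults(
            model=None,
            classes=["first", "second"],
            projection=np.eye(2),
            eigenvalues=np.array([1.0, 0.0]),
            class_means_2d=np.array([[0.0, 0.0], [2.0, 0.0]]),
        )
        res._features = (0, 1)
        assert res.predict(np.array([1.0, 0.0])) == "first"

    def test_well_separated_simulation_accuracy(self):
        train = gaussian_blob_dataset(
            {"a": (0, 0), "b": (6, 0), "c": (0, 6)}, n_per_class=100,
            sigma=1.0, seed=5,
        )
        res = fisher_lda_fit(train)
        pred = res.predict(train.vectors)
        assert np.mean(pred == np.array(train.labels)) >= 0.95

    def test_projection_roundtrips_through_json(self, fitted, tmp_path):
        res, ds = fitted
        before = res.project(ds.vectors)
        path = tmp_path / "model.json"
        res.to_json(path)
        loaded = FisherLDAResults.from_json(path)
        after = loaded.project(ds.vectors)
        assert np.array_equal(before, after)  # bit-for-bit
        assert loaded.classes == res.classes
        assert np.array_equal(loaded.predict(ds.vectors), res.predict(ds.vectors))

    def test_length_mismatch_rejected(self, fitted):
        res, _ = fitted
        with pytest.raises(ValueError):
            res.project(np.ones(3))


class TestDecisionBoundaries:
    def test_two_classes_single_bisector_equidistant(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (5, 1)}, seed=6)
        res = fisher_lda_fit(ds)
        bounds = res.decision_boundaries()
        assert len(bounds.lines) == 1
        line = bounds.lines[0]
        rng = np.random.default_rng(0)
        m0, m1 = res.class_means_2d
        for _ in range(100):
            # sample a point on the line a x + b y = c
            x = rng.uniform(-10, 10)
            y = (line["c"] - line["a"] * x) / line["b"]
            pt = np.array([x, y])
            assert np.linalg.norm(pt - m0) == pytest.approx(
                np.linalg.norm(pt - m1), rel=1e-9
            )

    def test_three_noncollinear_means_rays_meet_at_circumcenter(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (6, 0), "c": (1, 5)}, seed=7)
        res = fisher_lda_fit(ds)
        bounds = res.decision_boundaries()
        A, B, C = res.class_means_2d
        # computational-geometry oracle: circumcenter of the mean triangle
        d = 2 * (A[0] * (B[1] - C[1]) + B[0] * (C[1] - A[1]) + C[0] * (A[1] - B[1]))
        ux = ((A @ A) * (B[1] - C[1]) + (B @ B) * (C[1] - A[1]) + (C @ C) * (A[1] - B[1])) / d
        uy = ((A @ A) * (C[0] - B[0]) + (B @ B) * (A[0] - C[0]) + (C @ C) * (B[0] - A[0])) / d
        for line in bounds.lines:
            assert abs(line["a"] * ux + line["b"] * uy - line["c"]) < 1e-9

    def test_every_training_point_falls_in_its_predicted_region(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (6, 0), "c": (0, 6)}, seed=8)
        res = fisher_lda_fit(ds)
        bounds = res.decision_boundaries()
        latent = res.project(ds.vectors)
        regions = bounds.regions_of(latent)
        pred = res.predict(ds.vectors)
        assert np.all(regions == pred)

    def test_regions_partition_the_plane(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (4, 3), "c": (-2, 5)}, seed=9)
        res = fisher_lda_fit(ds)
        bounds = res.decision_boundaries()
        rng = np.random.default_rng(1)
        xmin, ymin, xmax, ymax = bounds.box
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, 2000), rng.uniform(ymin, ymax, 2000)]
        )
        regions = bounds.regions_of(pts)
        assert not np.any(regions == None)  # noqa: E711  every point assigned
        dists = ((pts[:, None, :] - res.class_means_2d[None]) ** 2).sum(-1)
        nearest = np.array([res.classes[i] for i in dists.argmin(1)])
        assert np.mean(regions == nearest) == 1.0


class TestBootstrapEvaluation:
    def test_separable_dataset_scores_near_perfect(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (10, 0)}, sigma=0.5, seed=10)
        ev = bootstrap_evaluate(ds, trainer=lambda d: fisher_lda_fit(d), B=30, seed=1)
        assert ev.accuracy >= 0.99

    def test_same_seed_reproduces_result_exactly(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (3, 0)}, sigma=1.5, seed=11)
        trainer = lambda d: fisher_lda_fit(d)  # noqa: E731
        ev1 = bootstrap_evaluate(ds, trainer, B=25, seed=42)
        ev2 = bootstrap_evaluate(ds, trainer, B=25, seed=42)
        assert ev1.accuracy == ev2.accuracy
        assert np.array_equal(ev1.oob_accuracies, ev2.oob_accuracies)
        assert np.array_equal(ev1.confusion, ev2.confusion)

    def test_degenerate_resample_equals_training_accuracy(self):
        # all rows of a class identical: every resample carries the same
        # information as the full dataset, so OOB accuracy must equal the
        # training accuracy of the deterministic trainer
        X = np.vstack([np.tile([0.0, 0.0], (10, 1)), np.tile([5.0, 1.0], (10, 1))])
        ds = LabeledDataset(X, ["a"] * 10 + ["b"] * 10, "short", ppm=np.arange(2.0))
        trainer = lambda d: fisher_lda_fit(d)  # noqa: E731
        ev = bootstrap_evaluate(ds, trainer, B=1, seed=0)
        train_acc = fisher_lda_fit(ds).training_accuracy()
        assert ev.accuracy == train_acc == 1.0

    def test_confusion_rows_total_oob_counts(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (4, 0)}, sigma=1.0, seed=12)
        ev = bootstrap_evaluate(ds, lambda d: fisher_lda_fit(d), B=10, seed=3)
        assert ev.confusion.sum() > 0
        assert ev.confusion.shape == (2, 2)


class TestEvaluateOnTest:
    def test_test_equals_training_on_separable_fixture(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (8, 0)}, sigma=0.5, seed=13)
        res = fisher_lda_fit(ds)
        ev = evaluate_on_test(res, ds)
        assert ev.accuracy == 1.0
        assert np.trace(ev.confusion) == ds.n

    def test_fresh_draw_from_training_distribution(self):
        means = {"a": (0, 0), "b": (6, 0), "c": (0, 6)}
        train = gaussian_blob_dataset(means, n_per_class=60, sigma=1.0, seed=14)
        test = gaussian_blob_dataset(means, n_per_class=60, sigma=1.0, seed=15)
        res = fisher_lda_fit(train)
        ev = evaluate_on_test(res, test)
        assert ev.accuracy >= 0.95

    def test_empty_test_set_raises(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (8, 0)}, seed=16)
        res = fisher_lda_fit(ds)
        empty = LabeledDataset(np.empty((0, 2)), [], "short", ppm=np.arange(2.0))
        with pytest.raises(ValueError):
            evaluate_on_test(res, empty)


class TestPeakHeightsAndRatios:
    def test_offset_is_minus_dataset_minimum(self):
        a = CanonicalSpectrum(np.full(N_POINTS, -5.0))
        b = CanonicalSpectrum(np.zeros(N_POINTS))
        assert dataset_offset([a, b]) == 5.0
        h = peak_height(a, 3.0, dataset_offset_value=dataset_offset([a, b]))
        assert h == 0.0  # -5 + 5; every height is now non-negative

    def test_offset_recomputed_when_a_new_case_arrives(self):
        spectra = [CanonicalSpectrum(np.full(N_POINTS, -5.0))]
        assert dataset_offset(spectra) == 5.0
        spectra.append(CanonicalSpectrum(np.full(N_POINTS, -9.0)))
        assert dataset_offset(spectra) == 9.0

    def test_all_positive_dataset_has_zero_offset(self):
        s = CanonicalSpectrum(np.ones(N_POINTS))
        assert dataset_offset([s]) == 0.0
        assert peak_height(s, 2.0) == 1.0

    def test_off_axis_ppm_rejected(self):
        with pytest.raises(ValueError):
            peak_height(CanonicalSpectrum(np.ones(N_POINTS)), 9.5)

    @staticmethod
    def _peaked(heights: dict[float, float], te: TeClass) -> CanonicalSpectrum:
        values = np.zeros(N_POINTS)
        for ppm, h in heights.items():
            values[AXIS.index_of(ppm)] = h
        return CanonicalSpectrum(values, te)

    def test_tumour_profile_has_choline_ratio_above_one(self):
        short = self._peaked({3.21: 8.0, 2.01: 1.0}, TeClass.SHORT)
        long = self._peaked({3.55: 2.0, 2.01: 1.0}, TeClass.LONG)
        x, y, label = ratio_classify(short, long)
        assert x > 1.0
        assert label is None  # boundary ships unset

    def test_equal_peak_heights_give_unit_ratio(self):
        short = self._peaked({3.21: 3.0, 2.01: 3.0}, TeClass.SHORT)
        long = self._peaked({3.55: 3.0, 2.01: 3.0}, TeClass.LONG)
        x, y, _ = ratio_classify(short, long)
        assert x == pytest.approx(1.0)
        assert y == pytest.approx(1.0)

    def test_inverted_long_te_lactate_keeps_denominators_positive(self):
        short = self._peaked({3.21: 5.0, 2.01: 2.0}, TeClass.SHORT)
        values = np.zeros(N_POINTS)
        values[AXIS.index_of(1.31)] = -20.0  # inverted lactate dominates the minimum
        values[AXIS.index_of(3.55)] = 1.0
        values[AXIS.index_of(2.01)] = 1.5
        long = CanonicalSpectrum(values, TeClass.LONG)
        x, y, _ = ratio_classify(short, long)
        assert np.isfinite(x) and np.isfinite(y)
        assert x > 0 and y > 0

    def test_boundary_rule_classifies_by_side(self):
        rule = RatioRule(boundary=((0.0, 1.0), (10.0, 1.0)),
                         class_above="tumoural", class_below="pseudotumoural")
        short_t = self._peaked({3.21: 8.0, 2.01: 1.0}, TeClass.SHORT)
        long_t = self._peaked({3.55: 5.0, 2.01: 1.0}, TeClass.LONG)
        _, _, label = ratio_classify(short_t, long_t, rule)
        assert label == "tumoural"


class TestManualOverview:
    def test_height_mode_with_equal_ppms_gives_diagonal(self):
        spectra = [
            lorentzian_canonical(3.21, height=float(h), noise_sd=0.0)
            for h in (10, 20, 30)
        ]
        coords = manual_overview(spectra, 3.21, 3.21, mode="height")
        assert np.allclose(coords[:, 0], coords[:, 1])

    def test_ratio_mode_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(17)
        spectra = [
            CanonicalSpectrum(rng.normal(0, 1.0, N_POINTS)) for _ in range(5)
        ]
        coords = manual_overview(spectra, 3.21, 2.01, mode="ratio")
        offset = max(0.0, -min(float(s.intensities.min()) for s in spectra))
        for s, (x, y) in zip(spectra, coords):
            ha = peak_height(s, 3.21, 5, offset)
            hb = peak_height(s, 2.01, 5, offset)
            assert x == pytest.approx(ha / hb)
            assert y == pytest.approx(hb / ha)

    def test_empty_dataset_gives_empty_result(self):
        coords = manual_overview([], 3.21, 2.01, mode="ratio")
        assert coords.shape == (0, 2)


class TestSummaryAndPlot:
    def test_summary_mentions_classes_and_accuracy(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (8, 0)}, seed=18)
        res = fisher_lda_fit(ds)
        text = res.summary()
        assert "a" in text and "b" in text
        assert "train accuracy" in text

    def test_plot_returns_axes(self):
        ds = gaussian_blob_dataset({"a": (0, 0), "b": (8, 0)}, seed=19)
        res = fisher_lda_fit(ds)
        ax = res.plot()
        assert ax is not None
        import matplotlib.pyplot as plt

        plt.close("all")
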