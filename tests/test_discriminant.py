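import numpy as np
import pytest

import balfprofiler as bp


def make_gaussian_cohort(rng, n_per_class=30, shift=1.5):
    """Two Gaussian classes embedded in valid fingerprint space."""
    X1 = rng.normal(0.0, 1.0, (n_per_class, 10))
    X2 = rng.normal(shift, 1.0, (n_per_class, 10))
    fps = [
        bp.FingerprintVector.from_values(f"G{i}", np.clip(50 + 5 * x, 0, 100))
        for i, x in enumerate(X1)
    ] + [
        bp.FingerprintVector.from_values(f"P{i}", np.clip(50 + 5 * x, 0, 100))
        for i, x in enumerate(X2)
    ]
    labels = ["Good"] * n_per_class + ["Poor"] * n_per_class
    return bp.LabeledCohort(tuple(fps), tuple(labels))


def point_mass_cohort():
    a = bp.FingerprintVector.from_values("a", [10, 10] + [0] * 8)
    b = bp.FingerprintVector.from_values("b", [40, 50] + [0] * 8)
    return bp.LabeledCohort((a, a, b, b), ("Good", "Good", "Poor", "Poor")), a, b


class TestFitLda:
    def test_point_mass_classes_separate_with_margin(self):
        cohort, a, b = point_mass_cohort()
        model = bp.fit_lda(cohort, n_axes=1)
        pa = bp.project(model, a)[0]
        pb = bp.project(model, b)[0]
        assert pb - pa > 0  # orientation: Poor above Good, positive margin
        assert bp.classify(model, a) == "Good"
        assert bp.classify(model, b) == "Poor"

    def test_two_class_direction_matches_closed_form(self, rng):
        """Fisher's two-class solution is S_W^-1 (mu2 - mu1) up to scale."""
        cohort = make_gaussian_cohort(rng)
        model = bp.fit_lda(cohort, n_axes=1, gamma=0.0)
        Z = (cohort.feature_matrix - model.feature_means) / model.feature_scales
        n = len(cohort.labels) // 2
        Z1, Z2 = Z[:n], Z[n:]
        Sw = (Z1 - Z1.mean(0)).T @ (Z1 - Z1.mean(0)) + (
            Z2 - Z2.mean(0)
        ).T @ (Z2 - Z2.mean(0))
        w = np.linalg.solve(Sw, Z2.mean(0) - Z1.mean(0))
        w /= np.linalg.norm(w)
        cosine = abs(float(w @ model.axes[0]))
        assert cosine > 0.999

    def test_matches_sklearn_eigen_lda_direction(self, labeled_cohort):
        """Cross-check LD1 against an independent eigen-solver implementation."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        model = bp.fit_lda(labeled_cohort, n_axes=2, gamma=0.0)
        Z = (
            labeled_cohort.feature_matrix - model.feature_means
        ) / model.feature_scales
        sk = sklearn_lda(solver="eigen", n_components=2).fit(
            Z, list(labeled_cohort.labels)
        )
        sk_axis = sk.scalings_[:, 0] / np.linalg.norm(sk.scalings_[:, 0])
        cosine = abs(float(sk_axis @ model.axes[0]))
        assert cosine > 0.999

    def test_identical_class_means_flagged_degenerate(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(20, 80, (6, 10))
        fps = tuple(
            bp.FingerprintVector.from_values(f"S{i}", np.concatenate([x, x])[:10])
            for i, x in enumerate(np.vstack([X[:3], X[:3]]))
        )
        cohort = bp.LabeledCohort(fps, ("Good",) * 3 + ("Poor",) * 3)
        model = bp.fit_lda(cohort)
        assert model.degenerate
        with pytest.raises(bp.DegenerateModelError):
            bp.classify(model, fps[0])

    def test_orientation_poor_above_good(self, labeled_cohort):
        model = bp.fit_lda(labeled_cohort)
        by_class = dict(zip(model.classes, model.centroids[:, 0]))
        assert by_class["Poor"] >= by_class["Good"]

    def test_axes_are_unit_norm(self, labeled_cohort):
        model = bp.fit_lda(labeled_cohort)
        np.testing.assert_allclose(np.linalg.norm(model.axes, axis=1), 1.0, atol=1e-12)

    def test_class_with_single_member_rejected(self):
        fps = tuple(
            bp.FingerprintVector.from_values(f"S{i}", np.full(10, float(i + 1)))
            for i in range(3)
        )
        with pytest.raises(bp.ValidationError, match="2 members"):
            bp.LabeledCohort(fps, ("Good", "Good", "Poor"))

    def test_invalid_gamma_rejected(self, labeled_cohort):
        with pytest.raises(bp.ValidationError, match="gamma"):
            bp.fit_lda(labeled_cohort, gamma=1.5)


class TestProject:
    def test_grand_mean_projects_to_origin(self, labeled_cohort):
        model = bp.fit_lda(labeled_cohort)
        grand = labeled_cohort.feature_matrix.mean(axis=0)
        np.testing.assert_allclose(bp.project(model, grand), 0.0, atol=1e-9)

    def test_point_mass_sample_lands_on_its_centroid(self):
        cohort, a, b = point_mass_cohort()
        model = bp.fit_lda(cohort, n_axes=1)
        idx = model.classes.index("Good")
        np.testing.assert_allclose(
            bp.project(model, a), model.centroids[idx], atol=1e-9
        )

    def test_projection_equals_brute_force_dot_products(self, labeled_cohort, rng):
        model = bp.fit_lda(labeled_cohort)
        for _ in range(100):
            x = rng.uniform(0, 100, 10)
            z = (x - model.feature_means) / model.feature_scales
            expected = np.array([model.axes[j] @ z for j in range(model.n_axes)])
            np.testing.assert_allclose(bp.project(model, x), expected, atol=1e-12)

    def test_affine_equivariance_under_constant_shift(self, labeled_cohort):
        """Adding a constant to all training + query data leaves canonical
        coordinates unchanged (absorbed by standardization)."""
        shift = 7.0
        shifted = bp.LabeledCohort(
            tuple(
                bp.FingerprintVector.from_values(f.sample_id, f.values + shift)
                for f in labeled_cohort.fingerprints
            ),
            labeled_cohort.labels,
        )
        m1 = bp.fit_lda(labeled_cohort)
        m2 = bp.fit_lda(shifted)
        q = labeled_cohort.fingerprints[5].values
        np.testing.assert_allclose(
            bp.project(m1, q), bp.project(m2, q + shift), atol=1e-8
        )

    def test_arity_mismatch_rejected(self, labeled_cohort):
        model = bp.fit_lda(labeled_cohort)
        with pytest.raises(bp.ValidationError, match="10-feature"):
            bp.project(model, np.ones(4))


class TestClassify:
    def test_centroid_classifies_as_own_class(self, labeled_cohort):
        model = bp.fit_lda(labeled_cohort)
        # nudge standardized class means back to raw space
        for k, cls in enumerate(model.classes):
            raw = model.class_means[k] * model.feature_scales + model.feature_means
            assert bp.classify(model, raw) == cls

    def test_midpoint_tie_breaks_to_worse_prognosis(self):
        cohort, a, b = point_mass_cohort()
        model = bp.fit_lda(cohort, n_axes=1)
        mid = (a.values + b.values) / 2
        assert bp.classify(model, mid) == "Poor"

    def test_matches_brute_force_nearest_centroid(self, labeled_cohort, rng):
        model = bp.fit_lda(labeled_cohort)
        for _ in range(50):
            x = rng.uniform(0, 100, 10)
            coords = bp.project(model, x)
            d = np.linalg.norm(model.centroids - coords, axis=1)
            assert bp.classify(model, x) == model.classes[int(np.argmin(d))]


class TestLoocv:
    def test_perfectly_separated_point_masses_score_100(self):
        a = bp.FingerprintVector.from_values("a", [10] * 10)
        b = bp.FingerprintVector.from_values("b", [80] * 5 + [20] * 5)
        cohort = bp.LabeledCohort((a, a, a, b, b, b), ("Good",) * 3 + ("Poor",) * 3)
        cm = bp.loocv(cohort, n_axes=1)
        assert cm.accuracy == 100.00
        assert cm.skipped_folds == 0

    def test_one_sample_per_class_is_structured_error(self):
        fps = tuple(
            bp.FingerprintVector.from_values(f"S{i}", np.full(10, 10.0 * (i + 1)))
            for i in range(3)
        )
        with pytest.raises(bp.ValidationError):
            bp.LabeledCohort(fps, ("Good", "Neutral", "Poor"))

    def test_matches_brute_force_reimplementation(self, labeled_cohort):
        cm = bp.loocv(labeled_cohort, n_axes=2, gamma=0.1)
        # independent loop: refit and classify each left-out sample
        correct = 0
        total = 0
        for i in range(len(labeled_cohort.fingerprints)):
            rest = bp.LabeledCohort(
                labeled_cohort.fingerprints[:i] + labeled_cohort.fingerprints[i + 1:],
                labeled_cohort.labels[:i] + labeled_cohort.labels[i + 1:],
            )
            model = bp.fit_lda(rest, n_axes=2, gamma=0.1)
            pred = bp.classify(model, labeled_cohort.fingerprints[i])
            correct += pred == labeled_cohort.labels[i]
            total += 1
        assert cm.total == total
        assert cm.accuracy == round(100.0 * correct / total, 2)

    def test_high_separation_cohort_classifies_accurately(self, labeled_cohort):
        cm = bp.loocv(labeled_cohort, n_axes=2, gamma=0.1)
        assert cm.accuracy >= 95.0


class TestLd1SeverityCorrelation:
    def test_identity_relation_gives_r_one(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = bp.correlate_ld1_severity(x, x)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_anti_monotone_pairs_give_r_minus_one(self):
        fit = bp.correlate_ld1_severity([1, 2, 3], [3, 2, 1])
        assert fit.pearson_r == pytest.approx(-1.0)

    def test_exponential_recovery_noiseless(self):
        x = np.linspace(-2, 2, 25)
        y = 2.0 * np.exp(0.5 * x)
        fit = bp.correlate_ld1_severity(x, y)
        assert fit.a == pytest.approx(2.0, abs=1e-6)
        assert fit.b == pytest.approx(0.5, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_severity_rejected(self):
        with pytest.raises(bp.NumericalError):
            bp.correlate_ld1_severity([1, 2, 3], [2, 2, 2])


class TestDecisionMesh:
    def test_mesh_equals_pointwise_classify(self, labeled_cohort):
        model = bp.fit_lda(labeled_cohort, n_axes=2)
        xx, yy, mesh = bp.decision_mesh(model, (-6, 6, -6, 6), resolution=50)
        # exhaustive pointwise check via canonical-space nearest centroid
        for i in range(0, 50, 7):
            for j in range(0, 50, 7):
                pt = np.array([xx[i, j], yy[i, j]])
                d = np.linalg.norm(model.centroids - pt, axis=1)
                assert mesh[i, j] == model.classes[int(np.argmin(d))]

    def test_centroid_cells_carry_their_class(self, labeled_cohort):
        model = bp.fit_lda(labeled_cohort, n_axes=2)
        c = model.centroids
        pad = 0.5
        bounds = (
            c[:, 0].min() - pad, c[:, 0].max() + pad,
            c[:, 1].min() - pad, c[:, 1].max() + pad,
        )
        xx, yy, mesh = bp.decision_mesh(model, bounds, resolution=60)
        for k, cls in enumerate(model.classes):
            i = int(np.argmin(np.abs(yy[:, 0] - c[k, 1])))
            j = int(np.argmin(np.abs(xx[0] - c[k, 0])))
            assert mesh[i, j] == cls

    def test_one_axis_model_unsupported(self, labeled_cohort):
        model = bp.fit_lda(labeled_cohort, n_axes=1)
        with pytest.raises(bp.ValidationError, match="2-axis"):
            bp.decision_mesh(model, (-1, 1, -1, 1), resolution=10)


class TestSerialization:
    def test_round_trip_is_exact(self, labeled_cohort, tmp_path):
        model = bp.fit_lda(labeled_cohort)
        path = tmp_path / "model.json"
        model.save(path)
        back = bp.DiscriminantModel.load(path)
        assert back.classes == model.classes
        np.testing.assert_array_equal(back.axes, model.axes)
        np.testing.assert_array_equal(back.feature_means, model.feature_means)
        np.testing.assert_array_equal(back.centroids, model.centroids)
        assert back.gamma == model.gamma
        q = labeled_cohort.fingerprints[0]
        np.testing.assert_array_equal(bp.project(back, q), bp.project(model, q))
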