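"""PCA, discriminant analysis and fusion against independent oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from oralfusion import (
    DiscriminantModel,
    FeatureMatrix,
    PcaModel,
    discriminant_scores,
    fit_discriminant,
    fit_pca,
    fuse_features,
    max_components,
    predict_discriminant,
    transform_pca,
)
from oralfusion.errors import (
    AlignmentError,
    DegenerateInputError,
    DimensionMismatchError,
    InvalidSpecError,
)
from oralfusion.models import load_model, save_model


def _fm(values, labels=None, ids=None, modality="raman"):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    labels = np.asarray(labels if labels is not None else ["normal"] * n)
    ids = ids if ids is not None else [f"S{i}" for i in range(n)]
    return FeatureMatrix(values, labels, ids, modality)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_matches_covariance_eigendecomposition_oracle(rng):
    """Loadings/scores/ratios agree with an explicit eigensolver to 1e-8."""
    X = rng.normal(size=(10, 6))
    fm = _fm(X)
    model = fit_pca(fm, k=5)
    # independent oracle: eigendecomposition of the sample covariance matrix
    mean = X.mean(axis=0)
    cov = (X - mean).T @ (X - mean) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    signed = np.empty((6, 5))
    for j in range(5):
        v = evecs[:, j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        signed[:, j] = v
        np.testing.assert_allclose(model.loadings[:, j], v, atol=1e-8)
    np.testing.assert_allclose(
        model.explained_variance_ratio, evals[:5] / evals.sum(), atol=1e-8
    )
    scores = transform_pca(model, fm).values
    np.testing.assert_allclose(scores, (X - mean) @ signed, atol=1e-8)


def test_pca_matches_sklearn_cross_check(rng):
    sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
    X = rng.normal(size=(30, 8))
    fm = _fm(X)
    model = fit_pca(fm, k=3)
    ref = sklearn_pca(n_components=3).fit(X)
    for j in range(3):
        a, b = model.loadings[:, j], ref.components_[j]
        sign = np.sign(a @ b)
        np.testing.assert_allclose(a, sign * b, atol=1e-8)
    np.testing.assert_allclose(
        model.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-8
    )


def test_pca_two_feature_table_ratios_sum_to_one(rng):
    """With k = n_features the component variances account for everything."""
    X = rng.normal(size=(70, 2)) @ np.array([[2.0, 0.3], [0.1, 0.5]])
    model = fit_pca(_fm(X), k=2)
    assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(model.explained_variance_ratio) <= 1e-15)
    # orthonormal loadings
    np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(2), atol=1e-10)


def test_pca_degenerate_and_bad_k(rng):
    with pytest.raises(DegenerateInputError):
        fit_pca(_fm(np.ones((6, 3))), k=2)
    with pytest.raises(InvalidSpecError):
        fit_pca(_fm(rng.normal(size=(5, 3))), k=5)


def test_transform_properties(rng):
    X = rng.normal(size=(12, 5))
    fm = _fm(X)
    model = fit_pca(fm, k=3)
    # the mean maps to the origin
    zero = transform_pca(model, _fm(model.mean_vector[None, :])).values
    np.testing.assert_allclose(zero, 0.0, atol=1e-10)
    # mean + first loading maps to (1, 0, 0)
    one = transform_pca(model, _fm((model.mean_vector + model.loadings[:, 0])[None, :])).values
    np.testing.assert_allclose(one, [[1.0, 0.0, 0.0]], atol=1e-10)
    # training scores have diagonal covariance
    S = transform_pca(model, fm).values
    cov = np.cov(S, rowvar=False)
    np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-10)
    with pytest.raises(DimensionMismatchError):
        transform_pca(model, _fm(rng.normal(size=(3, 4))))


@pytest.mark.parametrize(
    "sizes,expected",
    [([35, 35], 17), ([4, 10], 1), ([5, 5], 2), ([6, 8], 2), ([2, 2], 0)],
)
def test_max_components_rule(sizes, expected):
    assert max_components(sizes) == expected


def test_max_components_rejects_tiny_class():
    with pytest.raises(InvalidSpecError):
        max_components([1, 10])


# ---------------------------------------------------------------------------
# Discriminant analysis
# ---------------------------------------------------------------------------

def _two_class_data(rng, n=40, p=3, delta=2.0):
    Xa = rng.normal(size=(n, p)) + delta
    Xb = rng.normal(size=(n, p))
    X = np.vstack([Xa, Xb])
    y = np.asarray(["tumor"] * n + ["normal"] * n)
    return X, y


@pytest.mark.parametrize("kind", ["linear", "quadratic"])
def test_discriminant_scores_match_gaussian_logdensity_oracle(rng, kind):
    """Scores equal log N(x; mu_c, Sigma_c) + log prior_c to 1e-8."""
    X, y = _two_class_data(rng)
    model = fit_discriminant(X, y, kind=kind, ridge=0.0)
    probes = rng.normal(size=(25, 3)) * 2.0
    scores = discriminant_scores(model, probes)
    for j, c in enumerate(model.classes):
        ref = multivariate_normal.logpdf(
            probes, mean=model.class_means[j], cov=model.class_covariances[j]
        ) + np.log(model.class_priors[j])
        np.testing.assert_allclose(scores[:, j], ref, atol=1e-8)


def test_lda_1d_threshold_at_midpoint():
    """Equal covariances and priors in 1-D put the boundary at the mean midpoint."""
    base = np.array([-1.0, -0.5, 0.5, 1.0])
    X = np.concatenate([base, base + 5.0])[:, None]
    y = np.asarray(["normal"] * 4 + ["tumor"] * 4)
    model = fit_discriminant(X, y, kind="linear")
    mid = 2.5
    eps = 1e-6
    assert predict_discriminant(model, np.array([[mid - eps]]))[0] == "normal"
    assert predict_discriminant(model, np.array([[mid + eps]]))[0] == "tumor"
    d = discriminant_scores(model, np.array([[mid]]))
    assert d[0, 0] == pytest.approx(d[0, 1], abs=1e-8)


def test_linear_boundary_is_affine(rng):
    """For LDA the score difference is an affine function of x."""
    X, y = _two_class_data(rng, n=30)
    model = fit_discriminant(X, y, kind="linear")
    probes = rng.normal(size=(40, 3)) * 3.0
    diff = discriminant_scores(model, probes)[:, 1] - discriminant_scores(model, probes)[:, 0]
    # fit an affine model to the difference; residuals must vanish
    A = np.hstack([probes, np.ones((40, 1))])
    coef, *_ = np.linalg.lstsq(A, diff, rcond=None)
    np.testing.assert_allclose(A @ coef, diff, atol=1e-8)


def test_qda_approaches_lda_with_shared_covariance(rng):
    """Same data relabeled symmetrically: per-class covariances nearly equal,
    so quadratic and linear predictions agree on almost every probe."""
    shared = rng.normal(size=(400, 2))
    X = np.vstack([shared + [3.0, 0.0], shared[::-1] - [3.0, 0.0]])
    y = np.asarray(["tumor"] * 400 + ["normal"] * 400)
    lda = fit_discriminant(X, y, kind="linear")
    qda = fit_discriminant(X, y, kind="quadratic")
    probes = rng.normal(size=(1000, 2)) * 3.0
    agreement = np.mean(predict_discriminant(lda, probes) == predict_discriminant(qda, probes))
    assert agreement >= 0.99


def test_both_kinds_perfect_on_separable_toy(rng):
    X, y = _two_class_data(rng, n=20, delta=8.0)
    for kind in ("linear", "quadratic"):
        model = fit_discriminant(X, y, kind=kind)
        assert np.all(predict_discriminant(model, X) == y)


def test_predicting_class_mean_recovers_class(rng):
    X, y = _two_class_data(rng, n=25, delta=6.0)
    model = fit_discriminant(X, y, kind="quadratic")
    for j, c in enumerate(model.classes):
        assert predict_discriminant(model, model.class_means[j][None, :])[0] == c


def test_sklearn_discriminant_cross_check(rng):
    """Predictions agree with scikit-learn's LDA/QDA on generic data."""
    sk = pytest.importorskip("sklearn.discriminant_analysis")
    X, y = _two_class_data(rng, n=50, delta=1.0)
    probes = rng.normal(size=(200, 3)) * 2.0 + 1.0
    lda = fit_discriminant(X, y, kind="linear", ridge=0.0)
    ref = sk.LinearDiscriminantAnalysis().fit(X, y)
    assert np.mean(predict_discriminant(lda, probes) == ref.predict(probes)) == 1.0
    qda = fit_discriminant(X, y, kind="quadratic", ridge=0.0)
    refq = sk.QuadraticDiscriminantAnalysis(reg_param=0.0).fit(X, y)
    assert np.mean(predict_discriminant(qda, probes) == refq.predict(probes)) == 1.0


def test_duplicated_classes_degenerate(rng):
    X0 = rng.normal(size=(10, 2))
    X = np.vstack([X0, X0])
    y = np.asarray(["normal"] * 10 + ["tumor"] * 10)
    with pytest.raises(DegenerateInputError):
        fit_discriminant(X, y, kind="linear")


def test_singular_covariance_needs_ridge(rng):
    X = np.zeros((12, 3))
    X[:, 0] = rng.normal(size=12)  # two dead features -> singular covariance
    y = np.asarray(["normal"] * 6 + ["tumor"] * 6)
    X[6:, 0] += 5.0
    with pytest.raises(DegenerateInputError, match="ridge"):
        fit_discriminant(X, y, kind="quadratic", ridge=0.0)
    model = fit_discriminant(X, y, kind="quadratic")  # default ridge handles it
    assert np.all(np.isfinite(discriminant_scores(model, X)))


def test_tie_breaks_lexicographically():
    model = DiscriminantModel(
        kind="linear",
        classes=["normal", "tumor"],
        class_means=np.array([[0.0], [0.0]]),
        class_covariances=np.array([[[1.0]], [[1.0]]]),
        class_priors=np.array([0.5, 0.5]),
        ridge=0.0,
    )
    assert predict_discriminant(model, np.array([[0.7]]))[0] == "normal"


# ---------------------------------------------------------------------------
# Fusion and serialization
# ---------------------------------------------------------------------------

def test_fuse_concatenates_and_aligns(rng):
    ids = [f"P{i}:{c}" for i in range(3) for c in ("normal", "tumor")]
    labels = np.asarray([c for _ in range(3) for c in ("normal", "tumor")])
    a = FeatureMatrix(rng.normal(size=(6, 2)), labels, ids, "raman")
    perm = rng.permutation(6)
    b_vals = rng.normal(size=(6, 2))
    b = FeatureMatrix(b_vals[perm], labels[perm], [ids[i] for i in perm], "velscope")
    fused = fuse_features(a, b)
    assert fused.values.shape == (6, 4)
    assert fused.modality == "fused"
    assert fused.sample_ids == ids
    np.testing.assert_allclose(fused.values[:, :2], a.values)
    np.testing.assert_allclose(fused.values[:, 2:], b_vals)  # realigned to a's order


def test_fuse_with_itself_duplicates_columns(rng):
    a = _fm(rng.normal(size=(5, 2)), labels=["normal", "tumor"] * 2 + ["normal"])
    fused = fuse_features(a, a)
    assert fused.values.shape == (5, 4)
    np.testing.assert_allclose(fused.values[:, :2], fused.values[:, 2:])


def test_fuse_mismatched_ids_rejected(rng):
    a = _fm(rng.normal(size=(3, 2)), ids=["A", "B", "C"])
    b = _fm(rng.normal(size=(3, 2)), ids=["A", "B", "D"])
    with pytest.raises(AlignmentError, match="D"):
        fuse_features(a, b)


def test_model_serialization_round_trip(tmp_path, rng):
    X, y = _two_class_data(rng)
    fm = _fm(X, labels=y)
    pca = fit_pca(fm, k=2)
    save_model(pca, tmp_path / "pca.json")
    back = load_model(tmp_path / "pca.json")
    assert isinstance(back, PcaModel)
    np.testing.assert_allclose(back.loadings, pca.loadings)
    clf = fit_discriminant(X, y, kind="quadratic")
    save_model(clf, tmp_path / "clf.json")
    clf2 = load_model(tmp_path / "clf.json")
    probes = rng.normal(size=(10, 3))
    np.testing.assert_allclose(
        discriminant_scores(clf2, probes), discriminant_scores(clf, probes), atol=1e-12
    )
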