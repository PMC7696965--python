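"""Dimension reduction and discriminant classification, from scratch.

PCA is a mean-centered singular value decomposition with a deterministic sign
convention; LDA and QDA are Gaussian discriminants (pooled vs per-class
covariance) scored as full log joint densities log N(x; mu_c, Sigma_c) +
log prior_c.  Feature-level fusion concatenates the leading principal-
component scores of the two modalities (PC1-PC2 of Raman with PC1-PC2 of the
autofluorescence features) into one four-column matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateInputError,
    DimensionMismatchError,
    InvalidSpecError,
)

__all__ = [
    "FeatureMatrix",
    "PcaModel",
    "DiscriminantModel",
    "feature_matrix_from_frame",
    "fit_pca",
    "transform_pca",
    "max_components",
    "fit_discriminant",
    "discriminant_scores",
    "predict_discriminant",
    "fuse_features",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FeatureMatrix:
    """Samples x features with class labels, sample ids and a modality tag."""

    values: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    modality: str = "raman"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.values.shape[0] != self.labels.size or self.values.shape[0] != len(self.sample_ids):
            raise InvalidSpecError("values, labels and sample_ids disagree on sample count")
        if not np.all(np.isfinite(self.values)):
            raise InvalidSpecError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx],
            self.labels[idx],
            [self.sample_ids[i] for i in np.atleast_1d(idx)],
            self.modality,
        )

    def class_sizes(self) -> dict[str, int]:
        classes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))


def feature_matrix_from_frame(
    df: pd.DataFrame, feature_columns: list[str] | None = None, modality: str = "raman"
) -> FeatureMatrix:
    """Build a FeatureMatrix from a sample-indexed table (as produced by the
    preprocessing/quantification modules)."""
    if feature_columns is None:
        feature_columns = [
            c for c in df.columns if c not in ("patient_id", "tissue_class", "n_pixels")
        ]
    return FeatureMatrix(
        values=df[feature_columns].to_numpy(dtype=float),
        labels=df["tissue_class"].to_numpy(),
        sample_ids=list(df.index),
        modality=modality,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Mean vector, orthonormal loadings (n_features x k) and variance ratios."""

    mean_vector: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    def to_json(self) -> dict:
        return {
            "type": "pca",
            "mean_vector": self.mean_vector.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }

    @classmethod
    def from_json(cls, data: dict) -> "PcaModel":
        return cls(
            np.asarray(data["mean_vector"], dtype=float),
            np.asarray(data["loadings"], dtype=float),
            np.asarray(data["explained_variance_ratio"], dtype=float),
        )


def fit_pca(X: FeatureMatrix, k: int) -> PcaModel:
    """Mean-centered SVD with components ordered by decreasing variance.

    Sign convention: each loading column is flipped so its largest-magnitude
    entry is positive, making the decomposition deterministic.
    """
    n, p = X.values.shape
    if k < 1 or k > min(n - 1, p):
        raise InvalidSpecError(f"k={k} must satisfy 1 <= k <= min(n_samples-1, n_features) = {min(n - 1, p)}")
    mean = X.values.mean(axis=0)
    centered = X.values - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise DegenerateInputError("all samples identical: zero total variance")
    loadings = vt[:k].T.copy()
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
    ratio = (s[:k] ** 2) / total
    return PcaModel(mean_vector=mean, loadings=loadings, explained_variance_ratio=ratio)


def transform_pca(model: PcaModel, X: FeatureMatrix) -> FeatureMatrix:
    """Project onto the fitted components: scores = (X - mean) @ loadings."""
    if X.n_features != model.mean_vector.size:
        raise DimensionMismatchError(
            f"model expects {model.mean_vector.size} features, got {X.n_features}"
        )
    scores = (X.values - model.mean_vector) @ model.loadings
    return FeatureMatrix(scores, X.labels, list(X.sample_ids), X.modality)


def max_components(class_sizes: list[int]) -> int:
    """Largest component count strictly below half the smallest class size.

    This is the overfitting guard used when choosing how many principal
    components may feed a discriminant: e.g. two classes of 35 allow 17.
    """
    sizes = list(class_sizes)
    if not sizes or any(s < 2 for s in sizes):
        raise InvalidSpecError("every class must have at least 2 samples")
    return (min(sizes) - 1) // 2


# ---------------------------------------------------------------------------
# Discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantModel:
    """Gaussian discriminant: 'linear' (pooled covariance) or 'quadratic'."""

    kind: str
    classes: list[str]
    class_means: np.ndarray  # (K, p)
    class_covariances: np.ndarray  # (K, p, p); identical copies when linear
    class_priors: np.ndarray  # (K,)
    ridge: float
    _chol: np.ndarray | None = field(default=None, repr=False)

    def to_json(self) -> dict:
        return {
            "type": "discriminant",
            "kind": self.kind,
            "classes": list(self.classes),
            "class_means": self.class_means.tolist(),
            "class_covariances": self.class_covariances.tolist(),
            "class_priors": self.class_priors.tolist(),
            "ridge": self.ridge,
        }

    @classmethod
    def from_json(cls, data: dict) -> "DiscriminantModel":
        return cls(
            kind=data["kind"],
            classes=list(data["classes"]),
            class_means=np.asarray(data["class_means"], dtype=float),
            class_covariances=np.asarray(data["class_covariances"], dtype=float),
            class_priors=np.asarray(data["class_priors"], dtype=float),
            ridge=float(data["ridge"]),
        )


def _cholesky_factors(model: DiscriminantModel) -> np.ndarray:
    if model._chol is None:
        try:
            model._chol = np.linalg.cholesky(model.class_covariances)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInputError(
                "class covariance is not positive definite; increase the ridge"
            ) from exc
    return model._chol


def fit_discriminant(
    X: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    kind: str = "linear",
    ridge: float | None = None,
) -> DiscriminantModel:
    """Fit an LDA ('linear', pooled within-class covariance) or QDA
    ('quadratic', one covariance per class) model.

    ``ridge`` is added to every covariance diagonal; the default is
    1e-8 x mean diagonal, enough to stabilize near-singular 4-D covariances
    estimated from a few dozen samples.  Passing ridge=0 with a singular
    covariance raises an error recommending a positive ridge.
    """
    if isinstance(X, FeatureMatrix):
        values, y = X.values, X.labels
    else:
        values = np.atleast_2d(np.asarray(X, dtype=float))
        if labels is None:
            raise InvalidSpecError("labels are required when X is a plain array")
        y = np.asarray(labels)
    if kind not in ("linear", "quadratic"):
        raise InvalidSpecError("kind must be 'linear' or 'quadratic'")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise DegenerateInputError("need at least two classes")
    n, p = values.shape
    means, covs, priors, scatters = [], [], [], []
    for c in classes:
        xc = values[y == c]
        if xc.shape[0] < 2:
            raise InvalidSpecError(f"class {c!r} has fewer than 2 samples")
        mu = xc.mean(axis=0)
        centered = xc - mu
        means.append(mu)
        scatters.append(centered.T @ centered)
        covs.append(scatters[-1] / (xc.shape[0] - 1))
        priors.append(xc.shape[0] / n)
    means = np.asarray(means)
    if len(classes) == 2 and np.allclose(means[0], means[1], rtol=0.0, atol=1e-12) and np.allclose(
        covs[0], covs[1], rtol=0.0, atol=1e-12
    ):
        raise DegenerateInputError(
            "the two classes are statistically identical (equal means and covariances)"
        )

    if kind == "linear":
        pooled = np.sum(scatters, axis=0) / (n - len(classes))
        cov_stack = np.repeat(pooled[None, :, :], len(classes), axis=0)
    else:
        cov_stack = np.asarray(covs)

    mean_diag = float(np.mean([np.trace(c) / p for c in cov_stack]))
    eff_ridge = 1e-8 * mean_diag if ridge is None else float(ridge)
    cov_stack = cov_stack + eff_ridge * np.eye(p)[None, :, :]

    model = DiscriminantModel(
        kind=kind,
        classes=classes,
        class_means=means,
        class_covariances=cov_stack,
        class_priors=np.asarray(priors),
        ridge=eff_ridge,
    )
    try:
        _cholesky_factors(model)
    except DegenerateInputError:
        raise DegenerateInputError(
            "singular class covariance; refit with a positive ridge (e.g. 1e-6)"
        ) from None
    return model


def discriminant_scores(model: DiscriminantModel, X: np.ndarray | FeatureMatrix) -> np.ndarray:
    """Per-class log joint density log N(x; mu_c, Sigma_c) + log prior_c, (n, K)."""
    values = X.values if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    p = model.class_means.shape[1]
    if values.shape[1] != p:
        raise DimensionMismatchError(f"model expects {p} features, got {values.shape[1]}")
    chol = _cholesky_factors(model)
    scores = np.empty((values.shape[0], len(model.classes)))
    for j, (mu, L, prior) in enumerate(zip(model.class_means, chol, model.class_priors)):
        diff = (values - mu).T
        sol = np.linalg.solve(L, diff)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        scores[:, j] = -0.5 * (p * _LOG2PI + logdet + maha) + np.log(prior)
    return scores


def predict_discriminant(model: DiscriminantModel, X: np.ndarray | FeatureMatrix) -> np.ndarray:
    """Argmax class per sample; ties resolve to the lexicographically first class."""
    scores = discriminant_scores(model, X)
    idx = np.argmax(scores, axis=1)  # classes are sorted, argmax takes the first max
    return np.asarray([model.classes[i] for i in idx])


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def fuse_features(
    raman_scores: FeatureMatrix,
    velscope_scores: FeatureMatrix,
    *,
    standardize: bool = False,
) -> FeatureMatrix:
    """Column-concatenate two per-modality score matrices aligned by sample id.

    The second matrix is reordered to the first one's sample order; unmatched
    ids on either side raise an AlignmentError naming them.  With the default
    two components per modality the result is the four-feature fused matrix.
    ``standardize`` z-scores each column first (sensitivity analysis only).
    """
    ids_a, ids_b = list(raman_scores.sample_ids), list(velscope_scores.sample_ids)
    missing_in_b = [i for i in ids_a if i not in set(ids_b)]
    missing_in_a = [i for i in ids_b if i not in set(ids_a)]
    if missing_in_a or missing_in_b:
        raise AlignmentError(
            f"sample ids do not match across modalities; only in first: {missing_in_b}; "
            f"only in second: {missing_in_a}"
        )
    order = [ids_b.index(i) for i in ids_a]
    b = velscope_scores.subset(np.asarray(order))
    if not np.array_equal(raman_scores.labels, b.labels):
        raise AlignmentError("labels disagree between modalities after alignment")

    left, right = raman_scores.values, b.values
    if standardize:
        def _z(m: np.ndarray) -> np.ndarray:
            sd = m.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            return (m - m.mean(axis=0)) / sd

        left, right = _z(left), _z(right)
    return FeatureMatrix(
        np.hstack([left, right]), raman_scores.labels, ids_a, modality="fused"
    )


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def save_model(model: PcaModel | DiscriminantModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_json(), indent=1))


def load_model(path: str | Path) -> PcaModel | DiscriminantModel:
    data = json.loads(Path(path).read_text())
    if data.get("type") == "pca":
        return PcaModel.from_json(data)
    if data.get("type") == "discriminant":
        return DiscriminantModel.from_json(data)
    raise InvalidSpecError(f"unrecognized model file {path}")
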