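"""One-class anomaly scoring over peptide feature matrices.

All scorers share one contract: fit on positive-only data, emit a raw
per-sample anomaly score with *higher = more anomalous* (native OCSVM and
isolation-forest scores are negated to enforce this), then min-max normalize
over the scored set to [0, 1] so models are comparable, and finally label
outliers above a percentile threshold (default 95th).

Models:

- ``ocsvm``: one-class SVM; raw score = negated decision-function value
  (signed distance from the learned boundary).
- ``iforest``: isolation forest; raw score = negated native ``score_samples``.
- ``autoencoder``: compressive MLP trained to reproduce its input
  (mean-squared-error objective, 50 epochs by default); raw score =
  per-sample mean squared reconstruction error.
- ``pca``: raw score = squared residual after projecting onto the retained
  principal components.

:class:`AnomalyPipeline` bundles standardization, optional PCA reduction and
a scorer behind a single fit/score surface, serializable to one file.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest
from sklearn.neural_network import MLPRegressor
from sklearn.svm import OneClassSVM

from .features import FeatureMatrix

MODEL_NAMES = ("autoencoder", "ocsvm", "iforest", "pca")


class AnomalyError(ValueError):
    """Invalid model configuration or input."""


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature z-scoring with population (ddof=0) statistics.

    Features with standard deviation below 1e-12 on the training data are
    mapped to exactly 0 after transformation (never a division by zero).
    """

    feature_names: list[str]
    mean_: np.ndarray
    scale_: np.ndarray
    constant_mask_: np.ndarray

    @classmethod
    def fit(cls, train: FeatureMatrix) -> "Standardizer":
        if len(train.sample_ids) < 2:
            raise AnomalyError("standardizer needs at least 2 training samples")
        mean = train.values.mean(axis=0)
        sd = train.values.std(axis=0)
        constant = sd < 1e-12
        if constant.any():
            import logging

            logging.getLogger(__name__).info(
                "standardizer: %d constant feature(s) mapped to 0", constant.sum()
            )
        scale = np.where(constant, 1.0, sd)
        return cls(list(train.feature_names), mean, scale, constant)

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if matrix.feature_names != self.feature_names:
            raise AnomalyError("feature names do not match the fitted standardizer")
        z = (matrix.values - self.mean_) / self.scale_
        z[:, self.constant_mask_] = 0.0
        return FeatureMatrix(matrix.sample_ids, matrix.feature_names, z)


def fit_standardizer(train: FeatureMatrix) -> Standardizer:
    return Standardizer.fit(train)


def apply_standardizer(s: Standardizer, matrix: FeatureMatrix) -> FeatureMatrix:
    return s.transform(matrix)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Thin wrapper around a fitted sklearn PCA on standardized features."""

    pca: PCA
    feature_names: list[str]

    @property
    def n_components(self) -> int:
        return self.pca.n_components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, matrix: FeatureMatrix) -> np.ndarray:
        self._check(matrix)
        return self.pca.transform(matrix.values)

    def _check(self, matrix: FeatureMatrix) -> None:
        if matrix.feature_names != self.feature_names:
            raise AnomalyError("feature names do not match the fitted PCA")


def fit_pca(matrix: FeatureMatrix, k_or_variance: int | float = 0.95) -> PCAModel:
    """PCA on a standardized matrix.

    ``k_or_variance``: an integer retains exactly k components; a fraction in
    (0, 1) retains the smallest number of components reaching that explained
    variance. Components come ranked by decreasing eigenvalue.
    """
    n, p = matrix.shape
    if n < 2:
        raise AnomalyError("PCA needs at least 2 samples")
    max_k = min(n - 1, p)
    if isinstance(k_or_variance, (int, np.integer)):
        if not 1 <= k_or_variance <= max_k:
            raise AnomalyError(
                f"k must be in [1, {max_k}] for a {n}x{p} matrix, got {k_or_variance}"
            )
        n_components = int(k_or_variance)
    else:
        if not 0 < k_or_variance < 1:
            raise AnomalyError("variance fraction must be in (0, 1)")
        n_components = float(k_or_variance)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    pca.fit(matrix.values)
    return PCAModel(pca, list(matrix.feature_names))


def pca_reconstruction_error(model: PCAModel, matrix: FeatureMatrix) -> np.ndarray:
    """Per-sample squared reconstruction error through the retained components."""
    model._check(matrix)
    recon = model.pca.inverse_transform(model.pca.transform(matrix.values))
    return ((matrix.values - recon) ** 2).sum(axis=1)


# ---------------------------------------------------------------------------
# score containers
# ---------------------------------------------------------------------------

def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Min-max scale raw scores to [0, 1]; a constant vector maps to all zeros."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise AnomalyError("cannot normalize an empty score vector")
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-300:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


@dataclass
class AnomalyScoreSet:
    """Raw + min-max-normalized anomaly scores from one model (higher = more
    anomalous for every model)."""

    model_name: str
    sample_ids: list[str]
    raw: np.ndarray

    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise AnomalyError(f"unknown model name {self.model_name!r}")
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != len(self.sample_ids):
            raise AnomalyError("score vector length does not match sample ids")
        self.normalized = normalize_scores(self.raw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "model": self.model_name,
                "raw_score": self.raw,
                "normalized_score": self.normalized,
            }
        )


@dataclass
class ThresholdedResult:
    """Normalized scores + percentile threshold + inlier(+1)/outlier(-1) labels.

    A sample is an outlier iff its normalized score is strictly greater than
    the threshold (outliers above the boundary, inliers at or below it).
    """

    scores: AnomalyScoreSet
    percentile: float
    threshold: float
    labels: np.ndarray

    @property
    def outlier_fraction(self) -> float:
        return float((self.labels == -1).mean())

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.to_frame()
        df["threshold"] = self.threshold
        df["label"] = self.labels
        return df


def percentile_threshold(
    scores: AnomalyScoreSet, percentile: float = 95.0
) -> ThresholdedResult:
    """Label outliers above the given percentile of the normalized scores.

    The threshold is the linear-interpolation percentile (numpy's default
    definition) of the scored set itself.
    """
    if not 0 < percentile < 100:
        raise AnomalyError(f"percentile must be in (0, 100), got {percentile}")
    n = len(scores.sample_ids)
    if n == 0:
        raise AnomalyError("cannot threshold an empty score set")
    if n < 20:
        warnings.warn(
            f"percentile {percentile} on only {n} samples is poorly resolved",
            stacklevel=2,
        )
    threshold = float(np.percentile(scores.normalized, percentile))
    labels = np.where(scores.normalized > threshold, -1, 1)
    return ThresholdedResult(scores, percentile, threshold, labels)


@dataclass(frozen=True)
class ScoreSummary:
    """Mean / median / percentile threshold / flagged-percentage of a score set."""

    model_name: str
    n: int
    mean: float
    median: float
    percentile: float
    threshold: float
    outlier_pct: float


def summarize_scores(scores: AnomalyScoreSet, percentile: float = 95.0) -> ScoreSummary:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = percentile_threshold(scores, percentile)
    return ScoreSummary(
        model_name=scores.model_name,
        n=len(scores.sample_ids),
        mean=float(scores.normalized.mean()),
        median=float(np.median(scores.normalized)),
        percentile=percentile,
        threshold=res.threshold,
        outlier_pct=100.0 * res.outlier_fraction,
    )


# ---------------------------------------------------------------------------
# scorers
# ---------------------------------------------------------------------------

def fit_score_ocsvm(
    train: FeatureMatrix, kernel: str = "rbf", nu: float = 0.05, gamma="scale"
) -> tuple[OneClassSVM, AnomalyScoreSet]:
    """Fit a one-class SVM and score the training set.

    Raw anomaly score is the *negated* decision-function value, so samples far
    outside the learned boundary get the largest scores.
    """
    if kernel not in ("linear", "rbf"):
        raise AnomalyError(f"kernel must be 'linear' or 'rbf', got {kernel!r}")
    if len(train.sample_ids) < 2:
        raise AnomalyError("need at least 2 training samples")
    model = OneClassSVM(kernel=kernel, nu=nu, gamma=gamma)
    model.fit(train.values)
    raw = -model.decision_function(train.values)
    return model, AnomalyScoreSet("ocsvm", train.sample_ids, raw)


def fit_score_iforest(
    train: FeatureMatrix,
    n_trees: int = 100,
    contamination="auto",
    seed: int = 0,
) -> tuple[IsolationForest, AnomalyScoreSet]:
    """Fit an isolation forest and score the training set.

    Raw anomaly score is the negated native ``score_samples`` (isolation
    depth), so quickly isolated samples score highest. Seeded and reproducible.
    """
    if n_trees < 1:
        raise AnomalyError(f"n_trees must be >= 1, got {n_trees}")
    if len(train.sample_ids) < 2:
        raise AnomalyError("need at least 2 training samples")
    model = IsolationForest(
        n_estimators=n_trees, contamination=contamination, random_state=seed
    )
    model.fit(train.values)
    raw = -model.score_samples(train.values)
    return model, AnomalyScoreSet("iforest", train.sample_ids, raw)


@dataclass
class AutoencoderModel:
    """A compressive MLP trained input -> input with an MSE objective.

    Default architecture is the symmetric stack
    ``p -> ceil(p/2) -> ceil(p/4) -> ceil(p/2) -> p`` with ReLU hidden
    activations; the bottleneck must be narrower than the input.
    """

    net: MLPRegressor
    feature_names: list[str]
    widths: tuple[int, ...]
    epochs: int
    seed: int

    @property
    def loss_curve(self) -> list[float]:
        return list(self.net.loss_curve_)


def default_autoencoder_widths(p: int) -> tuple[int, ...]:
    return (math.ceil(p / 2), math.ceil(p / 4), math.ceil(p / 2))


def fit_autoencoder(
    train: FeatureMatrix,
    widths: tuple[int, ...] | None = None,
    epochs: int = 50,
    seed: int = 0,
) -> AutoencoderModel:
    n, p = train.shape
    if n < 2:
        raise AnomalyError("need at least 2 training samples")
    widths = tuple(widths) if widths is not None else default_autoencoder_widths(p)
    if min(widths) >= p:
        raise AnomalyError(
            f"bottleneck width {min(widths)} must be < input width {p}"
        )
    net = MLPRegressor(
        hidden_layer_sizes=widths,
        activation="relu",
        solver="adam",
        max_iter=epochs,
        shuffle=True,
        random_state=seed,
        tol=1e-12,
        n_iter_no_change=max(epochs, 10),
        batch_size=min(200, n),
    )
    with warnings.catch_warnings():
        # the epoch budget is the stopping rule, not convergence
        warnings.simplefilter("ignore")
        net.fit(train.values, train.values)
    return AutoencoderModel(net, list(train.feature_names), widths, epochs, seed)


def score_autoencoder(model: AutoencoderModel, matrix: FeatureMatrix) -> AnomalyScoreSet:
    """Per-sample mean squared reconstruction error through the trained net."""
    if matrix.feature_names != model.feature_names:
        raise AnomalyError("feature names do not match the fitted autoencoder")
    recon = model.net.predict(matrix.values)
    raw = ((matrix.values - recon) ** 2).mean(axis=1)
    return AnomalyScoreSet("autoencoder", matrix.sample_ids, raw)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnomalyPipeline:
    """standardize -> (optional PCA) -> one-class scorer, as one object.

    ``pca_components``: None disables reduction; an int retains k components;
    a fraction in (0, 1) retains the smallest k reaching that explained
    variance; the default ``"auto"`` retains the smaller of the 95%-variance
    count and ceil(sqrt(n)). The cap keeps the representation genuinely
    compressive when samples are few relative to features — with n close to
    p the 95%-variance rule retains nearly every direction, reconstructs
    anomalies as faithfully as inliers, and washes out reconstruction-based
    scores.
    """

    model: str = "autoencoder"
    pca_components: int | float | str | None = "auto"
    seed: int = 0
    params: dict = field(default_factory=dict)

    standardizer_: Standardizer | None = None
    pca_: PCAModel | None = None
    scorer_: object = None

    def _reduce(self, matrix: FeatureMatrix) -> FeatureMatrix:
        z = self.standardizer_.transform(matrix)
        if self.pca_ is None:
            return z
        scores = self.pca_.transform(z)
        return FeatureMatrix(
            z.sample_ids, [f"PC{i + 1}" for i in range(scores.shape[1])], scores
        )

    def _resolve_components(self, z: FeatureMatrix) -> int | float:
        if self.pca_components != "auto":
            return self.pca_components
        n, p = z.shape
        k95 = fit_pca(z, 0.95).n_components
        return max(1, min(k95, math.ceil(math.sqrt(n)), n - 1, p))

    def fit(self, train: FeatureMatrix) -> "AnomalyPipeline":
        if self.model not in MODEL_NAMES:
            raise AnomalyError(f"unknown model {self.model!r}")
        self.standardizer_ = Standardizer.fit(train)
        z = self.standardizer_.transform(train)
        if self.pca_components is not None and self.model != "pca":
            self.pca_ = fit_pca(z, self._resolve_components(z))
        reduced = self._reduce(train)
        if self.model == "ocsvm":
            self.scorer_, _ = fit_score_ocsvm(reduced, **self.params)
        elif self.model == "iforest":
            self.scorer_, _ = fit_score_iforest(reduced, seed=self.seed, **self.params)
        elif self.model == "autoencoder":
            self.scorer_ = fit_autoencoder(reduced, seed=self.seed, **self.params)
        else:  # pca reconstruction-error scorer on the standardized matrix
            self.scorer_ = fit_pca(z, self._resolve_components(z))
        return self

    def raw_scores(self, matrix: FeatureMatrix) -> np.ndarray:
        if self.standardizer_ is None:
            raise AnomalyError("pipeline is not fitted")
        if self.model == "pca":
            z = self.standardizer_.transform(matrix)
            return pca_reconstruction_error(self.scorer_, z)
        reduced = self._reduce(matrix)
        if self.model == "ocsvm":
            return -self.scorer_.decision_function(reduced.values)
        if self.model == "iforest":
            return -self.scorer_.score_samples(reduced.values)
        return score_autoencoder(self.scorer_, reduced).raw

    def score(self, matrix: FeatureMatrix) -> AnomalyScoreSet:
        return AnomalyScoreSet(self.model, matrix.sample_ids, self.raw_scores(matrix))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "AnomalyPipeline":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise AnomalyError(f"{path} does not contain a fitted AnomalyPipeline")
        return obj
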