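"""Feature attribution and the DPAS ranking.

DPAS (disease peptide anomaly score) fuses two per-sample terms on a common
[0, 1] scale:

    DPAS = alpha * normalized_anomaly_score + beta * importance_term

``alpha`` and ``beta`` are user weights (default 0.5 each). The importance
term is a per-sample summary of model-agnostic feature attributions: for each
feature, the mean absolute change in the model's raw anomaly score when that
feature is replaced by values permuted from the background (a SHAP-style
perturbation argument with a permutation estimator). The per-sample term
averages |attribution| over the top-k globally important features (default
k=3) and is min-max normalized across samples so both DPAS terms are
commensurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anomaly import normalize_scores
from .features import FeatureMatrix
from .seqio import PeptideSet


class RankingError(ValueError):
    """Invalid ranking/attribution input."""


@dataclass
class AttributionMatrix:
    """Per-sample, per-feature absolute-perturbation attributions."""

    sample_ids: list[str]
    feature_names: list[str]
    attributions: np.ndarray

    def __post_init__(self) -> None:
        self.attributions = np.asarray(self.attributions, dtype=float)
        if self.attributions.shape != (len(self.sample_ids), len(self.feature_names)):
            raise RankingError("attribution shape inconsistent with id lists")

    def global_importance(self) -> pd.Series:
        """Per-feature mean of absolute attributions across samples."""
        return pd.Series(
            np.abs(self.attributions).mean(axis=0), index=self.feature_names
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.attributions,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_names,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "AttributionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def feature_importance(
    pipeline, matrix: FeatureMatrix, n_perm: int = 5, seed: int = 0
) -> AttributionMatrix:
    """Permutation-based, model-agnostic attribution.

    For each feature, ``n_perm`` times, the column is replaced by a random
    permutation of itself (the scored set acts as the background
    distribution) and the model is re-scored; the attribution of feature j for
    sample i is the mean absolute change of sample i's raw anomaly score. A
    feature the model ignores — or one constant across the background — gets
    attribution 0. Seeded and deterministic.

    ``pipeline`` is anything exposing ``raw_scores(FeatureMatrix) ->
    np.ndarray`` (e.g. a fitted :class:`dpas.anomaly.AnomalyPipeline`).
    """
    if n_perm < 1:
        raise RankingError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    base = np.asarray(pipeline.raw_scores(matrix), dtype=float)
    n, p = matrix.shape
    attr = np.zeros((n, p))
    for j in range(p):
        col = matrix.values[:, j]
        if np.ptp(col) < 1e-300:  # constant in the background: no perturbation
            continue
        for _ in range(n_perm):
            perturbed = matrix.values.copy()
            perturbed[:, j] = rng.permutation(col)
            scores = pipeline.raw_scores(
                FeatureMatrix(matrix.sample_ids, matrix.feature_names, perturbed)
            )
            attr[:, j] += np.abs(np.asarray(scores) - base)
    attr /= n_perm
    return AttributionMatrix(list(matrix.sample_ids), list(matrix.feature_names), attr)


def top_k_features(global_importance: pd.Series, k: int = 3) -> list[str]:
    """The k most important feature names, decreasing importance, ties broken
    by feature-name order."""
    if k < 1:
        raise RankingError(f"k must be >= 1, got {k}")
    if k > len(global_importance):
        raise RankingError(
            f"k={k} exceeds the {len(global_importance)} available features"
        )
    order = sorted(
        global_importance.items(), key=lambda item: (-item[1], item[0])
    )
    return [name for name, _ in order[:k]]


def importance_term(attr: AttributionMatrix, features: list[str]) -> np.ndarray:
    """Per-sample mean |attribution| over the selected features, min-max
    normalized across samples to [0, 1]."""
    if not features:
        raise RankingError("feature list must be non-empty")
    missing = [f for f in features if f not in attr.feature_names]
    if missing:
        raise RankingError(f"unknown feature(s): {', '.join(missing)}")
    idx = [attr.feature_names.index(f) for f in features]
    per_sample = np.abs(attr.attributions[:, idx]).mean(axis=1)
    return normalize_scores(per_sample)


@dataclass(frozen=True)
class DPASWeights:
    """User weights for the two DPAS terms; at least one must be positive."""

    alpha: float = 0.5
    beta: float = 0.5
    top_k: int = 3

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise RankingError("alpha and beta must be >= 0")
        if self.alpha + self.beta <= 0:
            raise RankingError("alpha + beta must be > 0")
        if self.top_k < 1:
            raise RankingError("top_k must be >= 1")


@dataclass
class DPASRanking:
    """Per-peptide DPAS values with 1-based dense ranks (rank 1 = max DPAS).

    The table is ordered by rank, ties broken lexicographically by sample id.
    """

    table: pd.DataFrame  # sample_id, normalized_error, importance_term, dpas, rank

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DPASRanking":
        return cls(pd.read_csv(path, sep="\t"))


def dpas_score(
    sample_ids: list[str],
    normalized_error: np.ndarray,
    importance: np.ndarray,
    weights: DPASWeights = DPASWeights(),
) -> DPASRanking:
    """Compute DPAS = alpha*error + beta*importance and rank peptides.

    Dense ranking by decreasing DPAS (equal scores share a rank); row order is
    (rank, sample_id) so output is deterministic under ties.
    """
    normalized_error = np.asarray(normalized_error, dtype=float)
    importance = np.asarray(importance, dtype=float)
    if not (len(sample_ids) == len(normalized_error) == len(importance)):
        raise RankingError("sample ids and term vectors must have equal length")
    dpas = weights.alpha * normalized_error + weights.beta * importance
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "normalized_error": normalized_error,
            "importance_term": importance,
            "dpas": dpas,
        }
    )
    df["rank"] = df["dpas"].rank(method="dense", ascending=False).astype(int)
    df = df.sort_values(["rank", "sample_id"], kind="stable").reset_index(drop=True)
    return DPASRanking(df)


def select_top(ranking: DPASRanking, n: int, pset: PeptideSet) -> PeptideSet:
    """The n top-ranked peptides as a FASTA-exportable set, in rank order."""
    total = len(ranking.table)
    if not 1 <= n <= total:
        raise RankingError(f"n must be in [1, {total}], got {n}")
    top_ids = list(ranking.table["sample_id"].iloc[:n])
    return pset.subset(top_ids)
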