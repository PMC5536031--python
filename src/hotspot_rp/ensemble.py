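"""Random-projection classifier ensemble: train, rank, select, vote.

Training protocol, per candidate projection (K candidates in total):

1. generate a seeded random projection of the encoded instances to
   ``target_dim`` coordinates;
2. split the projected training data into an inner training subset and
   an inner validation subset (stratified; the validation share is
   1/n_folds);
3. rebalance the inner training subset to a 1:1 class ratio and fit the
   k-NN base learner on it;
4. score the fitted learner by F1 on the untouched (unbalanced) inner
   validation subset.

The K candidates are ranked by validation F1 (ties broken by projection
seed) and the top N are retained. At prediction time each retained
member projects the queries with its own matrix and votes; a residue is
called a hotspot when at least half the members — ``ceil(N/2)`` votes —
say so.

Selection F1 is computed on the unbalanced validation subset because a
rebalanced validation set would inflate every candidate's score by the
same prevalence factor and blur the ranking. An undefined validation F1
(no true or predicted positives) ranks as 0.

The outer evaluation loop is 10-fold cross-validation, stratified by
label by default: at <2% prevalence unstratified folds can easily lack
positives entirely.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .classifier import KnnModel, fit_knn, rebalance
from .errors import ConfigError, DegenerateInputError, DimensionError
from .evaluation import ConfusionCounts, MetricSet, confusion, metrics
from .projection import ProjectionMatrix, make_projection, project
from .seeds import derive_seed


@dataclass(frozen=True)
class EnsembleConfig:
    """Tunable parameters of the ensemble system.

    ``n_projections`` (K) candidate projections are trained and the
    ``top_n`` (N) best by validation F1 are kept. ``target_dim`` (L2) is
    the reduced dimension. ``n_folds`` controls both the outer
    cross-validation and the inner validation share (1/n_folds).
    """

    n_projections: int = 100
    top_n: int = 3
    target_dim: int = 5
    k: int = 1
    n_folds: int = 10
    master_seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        if self.n_projections < 1:
            raise ConfigError("n_projections must be >= 1")
        if not 1 <= self.top_n <= self.n_projections:
            raise ConfigError(
                f"top_n={self.top_n} must be between 1 and n_projections="
                f"{self.n_projections}"
            )
        if self.target_dim < 1:
            raise ConfigError("target_dim must be >= 1")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")


@dataclass(frozen=True)
class RankedMember:
    """One retained ensemble member."""

    projection: ProjectionMatrix
    model: KnnModel
    train_f1: float
    rank: int  # 1-based


@dataclass(frozen=True)
class EnsembleModel:
    """Top-N members plus the majority-vote rule (positive at >= half)."""

    members: tuple
    config: EnsembleConfig

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def votes_needed(self) -> int:
        return math.ceil(self.n_members / 2)


@dataclass(frozen=True)
class EvaluationResult:
    """Predictions aligned to the evaluated instances, plus pooled metrics."""

    labels: np.ndarray = field(repr=False)
    fractions: np.ndarray = field(repr=False)
    confusion: ConfusionCounts
    metrics: MetricSet
    folds: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def assign_folds(y: np.ndarray, n_folds: int, seed: int, stratify: bool = True) -> np.ndarray:
    """Deterministic fold assignment, one fold id per instance.

    Folds partition the data with sizes differing by at most one. With
    ``stratify=True`` instances are dealt round-robin within each class,
    so per-fold class counts also differ by at most one.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n_folds > n:
        raise ConfigError(f"n_folds={n_folds} exceeds instance count {n}")
    rng = np.random.default_rng(seed)
    if stratify:
        order = np.concatenate(
            [rng.permutation(np.flatnonzero(y == cls)) for cls in (1, 0)]
        )
    else:
        order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % n_folds
    return folds


def _inner_split(y: np.ndarray, n_folds: int, seed: int):
    """Stratified holdout: ~1/n_folds of each class for validation."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in (1, 0):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_val = max(1, round(len(idx) / n_folds)) if len(idx) else 0
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def train_ensemble(X: np.ndarray, y: np.ndarray, config: EnsembleConfig) -> EnsembleModel:
    """Train K projection/k-NN candidates, keep the top N by validation F1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise DimensionError("X and y row counts differ")
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("training data must contain both classes")
    l1 = X.shape[1]
    candidates = []
    for j in range(config.n_projections):
        proj = make_projection(l1, config.target_dim,
                               derive_seed(config.master_seed, "projection", j))
        Xp = project(X, proj)
        tr_idx, val_idx = _inner_split(
            y, config.n_folds, derive_seed(config.master_seed, "inner_split", j)
        )
        Xb, yb = rebalance(Xp[tr_idx], y[tr_idx],
                           derive_seed(config.master_seed, "resample", j))
        model = fit_knn(Xb, yb, k=min(config.k, len(yb)))
        val_labels, _ = model.predict(Xp[val_idx])
        val_f1 = metrics(confusion(y[val_idx], val_labels)).f1
        if math.isnan(val_f1):
            val_f1 = 0.0
        candidates.append((val_f1, proj.seed, proj, model))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    members = tuple(
        RankedMember(projection=proj, model=model, train_f1=f1, rank=i + 1)
        for i, (f1, _, proj, model) in enumerate(candidates[: config.top_n])
    )
    return EnsembleModel(members=members, config=config)


def predict_ensemble(model: EnsembleModel, X: np.ndarray):
    """Majority vote of the retained members over instance rows of *X*.

    Returns ``(labels, fractions)``; a row is labeled 1 when at least
    ``ceil(N/2)`` members vote positive, and ``fractions`` is
    votes / N.
    """
    if model.n_members == 0:
        raise ConfigError("empty ensemble")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError("queries must form a 2-D matrix")
    votes = np.zeros(X.shape[0], dtype=int)
    for member in model.members:
        member_labels, _ = member.model.predict(project(X, member.projection))
        votes += member_labels
    labels = (votes >= model.votes_needed).astype(int)
    return labels, votes / model.n_members


def cross_validate(X: np.ndarray, y: np.ndarray, config: EnsembleConfig) -> EvaluationResult:
    """Outer k-fold cross-validation of the full train/select/vote protocol.

    Each fold's ensemble is trained on the remaining folds and predicts
    the held-out fold once; confusion counts are pooled over folds.
    Folds without positives are evaluated anyway, with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = assign_folds(y, config.n_folds,
                         derive_seed(config.master_seed, "folds"), config.stratify)
    labels = np.empty(len(y), dtype=int)
    fractions = np.empty(len(y), dtype=float)
    for f in range(config.n_folds):
        test_mask = folds == f
        if y[test_mask].sum() == 0:
            warnings.warn(f"fold {f} contains no positive instances", stacklevel=2)
        ens = train_ensemble(X[~test_mask], y[~test_mask], config)
        labels[test_mask], fractions[test_mask] = predict_ensemble(ens, X[test_mask])
    counts = confusion(y, labels)
    return EvaluationResult(labels=labels, fractions=fractions,
                            confusion=counts, metrics=metrics(counts), folds=folds)


def transfer(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    config: EnsembleConfig,
):
    """Train on one corpus and evaluate on a disjoint one.

    Mirrors cross-corpus evaluation (e.g. train on one curated hotspot
    set, test on another). Returns ``(EnsembleModel, EvaluationResult)``.
    """
    if np.asarray(train_X).shape[1] != np.asarray(test_X).shape[1]:
        raise DimensionError("train and test instance widths differ")
    model = train_ensemble(train_X, train_y, config)
    labels, fractions = predict_ensemble(model, test_X)
    counts = confusion(test_y, labels)
    return model, EvaluationResult(labels=labels, fractions=fractions,
                                   confusion=counts, metrics=metrics(counts))


def with_seed(config: EnsembleConfig, master_seed: int) -> EnsembleConfig:
    """Copy of *config* with a different master seed."""
    return replace(config, master_seed=master_seed)
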