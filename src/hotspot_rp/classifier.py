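"""Instance-based (IBk-style) k-nearest-neighbour base learner.

Hotspots make up under 2% of whole-sequence residues, so each base
learner is trained on a class-balanced undersample: every minority-class
instance is kept and an equal number of majority-class instances is
drawn uniformly without replacement. Undersampling (rather than
oversampling) avoids duplicated coordinates, which would degenerate
nearest-neighbour votes.

Prediction is exact k-NN under Euclidean distance. Distance ties at the
k-th neighbour expand the vote set to all tied instances, making the
decision independent of storage order; vote ties go to the negative
(non-hotspot) class, the conservative call at this prevalence.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError, DegenerateInputError, DimensionError


def rebalance(X: np.ndarray, y: np.ndarray, seed: int):
    """Balanced undersampling to a 1:1 class ratio.

    Keeps every instance of the minority class and draws an equal number
    of the majority class uniformly without replacement; the combined
    set is then shuffled deterministically by *seed*. Returns ``(X, y)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise DimensionError("X and y row counts differ")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError("rebalance requires both classes present")
    rng = np.random.default_rng(seed)
    if len(pos) <= len(neg):
        keep_minority, majority = pos, neg
    else:
        keep_minority, majority = neg, pos
    drawn = rng.choice(majority, size=len(keep_minority), replace=False)
    idx = np.concatenate([keep_minority, drawn])
    idx = idx[rng.permutation(len(idx))]
    return X[idx], y[idx]


class KnnModel:
    """Exact k-nearest-neighbour classifier with lazy fitting.

    Fitting only stores the instances; all distance computation is
    deferred to :meth:`predict`.
    """

    def __init__(self, k: int = 1):
        if k < 1:
            raise ConfigError(f"k must be >= 1, got {k}")
        self.k = int(k)
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KnnModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise DimensionError("training instances must form a 2-D matrix")
        if X.shape[0] != y.shape[0]:
            raise DimensionError("X and y row counts differ")
        if self.k > X.shape[0]:
            raise ConfigError(f"k={self.k} exceeds number of stored instances {X.shape[0]}")
        self._X = X
        self._y = y
        return self

    @property
    def n_stored(self) -> int:
        if self._X is None:
            raise ConfigError("model is not fitted")
        return self._X.shape[0]

    def predict(self, queries: np.ndarray):
        """Majority vote over the k nearest stored instances.

        Returns ``(labels, fractions)`` where ``fractions`` is the share
        of positive labels among the (tie-expanded) neighbour set.
        """
        if self._X is None or self._y is None:
            raise ConfigError("model is not fitted")
        Q = np.asarray(queries, dtype=float)
        one_dim = Q.ndim == 1
        if one_dim:
            Q = Q[np.newaxis, :]
        if Q.shape[1] != self._X.shape[1]:
            raise DimensionError(
                f"query width {Q.shape[1]} != stored width {self._X.shape[1]}"
            )
        D = cdist(Q, self._X)
        kth = np.partition(D, self.k - 1, axis=1)[:, self.k - 1]
        # include every instance tied with the k-th distance
        mask = D <= kth[:, np.newaxis]
        counts = mask.sum(axis=1)
        positives = mask.astype(int) @ (self._y == 1).astype(int)
        labels = (2 * positives > counts).astype(int)  # vote tie -> 0
        fractions = positives / counts
        if one_dim:
            return int(labels[0]), float(fractions[0])
        return labels, fractions


def fit_knn(X: np.ndarray, y: np.ndarray, k: int = 1) -> KnnModel:
    """Convenience constructor: store *X*, *y* in a :class:`KnnModel`."""
    return KnnModel(k=k).fit(X, y)
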