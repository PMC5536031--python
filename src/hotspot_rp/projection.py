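"""Random projection of encoded instances.

Dimensionality reduction is a plain matrix product ``X_R = X R`` with a
random matrix ``R`` of shape (L1, L2), L2 <= L1. Raw entries are drawn
i.i.d. Uniform[0, 1) and each column is then scaled to unit Euclidean
norm, so each reduced coordinate is the inner product of the instance
with a random non-negative unit direction. Random mappings of this kind
approximately preserve the geometry of high-dimensional data, which is
what makes nearest-neighbour classification in the reduced space
meaningful.

A projection is fully described by (l1, l2, seed): matrices are
regenerated from the seed rather than persisted densely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DimensionError


@dataclass(frozen=True)
class ProjectionMatrix:
    """A seeded column-unit-norm random matrix."""

    entries: np.ndarray = field(repr=False)
    seed: int
    l1: int
    l2: int


def make_projection(l1: int, l2: int, seed: int) -> ProjectionMatrix:
    """Generate the (l1, l2) random projection for *seed*.

    Entries ~ Uniform[0, 1) from ``numpy.random.default_rng(seed)``,
    columns normalized to unit Euclidean length. Deterministic in the
    seed.
    """
    if l2 < 1:
        raise ConfigError(f"target dimension must be >= 1, got {l2}")
    if l1 < 1:
        raise ConfigError(f"source dimension must be >= 1, got {l1}")
    if l2 > l1:
        raise DimensionError(f"target dimension {l2} exceeds source dimension {l1}")
    rng = np.random.default_rng(seed)
    entries = rng.random((l1, l2))
    norms = np.linalg.norm(entries, axis=0)
    while (norms == 0.0).any():  # measure-zero; redrawn for robustness
        zero = norms == 0.0
        entries[:, zero] = rng.random((l1, int(zero.sum())))
        norms = np.linalg.norm(entries, axis=0)
    entries = entries / norms
    return ProjectionMatrix(entries=entries, seed=int(seed), l1=l1, l2=l2)


def project(X: np.ndarray, proj: ProjectionMatrix) -> np.ndarray:
    """Apply the projection: rows of *X* are mapped to length-l2 rows."""
    X = np.asarray(X, dtype=float)
    one_dim = X.ndim == 1
    if one_dim:
        X = X[np.newaxis, :]
    if X.ndim != 2 or X.shape[1] != proj.l1:
        raise DimensionError(
            f"instance width {X.shape[-1] if X.ndim else '?'} != projection "
            f"source dimension {proj.l1}"
        )
    out = X @ proj.entries
    return out[0] if one_dim else out
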