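"""Deterministic seed derivation.

One master seed reproduces a whole experiment: every consumer of
randomness (projection matrices, inner train/validation splits, class
rebalancing, fold assignment, synthetic corpora, the random-predictor
baseline) derives its own stream from the master seed, a role tag and an
index via ``numpy.random.SeedSequence``. Derived seeds are kept below
2**31 so they remain valid inputs everywhere an ``int`` seed is accepted.
"""

from __future__ import annotations

import numpy as np

_ROLES = {
    "projection": 1,
    "inner_split": 2,
    "resample": 3,
    "folds": 4,
    "synthetic": 5,
    "random_predictor": 6,
    "sweep": 7,
    "transfer": 8,
}


def derive_seed(master_seed: int, role: str, index: int = 0) -> int:
    """Derive a stable sub-seed for *role* / *index* from *master_seed*."""
    if role not in _ROLES:
        raise KeyError(f"unknown seed role: {role!r}")
    ss = np.random.SeedSequence([int(master_seed), _ROLES[role], int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
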