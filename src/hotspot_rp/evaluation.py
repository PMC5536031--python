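"""Evaluation: confusion counts, Sen/Prec/F1/MCC, baselines, sweeps.

Metrics over a 2x2 confusion table::

    Sen  = TP / (TP + FN)
    Prec = TP / (TP + FP)
    F1   = 2 * Prec * Sen / (Prec + Sen)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

A metric whose denominator is zero is reported as NaN (an explicit
"undefined" marker) rather than silently coerced to 0 — with one
conventional exception: MCC with a zero denominator is 0, the value of
an uninformative predictor.

The random-predictor baseline labels every residue positive with a
fixed probability, independently of the truth; repeated runs are
averaged metric-by-metric. For any truth-independent predictor the
expected precision equals the hotspot prevalence and the expected MCC
is zero, which is what makes it the natural floor for whole-sequence
hotspot prediction at <2% prevalence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DimensionError
from .seeds import derive_seed

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sen/Prec/F1/MCC; NaN marks an undefined (0/0) metric."""

    sen: float
    prec: float
    f1: float
    mcc: float

    def as_dict(self) -> dict:
        return {"sen": self.sen, "prec": self.prec, "f1": self.f1, "mcc": self.mcc}


def confusion(truth, predicted) -> ConfusionCounts:
    """Count the four confusion cells for 0/1 truth and prediction lists."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise DimensionError(f"truth length {t.shape} != prediction length {p.shape}")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def f1_from(sen: float, prec: float) -> float:
    """Harmonic mean of sensitivity and precision (NaN if undefined)."""
    if math.isnan(sen) or math.isnan(prec) or sen + prec == 0:
        return UNDEFINED
    return 2.0 * prec * sen / (prec + sen)


def metrics(c: ConfusionCounts) -> MetricSet:
    """All four metrics from confusion counts; total over all count values."""
    sen = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else UNDEFINED
    prec = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else UNDEFINED
    f1 = f1_from(sen, prec)
    # exact integer arithmetic in the numerator/denominator before the sqrt
    denom2 = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)
    return MetricSet(sen=sen, prec=prec, f1=f1, mcc=mcc)


def random_predictor(truth, positive_rate: float, n_runs: int = 100, seed: int = 0) -> MetricSet:
    """Average metrics of a truth-independent Bernoulli predictor.

    Each run labels every instance positive with probability
    *positive_rate*; metrics are computed per run and averaged across
    runs (an undefined metric in any run propagates as NaN).
    """
    if not 0.0 < positive_rate <= 1.0:
        raise ConfigError(f"positive_rate must be in (0, 1], got {positive_rate}")
    t = np.asarray(truth, dtype=int)
    rng = np.random.default_rng(seed)
    per_run = np.empty((n_runs, 4))
    for r in range(n_runs):
        predicted = (rng.random(len(t)) < positive_rate).astype(int)
        m = metrics(confusion(t, predicted))
        per_run[r] = (m.sen, m.prec, m.f1, m.mcc)
    means = per_run.mean(axis=0)
    return MetricSet(sen=float(means[0]), prec=float(means[1]),
                     f1=float(means[2]), mcc=float(means[3]))


def sweep(
    sequences: Sequence,
    props,
    config,
    target_dims: Sequence[int] | None = None,
    window_lengths: Sequence[int] | None = None,
    repeats: int = 1,
) -> pd.DataFrame:
    """Cross-validated metrics over a grid of reduced dimensions and windows.

    Each grid cell runs the full encode/train/vote protocol *repeats*
    times with master seeds derived from the shared config seed, and
    reports per-cell mean metrics plus the standard deviation of F1
    across repeats (the error bar of a window/dimension sweep). Returns
    a tidy DataFrame.
    """
    from dataclasses import replace

    from .encoding import DEFAULT_WINDOW_LENGTH, encode_dataset  # avoids cycle at load
    from .ensemble import cross_validate, with_seed

    dims = list(target_dims) if target_dims is not None else [config.target_dim]
    windows = list(window_lengths) if window_lengths is not None else [DEFAULT_WINDOW_LENGTH]
    if not dims or not windows or repeats < 1:
        raise ConfigError("sweep grid and repeats must be non-empty")

    encoded_cache: dict = {}
    rows = []
    for win_eff, dim in itertools.product(windows, dims):
        if win_eff not in encoded_cache:
            encoded_cache[win_eff] = encode_dataset(sequences, props, win_eff)
        dataset = encoded_cache[win_eff]
        f1s, sets = [], []
        for r in range(repeats):
            cfg = replace(
                with_seed(config, derive_seed(config.master_seed, "sweep", r)),
                target_dim=dim,
            )
            result = cross_validate(dataset.X, dataset.y, cfg)
            sets.append(result.metrics)
            f1s.append(result.metrics.f1)
        rows.append(
            {
                "window_length": win_eff,
                "target_dim": dim,
                "sen": float(np.mean([m.sen for m in sets])),
                "prec": float(np.mean([m.prec for m in sets])),
                "f1": float(np.mean(f1s)),
                "mcc": float(np.mean([m.mcc for m in sets])),
                "f1_std": float(np.std(f1s)),
                "n_repeats": repeats,
            }
        )
    return pd.DataFrame(rows)


def metrics_to_json_dict(m: MetricSet, counts: ConfusionCounts | None = None) -> dict:
    """JSON-safe dict (NaN -> None) for metric reports."""
    out: dict = {
        k: (None if isinstance(v, float) and math.isnan(v) else v)
        for k, v in m.as_dict().items()
    }
    if counts is not None:
        out.update(tp=counts.tp, fp=counts.fp, tn=counts.tn, fn=counts.fn)
    return out
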