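"""Physicochemical feature encoding of residues.

For residue *i* with substitution-frequency profile ``SP_i`` (a
20-vector) and an amino-acid property ``AAP_j`` (also a 20-vector), the
elementwise product ``MSK_ij = SP_i * AAP_j`` describes how the property
is distributed over the residue's evolutionary substitution spectrum.
Its spread — the standard deviation ``STD_ij`` over the 20 products —
summarizes the evolutionary variance of that property at that position.
Stacking over all J properties gives a J-vector per residue; a sliding
window of length ``winLen`` centered on the residue concatenates the
J-vectors of the neighbours, yielding a ``winLen × J`` feature vector
(7072 when winLen = 13 and J = 544).

The standard deviation is the population form (divisor 20): the 20
products are the complete set of outcomes, not a sample. Window
positions that fall outside the sequence contribute an all-zero J-block,
which keeps the dimension constant and marks missing context without
inventing signal. No standardization is applied before projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError, DimensionError
from .io_formats import LabeledSequence, PropertyTable, ResidueProfile

DEFAULT_WINDOW_LENGTH = 13


def residue_features(profile, props: PropertyTable) -> np.ndarray:
    """Per-property spread of the profile-weighted property values.

    *profile* may be a :class:`ResidueProfile` or a bare 20-vector.
    Returns a length-J vector of population standard deviations, one per
    property, each taken over the 20 elementwise products of the profile
    with that property's values.
    """
    freqs = profile.freqs if isinstance(profile, ResidueProfile) else np.asarray(profile, float)
    if freqs.shape != (20,):
        raise DimensionError(f"profile must have 20 entries, got {freqs.shape}")
    if props.n_properties == 0:
        raise DimensionError("empty property table")
    products = props.matrix * freqs[np.newaxis, :]  # (J, 20)
    return products.std(axis=1)  # population form, ddof=0


def feature_matrix(profile_rows: np.ndarray, props: PropertyTable) -> np.ndarray:
    """Vectorized :func:`residue_features` for an (L, 20) profile stack."""
    profile_rows = np.asarray(profile_rows, dtype=float)
    if profile_rows.ndim != 2 or profile_rows.shape[1] != 20:
        raise DimensionError(f"profile stack must be (L, 20), got {profile_rows.shape}")
    # (L, J, 20) product tensor; std over the amino-acid axis.
    products = profile_rows[:, np.newaxis, :] * props.matrix[np.newaxis, :, :]
    return products.std(axis=2)


@dataclass(frozen=True)
class EncodedInstance:
    """One residue's windowed feature vector with its hotspot target."""

    vector: np.ndarray = field(repr=False)
    target: int
    origin: tuple  # (sequence id, 1-based position)


@dataclass
class EncodedDataset:
    """Dense instance matrix for a corpus, one row per residue."""

    X: np.ndarray
    y: np.ndarray
    origins: list  # [(sequence id, 1-based position), ...]
    wild_types: list
    window_length: int
    n_properties: int

    def __post_init__(self):
        if self.X.shape[0] != len(self.y) or len(self.y) != len(self.origins):
            raise DimensionError("X/y/origins row counts differ")
        if self.X.shape[1] != self.window_length * self.n_properties:
            raise DimensionError(
                f"width {self.X.shape[1]} != window_length*n_properties "
                f"({self.window_length}*{self.n_properties})"
            )

    def __len__(self) -> int:
        return self.X.shape[0]


def _check_window(window_length: int) -> int:
    if window_length < 1 or window_length % 2 == 0:
        raise ConfigError(f"window length must be a positive odd integer, got {window_length}")
    return (window_length - 1) // 2


def _windowed(features: np.ndarray, window_length: int) -> np.ndarray:
    """Stack zero-padded windows: (L, J) -> (L, window_length*J)."""
    half = _check_window(window_length)
    L, J = features.shape
    padded = np.zeros((L + 2 * half, J))
    padded[half:half + L] = features
    # (L, J, winLen) view -> (L, winLen, J) -> flat rows ordered
    # [offset -half ... +half], each a contiguous J-block.
    view = np.lib.stride_tricks.sliding_window_view(padded, window_length, axis=0)
    return np.ascontiguousarray(view.transpose(0, 2, 1)).reshape(L, window_length * J)


def encode_window(
    seq: LabeledSequence,
    position: int,
    props: PropertyTable,
    window_length: int = DEFAULT_WINDOW_LENGTH,
) -> EncodedInstance:
    """Encode one residue (1-based *position*) of *seq*.

    Window offsets outside the sequence contribute a zero J-block.
    """
    half = _check_window(window_length)
    if not 1 <= position <= len(seq):
        raise DataError(f"position {position} outside sequence {seq.id!r}")
    J = props.n_properties
    blocks = []
    for offset in range(-half, half + 1):
        pos = position + offset
        if 1 <= pos <= len(seq):
            blocks.append(residue_features(seq.profiles[pos - 1], props))
        else:
            blocks.append(np.zeros(J))
    return EncodedInstance(
        vector=np.concatenate(blocks),
        target=int(seq.labels[position - 1]),
        origin=(seq.id, position),
    )


def encode_dataset(
    sequences: Sequence[LabeledSequence],
    props: PropertyTable,
    window_length: int = DEFAULT_WINDOW_LENGTH,
) -> EncodedDataset:
    """Encode every residue of every sequence (one instance per residue).

    Per-residue features are computed once per sequence and shared
    across the windows that reuse them.
    """
    _check_window(window_length)
    J = props.n_properties
    rows, targets, origins, wild_types = [], [], [], []
    for seq in sequences:
        features = feature_matrix(seq.profile_matrix, props)
        rows.append(_windowed(features, window_length))
        targets.append(seq.labels)
        origins.extend((seq.id, i + 1) for i in range(len(seq)))
        wild_types.extend(seq.residues)
    if rows:
        X = np.vstack(rows)
        y = np.concatenate(targets)
    else:
        X = np.empty((0, window_length * J))
        y = np.empty(0, dtype=int)
    return EncodedDataset(
        X=X, y=y.astype(int), origins=origins, wild_types=wild_types,
        window_length=window_length, n_properties=J,
    )


# ---------------------------------------------------------------------------
# dense TSV dump (CLI plumbing)
# ---------------------------------------------------------------------------

def write_features(dataset: EncodedDataset, path) -> None:
    """Dump an encoded dataset as dense TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"#window_length={dataset.window_length}\n")
        fh.write(f"#n_properties={dataset.n_properties}\n")
        cols = "\t".join(f"f{i:06d}" for i in range(dataset.X.shape[1]))
        fh.write(f"sequence_id\tposition\twild_type\ttarget\t{cols}\n")
        for row, target, (seq_id, pos), wt in zip(
            dataset.X, dataset.y, dataset.origins, dataset.wild_types
        ):
            vals = "\t".join(format(v, ".10g") for v in row)
            fh.write(f"{seq_id}\t{pos}\t{wt}\t{int(target)}\t{vals}\n")


def read_features(path) -> EncodedDataset:
    """Read back a :func:`write_features` dump."""
    window_length = n_properties = None
    origins, wild_types, targets, rows = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "window_length":
                    window_length = int(value)
                elif key == "n_properties":
                    n_properties = int(value)
                continue
            if line.startswith("sequence_id\t") or not line:
                continue
            parts = line.split("\t")
            origins.append((parts[0], int(parts[1])))
            wild_types.append(parts[2])
            targets.append(int(parts[3]))
            rows.append([float(v) for v in parts[4:]])
    if window_length is None or n_properties is None:
        raise DataError(f"{path}: missing provenance header")
    X = np.asarray(rows, dtype=float)
    if X.size == 0:
        X = X.reshape(0, window_length * n_properties)
    return EncodedDataset(
        X=X, y=np.asarray(targets, dtype=int), origins=origins,
        wild_types=wild_types, window_length=window_length,
        n_properties=n_properties,
    )
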