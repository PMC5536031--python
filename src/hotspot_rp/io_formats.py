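"""Readers and writers for the external file formats.

Formats handled here:

* **AAindex1 flat file** — one record per amino-acid index: an ``H``
  accession line, free-text annotation lines, and an ``I`` block holding
  the 20 per-residue values in the canonical two-row layout
  (``A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V``), records closed by
  ``//``. Missing cells are written ``NA``.
* **FASTA** — protein sequences, via Biopython.
* **PSI-BLAST ASCII PSSM** — per-residue rows with a position, the
  wild-type letter, 20 log-odds columns and 20 percentage columns (two
  trailing per-row statistics columns are tolerated). Only the
  percentage block is used: it holds the weighted observed substitution
  frequencies that the feature encoding is built on.
* **labels TSV** — ``sequence_id <TAB> position <TAB> label`` with
  1-based positions; unlisted positions are non-hotspots (label 0),
  matching the whole-sequence convention where every residue outside the
  annotated hotspot set is a negative.
* **predictions TSV** — one row per residue with the ensemble vote
  fraction and the predicted label.

Positions are 1-based in every file format and in the dataclasses below;
array indexing inside the package is 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, FormatError, ParseError

#: Canonical amino-acid order used for every 20-vector in the package.
#: This is the PSI-BLAST PSSM column order; the AAindex1 two-row layout
#: (A R N D C Q E G H I / L K M F P S T W Y V) concatenates to the same
#: order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_TO_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_PROFILE_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AminoAcidIndex:
    """One AAindex1 record: a property value per standard amino acid.

    ``values`` follows :data:`AMINO_ACIDS` order; ``None`` marks a
    missing cell (``NA`` in the flat file).
    """

    accession: str
    description: str
    values: tuple

    def __post_init__(self):
        if len(self.values) != 20:
            raise FormatError(
                f"{self.accession}: expected 20 values, got {len(self.values)}"
            )
        if all(v is None for v in self.values):
            raise FormatError(f"{self.accession}: all 20 values missing")

    @property
    def is_complete(self) -> bool:
        return all(v is not None for v in self.values)

    def value_for(self, amino_acid: str):
        return self.values[AA_TO_INDEX[amino_acid]]


@dataclass(frozen=True)
class PropertyTable:
    """Ordered collection of complete amino-acid indices.

    ``matrix`` has shape (J, 20): one row per property, columns in
    canonical amino-acid order. Records are accession-sorted so the
    column layout of downstream feature vectors is deterministic.
    """

    indices: tuple
    matrix: np.ndarray = field(repr=False)

    @classmethod
    def from_indices(cls, records: Iterable[AminoAcidIndex]) -> "PropertyTable":
        """Apply the missing-value policy (drop incomplete records) and sort."""
        usable = sorted(
            (r for r in records if r.is_complete), key=lambda r: r.accession
        )
        matrix = np.array([[float(v) for v in r.values] for r in usable], dtype=float)
        matrix = matrix.reshape(len(usable), 20)
        return cls(indices=tuple(usable), matrix=matrix)

    @property
    def n_properties(self) -> int:
        return len(self.indices)

    @property
    def accessions(self) -> tuple:
        return tuple(r.accession for r in self.indices)


@dataclass(frozen=True)
class ResidueProfile:
    """Substitution-frequency 20-vector for one sequence position.

    ``position`` is 1-based; ``freqs`` is non-negative and sums to 1.
    """

    position: int
    wild_type: str
    freqs: np.ndarray = field(repr=False)

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (20,):
            raise FormatError(f"profile at position {self.position}: need 20 freqs")
        if (freqs < 0).any():
            raise FormatError(f"profile at position {self.position}: negative freq")
        if not math.isclose(float(freqs.sum()), 1.0, abs_tol=_PROFILE_TOL):
            raise FormatError(
                f"profile at position {self.position}: freqs sum to {freqs.sum()}"
            )
        object.__setattr__(self, "freqs", freqs)


@dataclass
class LabeledSequence:
    """A protein sequence with per-residue profiles and hotspot labels."""

    id: str
    residues: str
    profiles: list
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.profiles) == len(self.residues) == len(self.labels)):
            raise DataError(
                f"{self.id}: residues/profiles/labels lengths differ "
                f"({len(self.residues)}/{len(self.profiles)}/{len(self.labels)})"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def profile_matrix(self) -> np.ndarray:
        """(L, 20) array of substitution frequencies, canonical column order."""
        return np.vstack([p.freqs for p in self.profiles])


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted residue: identity, ensemble vote fraction, label."""

    sequence_id: str
    position: int
    wild_type: str
    vote_fraction: float
    label: int


@dataclass(frozen=True)
class LabelSummary:
    """Hotspot composition of a corpus."""

    n_hotspots: int
    n_non_hotspots: int

    @property
    def total(self) -> int:
        return self.n_hotspots + self.n_non_hotspots

    @property
    def ratio_percent(self) -> float:
        """Hotspot share of all residues, in percent."""
        return 100.0 * self.n_hotspots / self.total


# ---------------------------------------------------------------------------
# AAindex1
# ---------------------------------------------------------------------------

def _parse_aaindex_record(block: str) -> AminoAcidIndex:
    accession = ""
    description_lines = []
    value_cells: list = []
    in_i = False
    for line in block.splitlines():
        if line.startswith("H "):
            accession = line[2:].strip()
            in_i = False
        elif line.startswith("D "):
            description_lines.append(line[2:].strip())
            in_i = False
        elif line.startswith("I "):
            in_i = True
        elif in_i and (line.startswith(" ") or line.startswith("\t")):
            value_cells.extend(line.split())
        else:
            in_i = False
    if not accession:
        raise ParseError("AAindex1 record without an H accession line")
    if len(value_cells) != 20:
        raise ParseError(
            f"{accession}: I block has {len(value_cells)} cells, expected 20"
        )
    values = []
    for cell in value_cells:
        if cell in ("NA", "na", "-"):
            values.append(None)
        else:
            try:
                values.append(float(cell))
            except ValueError as exc:
                raise ParseError(f"{accession}: unparsable I-block cell {cell!r}") from exc
    return AminoAcidIndex(accession=accession, description=" ".join(description_lines),
                          values=tuple(values))


def read_aaindex1_records(path) -> list:
    """Parse every record of an AAindex1 flat file, missing values included."""
    text = Path(path).read_text()
    blocks = [b.strip("\n") for b in text.split("//")]
    records = []
    for block in blocks:
        if block.strip():
            records.append(_parse_aaindex_record(block))
    if not records:
        raise FormatError(f"{path}: no AAindex1 records found")
    return records


def read_aaindex1(path) -> PropertyTable:
    """Read an AAindex1 flat file into a :class:`PropertyTable`.

    Records containing any missing (``NA``) cell are dropped, so the
    number of usable properties J is determined by the input file.
    """
    return PropertyTable.from_indices(read_aaindex1_records(path))


def write_aaindex1(records: Iterable[AminoAcidIndex], path) -> None:
    """Serialize records in the AAindex1 flat-file layout (round-trips)."""
    lines = []
    for rec in records:
        lines.append(f"H {rec.accession}")
        if rec.description:
            lines.append(f"D {rec.description}")
        lines.append("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V")
        cells = ["NA" if v is None else format(float(v), ".6g") for v in rec.values]
        lines.append("    " + "  ".join(f"{c:>8s}" for c in cells[:10]))
        lines.append("    " + "  ".join(f"{c:>8s}" for c in cells[10:]))
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    seqs = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

def read_pssm(path) -> list:
    """Read a PSI-BLAST ASCII PSSM into a list of :class:`ResidueProfile`.

    The 20 percentage columns are divided by 100 and renormalized to sum
    to 1. Rows whose percentages are all zero (PSI-BLAST emits these for
    positions with no alignment information) are replaced by the uniform
    1/20 background. Data rows must carry 40 numeric columns after the
    position and wild-type letter; the two trailing per-row statistics
    columns of real PSI-BLAST output are tolerated.
    """
    profiles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 2:
                continue
            try:
                position = int(parts[0])
            except ValueError:
                continue  # header / footer line
            wild_type = parts[1]
            if not (len(wild_type) == 1 and wild_type.isalpha()):
                raise ParseError(f"{path}:{lineno}: bad wild-type field {wild_type!r}")
            numeric = parts[2:]
            if len(numeric) not in (40, 42):
                raise ParseError(
                    f"{path}:{lineno}: expected 40 numeric columns "
                    f"(plus optional 2 trailing), got {len(numeric)}"
                )
            try:
                percentages = np.array([float(x) for x in numeric[20:40]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unparsable numeric cell") from exc
            if (percentages < 0).any():
                raise ParseError(f"{path}:{lineno}: negative percentage")
            total = percentages.sum()
            if total == 0.0:
                freqs = np.full(20, 1.0 / 20.0)
            else:
                freqs = percentages / total
            profiles.append(
                ResidueProfile(position=position, wild_type=wild_type.upper(), freqs=freqs)
            )
    if not profiles:
        raise FormatError(f"{path}: no PSSM data rows found")
    return profiles


def write_pssm(profiles: Sequence[ResidueProfile], path) -> None:
    """Write profiles in the ASCII PSSM dialect :func:`read_pssm` accepts.

    Log-odds columns are written as zeros (they are never consumed);
    percentages carry two decimals so frequencies survive a round trip
    to within renormalization.
    """
    header = (
        "\nLast position-specific scoring matrix computed\n"
        "            " + "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS) + "\n"
    )
    lines = [header.rstrip("\n")]
    for prof in profiles:
        log_odds = " ".join(["0"] * 20)
        pct = " ".join(f"{100.0 * f:.2f}" for f in prof.freqs)
        lines.append(f"{prof.position:5d} {prof.wild_type} {log_odds} {pct}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def read_labels(path, sequence_lengths: Mapping[str, int] | None = None) -> dict:
    """Read a labels TSV into a ``{(sequence_id, position): 0/1}`` map.

    Positions are 1-based. Duplicate rows must agree; conflicting
    duplicates raise :class:`DataError`. When *sequence_lengths* is
    given, positions are bounds-checked against it. An empty file yields
    an empty map (every residue defaults to non-hotspot downstream).
    """
    labels: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            seq_id, pos_s, label_s = parts
            try:
                position = int(pos_s)
                label = int(label_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer position/label") from exc
            if label not in (0, 1):
                raise ParseError(f"{path}:{lineno}: label must be 0 or 1")
            if position < 1:
                raise DataError(f"{path}:{lineno}: position {position} is not 1-based")
            if sequence_lengths is not None:
                if seq_id not in sequence_lengths:
                    raise DataError(f"{path}:{lineno}: unknown sequence {seq_id!r}")
                if position > sequence_lengths[seq_id]:
                    raise DataError(
                        f"{path}:{lineno}: position {position} beyond length "
                        f"{sequence_lengths[seq_id]} of {seq_id!r}"
                    )
            key = (seq_id, position)
            if key in labels and labels[key] != label:
                raise DataError(f"{path}:{lineno}: conflicting duplicate label for {key}")
            labels[key] = label
    return labels


def labels_to_array(labels: Mapping, sequence_id: str, length: int) -> np.ndarray:
    """Expand a label map to a dense per-residue 0/1 array for one sequence."""
    out = np.zeros(length, dtype=int)
    for (seq_id, position), label in labels.items():
        if seq_id == sequence_id:
            if not 1 <= position <= length:
                raise DataError(
                    f"label position {position} outside sequence {sequence_id!r} "
                    f"of length {length}"
                )
            out[position - 1] = label
    return out


def write_labels(sequences: Sequence[LabeledSequence], path) -> None:
    """Write the hotspot rows (label 1) of a corpus as a labels TSV."""
    lines = ["#sequence_id\tposition\tlabel"]
    for seq in sequences:
        for i, label in enumerate(seq.labels):
            if label:
                lines.append(f"{seq.id}\t{i + 1}\t1")
    Path(path).write_text("\n".join(lines) + "\n")


def label_summary(sequences: Sequence[LabeledSequence]) -> LabelSummary:
    """Count hotspots vs non-hotspots over a corpus."""
    n_pos = int(sum(int(seq.labels.sum()) for seq in sequences))
    total = sum(len(seq) for seq in sequences)
    return LabelSummary(n_hotspots=n_pos, n_non_hotspots=total - n_pos)


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

_PRED_HEADER = "sequence_id\tposition\twild_type\tvote_fraction\tlabel"


def write_predictions(records: Iterable[PredictionRecord], path) -> None:
    """Write per-residue predictions as TSV; vote fractions keep 10
    significant digits so a read-back reproduces them."""
    lines = [_PRED_HEADER]
    for rec in records:
        lines.append(
            f"{rec.sequence_id}\t{rec.position}\t{rec.wild_type}\t"
            f"{rec.vote_fraction:.10g}\t{rec.label}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path) -> list:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _PRED_HEADER:
        raise FormatError(f"{path}: missing predictions header")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields")
        records.append(
            PredictionRecord(
                sequence_id=parts[0],
                position=int(parts[1]),
                wild_type=parts[2],
                vote_fraction=float(parts[3]),
                label=int(parts[4]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------

def load_corpus(fasta_path, pssm_dir, labels_path) -> list:
    """Assemble :class:`LabeledSequence` objects from on-disk inputs.

    Expects one ``<sequence_id>.pssm`` file per FASTA record in
    *pssm_dir*; labels come from a labels TSV (unlisted residues are
    non-hotspots).
    """
    sequences = read_fasta(fasta_path)
    lengths = {name: len(seq) for name, seq in sequences.items()}
    labels = read_labels(labels_path, sequence_lengths=lengths)
    pssm_dir = Path(pssm_dir)
    corpus = []
    for name, residues in sequences.items():
        pssm_path = pssm_dir / f"{name}.pssm"
        if not pssm_path.exists():
            raise DataError(f"missing PSSM file for sequence {name!r}: {pssm_path}")
        profiles = read_pssm(pssm_path)
        if len(profiles) != len(residues):
            raise DataError(
                f"{name}: PSSM has {len(profiles)} rows but sequence has "
                f"{len(residues)} residues"
            )
        corpus.append(
            LabeledSequence(
                id=name,
                residues=residues,
                profiles=profiles,
                labels=labels_to_array(labels, name, len(residues)),
            )
        )
    return corpus
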