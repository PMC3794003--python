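"""Reading, validation and writing of labelled protein sequence datasets.

Sequences are plain FASTA.  A training dataset carries one class label per
record, drawn from the two class names used throughout the package
(by default ``acidic`` and ``alkaline``); a prediction dataset carries no
labels.  Validation enforces the 20-letter standard amino-acid alphabet and
an optional minimum sequence length (training conventionally uses 100
residues as the floor, since very short chains carry too little dipeptide
signal to classify reliably).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically ordered one-letter codes.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AMINO_ACIDS)

#: Class names: alkaline is the positive class in every downstream metric.
ACIDIC = "acidic"
ALKALINE = "alkaline"
CLASS_NAMES = (ACIDIC, ALKALINE)

#: Line width used when writing FASTA bodies.
FASTA_LINE_WIDTH = 80


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier, free-text description, residue string."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDataset:
    """An ordered collection of records with optional per-record class labels."""

    records: list[ProteinRecord]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in dataset: {', '.join(dupes)}")
        if self.labels is not None:
            if len(self.labels) != len(self.records):
                raise ValueError(
                    f"{len(self.labels)} labels for {len(self.records)} records"
                )
            bad = sorted(set(self.labels) - set(CLASS_NAMES))
            if bad:
                raise ValueError(f"unknown class labels: {', '.join(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def class_counts(self) -> dict[str, int]:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return {c: self.labels.count(c) for c in CLASS_NAMES}


def _as_text_stream(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def parse_fasta(source: str | Path | IO[str]) -> list[ProteinRecord]:
    """Parse FASTA text into a list of :class:`ProteinRecord`.

    Sequence lines are concatenated, whitespace stripped and residues
    uppercased.  Input order is preserved.

    Parameters
    ----------
    source:
        A path or an open text stream.

    Raises
    ------
    ValueError
        On an empty stream ("no sequences"), sequence data before the first
        header ("malformed FASTA"), or a header with no sequence lines.
    """
    stream = _as_text_stream(source)
    close = isinstance(source, (str, Path))
    try:
        text = stream.read()
        stripped = text.lstrip()
        if stripped and not stripped.startswith(">"):
            raise ValueError("malformed FASTA: sequence data before any header")
        pairs = list(SimpleFastaParser(StringIO(text)))
        if not pairs:
            raise ValueError("no sequences in FASTA input")
        records = []
        for title, seq in pairs:
            parts = title.split(None, 1)
            if not parts:
                raise ValueError("malformed FASTA: empty header line")
            rid = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            seq = "".join(seq.split()).upper()
            if not seq:
                raise ValueError(f"record '{rid}' has no sequence lines")
            records.append(ProteinRecord(id=rid, description=desc, sequence=seq))
        return records
    finally:
        if close:
            stream.close()


def parse_fasta_string(text: str) -> list[ProteinRecord]:
    """Parse FASTA from an in-memory string (convenience wrapper)."""
    return parse_fasta(StringIO(text))


def validate_records(
    records: Sequence[ProteinRecord],
    min_length: int = 1,
    strict: bool = True,
) -> list[ProteinRecord]:
    """Filter records by length and enforce the standard residue alphabet.

    Records shorter than ``min_length`` are removed.  Records containing a
    non-standard residue (anything outside the 20 one-letter codes,
    including ``B, J, O, U, X, Z``, ``*`` and ``-``) raise in strict mode
    and are dropped with a warning otherwise.  Survivors keep input order.

    Raises
    ------
    ValueError
        In strict mode, naming the offending record id and character; or
        when no record survives validation.
    """
    if min_length < 1:
        raise ValueError("min_length must be a positive integer")
    kept: list[ProteinRecord] = []
    for rec in records:
        if len(rec.sequence) < min_length:
            logger.info("dropping %s: length %d < %d", rec.id, len(rec.sequence), min_length)
            continue
        nonstandard = sorted(set(rec.sequence) - _STANDARD_SET)
        if nonstandard:
            if strict:
                raise ValueError(
                    f"record '{rec.id}' contains non-standard residue(s): "
                    f"{', '.join(nonstandard)}"
                )
            logger.warning(
                "dropping %s: non-standard residue(s) %s", rec.id, ", ".join(nonstandard)
            )
            continue
        kept.append(rec)
    if not kept:
        raise ValueError("empty dataset after validation")
    return kept


def write_fasta(records: Iterable[ProteinRecord], sink: str | Path | IO[str]) -> None:
    """Write records as FASTA with sequence lines wrapped at 80 characters.

    The output round-trips through :func:`parse_fasta` to an identical
    record list.
    """
    stream = _as_text_stream(sink) if not isinstance(sink, (str, Path)) else open(sink, "w")
    close = isinstance(sink, (str, Path))
    try:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            stream.write(header + "\n")
            for start in range(0, len(rec.sequence), FASTA_LINE_WIDTH):
                stream.write(rec.sequence[start : start + FASTA_LINE_WIDTH] + "\n")
    finally:
        if close:
            stream.close()


def load_labelled_fastas(
    acidic_path: str | Path,
    alkaline_path: str | Path,
    min_length: int = 1,
    strict: bool = True,
) -> SequenceDataset:
    """Build a labelled dataset from one FASTA file per class."""
    datasets = []
    for path, label in ((acidic_path, ACIDIC), (alkaline_path, ALKALINE)):
        recs = validate_records(parse_fasta(path), min_length=min_length, strict=strict)
        datasets.append((recs, label))
    records = [r for recs, _ in datasets for r in recs]
    labels = [label for recs, label in datasets for _ in recs]
    return SequenceDataset(records=records, labels=labels)


def load_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` file into a mapping."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
            rid, label = parts
            if label not in CLASS_NAMES:
                raise ValueError(f"{path}:{lineno}: unknown label '{label}'")
            if rid in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate id '{rid}'")
            mapping[rid] = label
    if not mapping:
        raise ValueError(f"{path}: no labels found")
    return mapping
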