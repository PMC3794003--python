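"""g-gap dipeptide composition encoding.

A *g-gap dipeptide* is an ordered pair of residues separated by exactly
``g`` intervening residues; ``g = 0`` is an ordinary adjacent dipeptide,
``g = 1`` a pair with one residue between, and so on.  A sequence of length
``L`` contains ``L - g - 1`` such pairs, tallied over the 20 x 20 = 400
ordered residue pairs and normalised to frequencies, so every encoded
sequence is a 400-component composition vector summing to one.

The pair-to-column bijection is fixed for the life of a model: row-major
over the alphabetically sorted standard residues (AA, AC, AD, ..., YY),
first residue major.  It is serialized with trained models so predictions
stay reproducible across versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_io import STANDARD_AMINO_ACIDS, SequenceDataset

N_FEATURES = 400

#: Canonical dipeptide ordering: "AA", "AC", ..., "YY" (first residue major).
DIPEPTIDES: tuple[str, ...] = tuple(
    a + b for a in STANDARD_AMINO_ACIDS for b in STANDARD_AMINO_ACIDS
)

DIPEPTIDE_INDEX: dict[str, int] = {dp: i for i, dp in enumerate(DIPEPTIDES)}

# residue -> 0..19 lookup table over ASCII codes
_CODE = np.full(128, -1, dtype=np.int64)
for _i, _aa in enumerate(STANDARD_AMINO_ACIDS):
    _CODE[ord(_aa)] = _i


def feature_names(gap: int) -> list[str]:
    """Column names such as ``AA.g2`` for exporting feature matrices."""
    return [f"{dp}.g{gap}" for dp in DIPEPTIDES]


def _residue_codes(sequence: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted(set(sequence) - set(STANDARD_AMINO_ACIDS))
        raise ValueError(f"non-standard residue(s) in sequence: {', '.join(bad)}")
    return codes


def count_ggap_dipeptides(sequence: str, gap: int) -> np.ndarray:
    """Count the 400 g-gap dipeptides of a sequence.

    Entry ``lambda`` holds the number of positions ``i`` with the ordered
    pair ``(R_i, R_{i+g+1})`` equal to the ``lambda``-th canonical pair.
    The counts total ``L - g - 1``.

    Raises
    ------
    ValueError
        If ``gap < 0`` or the sequence is shorter than ``gap + 2``.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    L = len(sequence)
    if L < gap + 2:
        raise ValueError(f"sequence too short for gap {gap}: length {L} < {gap + 2}")
    codes = _residue_codes(sequence)
    pair_idx = codes[: L - gap - 1] * 20 + codes[gap + 1 :]
    return np.bincount(pair_idx, minlength=N_FEATURES).astype(np.int64)


def encode_sequence(sequence: str, gap: int) -> np.ndarray:
    """Encode one sequence as 400 g-gap dipeptide frequencies (sums to 1)."""
    counts = count_ggap_dipeptides(sequence, gap)
    return counts / (len(sequence) - gap - 1)


@dataclass
class GGapFeatureMatrix:
    """M x 400 frequency matrix for a fixed gap, with ids and optional labels."""

    gap: int
    values: np.ndarray  # shape (M, 400), float64
    sample_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must have {N_FEATURES} columns")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match matrix rows")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length does not match matrix rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Export as a DataFrame with dipeptide column names and id index."""
        df = pd.DataFrame(
            self.values, columns=feature_names(self.gap), index=pd.Index(self.sample_ids, name="id")
        )
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def encode_dataset(dataset: SequenceDataset, gap: int) -> GGapFeatureMatrix:
    """Encode every record of a dataset at one gap.

    The whole dataset fails (no silent drop) if any sequence is shorter
    than ``gap + 2``; the error lists the offending ids.
    """
    too_short = [r.id for r in dataset.records if len(r.sequence) < gap + 2]
    if too_short:
        raise ValueError(
            f"sequences too short for gap {gap}: {', '.join(too_short)}"
        )
    values = np.empty((len(dataset), N_FEATURES), dtype=np.float64)
    for i, rec in enumerate(dataset.records):
        values[i] = encode_sequence(rec.sequence, gap)
    return GGapFeatureMatrix(
        gap=gap,
        values=values,
        sample_ids=dataset.ids,
        labels=list(dataset.labels) if dataset.labels is not None else None,
    )
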