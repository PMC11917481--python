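"""Aligned-FASTA io and gap-column filtering.

The phylogenetic workflow aligns SLRP protein sequences and removes
alignment columns that are almost entirely gaps before tree inference:
a column is excluded when its gap fraction strictly exceeds the threshold
(default 0.95, i.e. "gaps in more than 95% of the sequences").  Both '-'
and '.' count as gap characters; 'X' is a residue, not a gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

GAP_CHARS = frozenset("-.")


class AlignmentFormatError(ValueError):
    """Raised on ragged rows or duplicate sequence identifiers."""


@dataclass(frozen=True)
class Alignment:
    """An ordered protein multiple sequence alignment."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for seq_id, _ in self.records:
            if seq_id in seen:
                raise AlignmentFormatError(f"duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            offender = next(
                seq_id
                for seq_id, seq in self.records
                if len(seq) != len(self.records[0][1])
            )
            raise AlignmentFormatError(
                f"ragged alignment: row {offender!r} has a different length"
            )

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(seq_id for seq_id, _ in self.records)


def make_alignment(records: Iterable[tuple[str, str]]) -> Alignment:
    return Alignment(tuple((seq_id, seq.upper()) for seq_id, seq in records))


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file, enforcing equal row lengths."""
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Alignment(tuple(records))


def write_fasta_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as single-line-per-sequence FASTA."""
    with open(path, "w") as fh:
        for seq_id, seq in alignment.records:
            fh.write(f">{seq_id}\n{seq}\n")


def _char_matrix(alignment: Alignment) -> np.ndarray:
    return np.array([list(seq) for _, seq in alignment.records], dtype="U1")


def filter_gap_columns(
    alignment: Alignment,
    threshold: float = 0.95,
    gap_chars: frozenset[str] = GAP_CHARS,
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction strictly exceeds ``threshold``.

    Returns the filtered alignment (row order unchanged) and the kept
    column indices, 1-based relative to the input.  A column with a gap
    fraction exactly equal to the threshold is kept.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if alignment.n_rows == 0 or alignment.n_columns == 0:
        return alignment, []
    chars = _char_matrix(alignment)
    is_gap = np.isin(chars, sorted(gap_chars))
    gap_fraction = is_gap.mean(axis=0)
    keep = gap_fraction <= threshold
    kept_indices = [int(i) + 1 for i in np.flatnonzero(keep)]
    filtered = Alignment(
        tuple(
            (seq_id, "".join(np.compress(keep, list(seq))))
            for seq_id, seq in alignment.records
        )
    )
    return filtered, kept_indices
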