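"""Alignment data model, per-clade consensus, and column/residue mapping.

Gap characters ('-' or '.') are normalised to '.' on ingest.  Subsetting an
alignment never re-compacts columns, so column indices stay comparable across
sub-alignments extracted from one master alignment -- a requirement for
cross-cluster trace comparison, where the same alignment position must mean
the same thing in every group.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .exceptions import FormatError, InputError, LookupIdError
from .seqdef import AMINO_ACIDS

GAP = "."
_VALID_SYMBOLS = frozenset(AMINO_ACIDS) | {GAP}


def _normalise(row: str) -> str:
    return row.upper().replace("-", GAP)


@dataclass(frozen=True)
class Alignment:
    """A gapped residue matrix with uniquely-identified rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = [i for i, c in Counter(self.ids).items() if c > 1]
            raise InputError(f"duplicate ids: {dupes}")
        if self.rows:
            width = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != width:
                    raise FormatError(
                        f"row {sid!r} has length {len(row)}, expected {width}"
                    )
                bad = set(row) - _VALID_SYMBOLS
                if bad:
                    raise InputError(f"row {sid!r} has invalid symbols {sorted(bad)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        ids, rows = [], []
        for sid, row in pairs:
            ids.append(sid)
            rows.append(_normalise(row))
        return cls(tuple(ids), tuple(rows))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise LookupIdError(f"id {seq_id!r} not in alignment") from None

    def column(self, col: int) -> str:
        if not 0 <= col < self.n_columns:
            raise IndexError(f"column {col} out of range [0, {self.n_columns})")
        return "".join(row[col] for row in self.rows)


@dataclass(frozen=True)
class ColumnProfile:
    """Symbol counts for one alignment column."""

    counts: Mapping[str, int]


@dataclass(frozen=True)
class ConsensusSequence:
    """One symbol per alignment column; '.' where the gap rule fired."""

    symbols: str


@dataclass(frozen=True)
class ReferenceMapping:
    """Partial map alignment column (0-based) -> reference residue number (1-based)."""

    reference_id: str
    column_to_residue: Mapping[int, int]

    @property
    def residue_to_column(self) -> dict[int, int]:
        return {r: c for c, r in self.column_to_residue.items()}

    @property
    def reference_length(self) -> int:
        return len(self.column_to_residue)


def read_alignment(path: Path | str) -> Alignment:
    """Read an aligned FASTA file (optionally gzipped).

    Raises FormatError naming the first ragged record, or on an empty file.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = [(rec.id, _normalise(str(rec.seq))) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise FormatError(f"{path}: empty alignment")
    width = len(records[0][1])
    for sid, row in records:
        if len(row) != width:
            raise FormatError(f"{path}: record {sid!r} has ragged length")
    return Alignment.from_pairs(records)


def write_alignment(aln: Alignment, path: Path | str) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def column_profile(aln: Alignment, col: int) -> ColumnProfile:
    """Exact symbol counts (amino acids plus '.') in one column."""
    return ColumnProfile(dict(Counter(aln.column(col))))


def build_consensus(aln: Alignment) -> ConsensusSequence:
    """Most-frequent-residue consensus with the majority-gap rule.

    Per column: if more than half of the sequences carry a gap, the consensus
    symbol is '.'; otherwise it is the most frequent amino acid (gaps excluded
    from the vote), ties broken alphabetically.  Exactly half gaps is not
    "more than half", so the amino-acid vote still wins.
    """
    if aln.n_rows == 0:
        raise InputError("cannot build a consensus from an empty alignment")
    out = []
    for col in range(aln.n_columns):
        counts = Counter(aln.column(col))
        n_gap = counts.pop(GAP, 0)
        if n_gap * 2 > aln.n_rows or not counts:
            out.append(GAP)
        else:
            best = min(counts, key=lambda s: (-counts[s], s))
            out.append(best)
    return ConsensusSequence("".join(out))


def write_consensus(cons: ConsensusSequence, name: str, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n{cons.symbols}\n")


def map_to_reference(aln: Alignment, ref_id: str) -> ReferenceMapping:
    """Map non-gap columns of the reference row to 1-based residue numbers."""
    row = aln.row(ref_id)
    mapping: dict[int, int] = {}
    residue = 0
    for col, sym in enumerate(row):
        if sym != GAP:
            residue += 1
            mapping[col] = residue
    return ReferenceMapping(ref_id, mapping)


def write_mapping(mapping: ReferenceMapping, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("alignment_position\tresidue_number\n")
        for col in sorted(mapping.column_to_residue):
            fh.write(f"{col}\t{mapping.column_to_residue[col]}\n")


def subset_alignment(aln: Alignment, ids: Sequence[str]) -> Alignment:
    """Extract rows by id, preserving row content and column indices verbatim."""
    missing = [i for i in ids if i not in aln.ids]
    if missing:
        raise LookupIdError(f"ids not in alignment: {missing}")
    return Alignment(tuple(ids), tuple(aln.row(i) for i in ids))
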