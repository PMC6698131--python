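"""Family-membership filtering on the eight-cysteine motif (8CM).

Plant non-specific lipid transfer proteins (nsLTPs) share a scaffold of eight
cysteines arranged as ``C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C``: six cysteines separated
by spacers of at least one residue, plus one adjacent pair (``CC``) and one pair
separated by a single residue (``CXC``).  This module decides membership from
three criteria -- precursor length within 60..150 residues, exactly eight
cysteines in the mature chain, and the 8CM arrangement of those cysteines --
and reports the central ``CXC`` residue, whose chemistry (hydrophilic vs
apolar) hints at the type I vs type II structural fold.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .exceptions import InputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Residue classes for the CXC central-residue fold hint.  The dichotomy
#: (hydrophilic central residue in type I, apolar in type II) is a family
#: observation; the exact class membership is a configuration default.
HYDROPHILIC_RESIDUES = frozenset("STNQDEKRH")
APOLAR_RESIDUES = frozenset("AVLIFMW")

TYPE1_LIKE = "type1_like"
TYPE2_LIKE = "type2_like"
INDETERMINATE = "indeterminate"

#: Membership rule identifiers.
RULE_LENGTH = "length_bounds"
RULE_CYS_COUNT = "cys_count"
RULE_PATTERN = "pattern"


def _validate_residues(seq_id: str, residues: str) -> None:
    if not residues:
        raise InputError(f"{seq_id}: empty residue string")
    for i, ch in enumerate(residues):
        if ch not in _AA_SET:
            raise InputError(
                f"{seq_id}: non-amino-acid character {ch!r} at position {i}"
            )


@dataclass(frozen=True)
class MatureSequence:
    """A mature (signal-peptide-free) protein chain.

    ``precursor_length`` is the residue count of the full precursor including
    the signal peptide, when known; the length criterion of the family filter
    applies to the precursor, not the mature chain.
    """

    id: str
    residues: str
    precursor_length: Optional[int] = None

    def __post_init__(self) -> None:
        _validate_residues(self.id, self.residues)
        if self.precursor_length is not None and self.precursor_length < 1:
            raise InputError(f"{self.id}: precursor_length must be positive")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class EightCMMatch:
    """Located eight-cysteine motif within a mature sequence.

    ``cys_positions`` are 0-based indices of the eight cysteines;
    ``spacer_lengths`` holds the seven inter-cysteine segment lengths (the CC
    pair contributes 0 and the CXC pair contributes 1).
    """

    cys_positions: tuple[int, ...]
    cxc_central_residue: str
    spacer_lengths: tuple[int, ...]


@dataclass(frozen=True)
class MembershipDecision:
    """Outcome of the family filter: passed iff no rule fired."""

    passed: bool
    reasons: tuple[str, ...] = ()
    #: False when precursor_length was absent and the length rule was skipped.
    length_evaluated: bool = True

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def find_8cm(seq: MatureSequence, min_spacer: int = 1) -> Optional[EightCMMatch]:
    """Locate the 8CM pattern, or return None.

    A match requires exactly eight cysteines whose positions form
    ``C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C`` with every ``Xn`` spacer of length >=
    ``min_spacer``.  Terminal cysteines at either sequence end are allowed.
    """
    positions = tuple(i for i, ch in enumerate(seq.residues) if ch == "C")
    if len(positions) != 8:
        return None
    spacers = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(7)
    )
    # CC pair between 3rd and 4th cysteine; CXC between 5th and 6th.
    if spacers[2] != 0 or spacers[4] != 1:
        return None
    for idx in (0, 1, 3, 5, 6):
        if spacers[idx] < min_spacer:
            return None
    central = seq.residues[positions[4] + 1]
    return EightCMMatch(positions, central, spacers)


def passes_nsltp_criteria(
    seq: MatureSequence,
    min_precursor: int = 60,
    max_precursor: int = 150,
    min_spacer: int = 1,
) -> MembershipDecision:
    """Apply the three family-membership criteria to one sequence.

    Rules reported on failure: ``length_bounds`` (precursor length outside
    [min_precursor, max_precursor]; skipped and flagged unevaluated when the
    precursor length is unknown), ``cys_count`` (cysteine count != 8), and
    ``pattern`` (eight cysteines present but not in the 8CM arrangement).
    """
    reasons: list[str] = []
    length_evaluated = seq.precursor_length is not None
    if length_evaluated and not (
        min_precursor <= seq.precursor_length <= max_precursor  # type: ignore[operator]
    ):
        reasons.append(RULE_LENGTH)
    n_cys = seq.residues.count("C")
    if n_cys != 8:
        reasons.append(RULE_CYS_COUNT)
    elif find_8cm(seq, min_spacer=min_spacer) is None:
        reasons.append(RULE_PATTERN)
    return MembershipDecision(
        passed=not reasons,
        reasons=tuple(reasons),
        length_evaluated=length_evaluated,
    )


def cxc_fold_hint(
    match: EightCMMatch,
    hydrophilic: frozenset[str] = HYDROPHILIC_RESIDUES,
    apolar: frozenset[str] = APOLAR_RESIDUES,
) -> str:
    """Fold hint from the CXC central residue.

    Hydrophilic central residues point to the type I fold (residue exposed to
    solvent), apolar ones to the type II fold (residue buried toward the
    ligand cavity); anything else is indeterminate.
    """
    r = match.cxc_central_residue
    if r in hydrophilic:
        return TYPE1_LIKE
    if r in apolar:
        return TYPE2_LIKE
    return INDETERMINATE


# ---------------------------------------------------------------------------
# FASTA I/O


def _open_text(path: Path | str, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Path | str) -> Iterator[MatureSequence]:
    """Yield MatureSequence records from a (possibly gzipped) FASTA file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield MatureSequence(rec.id, str(rec.seq).upper())


def write_fasta(seqs: Iterable[MatureSequence], path: Path | str) -> None:
    with _open_text(path, "wt") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


def filter_report(
    seqs: Iterable[MatureSequence],
    min_precursor: int = 60,
    max_precursor: int = 150,
) -> "pandas.DataFrame":  # noqa: F821 - imported lazily
    """Tabulate the membership decision for each sequence.

    Columns: id, passed, reasons (comma-joined), cys_positions (comma-joined,
    0-based), cxc_central_residue, fold_hint.
    """
    import pandas as pd

    rows = []
    for s in seqs:
        decision = passes_nsltp_criteria(s, min_precursor, max_precursor)
        match = find_8cm(s)
        rows.append(
            {
                "id": s.id,
                "passed": decision.passed,
                "reasons": ",".join(decision.reasons),
                "cys_positions": ",".join(map(str, match.cys_positions))
                if match
                else "",
                "cxc_central_residue": match.cxc_central_residue if match else "",
                "fold_hint": cxc_fold_hint(match) if match else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "passed",
            "reasons",
            "cys_positions",
            "cxc_central_residue",
            "fold_hint",
        ],
    )
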