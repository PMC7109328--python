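"""Reading, validating and writing protein sequences in FASTA.

Sequences are normalized into the 20-letter amino-acid alphabet required by
the feature encoder.  Residues outside that alphabet (B, Z, X, U, O, J, gap
and stop symbols) are handled by a configurable sanitization policy, since
descriptor formulas are defined only on the 20 canonical residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids in fixed alphabetical one-letter order.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_ALPHABET)

#: Characters removed unconditionally (gaps, stops, whitespace handled separately).
_STRIP_CHARS = frozenset("-*.")

#: Minimum sequence length; transition features divide by L - 1.
MIN_LENGTH = 2


class Label(str, Enum):
    """Class label of a protein record."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNLABELED = "unlabeled"


class AmbiguityPolicy(str, Enum):
    """How residues outside the 20-letter alphabet are treated."""

    DROP_RESIDUE = "drop-residue"   # remove the character, keep the sequence
    REJECT_SEQUENCE = "reject-sequence"


class EmptyInputError(ValueError):
    """Raised when a FASTA file yields zero usable records."""


class DuplicateIdError(ValueError):
    """Raised when record identifiers collide within one dataset."""


@dataclass(frozen=True)
class ProteinRecord:
    """One validated amino-acid sequence with identifier and class label."""

    id: str
    sequence: str
    label: Label = Label.UNLABELED

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < MIN_LENGTH:
            raise ValueError(
                f"sequence {self.id!r} has length {len(self.sequence)} < {MIN_LENGTH}"
            )
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-canonical residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Rejection:
    """A sequence that failed sanitization, with the reason."""

    id: str
    reason: str


@dataclass
class SanitizeResult:
    """Outcome of :func:`sanitize_sequence`: a cleaned sequence or a rejection."""

    sequence: Optional[str]
    reason: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.sequence is not None


def sanitize_sequence(
    raw: str, policy: AmbiguityPolicy | str = AmbiguityPolicy.DROP_RESIDUE
) -> SanitizeResult:
    """Normalize a raw sequence string into the 20-letter alphabet.

    Upper-cases, removes whitespace, gap ('-'), stop ('*') and '.' characters,
    then applies the ambiguity policy to any remaining non-canonical letters.
    Rejection is a return state, never an exception.
    """
    policy = AmbiguityPolicy(policy)
    if not raw:
        return SanitizeResult(None, "empty input")
    cleaned = [
        ch
        for ch in raw.upper()
        if not ch.isspace() and ch not in _STRIP_CHARS
    ]
    noncanonical = [ch for ch in cleaned if ch not in _CANONICAL_SET]
    if noncanonical:
        if policy is AmbiguityPolicy.REJECT_SEQUENCE:
            return SanitizeResult(
                None, f"non-canonical residues {sorted(set(noncanonical))}"
            )
        cleaned = [ch for ch in cleaned if ch in _CANONICAL_SET]
    if not cleaned:
        return SanitizeResult(None, "empty after cleaning")
    if len(cleaned) < MIN_LENGTH:
        return SanitizeResult(None, f"length {len(cleaned)} < {MIN_LENGTH}")
    return SanitizeResult("".join(cleaned))


def load_fasta(
    path: str | Path,
    label: Label | str = Label.UNLABELED,
    policy: AmbiguityPolicy | str = AmbiguityPolicy.DROP_RESIDUE,
) -> tuple[list[ProteinRecord], list[Rejection]]:
    """Parse a FASTA file into records plus a tally of rejected entries.

    The id is the description-line text before the first whitespace.  Records
    failing sanitization are dropped and reported in the rejection list.
    """
    label = Label(label)
    path = Path(path)
    records: list[ProteinRecord] = []
    rejections: list[Rejection] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        result = sanitize_sequence(str(entry.seq), policy)
        if not result.ok:
            rejections.append(Rejection(entry.id, result.reason or "rejected"))
            continue
        if entry.id in seen:
            raise DuplicateIdError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, result.sequence, label))
    if not records:
        raise EmptyInputError(f"no parseable FASTA entries in {path}")
    if rejections:
        logger.info(
            "load_fasta: %d record(s) rejected from %s (%s)",
            len(rejections),
            path,
            "; ".join(f"{r.id}: {r.reason}" for r in rejections[:5]),
        )
    return records, rejections


def read_fasta(
    path: str | Path,
    label: Label | str = Label.UNLABELED,
    policy: AmbiguityPolicy | str = AmbiguityPolicy.DROP_RESIDUE,
) -> list[ProteinRecord]:
    """Read a FASTA file, returning sanitized records in file order.

    Rejected entries are counted in the structured log; use
    :func:`load_fasta` to receive the rejection tally directly.
    """
    records, _ = load_fasta(path, label, policy)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to a standard multi-line FASTA file."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def check_unique_ids(records: Iterable[ProteinRecord]) -> None:
    """Raise :class:`DuplicateIdError` if any id occurs twice."""
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise DuplicateIdError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
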