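"""Reading, validating and normalizing nucleotide sequence sets.

All sequences are held internally over the DNA alphabet {A, C, G, T}.
RNA-coded inputs are accepted and U is mapped to T on the way in, so
piRNA sets downloaded as RNA and transposon sets stored as DNA are
interchangeable. Ambiguity codes (N, R, Y, ...) are rejected rather than
skipped: silently dropping records would change dataset sizes invisibly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_ALPHABET = frozenset("ACGT")
_ACCEPTED = frozenset("ACGTUacgtu")

POSITIVE = "positive"
NEGATIVE = "negative"


class SequenceValidationError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,T,U}."""


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input (empty records, duplicate ids)."""


def normalize_sequence(raw: str) -> str:
    """Uppercase a raw nucleotide string and map U to T.

    Parameters
    ----------
    raw
        Non-empty nucleotide string; may be DNA- or RNA-coded, any case.

    Returns
    -------
    str
        String over {A, C, G, T}.

    Raises
    ------
    SequenceValidationError
        If ``raw`` is empty or contains a character outside
        {A, C, G, T, U} (case-insensitive). The error message names the
        1-based position of the first offending character.
    """
    if not raw:
        raise SequenceValidationError("empty sequence")
    for pos, ch in enumerate(raw, start=1):
        if ch not in _ACCEPTED:
            raise SequenceValidationError(
                f"invalid symbol {ch!r} at position {pos}: "
                "expected A, C, G, T or U (any case)"
            )
    return raw.upper().replace("U", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """One normalized nucleotide sequence with an id and optional label."""

    id: str
    residues: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        if not set(self.residues) <= VALID_ALPHABET:
            bad = next(c for c in self.residues if c not in VALID_ALPHABET)
            raise SequenceValidationError(
                f"record {self.id!r}: non-normalized symbol {bad!r}; "
                "call normalize_sequence first"
            )
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 'positive' or 'negative', got {self.label!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered collection of SequenceRecords with unique ids.

    Iteration order is the insertion order, so a set round-trips through
    FASTA deterministically.
    """

    records: list[SequenceRecord] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaParseError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.records]

    def subset(self, indices: Iterable[int], source: str = "") -> "SequenceSet":
        return SequenceSet([self.records[i] for i in indices], source=source or self.source)

    def relabel(self, label: Optional[str]) -> "SequenceSet":
        return SequenceSet(
            [SequenceRecord(r.id, r.residues, label) for r in self.records],
            source=self.source,
        )

    def min_length(self) -> int:
        if not self.records:
            raise ValueError("empty sequence set")
        return min(len(r) for r in self.records)


def read_fasta(path: str | Path, label: Optional[str] = None) -> SequenceSet:
    """Read a FASTA file into a SequenceSet, normalizing every sequence.

    Parameters
    ----------
    path
        FASTA file; multi-line sequences accepted.
    label
        If given, applied to every record ('positive' or 'negative').
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq)
        if not raw:
            raise FastaParseError(f"{path}: record {entry.id!r} has an empty sequence")
        try:
            residues = normalize_sequence(raw)
        except SequenceValidationError as exc:
            raise SequenceValidationError(f"{path}: record {entry.id!r}: {exc}") from exc
        records.append(SequenceRecord(entry.id, residues, label))
    try:
        return SequenceSet(records, source=str(path))
    except FastaParseError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write a SequenceSet as FASTA, wrapping sequence lines at 60 columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in seqs
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio)


def length_histogram(seqs: SequenceSet) -> dict[int, int]:
    """Length -> count histogram of a non-empty sequence set."""
    if len(seqs) == 0:
        raise ValueError("length_histogram: empty sequence set")
    return dict(Counter(len(r) for r in seqs))
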