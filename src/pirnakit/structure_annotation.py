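"""Per-nucleotide paired/unpaired annotation of queries against targets.

piRNAs guide PIWI proteins to transposon transcripts by near-perfect
sequence complementarity, so a simple ungapped complementarity scan
captures the paired/unpaired status each nucleotide would have in the
piRNA-transposon duplex. The built-in annotator slides the query along
the reverse complement of the target, keeps the placement with the most
Watson-Crick pairs, and marks positions paired only inside runs of at
least ``min_run`` consecutive pairs -- isolated single pairs that a
thermodynamic duplex predictor would not report are suppressed.
Alternatively, pre-computed duplex reports in an RNAplex-style
dot-bracket dialect can be parsed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from pirnakit.sequence_io import SequenceRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Watson-Crick pairs over the DNA-coded alphabet
WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})
#: additional G.T wobble pairs (G.U in RNA space)
WOBBLE_PAIRS = frozenset({("G", "T"), ("T", "G")})


@dataclass(frozen=True)
class PairingString:
    """Paired/unpaired states per nucleotide, rendered '(' / '.'."""

    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - {"(", ")", "."}
        if bad:
            raise ValueError(f"invalid pairing symbols {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_paired(self) -> int:
        return len(self.states) - self.states.count(".")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def annotate_builtin(
    query: SequenceRecord,
    target: SequenceRecord,
    min_run: int = 4,
    *,
    allow_wobble: bool = False,
) -> PairingString:
    """Annotate a query against one target by best ungapped complementarity.

    Every offset of the query along the reverse complement of the target
    (including partial overlaps at the ends) is scored by its number of
    complementary pairs; the best-scoring placement wins, ties broken by
    the smallest offset on the reverse-complemented target. Within the
    winning placement, only pairs inside maximal runs of length >=
    ``min_run`` are marked '('.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if not target.residues:
        raise ValueError("empty target sequence")
    pairs = WC_PAIRS | WOBBLE_PAIRS if allow_wobble else WC_PAIRS
    q = query.residues
    # base b of the query pairs with base c of the target exactly when b
    # equals the complement of c, i.e. matches the reverse complement.
    rc = reverse_complement(target.residues)
    lq, lt = len(q), len(rc)
    best_key = (-1, -1)
    best_states = "." * lq
    for offset in range(-(lq - 1), lt):
        mask = [
            0 <= offset + i < lt and (q[i], complement_of(rc[offset + i])) in pairs
            for i in range(lq)
        ]
        states = _mask_to_states(mask, min_run)
        # primary: total complementary pairs; secondary: pairs surviving
        # the min_run filter (keeps the annotation invariant under
        # reversal of both sequences); ties then go to the smallest offset
        key = (sum(mask), len(states) - states.count("."))
        if key > best_key:
            best_key = key
            best_states = states
    return PairingString(best_states)


def complement_of(base: str) -> str:
    return base.translate(_COMPLEMENT)


def _mask_to_states(mask: list[bool], min_run: int) -> str:
    out = ["."] * len(mask)
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = ["("] * (j - i)
            i = j
        else:
            i += 1
    return "".join(out)


class DuplexParseError(ValueError):
    """Raised for malformed duplex-report text (includes the line number)."""


_STRUCT_RE = re.compile(
    r"^(?P<qs>[().]+)(?:&(?P<ts>[().]+))?\s+"
    r"(?P<q1>\d+),(?P<q2>\d+)\s*:\s*(?P<t1>\d+),(?P<t2>\d+)"
)


def parse_duplex_output(
    text: str, query_lengths: Mapping[str, int]
) -> dict[str, PairingString]:
    """Parse RNAplex-style duplex reports into full-length pairing strings.

    The dialect per record is two '>' header lines (query id then target
    id) followed by one structure line::

        ((..((&))..))   5,12 : 3,10   (-7.20)

    The part before '&' is the query-side structure over the 1-based
    inclusive query span ``q1,q2``; bracketed offsets within the span
    are paired, everything outside the span is unpaired. Records for
    unknown query ids are an error; the last record wins if a query
    appears twice.
    """
    result: dict[str, PairingString] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise DuplexParseError(f"line {i + 1}: expected '>' query header, got {line!r}")
        query_id = line[1:].strip().split()[0]
        if i + 2 >= len(lines):
            raise DuplexParseError(f"line {i + 1}: truncated record for {query_id!r}")
        if not lines[i + 1].strip().startswith(">"):
            raise DuplexParseError(f"line {i + 2}: expected '>' target header")
        struct_line = lines[i + 2].strip()
        m = _STRUCT_RE.match(struct_line)
        if not m:
            raise DuplexParseError(f"line {i + 3}: malformed structure line {struct_line!r}")
        qs = m.group("qs")
        q1, q2 = int(m.group("q1")), int(m.group("q2"))
        if query_id not in query_lengths:
            raise DuplexParseError(f"line {i + 1}: unknown query id {query_id!r}")
        L = query_lengths[query_id]
        if not (1 <= q1 <= q2 <= L):
            raise DuplexParseError(
                f"line {i + 3}: query span {q1},{q2} outside sequence of length {L}"
            )
        if len(qs) != q2 - q1 + 1:
            raise DuplexParseError(
                f"line {i + 3}: structure has {len(qs)} symbols but query span "
                f"{q1},{q2} covers {q2 - q1 + 1} positions"
            )
        states = ["."] * L
        for k, ch in enumerate(qs):
            if ch in "()":
                states[q1 - 1 + k] = "("
        result[query_id] = PairingString("".join(states))
        i += 3
    return result


def write_annotations(annotations: Mapping[str, PairingString], path: str | Path) -> None:
    """Write id -> dot-bracket annotations as a two-column TSV."""
    with open(path, "w") as fh:
        for qid in annotations:
            fh.write(f"{qid}\t{annotations[qid].states}\n")


def read_annotations(path: str | Path) -> dict[str, PairingString]:
    out: dict[str, PairingString] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            qid, _, states = line.partition("\t")
            out[qid] = PairingString(states)
    return out
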