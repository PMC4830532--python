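"""Desk-scale reproduction of the piRNA dataset compilation procedure.

Positives are piRNAs that map to transposon sequences within a bounded
number of mismatches; negatives ("pseudo piRNAs") are short fragments
randomly cut from non-piRNA ncRNAs, filtered to those that also map to
transposons, deduplicated, and sampled to match the positives' count
and length distribution.

Approximate matching is ungapped with a Hamming-distance bound (default
3 mismatches), over both strands. The scanner uses pigeonhole seeding
-- the query is split into max_mm + 1 blocks, at least one of which
must match exactly -- and returns the identical hit set as a naive
per-window scan.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from pirnakit.sequence_io import SequenceRecord, SequenceSet
from pirnakit.structure_annotation import reverse_complement

FORWARD = "forward"
REVERSE = "reverse-complement"


@dataclass(frozen=True)
class MatchHit:
    """One ungapped placement of a query on a target within the mismatch bound."""

    query_id: str
    target_id: str
    offset: int  # 0-based start on the target's forward strand
    mismatches: int
    strand: str


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _scan_one_strand(
    pattern: str, target: str, max_mm: int
) -> list[tuple[int, int]]:
    """(offset, mismatches) for every placement of pattern within the bound.

    Pigeonhole seeding: split the pattern into max_mm + 1 contiguous
    blocks; any placement with <= max_mm mismatches contains at least
    one exactly matching block, so exact block hits generate the
    candidate offsets to verify.
    """
    lq, lt = len(pattern), len(target)
    if lq > lt:
        return []
    n_blocks = max_mm + 1
    bounds = np.linspace(0, lq, n_blocks + 1).astype(int)
    candidates: set[int] = set()
    for b in range(n_blocks):
        lo, hi = int(bounds[b]), int(bounds[b + 1])
        block = pattern[lo:hi]
        start = target.find(block)
        while start != -1:
            offset = start - lo
            if 0 <= offset <= lt - lq:
                candidates.add(offset)
            start = target.find(block, start + 1)
    hits = []
    for offset in sorted(candidates):
        mm = _hamming(pattern, target[offset : offset + lq])
        if mm <= max_mm:
            hits.append((offset, mm))
    return hits


def kmismatch_match(
    query: SequenceRecord,
    targets: SequenceSet,
    max_mm: int = 3,
    both_strands: bool = True,
) -> list[MatchHit]:
    """All ungapped placements of a query on the targets within ``max_mm``.

    Both strands are searched by default: a reverse-complement hit means
    the reverse complement of the query matches the target's forward
    strand at the reported offset. Hits are sorted by (target id,
    offset, strand). A query longer than every target yields an empty
    list.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    hits: list[MatchHit] = []
    rc = reverse_complement(query.residues)
    for target in targets:
        for offset, mm in _scan_one_strand(query.residues, target.residues, max_mm):
            hits.append(MatchHit(query.id, target.id, offset, mm, FORWARD))
        if both_strands:
            for offset, mm in _scan_one_strand(rc, target.residues, max_mm):
                hits.append(MatchHit(query.id, target.id, offset, mm, REVERSE))
    hits.sort(key=lambda h: (h.target_id, h.offset, h.strand))
    return hits


def empirical_length_sampler(positives: SequenceSet) -> Callable[[np.random.Generator], int]:
    """A sampler drawing lengths from the positives' empirical distribution."""
    lengths = np.array([len(r) for r in positives])

    def sample(rng: np.random.Generator) -> int:
        return int(rng.choice(lengths))

    sample.min_length = int(lengths.min())  # type: ignore[attr-defined]
    return sample


def cut_candidates(
    ncRNAs: SequenceSet,
    length_sampler: Callable[[np.random.Generator], int],
    per_seq: int = 1,
    seed: int = 0,
    min_length: Optional[int] = None,
) -> SequenceSet:
    """Cut candidate pseudo-piRNAs out of non-piRNA ncRNAs.

    ncRNAs shorter than ``min_length`` (the minimum positive length; read
    from ``length_sampler.min_length`` when not given) are dropped, then
    each remaining ncRNA contributes up to ``per_seq`` substrings of
    sampled length at uniformly random positions. A sampled length
    longer than the source ncRNA is clamped to the full ncRNA.
    """
    if per_seq < 1:
        raise ValueError("per_seq must be >= 1")
    if min_length is None:
        min_length = getattr(length_sampler, "min_length", 1)
    rng = np.random.default_rng(seed)
    kept = [r for r in ncRNAs if len(r) >= min_length]
    if not kept:
        raise ValueError(
            f"no ncRNA reaches the minimum positive length {min_length}"
        )
    records = []
    for rec in kept:
        for j in range(per_seq):
            length = min(int(length_sampler(rng)), len(rec))
            start = int(rng.integers(0, len(rec) - length + 1))
            records.append(
                SequenceRecord(
                    f"{rec.id}|cut{j}@{start}",
                    rec.residues[start : start + length],
                )
            )
    return SequenceSet(records, source=f"cut_candidates(seed={seed})")


def sample_negatives(
    candidates: SequenceSet,
    positives: SequenceSet,
    max_mm: int = 3,
    transposons: Optional[SequenceSet] = None,
    seed: int = 0,
) -> SequenceSet:
    """Select pseudo-piRNA negatives matching the positives' length profile.

    Candidates are first filtered to those that map to a transposon
    within ``max_mm`` mismatches (skipped when ``transposons`` is None),
    then deduplicated by exact sequence. From the survivors,
    |positives| records are drawn to reproduce the positives'
    per-length counts; when a length bin runs short, the nearest
    available length substitutes. Sampling is seeded and reproducible.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate pool")
    pool = list(candidates)
    if transposons is not None:
        pool = [
            r for r in pool if kmismatch_match(r, transposons, max_mm=max_mm)
        ]
    seen: set[str] = set()
    unique: list[SequenceRecord] = []
    for r in pool:
        if r.residues not in seen:
            seen.add(r.residues)
            unique.append(r)
    if not unique:
        raise ValueError("no candidate survives transposon filtering and deduplication")

    rng = np.random.default_rng(seed)
    by_length: dict[int, list[SequenceRecord]] = defaultdict(list)
    for r in unique:
        by_length[len(r)].append(r)
    for recs in by_length.values():
        rng.shuffle(recs)  # type: ignore[arg-type]

    wanted = Counter(len(r) for r in positives)
    chosen: list[SequenceRecord] = []
    shortfall: list[int] = []
    for length in sorted(wanted):
        supply = by_length.get(length, [])
        take = min(wanted[length], len(supply))
        chosen.extend(supply[:take])
        by_length[length] = supply[take:]
        shortfall.extend([length] * (wanted[length] - take))
    for length in shortfall:
        available = sorted(l for l, recs in by_length.items() if recs)
        if not available:
            raise ValueError(
                f"candidate pool exhausted with {len(chosen)} of "
                f"{len(positives)} negatives sampled"
            )
        nearest = min(available, key=lambda l: (abs(l - length), l))
        chosen.append(by_length[nearest].pop(0))
    return SequenceSet(
        [SequenceRecord(r.id, r.residues, "negative") for r in chosen],
        source=f"sample_negatives(seed={seed})",
    )
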