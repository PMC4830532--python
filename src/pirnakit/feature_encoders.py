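"""Six fixed-length feature encodings of variable-length small-RNA sequences.

The encoders turn a nucleotide sequence (16-35 nt in the intended use,
any length in principle) into fixed-length numeric vectors:

* ``spectrum_profile`` -- exact k-mer occurrence counts, k = 1..5 merged
  (4 + 16 + 64 + 256 + 1024 = 1364 columns).
* ``mismatch_profile`` -- k-mer counts where each window also credits
  every k-mer type within Hamming distance m of it.
* ``subsequence_profile`` -- gapped-subsequence counts: every ordered
  index tuple spelling a k-mer contributes 1 if contiguous, else a
  penalty delta raised to the tuple's span length.
* ``train_pssm`` / ``encode_pssm`` -- a position-specific scoring matrix
  of fixed width d learned from positive training sequences (long
  sequences truncated to d, short ones padded with a neutral symbol),
  applied per position as a log-odds score.
* ``psednc`` -- pseudo dinucleotide composition: the 16 dinucleotide
  occurrence terms plus lambda sequence-order correlation factors over
  six physicochemical dinucleotide step properties.
* ``lsste`` -- local structure-sequence triplet elements: 32 counts
  indexed by the paired/unpaired pattern of three adjacent nucleotides
  (8 structural types) and the center base (4 nucleotides).

All encoders are pure functions: the same input yields bit-identical
output. Counts are raw occurrences, not length-normalized.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from pirnakit.sequence_io import POSITIVE, SequenceRecord, SequenceSet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: default k-mer sizes for the three merged profiles
DEFAULT_KS: tuple[int, ...] = (1, 2, 3, 4, 5)
#: max mismatches per k: at most one third of the k-mer length
DEFAULT_M_OF_K: dict[int, int] = {k: k // 3 for k in DEFAULT_KS}
#: gap penalty per k: 0 for k = 1, 2 (no meaningful gaps), 1 for k >= 3
DEFAULT_DELTA_OF_K: dict[int, float] = {1: 0.0, 2: 0.0, 3: 1.0, 4: 1.0, 5: 1.0}
#: fixed PSSM width, matching the modal piRNA length in human and mouse
DEFAULT_PSSM_WIDTH = 30
#: highest correlation rank in the pseudo dinucleotide composition
DEFAULT_LAMBDA = 1
#: weight of the correlation terms in the pseudo dinucleotide composition
DEFAULT_W = 0.05

#: the 8 pairing patterns of three adjacent nucleotides, "(" = paired
STRUCT_TRIPLET_TYPES: tuple[str, ...] = (
    "(((", "((.", "(.(", ".((", "(..", ".(.", "..(", "...",
)

FEATURE_NAMES = ("spectrum", "mismatch", "subsequence", "pssm", "psednc", "lsste")


def kmer_labels(k: int) -> list[str]:
    """All 4**k k-mers over {A,C,G,T} in lexicographic order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def _check_ks(ks: Sequence[int]) -> list[int]:
    ks = list(ks)
    if not ks or any(k < 1 for k in ks):
        raise ValueError(f"k-mer sizes must be positive integers, got {ks}")
    return ks


def _short_block(seq_id: str, k: int, on_short: str) -> np.ndarray:
    if on_short == "zero":
        return np.zeros(4**k)
    raise ValueError(f"sequence {seq_id!r} is shorter than k={k}")


# ---------------------------------------------------------------------------
# spectrum / mismatch / subsequence profiles


def spectrum_profile(
    seq: SequenceRecord, ks: Sequence[int] = DEFAULT_KS, *, on_short: str = "error"
) -> np.ndarray:
    """Concatenated exact k-mer counts for each k in ``ks``.

    For each k the block has 4**k components, one per k-mer in
    lexicographic order, and the components sum to L - k + 1.
    """
    ks = _check_ks(ks)
    codes = _encode(seq.residues)
    L = len(codes)
    out = []
    for k in ks:
        if k > L:
            out.append(_short_block(seq.id, k, on_short))
            continue
        idx = np.zeros(L - k + 1, dtype=np.int64)
        for offset in range(k):
            idx = idx * 4 + codes[offset : offset + L - k + 1]
        counts = np.bincount(idx, minlength=4**k).astype(float)
        out.append(counts)
    return np.concatenate(out)


def _hamming_ball(window: tuple[int, ...], m: int, _memo: dict = {}) -> np.ndarray:
    """Indices of all k-mer types within Hamming distance m of ``window``."""
    key = (window, m)
    hit = _memo.get(key)
    if hit is not None:
        return hit
    k = len(window)
    base_idx = 0
    for c in window:
        base_idx = base_idx * 4 + c
    found = {base_idx}
    frontier = {tuple(window)}
    for _ in range(m):
        nxt = set()
        for w in frontier:
            for pos in range(k):
                for b in range(4):
                    if b != w[pos]:
                        nxt.add(w[:pos] + (b,) + w[pos + 1 :])
        frontier = nxt
        for w in frontier:
            idx = 0
            for c in w:
                idx = idx * 4 + c
            found.add(idx)
    arr = np.fromiter(sorted(found), dtype=np.int64)
    _memo[key] = arr
    return arr


def mismatch_profile(
    seq: SequenceRecord,
    ks: Sequence[int] = DEFAULT_KS,
    m_of_k: Optional[Mapping[int, int]] = None,
    *,
    on_short: str = "error",
) -> np.ndarray:
    """Concatenated inexact k-mer counts allowing up to m mismatches per k.

    Each length-k window increments the component of every k-mer type
    within Hamming distance m of it, so with m = 0 the profile equals
    the spectrum profile, and for each k the components sum to
    (L - k + 1) * sum_{j<=m} C(k, j) * 3**j.
    """
    ks = _check_ks(ks)
    if m_of_k is None:
        m_of_k = DEFAULT_M_OF_K
    for k in ks:
        m = m_of_k.get(k, 0)
        if not 0 <= m < k:
            raise ValueError(f"max mismatches must satisfy 0 <= m < k, got m={m} for k={k}")
    codes = _encode(seq.residues)
    L = len(codes)
    out = []
    for k in ks:
        m = m_of_k.get(k, 0)
        if k > L:
            out.append(_short_block(seq.id, k, on_short))
            continue
        counts = np.zeros(4**k)
        for start in range(L - k + 1):
            window = tuple(codes[start : start + k])
            counts[_hamming_ball(window, m)] += 1.0
        out.append(counts)
    return np.concatenate(out)


def _subsequence_block(codes: np.ndarray, k: int, delta: float) -> np.ndarray:
    """Gap-weighted subsequence counts for one k via prefix dynamic programming.

    W[j, s] holds the sum over index tuples i_1 < ... < i_p = j spelling
    prefix s of delta**(j - i_1); advancing one level multiplies in the
    geometric gap weight via a running per-prefix accumulator. The full
    tuple weight delta**span is then delta * W, and contiguous tuples
    (weight 1 by definition, not delta**k) are corrected using the exact
    spectrum counts.
    """
    L = len(codes)
    exact = np.zeros(4**k)
    idx = np.zeros(L - k + 1, dtype=np.int64)
    for offset in range(k):
        idx = idx * 4 + codes[offset : offset + L - k + 1]
    np.add.at(exact, idx, 1.0)

    W = np.zeros((L, 4))
    W[np.arange(L), codes] = 1.0
    for p in range(2, k + 1):
        prev = W
        W = np.zeros((L, 4**p))
        acc = np.zeros(4 ** (p - 1))
        stride = np.arange(4 ** (p - 1)) * 4
        for j in range(1, L):
            acc = delta * (acc + prev[j - 1])
            W[j, stride + codes[j]] = acc
    weighted = delta * W.sum(axis=0)
    return weighted + exact * (1.0 - delta**k)


def subsequence_profile(
    seq: SequenceRecord,
    ks: Sequence[int] = DEFAULT_KS,
    delta_of_k: Optional[Mapping[int, float]] = None,
    *,
    on_short: str = "error",
) -> np.ndarray:
    """Concatenated gapped-subsequence counts with per-k penalty delta.

    The component for k-mer type alpha sums, over every increasing index
    tuple i_1 < ... < i_k spelling alpha, a weight of 1 for contiguous
    tuples and delta**(i_k - i_1 + 1) for gapped ones. delta = 0 reduces
    to the spectrum profile; delta = 1 counts all C(L, k) tuples.
    """
    ks = _check_ks(ks)
    if delta_of_k is None:
        delta_of_k = DEFAULT_DELTA_OF_K
    for k in ks:
        d = delta_of_k.get(k, 0.0)
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"gap penalty delta must lie in [0, 1], got {d} for k={k}")
    codes = _encode(seq.residues)
    L = len(codes)
    out = []
    for k in ks:
        if k > L:
            out.append(_short_block(seq.id, k, on_short))
            continue
        out.append(_subsequence_block(codes, k, float(delta_of_k.get(k, 0.0))))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# position-specific scoring matrix


@dataclass(frozen=True)
class PSSMModel:
    """Position x nucleotide log-odds table of fixed width d.

    ``scores[b, k]`` is the log2-odds of base ``BASES[b]`` at column k
    relative to a uniform 0.25 background, with a pseudocount of 1
    distributed uniformly. Padding positions score 0.
    """

    d: int
    scores: np.ndarray  # shape (4, d)

    def __post_init__(self) -> None:
        if self.scores.shape != (4, self.d):
            raise ValueError(f"scores must have shape (4, {self.d})")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("base\t" + "\t".join(str(k + 1) for k in range(self.d)) + "\n")
            for b, base in enumerate(BASES):
                fh.write(base + "\t" + "\t".join(f"{v:.10g}" for v in self.scores[b]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PSSMModel":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            d = len(header) - 1
            scores = np.zeros((4, d))
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                scores[_BASE_INDEX[parts[0]]] = [float(v) for v in parts[1:]]
        return cls(d=d, scores=scores)


def train_pssm(training: SequenceSet, d: int = DEFAULT_PSSM_WIDTH) -> PSSMModel:
    """Learn a width-d PSSM from the positive-labeled training sequences.

    Sequences longer than d are truncated to their first d nucleotides;
    shorter ones are conceptually padded with a neutral symbol that
    contributes to no count. Column k scores base b as

        m_k(b) = log2( ((count_k(b) + 0.25) / (n_k + 1)) / 0.25 )

    where n_k is the number of positives whose (truncated) length
    reaches column k and the pseudocount 1 is split uniformly.
    """
    if d < 1:
        raise ValueError("PSSM width d must be >= 1")
    positives = [r for r in training if r.label == POSITIVE]
    if not positives:
        raise ValueError("train_pssm requires positive-labeled training records")
    counts = np.zeros((4, d))
    n_k = np.zeros(d)
    for rec in positives:
        codes = _encode(rec.residues[:d])
        counts[codes, np.arange(len(codes))] += 1.0
        n_k[: len(codes)] += 1.0
    scores = np.log2((counts + 0.25) / (n_k + 1.0) / 0.25)
    return PSSMModel(d=d, scores=scores)


def encode_pssm(seq: SequenceRecord, model: PSSMModel) -> np.ndarray:
    """Score a sequence per position against a trained PSSM.

    Position k of the output is the model's score for the k-th
    nucleotide; positions beyond the sequence end (padding) are 0, and
    nucleotides beyond column d are ignored.
    """
    codes = _encode(seq.residues[: model.d])
    out = np.zeros(model.d)
    out[: len(codes)] = model.scores[codes, np.arange(len(codes))]
    return out


# ---------------------------------------------------------------------------
# pseudo dinucleotide composition


@dataclass(frozen=True)
class PhysicoChemicalTable:
    """Six standardized physicochemical properties of the 16 dinucleotides.

    ``values[i, u]`` is property u of the i-th dinucleotide in
    lexicographic order, standardized so each property has mean 0 and
    standard deviation 1 over the 16 dinucleotides.
    """

    property_names: tuple[str, ...]
    values: np.ndarray  # shape (16, n_properties)

    def __post_init__(self) -> None:
        if self.values.shape[0] != 16 or self.values.shape[1] != len(self.property_names):
            raise ValueError("values must be 16 x n_properties")

    @classmethod
    def from_raw(
        cls, property_names: Sequence[str], raw: np.ndarray
    ) -> "PhysicoChemicalTable":
        """Standardize a raw 16 x n table column-wise (population sd)."""
        raw = np.asarray(raw, dtype=float)
        mu = raw.mean(axis=0)
        sd = raw.std(axis=0)
        if np.any(sd == 0):
            flat = [property_names[u] for u in np.where(sd == 0)[0]]
            raise ValueError(f"properties with zero variance cannot be standardized: {flat}")
        return cls(tuple(property_names), (raw - mu) / sd)

    @classmethod
    def from_tsv(cls, path: str | Path, standardize: bool = True) -> "PhysicoChemicalTable":
        """Read a dinucleotide-property TSV (header row, '#' comments)."""
        rows: dict[str, list[float]] = {}
        names: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if not names:
                    names = parts[1:]
                    continue
                rows[parts[0]] = [float(v) for v in parts[1:]]
        order = kmer_labels(2)
        missing = [d for d in order if d not in rows]
        if missing:
            raise ValueError(f"property table is missing dinucleotides: {missing}")
        raw = np.array([rows[d] for d in order])
        if standardize:
            return cls.from_raw(names, raw)
        return cls(tuple(names), raw)


_DEFAULT_TABLE: Optional[PhysicoChemicalTable] = None


def load_default_table() -> PhysicoChemicalTable:
    """The bundled Twist/Tilt/Roll/Shift/Slide/Rise step-parameter table."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("pirnakit") / "data" / "dinucleotide_properties.tsv"
        with resources.as_file(ref) as path:
            _DEFAULT_TABLE = PhysicoChemicalTable.from_tsv(path)
    return _DEFAULT_TABLE


def psednc(
    seq: SequenceRecord,
    lam: int = DEFAULT_LAMBDA,
    w: float = DEFAULT_W,
    table: Optional[PhysicoChemicalTable] = None,
) -> np.ndarray:
    """Pseudo dinucleotide composition: 16 + lambda components summing to 1.

    The first 16 components are dinucleotide occurrences and the last
    ``lam`` are rank-k correlation factors theta_k, each theta_k the
    average squared physicochemical distance between dinucleotides k
    steps apart; all are normalized by the common denominator
    (sum of counts) + w * (sum of theta), so the vector sums to 1.
    """
    if table is None:
        table = load_default_table()
    L = len(seq.residues)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam > L - 2:
        raise ValueError(
            f"sequence {seq.id!r} (length {L}) is too short for lambda={lam}; "
            "lambda may not exceed length - 2"
        )
    if w <= 0:
        raise ValueError("weight w must be > 0")
    codes = _encode(seq.residues)
    di = codes[:-1] * 4 + codes[1:]  # L-1 dinucleotide indices
    counts = np.bincount(di, minlength=16).astype(float)
    props = table.values[di]  # (L-1) x n
    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        diff = props[: L - 1 - k] - props[k:]
        thetas[k - 1] = np.mean(diff**2, axis=1).sum() / (L - k - 1)
    denom = counts.sum() + w * thetas.sum()
    return np.concatenate([counts, w * thetas]) / denom


# ---------------------------------------------------------------------------
# local structure-sequence triplet elements


def lsste_labels() -> list[str]:
    """The 32 triplet-element names: pairing pattern + center base."""
    return [f"{t}{b}" for t in STRUCT_TRIPLET_TYPES for b in BASES]


_TYPE_INDEX = {t: i for i, t in enumerate(STRUCT_TRIPLET_TYPES)}


def lsste(seq: SequenceRecord, annotation) -> np.ndarray:
    """Count the 32 structure-sequence triplet elements of a sequence.

    ``annotation`` is a per-nucleotide paired/unpaired string (a
    PairingString or a plain string over '(' and '.') of the same length
    as the sequence. Each of the L - 2 adjacent nucleotide triples
    increments the element indexed by the pairing pattern of its three
    positions and its center nucleotide, so the counts sum to L - 2.
    """
    states = getattr(annotation, "states", annotation)
    if len(states) != len(seq.residues):
        raise ValueError(
            f"annotation length {len(states)} != sequence length "
            f"{len(seq.residues)} for record {seq.id!r}"
        )
    bad = set(states) - {"(", ".", ")"}
    if bad:
        raise ValueError(f"annotation contains invalid symbols {sorted(bad)!r}")
    states = states.replace(")", "(")  # either bracket means paired
    counts = np.zeros(32)
    for i in range(len(states) - 2):
        t = _TYPE_INDEX[states[i : i + 3]]
        counts[t * 4 + _BASE_INDEX[seq.residues[i + 1]]] += 1.0
    return counts


# ---------------------------------------------------------------------------
# assembly into feature matrices


@dataclass(frozen=True)
class FeatureBlock:
    """Metadata for one named feature: parameters and column labels."""

    name: str
    params: dict
    column_labels: tuple[str, ...]

    @property
    def dimension(self) -> int:
        return len(self.column_labels)


@dataclass
class FeatureMatrix:
    """Rows of per-sequence feature values grouped into named blocks."""

    row_ids: list[str]
    blocks: list[FeatureBlock]
    values: np.ndarray

    def __post_init__(self) -> None:
        total = sum(b.dimension for b in self.blocks)
        if self.values.shape != (len(self.row_ids), total):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {total} block columns"
            )

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def block_slice(self, name: str) -> slice:
        start = 0
        for b in self.blocks:
            if b.name == name:
                return slice(start, start + b.dimension)
            start += b.dimension
        raise KeyError(f"no feature block named {name!r}")

    def block_values(self, name: str) -> np.ndarray:
        return self.values[:, self.block_slice(name)]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """A new matrix keeping only the named blocks, in the given order."""
        blocks = []
        cols = []
        for name in names:
            sl = self.block_slice(name)
            blocks.append(next(b for b in self.blocks if b.name == name))
            cols.append(self.values[:, sl])
        return FeatureMatrix(list(self.row_ids), blocks, np.hstack(cols))

    def column_labels(self) -> list[str]:
        return [f"{b.name}.{lab}" for b in self.blocks for lab in b.column_labels]

    def to_tsv(self, path: str | Path) -> None:
        """Write values as TSV with block-qualified headers plus a
        ``<path>.meta`` key-value sidecar recording all block parameters."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.column_labels()) + "\n")
            for rid, row in zip(self.row_ids, self.values):
                fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
            fh.write(f"blocks = {','.join(self.block_names())}\n")
            for b in self.blocks:
                fh.write(f"{b.name}.dimension = {b.dimension}\n")
                for key, val in sorted(b.params.items()):
                    fh.write(f"{b.name}.{key} = {val}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            row_ids = []
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                row_ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        # reconstruct block boundaries from the qualified labels
        blocks: list[FeatureBlock] = []
        labels: list[str] = []
        current = None
        for qual in header:
            name, _, lab = qual.partition(".")
            if name != current:
                if current is not None:
                    blocks.append(FeatureBlock(current, {}, tuple(labels)))
                current, labels = name, []
            labels.append(lab)
        if current is not None:
            blocks.append(FeatureBlock(current, {}, tuple(labels)))
        return cls(row_ids, blocks, np.array(rows, dtype=float))


@dataclass(frozen=True)
class FeatureParams:
    """Encoder parameters shared across a feature-extraction run."""

    ks: tuple[int, ...] = DEFAULT_KS
    m_of_k: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_M_OF_K))
    delta_of_k: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_DELTA_OF_K))
    d: int = DEFAULT_PSSM_WIDTH
    lam: int = DEFAULT_LAMBDA
    w: float = DEFAULT_W


def _profile_labels(ks: Sequence[int]) -> tuple[str, ...]:
    return tuple(f"k{k}.{mer}" for k in ks for mer in kmer_labels(k))


def extract_features(
    seqs: SequenceSet,
    feature_names: Sequence[str],
    params: Optional[FeatureParams] = None,
    pssm: Optional[PSSMModel] = None,
    annotations: Optional[Mapping[str, object]] = None,
    table: Optional[PhysicoChemicalTable] = None,
    extra_encoders: Optional[Mapping[str, tuple[Sequence[str], Callable]]] = None,
) -> FeatureMatrix:
    """Encode a sequence set into a FeatureMatrix of the named blocks.

    Parameters
    ----------
    feature_names
        Any of {spectrum, mismatch, subsequence, pssm, psednc, lsste} or
        a key of ``extra_encoders``; order defines the column layout.
    pssm
        Required when 'pssm' is requested (train with :func:`train_pssm`).
    annotations
        id -> PairingString mapping, required when 'lsste' is requested.
    extra_encoders
        Optional plug-in features: name -> (column_labels, fn) where
        ``fn(record) -> vector``. Used e.g. for control features in
        benchmarking.

    Sequences shorter than a requested k contribute zero vectors for
    that k-block so mixed-length sets encode uniformly.
    """
    if params is None:
        params = FeatureParams()
    feature_names = list(feature_names)
    if not feature_names:
        raise ValueError("extract_features: empty feature list")
    extra_encoders = extra_encoders or {}
    for name in feature_names:
        if name not in FEATURE_NAMES and name not in extra_encoders:
            raise ValueError(f"unknown feature {name!r}; expected one of {FEATURE_NAMES}")
    if "pssm" in feature_names and pssm is None:
        raise ValueError("feature 'pssm' requested but no PSSM model supplied")
    if "lsste" in feature_names and annotations is None:
        raise ValueError("feature 'lsste' requested but no pairing annotations supplied")

    blocks: list[FeatureBlock] = []
    columns: list[np.ndarray] = []
    for name in feature_names:
        if name == "spectrum":
            block = FeatureBlock(name, {"ks": list(params.ks)}, _profile_labels(params.ks))
            vals = [spectrum_profile(r, params.ks, on_short="zero") for r in seqs]
        elif name == "mismatch":
            block = FeatureBlock(
                name,
                {"ks": list(params.ks), "m_of_k": dict(params.m_of_k)},
                _profile_labels(params.ks),
            )
            vals = [mismatch_profile(r, params.ks, params.m_of_k, on_short="zero") for r in seqs]
        elif name == "subsequence":
            block = FeatureBlock(
                name,
                {"ks": list(params.ks), "delta_of_k": dict(params.delta_of_k)},
                _profile_labels(params.ks),
            )
            vals = [
                subsequence_profile(r, params.ks, params.delta_of_k, on_short="zero")
                for r in seqs
            ]
        elif name == "pssm":
            assert pssm is not None
            block = FeatureBlock(
                name, {"d": pssm.d}, tuple(f"pos{i+1}" for i in range(pssm.d))
            )
            vals = [encode_pssm(r, pssm) for r in seqs]
        elif name == "psednc":
            block = FeatureBlock(
                name,
                {"lambda": params.lam, "w": params.w},
                tuple(kmer_labels(2)) + tuple(f"theta{i+1}" for i in range(params.lam)),
            )
            vals = [psednc(r, params.lam, params.w, table) for r in seqs]
        elif name == "lsste":
            assert annotations is not None
            missing = [r.id for r in seqs if r.id not in annotations]
            if missing:
                raise ValueError(f"no pairing annotation for records {missing[:5]!r}")
            block = FeatureBlock(name, {}, tuple(lsste_labels()))
            vals = [lsste(r, annotations[r.id]) for r in seqs]
        else:
            labels, fn = extra_encoders[name]
            block = FeatureBlock(name, {"plugin": True}, tuple(labels))
            vals = [np.asarray(fn(r), dtype=float) for r in seqs]
        blocks.append(block)
        columns.append(np.vstack(vals))
    return FeatureMatrix(seqs.ids(), blocks, np.hstack(columns))
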