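import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from pirnakit.feature_encoders import (
    FeatureParams,
    PhysicoChemicalTable,
    encode_pssm,
    extract_features,
    kmer_labels,
    load_default_table,
    lsste,
    lsste_labels,
    mismatch_profile,
    psednc,
    spectrum_profile,
    subsequence_profile,
    train_pssm,
)
from pirnakit.sequence_io import SequenceRecord, SequenceSet

dna = st.text(alphabet="ACGT", min_size=5, max_size=12)


def rec(seq: str) -> SequenceRecord:
    return SequenceRecord("t", seq)


# ---------------------------------------------------------------------------
# independent brute-force oracles


def oracle_spectrum(seq: str, k: int) -> np.ndarray:
    out = np.zeros(4**k)
    labels = {m: i for i, m in enumerate(kmer_labels(k))}
    for i in range(len(seq) - k + 1):
        out[labels[seq[i : i + k]]] += 1
    return out


def oracle_mismatch(seq: str, k: int, m: int) -> np.ndarray:
    out = np.zeros(4**k)
    for idx, mer in enumerate(kmer_labels(k)):
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if sum(a != b for a, b in zip(mer, window)) <= m:
                out[idx] += 1
    return out


def oracle_subsequence(seq: str, k: int, delta: float) -> np.ndarray:
    out = np.zeros(4**k)
    labels = {m: i for i, m in enumerate(kmer_labels(k))}
    for tup in itertools.combinations(range(len(seq)), k):
        mer = "".join(seq[i] for i in tup)
        span = tup[-1] - tup[0] + 1
        out[labels[mer]] += 1.0 if span == k else delta**span
    return out


# ---------------------------------------------------------------------------
# spectrum profile


def test_spectrum_single_bases():
    v = spectrum_profile(rec("ACGT"), [1])
    assert v.tolist() == [1, 1, 1, 1]


def test_spectrum_k3_has_64_types_and_counts_windows():
    v = spectrum_profile(rec("AACTACG"), [3])
    assert len(v) == 64
    labels = kmer_labels(3)
    expected = {"AAC": 1, "ACT": 1, "CTA": 1, "TAC": 1, "ACG": 1}
    for mer, count in zip(labels, v):
        assert count == expected.get(mer, 0)


def test_spectrum_k_longer_than_sequence_errors():
    with pytest.raises(ValueError):
        spectrum_profile(rec("ACG"), [4])


@settings(deadline=None, derandomize=True)
@given(dna, st.integers(min_value=1, max_value=5))
def test_spectrum_matches_oracle_and_conserves_counts(seq, k):
    if k > len(seq):
        return
    v = spectrum_profile(rec(seq), [k])
    assert np.array_equal(v, oracle_spectrum(seq, k))
    assert v.sum() == len(seq) - k + 1


# ---------------------------------------------------------------------------
# mismatch profile


def test_mismatch_zero_m_equals_spectrum(rng):
    for _ in range(20):
        seq = random_dna(rng, int(rng.integers(5, 13)))
        m0 = {k: 0 for k in (1, 2, 3)}
        assert np.array_equal(
            mismatch_profile(rec(seq), [1, 2, 3], m0),
            spectrum_profile(rec(seq), [1, 2, 3]),
        )


def test_mismatch_single_window_hits_10_types():
    # one window "AAA": itself plus its 9 Hamming-1 neighbors
    v = mismatch_profile(rec("AAA"), [3], {3: 1})
    assert int((v > 0).sum()) == 10
    assert v.sum() == 10
    labels = kmer_labels(3)
    assert v[labels.index("AAA")] == 1
    for neighbor in ("AAC", "CAA", "ATA"):
        assert v[labels.index(neighbor)] == 1


def test_mismatch_requires_m_below_k():
    with pytest.raises(ValueError):
        mismatch_profile(rec("ACGTACGT"), [3], {3: 3})


def test_mismatch_matches_oracle_and_conservation(rng):
    for _ in range(40):
        seq = random_dna(rng, int(rng.integers(5, 13)))
        for k in (1, 2, 3, 4, 5):
            if k > len(seq):
                continue
            m = k // 3
            v = mismatch_profile(rec(seq), [k], {k: m})
            assert np.array_equal(v, oracle_mismatch(seq, k, m))
            ball = sum(math.comb(k, j) * 3**j for j in range(m + 1))
            assert v.sum() == (len(seq) - k + 1) * ball


# ---------------------------------------------------------------------------
# subsequence profile


@pytest.mark.parametrize("delta,expected", [(0.0, 1.0), (0.5, 1.0625), (1.0, 4.0)])
def test_subsequence_worked_example(delta, expected):
    # occurrences of AAC in AACTACG: 1 exact + two span-6 + one span-5 gapped
    v = subsequence_profile(rec("AACTACG"), [3], {3: delta})
    aac = kmer_labels(3).index("AAC")
    assert v[aac] == pytest.approx(1 + 2 * delta**6 + delta**5)
    assert v[aac] == pytest.approx(expected)


def test_subsequence_delta_zero_equals_spectrum(rng):
    for _ in range(20):
        seq = random_dna(rng, int(rng.integers(5, 13)))
        d0 = {k: 0.0 for k in (1, 2, 3, 4)}
        assert np.allclose(
            subsequence_profile(rec(seq), [1, 2, 3, 4], d0),
            spectrum_profile(rec(seq), [1, 2, 3, 4]),
        )


@settings(deadline=None, derandomize=True)
@given(dna, st.integers(min_value=1, max_value=5))
def test_subsequence_delta_one_counts_all_tuples(seq, k):
    if k > len(seq):
        return
    v = subsequence_profile(rec(seq), [k], {k: 1.0})
    assert v.sum() == pytest.approx(math.comb(len(seq), k))


def test_subsequence_matches_bruteforce_oracle(rng):
    for _ in range(30):
        seq = random_dna(rng, int(rng.integers(5, 11)))
        delta = float(rng.uniform(0, 1))
        for k in (2, 3, 4, 5):
            if k > len(seq):
                continue
            v = subsequence_profile(rec(seq), [k], {k: delta})
            assert np.allclose(v, oracle_subsequence(seq, k, delta), atol=1e-12)


def test_subsequence_rejects_delta_outside_unit_interval():
    with pytest.raises(ValueError):
        subsequence_profile(rec("ACGTACGT"), [3], {3: 1.5})


# ---------------------------------------------------------------------------
# PSSM


def _positives(seqs):
    return SequenceSet(
        [SequenceRecord(f"p{i}", s, "positive") for i, s in enumerate(seqs)]
    )


def test_pssm_closed_form_on_identical_positives():
    n = 8
    training = _positives(["ACGTAC"] * n)
    model = train_pssm(training, d=6)
    expected_hit = math.log2((n + 0.25) / (n + 1) / 0.25)
    expected_miss = math.log2(0.25 / (n + 1) / 0.25)
    a, c = 0, 1
    assert model.scores[a, 0] == pytest.approx(expected_hit)
    for b in (1, 2, 3):
        assert model.scores[b, 0] == pytest.approx(expected_miss)
        assert model.scores[b, 0] < 0
    assert model.scores[c, 1] == pytest.approx(expected_hit)


def test_pssm_default_width_is_30(toy_labeled_set):
    model = train_pssm(toy_labeled_set)
    assert model.d == 30
    assert model.scores.shape == (4, 30)


def test_pssm_scores_vanish_for_uniform_positives(rng):
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 30)) for _ in range(10_000)]
    model = train_pssm(_positives(seqs), d=30)
    assert np.max(np.abs(model.scores)) < 0.1


def test_pssm_requires_positive_labels():
    seqs = SequenceSet([SequenceRecord("n", "ACGT", "negative")])
    with pytest.raises(ValueError):
        train_pssm(seqs, d=4)


def test_encode_pssm_padding_and_truncation(toy_labeled_set):
    model = train_pssm(toy_labeled_set, d=30)
    short = encode_pssm(SequenceRecord("s", "A" * 20), model)
    assert short.shape == (30,)
    assert np.all(short[20:] == 0)
    long = encode_pssm(SequenceRecord("l", "A" * 40), model)
    assert np.array_equal(long, model.scores[0])  # only first 30 nt used


def test_encode_pssm_consensus_maximal(toy_labeled_set):
    model = train_pssm(toy_labeled_set, d=10)
    consensus = "".join("ACGT"[b] for b in model.scores.argmax(axis=0))
    v = encode_pssm(SequenceRecord("c", consensus), model)
    assert np.array_equal(v, model.scores.max(axis=0))


# ---------------------------------------------------------------------------
# PseDNC


def oracle_psednc(seq: str, lam: int, w: float, table) -> np.ndarray:
    """Direct transcription of the composition formula, no vectorization."""
    L = len(seq)
    order = kmer_labels(2)
    counts = [0.0] * 16
    for i in range(L - 1):
        counts[order.index(seq[i : i + 2])] += 1
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - 1 - k):
            a = table.values[order.index(seq[i : i + 2])]
            b = table.values[order.index(seq[i + k : i + k + 2])]
            total += sum((x - y) ** 2 for x, y in zip(a, b)) / len(a)
        thetas.append(total / (L - k - 1))
    denom = sum(counts) + w * sum(thetas)
    return np.array(counts + [w * t for t in thetas]) / denom


def test_default_table_is_standardized():
    table = load_default_table()
    assert table.values.shape == (16, 6)
    assert np.allclose(table.values.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(table.values.std(axis=0), 1, atol=1e-9)
    assert table.property_names == ("Twist", "Tilt", "Roll", "Shift", "Slide", "Rise")


def test_psednc_lambda_zero_is_dinucleotide_frequencies():
    v = psednc(rec("ACACAC"), lam=0)
    assert len(v) == 16
    assert v.sum() == pytest.approx(1.0)
    labels = kmer_labels(2)
    assert v[labels.index("AC")] == pytest.approx(3 / 5)
    assert v[labels.index("CA")] == pytest.approx(2 / 5)


def test_psednc_constant_table_gives_zero_thetas():
    flat = PhysicoChemicalTable(("p1", "p2"), np.zeros((16, 2)))
    v = psednc(rec("ACGTACGT"), lam=3, table=flat)
    assert np.all(v[16:] == 0)
    assert v.sum() == pytest.approx(1.0)


def test_psednc_matches_hand_computation():
    table = load_default_table()
    for seq in ("ACACAC", "TTGACGTACG", "ACGTACGTACGTACG"):
        for lam in (1, 2):
            v = psednc(rec(seq), lam=lam, table=table)
            assert np.allclose(v, oracle_psednc(seq, lam, 0.05, table), atol=1e-12)


def test_psednc_sums_to_one_and_property_order_invariant(rng):
    table = load_default_table()
    perm = rng.permutation(6)
    shuffled = PhysicoChemicalTable(
        tuple(table.property_names[i] for i in perm), table.values[:, perm]
    )
    for _ in range(20):
        seq = random_dna(rng, int(rng.integers(16, 36)))
        v = psednc(rec(seq), lam=3, table=table)
        assert np.all(v >= 0)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(v, psednc(rec(seq), lam=3, table=shuffled))


def test_psednc_lambda_exceeding_length_errors():
    with pytest.raises(ValueError, match="t'"):
        psednc(rec("ACGT"), lam=3)


# ---------------------------------------------------------------------------
# LSSTE


def test_lsste_has_32_elements():
    assert len(lsste_labels()) == 32


def test_lsste_all_unpaired_homopolymer():
    v = lsste(rec("AAAA"), "....")
    labels = lsste_labels()
    assert v[labels.index("...A")] == 2
    assert v.sum() == 2
    assert int((v > 0).sum()) == 1


def test_lsste_sum_is_length_minus_two(rng):
    for _ in range(20):
        L = int(rng.integers(16, 36))
        seq = random_dna(rng, L)
        ann = "".join("(." [i] for i in rng.integers(0, 2, L))
        v = lsste(rec(seq), ann)
        assert v.sum() == L - 2
        # direct triple enumeration
        labels = lsste_labels()
        expected = np.zeros(32)
        for i in range(L - 2):
            expected[labels.index(ann[i : i + 3] + seq[i + 1])] += 1
        assert np.array_equal(v, expected)


def test_lsste_length_mismatch_errors():
    with pytest.raises(ValueError, match="length"):
        lsste(rec("ACGT"), "...")


# ---------------------------------------------------------------------------
# extract_features assembly


def test_merged_profile_dimension_is_1364(toy_labeled_set):
    matrix = extract_features(toy_labeled_set, ["spectrum"])
    assert matrix.n_columns == 4 + 16 + 64 + 256 + 1024 == 1364


def test_spectrum_plus_pssm_dimension(toy_labeled_set):
    from pirnakit.feature_encoders import train_pssm

    ten = toy_labeled_set.subset(range(10))
    pssm = train_pssm(toy_labeled_set, d=30)
    matrix = extract_features(ten, ["spectrum", "pssm"], pssm=pssm)
    assert matrix.values.shape == (10, 1394)


def test_five_default_features_dimension(toy_labeled_set):
    pssm = train_pssm(toy_labeled_set, d=30)
    matrix = extract_features(
        toy_labeled_set,
        ["spectrum", "mismatch", "subsequence", "pssm", "psednc"],
        pssm=pssm,
    )
    assert matrix.n_columns == 1364 * 3 + 30 + 17


def test_extract_requires_prerequisites(toy_labeled_set):
    with pytest.raises(ValueError):
        extract_features(toy_labeled_set, [])
    with pytest.raises(ValueError, match="pssm"):
        extract_features(toy_labeled_set, ["pssm"])
    with pytest.raises(ValueError, match="lsste|annotation"):
        extract_features(toy_labeled_set, ["lsste"])
    with pytest.raises(ValueError, match="unknown"):
        extract_features(toy_labeled_set, ["bogus"])


def test_encoders_are_deterministic(toy_labeled_set):
    pssm = train_pssm(toy_labeled_set, d=30)
    kw = dict(params=FeatureParams(ks=(1, 2, 3)), pssm=pssm)
    a = extract_features(toy_labeled_set, ["spectrum", "mismatch", "subsequence", "pssm", "psednc"], **kw)
    b = extract_features(toy_labeled_set, ["spectrum", "mismatch", "subsequence", "pssm", "psednc"], **kw)
    assert np.array_equal(a.values, b.values)


def test_feature_matrix_tsv_roundtrip(tmp_path, toy_labeled_set):
    matrix = extract_features(
        toy_labeled_set.subset(range(5)), ["psednc"], params=FeatureParams(lam=2)
    )
    path = tmp_path / "feat.tsv"
    matrix.to_tsv(path)
    again = type(matrix).from_tsv(path)
    assert again.row_ids == matrix.row_ids
    assert again.block_names() == ["psednc"]
    assert np.allclose(again.values, matrix.values, atol=1e-9)
    assert (tmp_path / "feat.tsv.meta").exists()
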