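# Methods

`pirnakit` classifies short nucleotide sequences as transposon-derived
piRNAs versus pseudo-piRNA negatives. This note records the model, the
parameter choices, the synthetic-data design and the numerical
decisions that the code embodies.

## Problem and model

piRNAs are 16–35 nt germline small RNAs that guide PIWI proteins to
transposon transcripts by near-perfect complementarity; a 5′ uridine is
common and their k-mer composition differs from that of other short
ncRNA fragments. The classifier operates purely on sequence (plus,
optionally, a predicted piRNA–transposon duplex): each sequence is
encoded by up to six fixed-length feature vectors, a random forest is
fitted per feature (or on a concatenation), and two combination rules
are supported:

* **Direct combination** — concatenate the selected feature blocks and
  fit one forest on the merged vector.
* **Ensemble learning** — fit one forest per feature; weight each
  model by its internal 5-fold cross-validation AUC,
  `w_i = score_i / Σ_j score_j`, and predict
  `F(x) = Σ_i w_i f_i(x)`, a convex combination of per-feature
  positive-class probabilities.

Which features enter the combination is itself learned: all `2^N − 1`
non-empty subsets of the N candidate features are scored by internal
cross-validation AUC on the training data, and the best subset (ties
broken toward fewer features, then lexicographic name order) is
refitted on the full training set. With the five default sequence
features this is 31 subsets. Exhaustive search is refused above N = 10.

## Feature encodings

| feature | dimension | parameters (default) |
|---|---|---|
| spectrum profile | 1364 | k = 1..5 merged (4+16+64+256+1024) |
| mismatch profile | 1364 | m per k: ⌊k/3⌋ → 0,0,1,1,1 |
| subsequence profile | 1364 | gap penalty δ per k: 0,0,1,1,1 |
| PSSM | d = 30 | width d (modal piRNA length) |
| PseDNC | 16 + λ | λ = 1, weight w = 0.05 |
| LSSTE | 32 | none |

**Spectrum** counts exact k-mer occurrences; for each k the block sums
to L − k + 1. **Mismatch** credits, for every length-k window, each
k-mer type within Hamming distance m; m < k is required and the block
sums to (L − k + 1)·Σ_{j≤m} C(k,j)·3^j. **Subsequence** counts ordered
index tuples i₁ < … < i_k spelling each k-mer: a contiguous tuple
weighs 1, a gapped one δ^(i_k − i_1 + 1). At δ = 0 both inexact
profiles reduce to the spectrum; at δ = 1 the subsequence block sums to
C(L, k). The subsequence profile is computed by a prefix dynamic
program over (position, matched-prefix) states in which the geometric
span weight factorizes into per-step gap multipliers; the uniform
δ^span total is then corrected so contiguous tuples weigh exactly 1.
Naive tuple enumeration is exponential in k and serves only as the
test oracle (L ≤ 12).

**PSSM.** Sequences are forced to width d = 30 by truncating longer
ones and conceptually padding shorter ones with a neutral symbol that
contributes to no count and scores 0. Column k scores base b as
`log2(((count_k(b) + 0.25) / (n_k + 1)) / 0.25)`: a log-odds against a
uniform background with a unit pseudocount split evenly, where n_k is
the number of positive training sequences reaching column k. Counts
come from positive-labeled training sequences only, so the matrix is a
positional portrait of the piRNA class (the 5′-U bias concentrates in
column 1). Both the positives-only convention and the log-odds form
are deliberate design choices isolated behind `train_pssm`; a
frequency-based or all-sequence variant would drop in without touching
any consumer.

**PseDNC.** The 16 dinucleotide occurrence counts are extended with λ
sequence-order correlation factors
`θ_k = (1/(L−k−1)) Σ_i (1/6) Σ_u (v_u(d_i) − v_u(d_{i+k}))²`
over six standardized physicochemical step properties (Twist, Tilt,
Roll, Shift, Slide, Rise), and the whole vector is normalized by
(Σ counts + w·Σθ) so it sums to 1. L is the sequence's own length;
the dataset-wide shortest sequence only bounds the admissible λ
(λ ≤ L − 2 is enforced per sequence). The bundled property table
(`data/dinucleotide_properties.tsv`) holds representative
crystallographic step-parameter means with reverse-complement
symmetry; each property is standardized to mean 0 / sd 1 over the 16
dinucleotides at load time, so any published variant of the table can
be substituted without rescaling artifacts. The encoding is invariant
to the order of properties.

**LSSTE.** Given a per-nucleotide paired/unpaired annotation, each of
the L − 2 adjacent triples increments one of 32 counts indexed by the
8 pairing patterns of the triple and the 4 center bases. Annotations
come either from parsing external duplex-prediction reports
(dot-bracket dialect with query/target spans) or from the built-in
annotator: an ungapped scan of the query along the reverse complement
of a transposon target that keeps the placement with the most
Watson–Crick pairs (ties broken toward more pairs surviving the run
filter, then the smallest offset) and marks positions paired only
inside runs of ≥ 4 consecutive pairs, since isolated single pairs
would not be reported by a thermodynamic duplex tool. G·T wobble
pairing is off by default (the alphabet is DNA-coded) and available by
flag. The builtin annotator is a deterministic stand-in for a
free-energy duplex predictor; it models no thermodynamics.

## Classifier and evaluation

The base classifier is a random forest: 500 trees by default,
square-root feature sampling, probability = class-vote fraction, all
seeded; identical spec + identical data gives bit-identical
predictions. Internal cross-validation uses stratified 5-fold splits
derived from the classifier seed (the fold count and stratification
are package choices; nothing forces 5). For ensemble-mode subset
scoring, per-feature out-of-fold probabilities are computed once per
training set and every subset is scored as the per-fold AUC of the
weight-combined out-of-fold scores — equivalent in information to
refitting per subset but N-fold cheaper. Direct-mode subset scoring
refits the concatenated classifier per subset, with per-feature
encodings computed once and reused.

Outer evaluation is stratified 10-fold cross-validation; everything a
model learns, including subset selection and the PSSM, happens inside
the training folds. SN, SP and ACC are reported at probability
threshold 0.5; AUC (trapezoidal / Mann–Whitney, ties ½) is the primary
metric. Per-fold means are reported, and the pooled-over-folds AUC is
given alongside since the two conventions differ slightly.

## Dataset construction

`build-dataset` mirrors the compilation of a transposon-derived piRNA
dataset at desk scale: piRNAs are kept as positives if they map to a
transposon within 3 mismatches (ungapped, both strands); candidate
negatives are substrings cut from non-piRNA ncRNAs at lengths drawn
from the positives' empirical length distribution (ncRNAs shorter than
the shortest positive are dropped); candidates are filtered to those
that also map to transposons, deduplicated by exact sequence, and
sampled to match the positives' count and per-length histogram, with
nearest-length substitution when a bin runs short. The matcher uses
pigeonhole seeding (max_mm + 1 exact blocks) and is property-tested to
return the identical hit set as a naive per-window Hamming scan.

## Synthetic data: what it does and does not emulate

The generator draws lengths from a discretized normal (mode 30, sd 3,
floor 16 — matching the unimodal mammalian piRNA length profile; a
fly-like preset would use mode 25) and emits bases from a background
distribution (uniform by default). Positive-class signal is planted
two ways: the first base is forced to T with probability
`five_prime_U_prob`, and a k-mer bias table multiplies the emission
odds of any base that would complete a listed k-mer.

The `strong_signal_config` preset fixes `five_prime_U_prob = 0.9` and
a two-fold enrichment of a fixed panel of 16 of the 64 3-mers. The
panel breadth was calibrated once so that the preset earns its name
robustly: at n = 500 + 500, 10-fold CV with the spectrum (k = 1..4) +
PSSM recipe and 150-tree forests attains mean AUC ≈ 0.91–0.94 across
seeds in both combination modes. The `null_config` preset plants no
signal; the same pipeline averages AUC ≈ 0.5 over seeds (measured
0.506 ± 0.033 per seed over ten seeds), a calibration check that the
cross-validation machinery does not leak labels.

What the synthetic data does *not* emulate: transposon family
structure, ping-pong 10-nt overlap signatures, genomic background
composition, sequencing error, or any secondary-structure property.
Passing the synthetic benchmarks therefore demonstrates that the
pipeline recovers planted compositional and positional signal without
leakage — not that its absolute accuracy transfers to real
human/mouse/fly data, which additionally require the external piRNA,
ncRNA and transposon resources this package deliberately does not
download.

## Problem sizes used in the shipped checks

The library defaults remain k = 1..5 and 500 trees. The test suite and
the reproduction script evaluate at a reduced scale chosen as a
package decision: k = 1..3 or 1..4 profiles, 30–150 trees, n ≤ 1000
sequences; brute-force oracle comparisons run at L ≤ 12 where
enumeration is exact and cheap.

## Known limitations

* The PSSM functional form (log-odds, positives-only, pseudocount 1)
  is one reasonable convention among several; no claim is made that it
  reproduces any particular prior implementation.
* The physicochemical table ships representative step-parameter values;
  users with a preferred published table should substitute it (the
  standardization makes results insensitive to affine differences).
* The builtin duplex annotator is complementarity-only and ungapped.
* Direct-mode subset search costs 31 refits of a wide forest per fold;
  at full feature dimension this is the dominant runtime.
* Probabilities are vote fractions and are not calibrated.
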