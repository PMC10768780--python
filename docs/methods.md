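# Methods

## Scope and data model

`nmsite` classifies 41-nt RNA windows by whether the central nucleotide
(0-based index 20) carries a 2'-O-methyl mark. Windows are strings over
{A, C, G, U}; DNA-style input (T, lowercase) is normalized on read, and any
other character is rejected in strict mode because every encoder is defined
only over the 4-letter alphabet. Datasets are typed by central base
(A/C/G/U) or untyped (N); the generic dataset is built by merging typed
datasets and removing exact duplicate sequences (first occurrence wins,
conflicting labels are an error). Near-duplicate removal at 80 % identity
is out of scope: it belongs to an external CD-HIT invocation, which users
can run on the exported FASTA before training.

Labels enter either through paired positive/negative FASTA files or a
`label=0/1` token in the description line; both dialects are read and the
writer emits the token form, making read→write→read the identity on
(id, sequence, label).

## Descriptors

The 14 descriptor encoders are deterministic, total on valid input, and
length-generic (any L above each encoder's minimum), although production
windows are always 41 nt. Nucleotides are ordered A < C < G < U throughout;
k-mers are enumerated lexicographically under that order. Frequencies are
always over overlapping windows at stride 1.

Defaults (all exposed in `DescriptorConfig`): Kmer k = 3, RCKmer k = 3,
CKSNAP gap maximum 5, ENAC window 5, ASLPN maximum skip L−1. These are
conventional choices for fixed 41-nt windows; with them the per-window
dimensions are BPF 164, NCP 123, DBE 640, PS2 640, Kmer 64, RCKmer 32,
PseEIIP 64, CKSNAP 96, ENAC 148, Zcurve 144, ASLPN 56, MMNF 71, and
DPCP 16·p / p for a p-property table.

Choices worth recording:

* **NCP** uses the standard chemical-property triplet A=(1,1,1), C=(0,1,0),
  G=(1,0,0), U=(0,0,1) (ring structure, hydrogen-bond strength, functional
  group).
* **PS2 is an alias of DBE** under the common position-specific
  dinucleotide one-hot definition; a distinct variant can be slotted in via
  the encoder registry if a different convention is needed.
* **RCKmer** collapses each k-mer with its RNA reverse complement
  (A↔U, C↔G, reversed) to the lexicographically smaller form; for k = 3
  this gives 32 classes (no odd-length k-mer is its own reverse
  complement), for k = 2, 10 classes.
* **PseEIIP** weights trinucleotide frequencies by summed per-base
  electron–ion interaction pseudo-potentials (A 0.1260, C 0.1340, G 0.0806,
  U 0.1335), shipped as `data/eiip.tsv`.
* **DPCP** ships with a bundled default table of RNA dinucleotide
  nearest-neighbor stacking thermodynamics (ΔG°37 and ΔH from the standard
  RNA nearest-neighbor set, ΔS derived as (ΔH − ΔG)/T at 310.15 K), in
  `data/rna_dinucleotide_properties.tsv`. Properties are standardized to
  zero mean / unit variance across the 16 dinucleotides before use — a
  constant property is rejected rather than silently zeroed. Variant 1 is
  the frequency-weighted per-dinucleotide profile (dim 16·p,
  property-major); variant 2 is the per-property mean over the window's 40
  dinucleotide positions (dim p). Any delimited 16-row table can replace
  the default via config.
* **Zcurve** is the 144-parameter phase-specific trinucleotide variant:
  for each reading phase (start index mod 3) and each dinucleotide prefix,
  three contrasts of the phase-restricted trinucleotide frequencies along
  the purine/pyrimidine, amino/keto and strong/weak axes. A phase with no
  trinucleotide contributes zeros.
* **ASLPN** concatenates adaptive-skip dinucleotide composition (ordered
  pairs pooled over all gaps 1..L−1, normalized to sum 1) with the local
  position-specific dinucleotide frequency (density of each dinucleotide
  within its own prefix).
* **MMNF** concatenates 30 multivariate mutual-information terms over the
  10 unordered base pairs and 20 unordered triplets — computed from
  multiset frequencies of overlapping mono/di/trinucleotides, with the
  continuity conventions 0·ln(·) = 0 and zero-denominator → 0 — and the
  41 accumulated nucleotide frequencies.

Every encoder is checked in the test suite against an independent
brute-force implementation written loop-style from the definitions above.

## Embedding channels

Sequences are tokenized into overlapping k-mer words (default k = 3) and
padded symmetrically with `<pad>` tokens to exactly T = 41 time steps, so
all recurrent branches see the same sequence length regardless of k; pad
positions embed to the zero vector. Four channels are trained on the task
corpus itself (the training split), single-threaded and seeded:

* **word2vec** — skip-gram with negative sampling (unigram^0.75 noise),
  fixed context window (no random window shrinking, for exact
  reproducibility), linearly decaying learning rate.
* **fasttext** — the same objective with subword augmentation: each word's
  input vector is the mean of its word vector and its character 3–4-gram
  vectors of the bracketed word.
* **GloVe** — symmetric windowed co-occurrence counts (unit weight per
  pair) factorized by full-batch gradient descent on the weighted
  least-squares objective Σ w(X_ij)(u_i·v_j + b_i + c_j − ln X_ij)² with
  w(x) = min(1, (x/x_max)^α); the step is backtracked (halved) whenever it
  would increase the objective, so the training curve is non-increasing by
  construction. Token vector = u + v.
* **seq2vec** — a paragraph-vector (distributed bag-of-words) model: one
  vector per distinct token sequence trained to predict its own tokens
  against negative samples. The per-sequence vector is tiled across all 41
  time steps so the branch interface stays uniform; unseen sequences are
  embedded by a fixed number of seeded gradient steps against the frozen
  output matrix.

The fifth channel loads an external token→vector table (the adapter for
embeddings exported from a pretrained DNA language model). When no table is
supplied, a deterministic hash-based stub generates a fixed pseudo-random
vector per k-mer from (seed, token); this keeps the five-branch topology
and the full pipeline exercisable offline. The stub is a synthetic
stand-in, not a trained language model, and is labelled as such.

Defaults: d = 100, window 5, 50 epochs, 5 negative samples. The compact
configuration (below) reduces these for CPU-scale runs.

## Network

One CNN branch per descriptor: the vector enters as a single-channel 1-D
signal; three stages of cross-correlation (no kernel flip; default channels
32/64/128, κ = 3, stride 1, padding 1, dilation 1) each followed by ReLU
and max pooling (κ = stride = 2); flatten; dropout (0.5, inverted, training
only); FC to a 32-dim representation. Output lengths follow
`⌊1 + (L + 2P − D(κ−1) − 1)/S⌋`; a configuration that would drive a length
below 1 is rejected. For very short descriptors (e.g. the p-dim DPCP type-2
vector) the pooling kernel is clamped to the current signal length so the
branch keeps its three conv + three pool stages; a kernel-1 pool is the
identity.

One Bi-GRU-attention branch per embedding channel: two stacked
bidirectional GRU layers (the first layer's 2H-dim output feeds the
second; both share hidden size H = 64 by default; initial states zero;
update/reset/candidate gates with separate input and hidden biases),
additive attention over the 41 time steps (scores x_aᵀ tanh(W_a h_t + b),
softmax weights, weighted-sum context), FC to a 32-dim representation.

Fusion: concatenate the 19 branch outputs, one hidden FC layer (128) with
ReLU, one sigmoid output unit. The decision threshold is 0.5.

The loss is the standard negative mean binary cross-entropy with
probability clipping at 1e−7. Parameters are initialized Glorot-uniform
(biases zero, attention query ~0.1·N(0,1)) from a seeded generator, so
(inventory, seed) determines every weight.

The whole network runs on a small reverse-mode autodiff engine over numpy
arrays. Each GRU direction is a single fused graph node whose backward pass
is hand-written backpropagation through time; the engine's gradients are
validated end-to-end by a numerical-vs-analytic check at 1e−4 relative
tolerance on a tiny model, and every forward primitive against loop
oracles at 1e−6.

## Training and evaluation

Adam (lr 1e−3, β = 0.9/0.999), batch 64, at most 100 epochs, early stopping
on a seeded stratified 10 % holdout with patience 10, best-epoch weights
restored. Runs are single-threaded; identical (config, seed) yields
identical checkpoints and predictions.

Metrics follow the standard confusion-table formulas; MCC is defined as 0
when any denominator factor vanishes. AUC is the Mann–Whitney rank
statistic with ties counted ½ (identical to trapezoidal ROC integration).
Cross-validation uses seeded stratified k-fold (5-fold for tuning, 10-fold
for descriptor assessment harnesses); hyperparameter search selects by mean
validation MCC, breaking ties by AUC and then by parameter count.
Cross-nucleotide transfer evaluates every site-specific model on every
site-typed test set and writes the MCC/ACC/AUC matrix as CSV.

## Synthetic benchmark

The generator emulates the study design of the real Nm benchmarks:
balanced 1:1 training sets and 1:10 imbalanced independent test sets of
41-nt windows with a fixed central base (mixed bases for N), with
train/test disjointness enforced on exact sequence identity. Negatives are
i.i.d. draws from a background composition (uniform by default,
configurable). Positives start as background and have each motif column
resampled from λ·PWM + (1−λ)·background. The default motif is a
deterministic consensus (G, G, A, C at offsets −2, −1, +1, +2): λ alone
then controls implantation fidelity, λ = 0 being label-free noise and
λ = 1 a hard consensus. At λ = 0.9 the Bayes-optimal AUC of the default
design is ≈ 0.987 (from the binomial distributions of consensus matches in
positives vs negatives), comfortably above the 0.95 the recovery check
demands; softer PWMs (e.g. 0.85-peak columns) would cap the achievable AUC
below that bar, which is why the default is a consensus.

What the generator does **not** emulate: transcript context, composition
bias around real Nm sites, sequencing artifacts, near-duplicate sequence
families, or hard negatives from motif-shuffled sites (available as a
config option but off by default). Passing the recovery check therefore
shows that the architecture, featurization, optimizer and evaluation
pipeline can extract a planted flanking signal end-to-end — not that the
model attains any particular accuracy on real transcriptomes.

The signal-recovery check trains the model on the λ = 0.9 benchmark
(500 positives) and requires test AUC ≥ 0.95 for each of three seeds, and
chance-level AUC ∈ [0.45, 0.55] for λ = 0.

## Problem sizes and the compact configuration

The recovery and reproducibility checks run with a compact configuration
(`compact_run_config()`): embedding d = 16 with 5 epochs, conv channels
8/16/32, branch FC 16, GRU hidden 16, fusion 64, dropout 0.2, at most 20
training epochs with patience 4. This keeps a full train/evaluate cycle on
the 1 000-window training set and 5 500-window test set to roughly two
minutes on a single core while preserving the full 14 + 5 branch topology
and every architectural constraint of the default model. The default
configuration (d = 100, channels 32/64/128, H = 64) is what `RunConfig()`
instantiates and what the structural checks inspect.

## Known limitations

* No GPU path, no mixed precision; float64 throughout (chosen for gradient
  checkability over speed).
* The external-embedding channel defaults to a synthetic hash stub; real
  pretrained-language-model embeddings must be exported to a token table
  by the user.
* Exact-duplicate removal only; identity-threshold clustering is delegated
  to external tools.
* The descriptor set and hyperparameter defaults are registry conventions;
  exact parity with any particular published parameterization is not
  claimed, and all of them are config-exposed.
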