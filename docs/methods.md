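# Methods

## Problem and model

`rnagru` predicts RNA secondary structure — including pseudoknots — by
framing it as per-base multi-class classification: base j of a sequence of
length n ≤ N is assigned one of N + 1 classes, either "unpaired" (class 0)
or "paired with base k" (class k). Two pairs (i, j) and (m, n) with
i < m < j < n form a pseudoknot; because the label space is a partner index
rather than a bracket tree, crossing pairs need no special treatment in the
model or the decoder.

The classifier is a bidirectional gated recurrent network:

1. **Input features** (per base, width N + 5): the base's row of the n×n
   equilibrium pair-probability matrix zero-padded to N, the relative
   frequency of the base's own type within the sequence, and a one-hot base
   identity (A→0001, G→0010, C→0100, U→1000, other→0000, digits read
   left-to-right into the vector).
2. **Network**: a linear projection to the hidden width H, a forward and a
   backward GRU chain whose per-position states are summed (output width
   stays H), two fully connected ReLU layers of width F, dropout, and a
   linear-softmax output over N + 1 classes. The GRU cell uses the
   convention h_t = z ⊙ h_{t−1} + (1 − z) ⊙ h̃_t, i.e. the update gate
   gates the *old* state.
3. **Loss**: cross-entropy per base, combined per sequence as

       L = Σ_i flag[i]·weight[i]·ℓ_i / Σ_i flag[i]·weight[i]

   where `flag` zeroes the padded positions i > n exactly (padding
   invariance is tested as an identity, not an approximation), and `weight`
   is 1 for unpaired bases and u (the count of unpaired bases in the
   sequence, floored at 1) for paired bases. Since paired:unpaired is
   roughly 2:3 in curated RNA data while the paired bases are split over n
   partner classes, the weighting counteracts the "predict everything
   unpaired" local optimum. Three modes expose the ablation: `plain`
   (no masking; padding labelled unpaired and scored), `flag` (mask only),
   `vldb` (mask + weights).

## Pair probabilities

The paper-facing tools around this model usually obtain pair probabilities
from a thermodynamic partition function. Here they come from an internal
McCaskill-style inside/outside dynamic program over all *nested* structures
under a simple additive pair-energy model: E(GC) = −3, E(AU) = −2,
E(GU) = −1 (units of kT), minimum hairpin loop 3. This model is
deliberately minimal: it is exactly verifiable against exhaustive
enumeration (the test suite checks equality to 1e−9 over hundreds of random
sequences), and the classifier only needs an informative signal, not
calibrated thermodynamics. An adapter (`load_external_matrix`) accepts
matrices computed by external folding software (full n×n text or `i j p`
triplets), so fidelity-critical users can substitute real
nearest-neighbour probabilities. Recursions run in plain double precision;
a per-nucleotide rescaling engages automatically for long, pair-rich
sequences (roughly n > 230 under the default energies) to keep
intermediates in range. Pseudoknots are excluded from the ensemble — the
standard McCaskill restriction — so pseudoknot recovery is entirely the
classifier's and decoder's job.

## Training

No autodiff framework is used: forward and backward passes of the full
network (projection, both GRU chains, FC stack, dropout, softmax plus the
masked weighted loss) are implemented directly in NumPy, and the analytic
gradients are validated against central finite differences in the test
suite (relative error ≤ 1e−4 at sampled coordinates).

Defaults follow the reference configuration: H = 50, F = 150, learning rate
0.1 with plain SGD (the magnitude of the rate strongly suggests vanilla
SGD; momentum is selectable), 2000 iterations, batch size 200, dropout 0.5.
"Iterations" counts parameter updates. N defaults to the longest training
sequence. Model selection keeps the parameters with the best pooled MCC on
the validation split (the training set itself when no split is requested),
evaluated every `eval_every` updates; there is no early stopping.
Initialization is uniform(−0.1, 0.1), seeded. Checkpoints store every
array plus N, widths, dropout and a format version.

Two training behaviours worth knowing:

* With small nets and plain SGD the model typically sits in the
  all-unpaired plateau (ACC ≈ unpaired fraction, MCC 0) for the first
  ~1000 updates before pairing classes break out; this is the local
  optimum the dynamic weighting is designed to counteract, and the
  weighted mode escapes it more reliably than the plain mode at equal
  budget.
* Dropout 0.5 is a generalization default; memorization-style checks (and
  the acceptance overfit run) disable it.

## Decoding

Per-base argmaxes need not be mutually consistent, so two policies produce
the final structure: `mutual_argmax` keeps a pair only when the two bases
select each other (default; closest to scoring raw per-base
classifications), and `greedy_probability` ranks candidate pairs by
min(y[i→j], y[j→i]) and accepts greedily while both ends are free,
optionally restricted to canonical pairs. Canonical filtering is off by
default — modified bases pair promiscuously in real data. Both policies
always emit a valid pairing map (symmetric, no self-pairs) and may emit
crossing pairs.

## Evaluation

Per-base confusion counting: TP = paired with the correct partner,
TN = correctly unpaired, FN = predicted unpaired but truly paired, and
FP = predicted paired when unpaired in truth *or* paired to the wrong
partner. Wrong-partner bases count FP only, so the four cells partition
the n bases. SEN, PPV, ACC and MCC follow the standard formulas with any
0/0 defined as 0. Datasets are reported both pooled (metrics on summed
counts, the default) and macro (mean of per-sequence metrics).

## Synthetic data

The generator works structure-first: nested helices of 2–4 pairs are
placed by recursive interval splitting until the paired-base count reaches
round(n · fraction) ± 2 (default fraction 0.4 = the 2:3 paired:unpaired
ratio), then, with probability `pk_prob` (default 0.3), one extra helix is
inserted crossing an existing one. Sequences are filled complementary at
paired positions (Watson–Crick, or GU with probability `gu_freq`,
default 0.1) and uniform elsewhere. This guarantees that the partition
function concentrates probability on true pairs — the test suite checks
the mean true-pair probability exceeds three times the random-pair
background — which is what makes memorization and ablation tests
meaningful. What the generator does *not* emulate: family-specific
architecture (tRNA cloverleafs, long-range kissing loops), modified bases,
non-canonical pairs in helices, or natural length distributions; passing
tests demonstrate the machinery learns and evaluates correctly, not
field-realistic accuracy.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale as the package's own
choice of study conditions: overfit checks use 10 records of length 20–30
trained for 2000 iterations (full-batch); the weighted-vs-plain ablation
uses the same data with 5 seeds per mode; partition-function verification
uses 200 random sequences of length 5–14 against the enumeration oracle.
Predicted probabilities are clamped at 1e−12 before logs; the MCC
denominator convention and the all-paired weight floor are the only other
guards against degenerate inputs. The dot-bracket writer supports at most
4 bracket layers (structures needing more are rejected with a clear
error); CT and BPSEQ have no such limit.

## Known limitations

* The energy model is not the Turner nearest-neighbour model; absolute
  probabilities differ from thermodynamic folders even though rankings are
  broadly similar on complementary-designed sequences.
* One model per dataset: N is fixed at training time and longer sequences
  are rejected at prediction.
* Training is CPU-bound NumPy; hundreds of nucleotides per sequence and
  thousands of records are outside the intended envelope.
* The decoder is local; no dynamic-programming/MEA decoding is provided.
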