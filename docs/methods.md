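# Methods

## Problem and feature construction

A back-splice junction (BSJ) joins a transcript's downstream splice donor
to an upstream splice acceptor, circularizing the RNA. Candidate spans
arrive as BED records (0-based half-open, strand optional and defaulting to
`+`) over a genome FASTA. Rather than modelling the whole transcript, the
feature for one record is built from the sequence around its two endpoints,
which is where splice-site signals concentrate:

- plus strand: the `2·flank_len` window centred on `start` (acceptor side)
  concatenated with the window centred on `end` (donor side);
- minus strand: the reverse complement of that concatenation. Reverse
  complementation alone already puts the window around the genomic end —
  which is the acceptor for a minus-strand transcript — first, so the
  acceptor side leads in transcript orientation on both strands. This is
  the only choice consistent with the mirror property the tests enforce:
  minus-strand extraction on a genome equals plus-strand extraction on the
  reverse-complemented genome with mirrored coordinates.

`flank_len` defaults to 50 nt per side per site, giving a 200-nt feature.
The two "back-splicing sites" are taken to be the BED span's start and end
coordinates; nothing else in the record identifies them. Windows that fall
off a chromosome are a reported, skippable failure (an N-padding mode
exists behind a flag) — fabricating sequence silently is never acceptable.
Duplicate extracted feature sequences are removed, keyed on the sequence
itself rather than the record name, since upstream databases overlap.

FASTA input is normalized to uppercase, U→T, and any non-ACGT letter → N.

## Embedding contract

Every embedder maps a length-L sequence to an (L+2)×D matrix. The two
extra rows mirror the boundary tokens a nucleic-acid foundation model adds
around a sequence (202 rows for a 200-nt input); treating them as sentinel
rows keeps every downstream shape identical across embedders, so the
one-hot ablation (D = 4, zero sentinel rows, N → zero row) and a
2560-dimensional foundation-model embedding are interchangeable. The mock
embedder hashes (position, token, seed) into uniform values in [−1, 1]; it
is a pure function, so tests get foundation-model-shaped inputs offline,
but it carries no sequence semantics beyond per-position token identity.
The external adapter only validates shape, finiteness and a 1280-token
input cap; it never loads a model itself and the toolkit works without it.

## Classifier

Implemented in numpy with hand-derived gradients (`bsjnet/_nn.py`);
finite-difference checks in the test suite hold each analytic gradient to
1e−4 relative error.

- Convolution module: 3 layers, kernel 3 with symmetric zero padding
  (position count preserved), channels (256, 128, 64) by default,
  each followed by normalization and LeakyReLU (slope 0.01). Batch
  normalization over batch×positions per channel is the default; layer
  normalization is selectable. Conv channel widths and kernel size are
  conventional defaults for this problem size, all configurable.
- Self-attention: Q/K/V are independent linear maps of the conv features;
  the attention matrix is the row-wise softmax of QKᵀ/√D_k and the output
  is attention·V. Row-wise softmax over keys is the orientation that makes
  the weight matrix row-stochastic (each query's weights sum to 1); the
  transposed form is dimensionally inconsistent with that normalization.
  Four heads by default (per-head width D_k = width/heads); head count is
  configurable 1–8 and the whole layer can be ablated (`use_attention`).
- Adaptive max pooling with output size 1: the per-channel maximum over
  all positions, collapsing variable-length inputs to a fixed vector.
- Fully connected head: one linear layer to 2 logits by default; deeper
  heads (e.g. 3 layers) interleave LeakyReLU and stay selectable.
- Softmax with max-subtraction; cross-entropy clamps log arguments at
  1e−12. Ties in argmax decisions resolve to the lower class index.

## Training

Adam (default) or SGD on mean cross-entropy; learning rate defaults to
0.005, batch size 64, early stopping on validation loss with patience 5,
and the checkpoint with the best validation loss is returned when a
validation split exists. Optimizer choice, batch size and epoch count are
package conventions, not reproductions of any reference setup. Class
weighting is off by default; an inverse-frequency option exists for
imbalanced corpora. A NaN loss aborts with diagnostics instead of
continuing. All randomness (init, shuffling, dropout) flows from one seed
through `numpy.random.default_rng`, so a (seed, data, config) triple fixes
the metrics bit-for-bit on CPU.

The decision rule at evaluation is argmax over the two probabilities,
equivalent to a 0.5 threshold on the circRNA probability. Metrics come in
closed form from the confusion table; any zero denominator defines the
metric as 0 with a warning (never NaN). Recall and sensitivity coincide
for the positive class and are reported as one metric.

## Synthetic data

The generator emulates the statistical handle of real circRNA/lncRNA
training sets — a discriminative signal localized at the splice sites —
and nothing else. Chromosomes are i.i.d. draws from `base_composition`
(uniform by default). Records are laid out in non-overlapping slots
(span 150–400 nt, 50-nt flank margins) so planted motifs cannot bleed
between records; negatives are placement-matched to positives, removing
length and composition confounds. Positives receive an acceptor-side motif
(`TTTAG`, ending at the span start) and a donor-side motif (`AGGTAAGT`,
starting at the span end) written into the genome for a `motif_rate`
fraction of records; the motifs echo canonical splice elements
(polypyrimidine-tract/AG acceptor, GT-rich donor) but are otherwise
arbitrary fixtures. `label_noise` flips emitted labels while a manifest
retains the truth.

What passing tests on this generator show: the extraction geometry, the
embedding contract, the optimization loop and the evaluation stack are
correct, and the model can recover a planted junction signal from one-hot
input. What they do not show: performance on real genomes, where signal is
degenerate, context-dependent and entangled with repeats, composition and
secondary structure — none of which the generator imitates.

## Problem sizes and numerical choices

Learnability checks run at desk scale: 400 training / 100 test examples
for the planted-motif condition (held-out accuracy ≥ 0.95 expected with
the one-hot embedder) and a 400-example test split for the motif-free null
so the chance-level band (0.5 ± 0.05) sits at roughly two binomial
standard errors. The split protocol is stratified 80/10/10 with floored
validation/test sizes per class and the remainder in train.

Attention-weight rows sum to 1 within 1e−6; the attention implementation
is held to a literal per-element oracle at 1e−8 on ≤4-position inputs.
Parameter initialization is uniform fan-in, U(±1/√fan_in), from the
seeded generator.

## Known limitations

- No real-data benchmark ships with the package; nothing here certifies
  accuracy on biological circRNA/lncRNA corpora.
- The foundation-model path is an adapter contract only; embedding quality
  is entirely the external model's.
- Multi-exon structure is ignored: the BED span endpoints are assumed to
  be the back-splice sites, which is wrong for records whose annotated
  span differs from the circularized exon boundaries.
- Binary classification only; no multi-class extension.
- The numpy implementation is CPU-only and single-device; it favours
  determinism and transparency over speed.
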