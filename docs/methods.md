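# Methods

This note records the models, conventions and numerical choices behind
`atactf`, with the reasoning for the decisions that were genuinely open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open (BED convention); 1-based
formats (VCF-like variant TSVs) are converted at the boundary. bedGraph is
the canonical on-disk track format because it is text-exact and diffable;
bigWig is an optional encoder over the same runs (values round-trip only to
float32 precision). Zero runs are omitted on write, so sparse genomic
tracks stay small.

## Tn5 cut-site signal

The Tn5 transposase inserts adapters with a 9 bp stagger, so the true
insertion point is recovered by shifting plus-strand read starts +4 bp and
minus-strand (exclusive) read ends −5 bp. Both cut sites of every fragment
are retained, and duplicate cut sites are kept (duplicate marking is
upstream of this package). Fragments-TSV input (10x dialect) is treated as
already Tn5-corrected: each fragment contributes its start and its last
base (`end − 1`) with no further shift.

Insertion points are *between-base* points. Smoothing a point `c` with the
default flank of 20 bp therefore yields the half-open window
`[c−20, c+20)` of width exactly 40 bp. The alternative reading — a 1 bp
interval extended ±20 bp — would give 41 bp and was rejected because the
40 bp window is what the method's description and the ~38 bp Tn5 dimer
footprint support. A flank of 0 degenerates to a 1 bp window so the
operation never emits empty intervals.

Coverage is scaled to reads-per-20-million (`scale = 2e7 / depth`, where
depth = number of retained cut sites). Replicates are averaged on the
RP20M scale *before* min-max fitting (the order is not prescribed by the
method description; fitting on the average is the choice documented here).

### Robust min-max normalization

`minmax_p(s) = (s − min)/(max_p − min)` with `min` fixed at 0 and `max_p`
the p-th percentile of the signal (p = 99 by default; 95 and 100 are the
other supported settings, 100 being standard min-max). Two things are
deliberately pinned down because the reference description leaves them
open:

- **Reference distribution.** The percentile is computed over *nonzero*
  per-base values with the nearest-rank definition
  (`ceil(p/100 · n)`-th smallest). A percentile over all bases would
  degenerate to 0 on a mostly-zero genome.
- **Clipping.** Values above `max_p` are clipped to 1.0 by default, since
  the normalized track is defined to live in [0, 1]; `clip=False` exposes
  the raw ratio.

This normalization is scale-equivariant: normalizing `c·track` with
parameters fit on `c·track` equals normalizing `track` with parameters fit
on `track` (property-tested).

## Network architecture

Input is 1,024 bp × 5 channels (A, C, G, T one-hot + min-max normalized
accessibility); output is 32 sigmoid scores, one per 32 bp bin. Five
blocks of two same-padded, ReLU-activated width-7 convolutions are each
followed by batch normalization and width-2 max pooling; filter counts
are `trunc(15 · 1.5^(k−1))` = 15, 22, 33, 50, 75. Weights are Glorot
(Xavier) uniform, deterministic per seed.

The printed dilation sequence has six entries (1, 1, 2, 4, 8, 16) for five
blocks. The mapping adopted here: dilations 1, 1, 2, 4, 8 on blocks 1–5
and dilation 16 on a final two-layer convolutional stage at the deepest
resolution, before the single sigmoid-activated output convolution. This
honors the printed sequence and is guarded by the receptive-field check
(≥ ±512 bp). Padding mode and pooling width are not stated in the
reference description; same-padding plus width-2/stride-2 max pooling are
forced by the 1024 → 32 shape constraint (the number of pooling stages is
derived as log₂(input/output bins), and inconsistent specs fail
construction with the implied output length). Batch normalization is
placed after each convolution pair.

The receptive field is computed analytically as
`Σ (kernel−1)/2 · dilation · stride` over the convolution stack (stride =
cumulative pooling factor), truncated at the input boundary; for the
default architecture this yields one-sided ±512 bp, i.e. the whole window.
The analytic value is cross-checked by input perturbation on a
ones-weight, normalization-free network (span = 2·rf + stride).

### Numpy engine

No deep-learning framework is a dependency: convolution (im2col + one
GEMM per layer), batch norm, max pooling, the logits-form binary
cross-entropy and the Adam optimizer are implemented directly in numpy
with hand-written backward passes, each verified against numerical
differentiation. Training uses the numerically stable
`max(z,0) − z·t + log(1+e^−|z|)` loss on logits; the standalone
`bce_loss` on probabilities clamps at 1e-7. All tensors are float32.

## Training

- Chromosome split: train chr3–7, 9–11, 13–18, 20; validation chr2+chr19;
  test chr1+chr8. The sets must be disjoint; no training window touches
  validation/test chromosomes.
- **Labels:** a 32 bp bin is positive iff ChIP peaks cover *strictly* more
  than 16 bp of it (">50%" read literally; exactly half is negative, and
  the boundary is pinned by tests).
- **Peak-centric sampling:** windows are placed around the midpoint of a
  uniformly drawn region of interest (the union of every training cell
  type's ATAC and ChIP peaks on the partition's chromosomes, blacklist
  entries removed), clamped to chromosome bounds. The window center is
  jittered uniformly by ±448 bp by default (`jitter_bp`; the peak center
  stays inside the 1,024 bp window). Jitter is essential, not cosmetic: a
  same-padded CNN can sense its distance to the window edges through the
  zero padding, and with peaks always dead-center at training time it
  learns *where in the window* binding occurs rather than *what* binding
  looks like — genome-tiled prediction, where sites fall anywhere in a
  window, then collapses (observed directly on the synthetic fixture:
  tiled AUPR a few-fold over random without jitter versus tens-fold with
  it, while example-level validation metrics looked excellent either
  way). Set `jitter_bp=0` to recover exact centering. `random_ratio`
  mixes in windows uniform over the partition's chromosomes
  (length-weighted, blacklist-excluded); the default 0 is fully
  peak-centric.
- **Pan-cell:** the cell type supplying signal *and* labels is drawn
  uniformly from the training cell types, independent of the interval's
  origin — labels always describe binding in the cell type whose
  accessibility is shown, so signal/label pairs are never mismatched.
- Optimization: Adam, learning rate 1e-3, binary cross-entropy. The full
  published regime is 100 epochs × 100 batches × 1000 examples;
  desk-scale runs here use reduced schedules (see below). The epoch with
  maximal validation dice (soft dice on a fixed validation example set,
  drawn once peak-centric/pan-cell — with the same jitter as training —
  from validation chromosomes) supplies the returned parameters.
  Non-finite loss aborts with a diagnostic.
- Reverse-complement augmentation (channel swap + reversal of sequence,
  signal and labels; an involution) is available but off by default — it
  doubles cost without robust test-performance gains.
- All randomness flows from the single `TrainConfig.seed` through one
  generator; identical seeds give identical histories.

## Prediction and calibration

Chromosomes are tiled with non-overlapping 1,024 bp windows from position
0; the trailing partial window is padded with N sequence (zero one-hot)
and zero signal and its out-of-range bins discarded. Overlap-averaged
sliding windows are a possible refinement; non-overlapping tiling is the
documented choice and is isolated in one function. Scores are stored
densely per base (constant within each 32 bp bin); bins overlapping the
blacklist by ≥1 bp are zeroed. Donor-specific prediction substitutes
homozygous-alternate SNVs into the reference sequence (reference-allele
mismatches and indels are errors; het calls are ignored since they would
require phasing).

Calibration evaluates precision/recall/F1 at thresholds on a fixed 0.001
grid (bounded table size, comparable across models). Because precision is
not monotone in score, duplicate precision values are collapsed keeping
the threshold of maximal recall (ties broken toward the lower threshold);
the resulting table is one-to-one in precision. F1 at P = R = 0 is defined
as 0. The log2(precision/random-precision) column uses a 0.1 pseudocount
so it is total.

`threshold_to_bed` merges maximal runs of consecutive 32 bp bins scoring
≥ cutoff into intervals carrying the run maximum.

## Benchmarking

200 bp non-overlapping bins; the trailing partial bin is dropped so Eq-6
style totals use a constant bin width. Bin score = max per-base value;
gold label = ≥1 bp ChIP-peak overlap; blacklist-overlapping bins leave
both numerator and denominator of every statistic. Thresholds are the
unique positive scores, descending, with tied scores entering together;
bins scoring exactly 0 are treated as *unscored* (never predictions), so a
motif ranking with no hits has recall 0 rather than trivially recalling
everything at threshold 0. AUPR is the average-precision step sum
`Σ (R_i − R_{i−1}) P_i` — matching scikit-learn's `average_precision_score`
convention, which the tests verify on random instances — not the
trapezoid. Precision at r% recall is the precision at the highest
threshold whose recall reaches r.

PWM scanning derives the score threshold for a match p-value by exact
dynamic programming over the discretized score distribution under the
background model (default uniform, granularity 1e-3 in log2-odds units;
scanning uses the same discretized scores so the threshold is exact in
that space). Both strands are scanned; exact-coordinate duplicate hits are
removed while overlapping non-identical hits are kept; hits per 200 bp bin
(≥1 bp overlap, straddling hits counted in both bins) form the ranking.
The averaged-ChIP baseline is the per-base mean of arcsinh-transformed
−log10 p-value tracks across training cell types.

## Synthetic fixture

The generator emulates the structure of a multi-cell-type TFBS benchmark
at toy scale: chr1 (test, 50 kb), chr2 (validation, 50 kb), chr3+chr4
(train, 100 kb each); i.i.d. uniform background sequence (no GC structure,
keeping motif-match p-values analytically exact); one accessible candidate
region (300 bp) per 4 kb slot; a planted 8-mer consensus motif in half the
regions; half the regions shared by all cell types, the rest private to
one. A region is *bound* in a cell type iff it carries the motif and is
accessible there — binding is a joint function of sequence and
accessibility, which is exactly the signal the model must learn, and
cell-type specificity arises from the partially shared accessibility.
40,000 fragments per cell type give ~10× coverage enrichment inside
accessible regions (about 10–15× mean coverage); ChIP tracks are
triangular bumps (height 5–15) on true sites plus half-normal noise
(σ = 0.05); one 400 bp blacklist region per chromosome is placed in the
background. Accessible fractions (~7%) and positive-bin rates are higher
than in a real genome (~1% accessible) so that toy chromosomes contain
enough positives; fragment-length periodicity, duplication artifacts,
footprint shape and GC bias are *not* modeled, so passing tests
demonstrate the pipeline's correctness and the sampler/objective's
behavior, not real-genome performance.

`oracle_scores` (1 on every 32 bp bin overlapping a true site) pins the
benchmark ceiling at AUPR = 1; its inversion lands near random precision.

## Desk-scale problem sizes

End-to-end tests train a narrower network (base 8 filters → 8, 12, 18,
27, 40; identical topology otherwise) for 12 epochs × 12 batches × 64
examples on the fixture, with 192 validation examples — enough for
validation dice to climb from ~0.18 to ~0.78 and for held-out
(unseen cell type, test chromosome) AUPR around 10–20× random precision.
The trans-cell-type recovery check uses a 3-cell-type fixture (two for
training, one held out) and reports the median over 3 seeds; the sampling-
strategy comparison trains matched-budget models at `random_ratio` 0
vs 1 and compares median held-out AUPR.

## Known limitations

- Single-task (one TF per model); no multi-TF heads or regression outputs.
- Non-overlapping prediction tiling can split a binding site across a
  window boundary.
- The numpy engine is CPU-only and intended for desk-scale models; the
  published-scale regime (100×100×1000) is supported by the API but slow.
- BAM parsing requires pysam at call time; the fragments-TSV path is the
  first-class scATAC route.
- Blacklist derivation, peak calling and alignment are out of scope; all
  three are inputs.
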