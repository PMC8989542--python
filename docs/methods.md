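# Methods

## The prediction problem

Intrinsic cyclizability is a per-fragment bendability score measured by
loop-capture sequencing assays on fixed-length (50 bp) DNA.  Measured
scores are standardized and comparable across libraries only up to an
additive library constant, which dictates two modelling choices used
throughout this package: labels are z-scored before training (the C-score
scale), and accuracy is evaluated by Pearson correlation rather than
absolute error.

## Network architecture

The IR+LSTM maps a one-hot 50×4 matrix to one real value.

* **Stem.**  A 3×4 2-D convolution, valid across the 4-wide base axis and
  length-preserving along the position axis, collapses the input to a
  50×64 feature map (ReLU → batch-norm → dropout 0.2; the stem has no
  pooling).
* **Inception module.**  Two parallel branches of two serial convolutions
  each (kernels 3,3 and 11,21; stride 1 everywhere; `same` padding).  Each
  convolution is followed by ReLU; the second convolution of each branch
  additionally gets a 2×1 max-pool before batch-norm and dropout, so each
  branch emits 25×32.  The kernel sizes cover features at codon scale,
  poly(dA:dT)-tract scale and the ~10-bp helical period (a 21-wide kernel
  spans two periods).
* **Residual shortcut.**  Branch outputs are concatenated channel-wise
  (25×64) and the stem output is added elementwise.  Because the branch
  pooling halves the length, the shortcut path is itself passed through a
  parameter-free 2×1 max-pool so the shapes agree; this preserves the
  "add the module input back" semantics without introducing learned
  projection layers.  This also forces `2 × filters_per_branch ==
  stem_filters`, validated at configuration time.
* **Head.**  2×1 max-pool → batch-norm → dropout → LSTM (20 hidden units,
  final state read out) → dropout → dense linear layer → scalar.

Choices the architecture description leaves open, fixed here and kept
configurable: filter counts (64 stem / 32 per branch — the smallest
symmetric choice making the residual addition well-typed), length-preserving
padding for all position-axis convolutions, block ordering ReLU → (pool) →
batch-norm → dropout, LSTM read-out of the final hidden state only (scalar
target), and Glorot-uniform seeded initialization with the seed stored in
the model archive.  One-hot channel order is (A, C, G, T) and is recorded
in every serialized model so weights cannot be silently misinterpreted.

`N` bases encode as the uniform row (0.25, 0.25, 0.25, 0.25) in
single-sequence mode; in genome-track mode any window containing an `N`
is skipped and produces a track gap rather than a fabricated score.

## Prediction contract

`C(s) = a + b · (f(s) + f(rc(s)))/2`.  Averaging the raw outputs of a
sequence and its reverse complement makes the score strand-symmetric *by
construction* (exactly, not approximately).  The linear detrend `(a, b)`
corrects the mean drift and variance shrinkage we (like others) observe in
raw deep-regression outputs: it is fitted by regressing *labels on raw
outputs* over the internal validation split — the recalibration direction,
chosen because applying `a + b·raw` then reproduces the calibration
labels' mean exactly and makes the OLS slope of labels on corrected
predictions exactly 1 (least-squares identities, asserted in tests).
Calibrating on held-out rather than training data avoids under-correcting
the shrinkage, since raw outputs on training data are optimistically
fitted.

## Training protocol

RMSprop (lr 1e-3, ρ 0.9, ε 1e-7) on MSE, batch size 128, with an
early-stopping checkpoint: after every epoch the validation MSE is
evaluated in inference mode, and the weights ultimately returned are those
of the best epoch, not the last.  `patience` counts non-improving epochs
after the best before stopping.  Default schedule caps at 100 epochs;
the acceptance workloads use 15 epochs, which on the synthetic library is
past the point where the validation curve flattens (checkpoint typically
lands around epoch 10–14).  Where the protocol's constants are not
dictated by the problem (batch size, patience, epoch budget, the 10%
internal validation fraction) they are exposed as estimator parameters.

Cross-validation is a random k-fold partition (sizes differing by at most
one); each fold's model trains on the other k−1 folds with its own
internal validation split for checkpointing and detrending, and is scored
by Pearson correlation on the held-out fold.  Best-fold ties break to the
lowest fold index.

## Window semantics

The score of a 50-bp window starting at 1-based position `start` is
anchored at the window's 25th base, `center = start + 24`; an N-free
sequence of length L yields scores at centers 25 … L−25.  For the even
window width the center is inherently asymmetric; the left-of-center
convention is applied uniformly (windows, poly(dA:dT) tract anchors, PWM
site centers).  Batched evaluation of long sequences is a throughput knob
only and cannot change results (asserted in tests).

## Time-dependent Markov chains

An order-k chain fitted on an equal-length alignment stores, per position
t, the conditional base distribution given the previous min(t, k) bases.
With pseudocount 0 the implied position-specific (k+1)-mer law equals the
training frequencies exactly; the package computes that implied law
analytically (dynamic programming over context joints), which is how the
order-monotonicity of divergence from training is checked without
sampling noise.  Never-seen contexts fall back to the uniform
distribution; the pseudocount is configurable but defaults to 0 to keep
the k-mer capture property exact.  Orders above 3 are not offered: the
parameter count grows as 4^k and desk-scale alignments cannot train them.

"Top decile" selection uses the linear-interpolation empirical 90th
percentile with *strict* inequality, so a fully tied score vector selects
nothing; the convention is recorded here because ≥ vs > at the percentile
is ambiguous in common usage.

## PWM machinery

JASPAR-style text matrices (counts or probabilities) are column-normalized
on load.  Motif simulation draws each position independently from its
column; padded simulation embeds the motif centrally between equal-length
i.i.d. pads (parity of `total_length − width` is validated, with the
nearest valid length suggested).  Site refinement scans regions with
log-odds scores `log((p + 1e-3)/(0.25 + 1e-3))` — uniform background with
a small pseudocount inside the ratio — on both strands (the reverse strand
scores the reverse complement), anchors at the motif center, and breaks
ties leftmost-then-plus-strand.

## The synthetic oracle and what it does (not) show

The generator emulates the three sequence determinants that dominate
measured bendability: phase-coherent WW (AA/AT/TA/TT) dinucleotides at the
~10-bp helical period, overall WW content, and the stiffness of
poly(dA:dT) tracts.  The oracle is

```
score(s) = w_per·A(s) + w_ww·f_WW(s) − w_polyA·P(s)
A(s) = (2/L)·|Σ_t I_WW(t)·exp(2πi·t/period)|
```

with defaults `w_per = 1.0`, `w_ww = 0.5`, `w_polyA = 0.3` (penalty per
tract base beyond run length 4), `period = 10.0` bp (10.5 is the other
natural choice; 10.0 keeps phase arithmetic simple and the period is
configurable), label noise sd 0.3.  `P` sums over maximal pure-A and
pure-T runs, matching the dA:dT notation (mixed A/T runs are not tracts).

Libraries mix three classes in equal thirds: uniform-random sequences;
periodic-enriched sequences (4-bp A/T words planted at 10-bp spacing with
a random per-sequence global phase, on a background with G+C raised to
0.7, emulating the counter-phase SS signal of rotationally positioned
sequence — the random phase gives the library the phase diversity real
loopable fragments show); and polyA-enriched sequences (one pure A or T
run of length 5–9 at a random position).  Under these defaults the
periodic class sits >0.5 sd above the random class in standardized label
units, and the full-size model recovers held-out labels at r ≈ 0.90
(ceiling ≈ 0.95 at noise sd 0.3).

What passing these tests shows: the architecture, optimizer,
checkpointing, detrending and windowing machinery can learn and transport
a bendability-like signal end to end.  What it does not show: performance
on real loop-capture data, whose determinants are richer than the
three-term oracle (long-range dependence, assay noise structure,
library-specific offsets).  The oracle's formula is frozen so that the
recovery thresholds are stable, and generators are pure functions of
(arguments, seed).

Synthetic genomes plant nucleosome-like periodic elements, exact-length
tracts (flanked by guard C/G bases so maximality holds), and PWM sites
(isolated by a 150-bp feature-free margin so each refinement region
contains one true site), each with truth anchor tables.

## Profile analytics

Anchored mean profiles are strand-aware (offset d reads position p+d at a
+ anchor and p−d at a − anchor) and *exclude* missing positions (track
gaps, chromosome edges) from both mean and count rather than zero-filling;
per-offset counts are reported so edge attrition is visible.  Quartile
stratification uses 25/50/75 linear-interpolation percentiles with
boundary ties assigned to the lower quartile.  A z-scoring utility is
provided for occupancy/positioning tracks so they can be read against the
genome average.

## Numerical and engineering notes

* All computation is float64.  Activations are time-major `(L, B, C)`;
  convolutions run as k shifted contiguous GEMMs (no im2col copies),
  which is the difference between impractical and ~20 s/epoch training on
  the 20 000-sequence library on one CPU.
* Batch-norm uses exponential running moments (momentum 0.9) so inference
  is a pure function of the input; serialization stores them along with
  weights, detrend coefficients, label constants, channel order and the
  init seed, and round-trips to bit-identical predictions.
* Dropout uses a dedicated seeded generator; training is reproducible
  end to end given `random_state`.
* Problem sizes in the shipped tests and acceptance script (20 000
  training sequences, 10 000 Markov simulants, 100 000 motif draws) were
  chosen as the smallest sizes at which the measured quantities are
  stable; generators regenerate everything at run time, so no data files
  ship with the package.

## Known limitations

* The C-score is defined for 50-bp fragments only; shorter sequences are
  rejected rather than padded.
* Ambiguity codes beyond N are not supported.
* The detrend's transferability across libraries with different additive
  offsets cannot be verified without cross-library spike-ins; correlations
  are unaffected, absolute levels may shift.
* Prediction uncertainty is not quantified; retraining with different
  seeds is the available (expensive) route.
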