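# Methods

## Problem and pipeline

`fbgchew` classifies the ingestive behavior of a ruminant from the strain a
fiber Bragg grating (FBG) sensor measures on the mandible during jaw
movements.  Five behavioral classes are distinguished: three feeding patterns
(dietary supplement, hay, ryegrass), rumination, and idleness.  The pipeline
has four stages:

1. **Signal.**  The interrogator reports the Bragg wavelength
   λ(t) = λ_B + k·ε(t), with λ_B = 1541 nm and ε the jaw strain in µm/m,
   sampled at 1 kS/s.  Because no public recordings of this preparation
   exist, a synthetic generator stands in for the acquisition (below).
2. **Segmentation.**  The signal mean is evaluated over consecutive 1 s
   blocks and subtracted; rising zero crossings of the detrended signal
   delimit individual chew movements; each movement is restored to its
   original values (mean re-added).
3. **Features.**  Each movement becomes a 1030-attribute instance: the first
   1000 attributes are the movement samples padded at the tail with the block
   mean (or truncated) to exactly 1000 values; attributes 1001–1030 are the
   magnitudes of the first 30 components of the DFT
   X(k) = (1/N) Σ_{n=0}^{N−1} x(n) e^{−j2πkn/N} computed on the *unpadded*
   native segment (N = native length).  Under the 1/N normalization the k = 0
   magnitude is the segment mean, so attribute 1001 carries the DC level; the
   bin spacing f_s/N sits at the chew fundamental because a segment spans one
   cycle.
4. **Classifier.**  A from-scratch C4.5 decision tree (entropy, information
   gain, gain ratio, binary midpoint thresholds, error-based post-pruning)
   evaluated by stratified 10-fold cross-validation; the aggregated
   out-of-fold confusion matrix is the performance surface, and the tree with
   the best fold accuracy is reported as the selected classifier.

## Synthetic-data generator

The generator emulates the *statistical structure the classifier exploits*,
not the biomechanics.  Per class: a quasi-periodic chew cycle — a
raised-cosine aperture pulse over ~60% of the cycle followed by a negative
raised-cosine closure trough (depth `trough_fraction = 0.3` of the peak) —
riding on a class DC offset, with multiplicative amplitude and period jitter
and additive band-limited Gaussian noise.  Defaults:

| class              | peak (µm/m) | DC (µm/m) | fundamental (Hz) | noise sd (µm/m) |
|--------------------|------------:|----------:|-----------------:|----------------:|
| dietary supplement |          50 |        30 |             2.49 |             2.0 |
| hay                |         178 |        40 |             1.66 |             2.0 |
| ryegrass           |         100 |        35 |             2.00 |             2.0 |
| rumination         |          42 |        15 |             1.66 |             1.5 |
| idleness           |          12 |         5 |             1.54 |             0.5 |

Rationale for the defaults:

- Peak strains and fundamentals are the published per-class figures of the
  instrumented-calf experiment this pipeline re-implements.  Ryegrass is
  reported with peaks of both ~100 and ~60 µm/m; this is modeled as
  within-class spread by giving ryegrass a larger amplitude jitter
  (CV 0.2 vs 0.05 elsewhere), so its peaks range roughly 60–140 µm/m.
- DC offsets are *invented*, constrained only by the documented ordering
  idleness < rumination < every food class.
- Additive noise is **band-limited** (white Gaussian low-passed to a 15 ms
  correlation time, rescaled to the stated sd).  Jaw-strain disturbances are
  slow relative to a 1 kS/s sampling rate; broadband white noise at this rate
  would pepper the baseline-crossing regions with sample-scale sign flips
  that no plausible recording shows, splitting movements in two.  For the
  same reason the quiet classes carry smaller noise scales (0.5/1.5 µm/m for
  idleness/rumination): their whole dynamic range is 12–42 µm/m, and a flat
  2 µm/m floor would be a third of the idleness gap depth.
- The strain→wavelength sensitivity defaults to k = 1.2 pm per µm/m, a
  typical silica-FBG figure near 1550 nm (the source experiment never states
  its calibration); it is configurable on `SensorModel`.

Session assembly: movements are concatenated with 0.1 s baseline gaps (gap
samples carry the segment's class label).  Two structural choices make the
segmentation stage exactly invertible on clean signals:

- each class segment is padded, by widening its gaps evenly, to a whole
  number of 1 s averaging blocks, so block means never mix classes;
- the session ends with one extra second of baseline carrying a 1 µm/m
  settling ramp, which guarantees a final rising crossing that closes the
  last movement (a perfectly flat terminal block would sit numerically at
  ±1 ulp of its own mean).

With these defaults a clean (zero-noise, zero-jitter) session of n movements
per class segments into *exactly* n movements per class with 100% label
fidelity.  Alignment padding can be disabled (`align_block_s=None`), in which
case the session duration is just the sum of movements and gaps.

What the generator does **not** model: sensor temperature cross-sensitivity,
bone-healing drift, interrogator noise spectra, chewing-bout structure
(pauses between bouts longer than between chews), inter-animal variability,
or within-session nonstationarity.  Consequently a high cross-validated
accuracy here demonstrates that the pipeline's mechanics are sound and that
the published class structure (amplitude/DC/frequency separation) is
learnable by C4.5 — it does not certify performance on real recordings.

## Segmentation details

- A movement is the span between consecutive *rising* crossings
  (previous sample < 0, current ≥ 0, exact zeros non-negative), so each span
  leads with the aperture peak.  The leading span before the first crossing
  and the trailing span after the last are discarded.
- Spans shorter than `min_movement_s = 0.05` s are rejected; with noisy
  signals, crossing clusters at a boundary otherwise generate sample-scale
  junk spans.
- A movement's label is the modal per-sample label over its span (ties break
  toward the earlier class in the canonical order); spans with no labeled
  samples are dropped.
- The restored mean of a movement is the average of the per-sample
  block-mean baseline over its span (identical to the block mean when the
  span lies within one block).
- Segments longer than 1000 samples are tail-truncated; shorter ones are
  tail-padded with the restored mean.

## Feature details

- The spectrum is computed on the native segment, N = native length.  This
  is the only reading under which the per-class bin spacings
  (2.49/1.66/2/1.66/1.54 Hz for native lengths 402/602/500/602/649 at
  1 kS/s) are arithmetically possible; a padded N = 1000 would force a
  uniform 1 Hz spacing.  The padded alternative remains available via
  `FeatureParams(fft_input="padded")`.
- The stored spectral attribute is the magnitude |X(k)| (spectra are plotted
  non-negative in the source experiment; the real part is never mentioned).
- Attributes stay in wavelength units (nm), as the classifier in the source
  experiment consumed interrogator output directly.
- Reduced variants keep 500 or 250 time attributes by uniform decimation of
  the padded vector (every 2nd/4th sample, keeping the first); the 30
  spectral attributes are unchanged.

## C4.5 details

- Binary splits `a ≤ t / a > t` only: every attribute in this pipeline is
  continuous, so the categorical multiway machinery is unexercised and
  omitted.  Candidate thresholds are midpoints between consecutive distinct
  sorted values (Quinlan's "largest value ≤ midpoint" variant is available
  via `threshold_style="largest_leq"`).
- Split selection maximizes gain ratio among candidates whose gain reaches
  the mean gain of all positive-gain candidates (the average-gain guard);
  both branches must hold at least `min_leaf = 2` instances.  Ties break
  toward the lowest attribute index, then the lowest threshold; leaf classes
  break ties toward the earliest class.  Induction is fully deterministic.
- Post-pruning is bottom-up subtree replacement using the pessimistic error:
  a node's error count is inflated to its binomial upper confidence limit at
  `confidence_factor = 0.25` (Clopper–Pearson, the (1−CF) quantile of
  Beta(E+1, N−E)); a subtree collapses when the collapsed leaf's estimated
  errors do not exceed its children's sum.  Subtree raising and
  missing-value fractional instances are not implemented.
- The published tree for the real recordings (83 nodes: 41 decision, 42
  leaves, rooted at the fundamental-frequency attribute) is *not* a
  reproduction target — it depends on the unavailable in vivo data — but the
  structural identity n_leaves = n_decision + 1 holds for every binary tree
  this package induces, and the same attribute families (a1001 DC, a1002
  fundamental) dominate the synthetic trees' upper levels.

## Evaluation details

- Folds are stratified: per class, a seeded shuffle followed by round-robin
  assignment, so fold sizes differ by at most one instance per class.
  Pruning happens inside each fold (training folds only).
- The aggregated out-of-fold matrix is the accuracy surface: with 200
  instances per class its rows sum to 200, matching the reference
  experiment's published matrix layout.
- "Best classifier" selection by maximum fold test accuracy follows the
  reference procedure (statistically unusual, but cheap and reported
  alongside the aggregate, never instead of it).

## Problem sizes and numerical choices

- The default study conditions are 200 movements per class (1000 instances,
  1030 attributes); a full simulate → cross-validate run takes tens of
  seconds on one CPU.  The chance-level (label-shuffling) check runs on a
  40-per-class subset with 5 folds — trees grown on unstructured labels are
  an order of magnitude larger, and chance level is scale-free.
- Gains are clipped at 0 against −1e−16 float residue; candidates need
  gain > 1e−12 to count as positive; gain-ratio comparisons use a 1e−12
  tolerance so float noise cannot flip a tie-break.
- Encode/decode round trips are exact to ~1e−10 relative (float64); tests
  assert 1e−9.
- Degenerate inputs: empty traces, empty datasets, single-class nodes,
  all-positive detrended series, segments shorter than 30 samples, and
  zero-row confusion matrices all raise or return empty results explicitly.

## Known limitations

- Synthetic stand-in only; see the generator section for what is not
  modeled.  The reported ≥94% out-of-fold accuracy is a property of the
  emulated class structure.
- C4.5 subset: no categorical attributes, no missing values, no subtree
  raising, no rule post-simplification, no windowing/boosting.
- Segmentation assumes the chew fundamental is below half the block rate;
  movements slower than one averaging block (under ~1 Hz with 1 s blocks)
  would be distorted by detrending.
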