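# Methods

`ecgdx` implements a four-stage diagnostic system for binary habit
classification from a single ECG lead: feature extraction, clustering of the
training set into learning subsets, one classifier per subset, and a
decision rule that combines the per-classifier outputs. This note records
the models, the parameters that matter, the numerical choices, and the
limits of what the synthetic evaluation shows.

## Signal model and pre-processing

A record is a single-lead voltage trace in mV at a known sampling rate.
Supported sources are WFDB-style header/signal pairs restricted to signal
format 16 (16-bit little-endian two's complement, the encoding of PTB-style
diagnostic records; other formats are rejected with a clear error) and bare
one-column CSV traces. A case-insensitive `Smoker: yes/no` field in the
header comments supplies the class label; anything else maps to `unknown`
rather than an error, because clinical headers are routinely incomplete.

Two denoising options are provided. The FIR band-pass (default 0.5–40 Hz,
order 256) is applied forward–backward, so it is zero-lag: R-peak positions
are not shifted, at the cost of squaring the magnitude response. Wavelet
denoising decomposes with db4, soft-thresholds detail coefficients at the
universal threshold `sigma * sqrt(2 ln N)` with `sigma` estimated from the
finest detail level by MAD, and reconstructs. For clean synthetic input the
pipeline default is no filtering.

## QRS detection

R peaks are found with the classic slope/amplitude/width recipe: 5–15 Hz
band-pass, five-point derivative, squaring, 150 ms moving-window
integration, then dual running signal/noise peak estimates (EMA weight
0.125) with detection threshold `noise + 0.25 * (signal - noise)`, a 200 ms
refractory period, and a search-back pass triggered when no beat has been
accepted for 1.66 times the running R-R average. Detections are refined to
the local maximum of the band-passed signal within ±50 ms. All statistics
are relative, so the detector is exactly invariant to positive amplitude
rescaling. The first 2 s seed the threshold estimates and are excluded from
the reported peaks; evaluations against ground truth therefore consider
only true peaks after that warmup.

## Reduced binary patterns

The RBP feature maps a trace to bits by order comparisons at index distance
`alpha` (`bit[i] = 1` iff `x[i] > x[i+alpha]`; ties give 0; `alpha = 1` is
the basic adjacent comparison), groups bits into `m`-bit words read MSB
first, and uses the relative frequency of the `2^m` possible words as the
feature vector. Words are taken from overlapping windows (stride 1) by
default — this maximizes the word count on short records — with the
non-overlapping variant (`stride = m`) available. The vector is
value-indexed (entry `v` is the frequency of word `v`) so attributes are
comparable across records; a rank-sorted orientation (frequencies sorted
descending) is available as a config switch. Because only order relations
enter, the feature is invariant under any strictly increasing amplitude
transform — which also means it is blind to pure level shifts applied to a
whole record.

## Wavelet features

Each R-R cycle is linearly resampled to a fixed length (default 284
points), cut into three parts (default 85/156/43), and the first and last
parts of the same cycle are concatenated into one segment (default 128
points), discarding the mid-cycle region. Consecutive runs of four
segments form a group; each segment of a group is transformed with an
n-level DWT (default db4, level 4) and the level-n approximation
coefficients are concatenated in segment order (all detail levels can be
included instead). The transform uses periodization mode, which makes it
exactly orthogonal: perfect reconstruction and Parseval energy conservation
hold to machine precision, and the admissible level is
`floor(log2(segment_len))`. A second segmentation preset uses 256-point
cycles with 169/85 pre/post cuts, giving 254-point segments; the pre and
post counts are the configuration's primitives and the segment length is
their sum. Per-segment transformation (rather than one DWT over the
concatenated group) is the default because it yields a fixed-length vector
whose blocks align across groups; the single-DWT variant is switchable.

## SOM clustering

The map is a 1 × c line of prototype vectors, so the number of map units is
exactly the number of learning subsets requested. Training is online: draw
a sample (seeded RNG), find the best-matching unit (nearest prototype,
Euclidean, ties to the lowest index), and pull every prototype toward the
sample with a Gaussian neighborhood weight. The learning rate decays
linearly from 0.5 to 0 and the radius from c/2 to 0.5 grid units. The last
10 % of steps update the BMU only: this convergence phase lets each
prototype settle at the centroid of its receptive field and removes the
shrinkage bias the neighborhood kernel would otherwise leave (without it,
the trained quantization error can exceed that of a lucky initialization).
Prototypes are initialized from distinct data rows. Empty clusters are
legal at assignment time; downstream simply trains no network for them.

## Backpropagation networks

Each learning subset trains a sigmoid MLP (default one hidden layer of
`max(8, round(sqrt(d)))` units, single sigmoid output, 0.5 threshold) by
full-batch gradient descent on mean squared error, weights initialized
uniformly in [−0.5, 0.5] from the seed. Full-batch descent was chosen for
bit-exact reproducibility; there is no momentum, regularization or early
stopping. Features are standardized per attribute with training-split
statistics before both the SOM and the networks — RBP vectors are sparse
and scale-skewed, and wavelet coefficients span orders of magnitude.
Analytic gradients agree with central finite differences to ~1e-10
relative; a subset containing one class trains with a warning and converges
to a constant output.

## Decision rules and evaluation protocol

Records are split 60/20/20 into train/validation/test, stratified by class
and seeded. Each network is scored on the shared validation split. The
majority rule takes the per-sample vote across all networks, breaking exact
ties with the vote of the network with the best validation accuracy; the
best-learning-subset rule adopts that network's output wholesale (ties to
the lowest index). With a single cluster the two rules coincide by
construction. Reported accuracies are always held-out test accuracies. The
grid evaluator sweeps (m, alpha) for RBP or (n, c) for the wavelet
pipeline, refitting the entire system per cell with a derived seed;
invalid combinations (e.g. a DWT level past the admissible bound) leave a
NaN cell and the sweep continues.

## Synthetic cohorts

The generator synthesizes each beat as five Gaussians (P, Q, R, S, T) at
fixed fractions of the beat period, a fixed-template simplification of the
Gaussian-wave ECG models used in simulation studies; beat periods carry
±3 % uniform jitter, and traces add a 0.3 Hz sinusoidal baseline wander and
white noise. True R-peak positions are returned exactly. Default study
conditions: 200 records per class, 500 Hz, 20 s, heart rate N(70, 5) bpm,
noise 0.05 mV, wander 0.1 mV. The class effect applied to the "smoker"
class is an ST-segment level shift of −0.15 mV (boxcar between the S and T
waves) plus a 20 % T-amplitude reduction — the repolarization morphology
reported in clinical observations of smoking; the magnitudes are simulation
parameters, not physiological claims. The end-to-end evaluation uses the
wavelet feature by default: the simulated effect is an amplitude change,
and the RBP feature's monotone-transform invariance makes it deliberately
insensitive to pure level shifts.

What the synthetic cohort does not emulate: realistic heart-rate
variability spectra, arrhythmia, electrode-motion artifacts, inter-subject
template variability beyond heart rate, or multi-lead structure. Passing
the power/null checks therefore demonstrates that the pipeline's machinery
is correct and well-calibrated (it finds a known morphological effect and
does not hallucinate one under the null), not that any particular accuracy
will transfer to clinical recordings.

## Problem sizes and determinism

The default test-suite and acceptance runs use: the full 200-per-class
cohort for the power/null evaluation; 20 noisy records (≈ 410 beats) for
detector recovery at 10 dB SNR; 1800 random sequences for the RBP oracle
comparison; 50 random groups for the DWT properties; and a 12-per-class
cohort for the two parameter sweeps (48 and 36 cells, one replicate per
cell). Every stochastic step — cohort generation, splits, SOM sampling,
weight initialization — draws from explicitly passed seeds, and identical
inputs give bit-identical models.

## Known limitations

- The WFDB dialect is deliberately minimal: format 16 only, one `.dat`
  file per record, no skew/checksum verification.
- The squared-error sigmoid MLP has local minima; seeds that train poorly
  on a given subset are possible, and no restart logic is attempted.
- With two networks the majority rule reduces to the best-validation
  network's output (any disagreement is a tie), so the two decision rules
  differ only for three or more non-empty clusters.
- The 169/85 segmentation preset produces 254-point segments; configs are
  validated on the pre/mid/post cuts summing to the cycle length, and no
  attempt is made to force power-of-two segment lengths.
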