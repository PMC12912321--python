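# Methods

## Problem and model

A standard 12-lead ECG measures the heart's electrical activity from ten
electrodes; wearable devices usually record a single lead. Because all leads
are projections of one underlying cardiac source, a single lead carries much
of the information needed to reconstruct the other eleven. The package
implements a multi-channel masked autoencoder (MCMA) for this task: the
single available lead is embedded at its own position in a 12×1024 frame
with the other 11 channels masked to zero (zero-padding; copy-padding, which
replicates the lead into all 12 channels, is kept as an ablation), and a
convolutional encoder–decoder maps that frame to a full 12×1024
reconstruction. Because the lead keeps its channel position, one model
serves all 12 possible input leads.

The network is a U-Net-style 1-D encoder–decoder. Each encoder level is an
MCBlock with two branches: a strided convolution (kernel 5, stride 2)
followed by layer normalization, GELU, a second unit-stride convolution and
instance normalization; and a pointwise strided projection. The branches are
summed and passed through GELU. Decoder levels (MCTBlocks) mirror this with
transposed convolutions so each level exactly doubles the temporal length
(output padding 1), and each encoder level's output is added to the matching
decoder level (skip connections; concatenation is available behind a config
flag). A final pointwise linear convolution emits 12 channels in mV —
unbounded, since no amplitude normalization is applied anywhere in the
pipeline (the signal path applies no filtering or scaling at all).

Training minimizes the mean squared error between the reconstruction and
the true 12-lead window. Each window is masked down to one lead per epoch —
drawn uniformly at random over the 12 leads ("arbitrary"), or held fixed for
the fixed-lead ablation. The published recipe is Adam at learning rate 1e-3,
batch size 256, 100 epochs, window length 1024. The best-validation-MSE
weights are returned. Inference is definitionally `forward(zero_pad(x, i))`;
arbitrary-length signals are cut into 1024-sample windows (zero-padded
tail, e.g. a 5000-sample record becomes 5 windows with 120 padded samples),
reconstructed window-wise and stitched back.

## Implementation notes

The network, including all backward passes, is implemented directly on
NumPy in float32: convolutions as im2col + GEMM with a tap-loop fast path
for unit stride, the transposed convolution as the exact adjoint of the
strided convolution, and GELU in the standard tanh parameterization.
Gradients are exact for the computation graph as written; the test suite
verifies them against central finite differences (coordinate-wise for a
norm-free configuration, and as a directional derivative for the full
architecture, since parameters that feed a normalization layer include
exactly-null directions such as a bias immediately before layer norm).
Layer norm here normalizes each channel of each sample over the time axis
with a learned per-channel affine transform; instance norm applies the same
normalization without an affine term. Both are per-sample operations, so a
window's reconstruction is independent of its batch, and forward passes are
bit-reproducible. Weight initialization is He-scaled and seeded from the
model config; training is bit-reproducible given the config seed on one
platform.

The architecture figure in the source work does not enumerate channel
widths, and the hyperparameter-sweep supplement is not available; the
defaults here are widths (32, 64, 128, 256, 512) over 5 levels (bottleneck
512×32 for a 1024-sample window), fully configurable. Skip fusion defaults
to addition, which keeps encoder/decoder widths symmetric. The placement of
the two normalizations inside a block (LN after the strided conv, IN after
the second conv) is likewise a design choice the source only constrains to
"both are used in each block".

## Evaluation benchmark

**Signal level.** Pearson correlation (population moments, per Eq.-style
μ/σ definitions) and MSE between each reconstructed lead and the truth, for
every input lead × output lead pair: a 12×12 matrix per metric, averaged
over windows, with row means and a grand mean. Trailing padded samples are
excluded. A constant trace on either side of the correlation is degenerate
and scores 0 — an uninformative flat reconstruction earns no credit and
leaves the averages defined. Per-window metrics are averaged across windows
(rather than pooling samples per lead) to match per-recording table
semantics.

**Feature level.** Per-lead mean heart rate MHR(j) = 60(n−1)/(R(n)−R(1))
from detected R peaks; across the 12 leads the mean (MMHR), population
standard deviation (divisor = number of valid leads), max−min range, and
CV = SD/MMHR. Real leads see the same beats simultaneously, so tight
cross-lead agreement indicates physiologically coherent reconstructions.
Leads with fewer than two detected peaks are excluded (zero-filling would
corrupt the mean); with fewer than two valid leads the result is flagged
invalid. Heart-rate statistics need several beats, so the evaluation unit
is the full stitched recording, not the 2-s window. The detector is
Pan–Tompkins-style (band-pass 5–15 Hz, derivative, squaring, 150 ms
moving-window integration, adaptive signal/noise thresholds, 200 ms
refractory, fiducial refinement on the absolute band-passed signal so
inverted QRS complexes are handled); it is a plug-in seam — any callable
`(x, fs) -> RPeakTrain` may replace it, and reports should name the
detector used. When all per-lead rates coincide exactly the SD is returned
as exactly 0 rather than accumulating float rounding.

**Diagnostic level.** A 12-lead classifier is run on (a) the true 12-lead
record, (b) the zero-padded single lead, and (c) the generated 12-lead
record; per class, one-vs-rest precision, recall, specificity and
F1 = 2TP/(2TP+FN+FP) are computed, 0/0 cells scoring 0 (the convention that
prints 0.0000 for never-predicted classes), with unweighted macro averages.
The gain of the generator is (c) − (b) on the macro metrics. Trained
classifier weights are out of scope; any callable
`(12×L array) -> binary vector` plugs in. The shipped
`RuleBasedHrClassifier` is a synthetic stand-in that thresholds the lead-II
heart rate (bradycardia < 60 bpm, tachycardia > 100 bpm); reading only
lead II also makes the single-lead baseline degradation visible, since a
zero-padded non-II input leaves it blind.

## Synthetic data generator

The generator is the package's test bed: a rotating 3-D dipole whose
trajectory is a sum of five Gaussian waves (P, Q, R, S, T) in beat phase,
ECGSYN-like in spirit but with closed-form ground truth. Beat phase
advances 2π per RR interval; RR intervals are 60/HR perturbed by a
fractional jitter (clipped Gaussian). Leads I, II and V1–V6 are fixed
linear projections of the dipole through a classical Dower-style matrix
(shipped as a documented constant); III, aVR, aVL and aVF are *derived*
through the exact Einthoven/Goldberger identities, so at zero noise those
identities hold to machine precision — exactly the redundancy the
reconstruction method exploits, which makes "III from lead I" a learnable,
memorization-free target. Independent Gaussian sensor noise is added per
lead after projection, so the clean source still beats simultaneously
across leads, as the feature-level premise assumes. R-peak times and
rate-based labels (tachycardia > 100, bradycardia < 60 bpm) are known by
construction.

Study conditions (fixed defaults): 500 Hz sampling, 10-s records, heart
rate drawn uniformly from 50–110 bpm per record, RR jitter 0.02, overall
voltage gain 0.85–1.15 and T-wave gain 0.8–1.2 per record ("subject"
variability), sensor noise SD 0.02 mV; noise-free records are used where a
check requires clean ground truth. What the generator does **not** emulate:
pathological morphology (bundle-branch blocks, fibrillation waves), baseline
wander, electrode motion artifacts, or morphology variation between beats.
Tests passing on this data therefore demonstrate the machinery —
correct algebra, learnable cross-lead structure, end-to-end plumbing — not
clinical-grade reconstruction on real ECG.

## Problem sizes and numerical choices

The end-to-end learning checks run on a reduced problem chosen as a
CPU-scale counterpart of the published setup: channel widths
(16, 32, 64, 128, 256), 2000 training windows (500 simulated 10-s records,
4 unpadded windows each), 30 epochs, batch 32 (batch scaled down with the
dataset so the optimizer still takes ~60 steps per epoch), seed fixed.
Success criteria: final validation MSE below half its initial value, and
mean PCC ≥ 0.8 between reconstructed and true III/aVR/aVL/aVF on 200
held-out noise-free windows with lead I as input. `scripts/acceptance.py`
runs the same pipeline at 1000 windows / 20 epochs and additionally reports
signal/feature/diagnostic summaries on held-out data.

Other numerical choices: resampling uses a polyphase filter with the rate
ratio as a limited-denominator fraction, output length rounded;
normalization layers use eps = 1e-5; WFDB output is format 16 at gain
1000 ADC units/mV (1 LSB = 1 µV); checkpoint archives are zip files of raw
weight arrays plus JSON config/history, with an explicit format version.

## Known limitations

- Pure-NumPy training is single-threaded BLAS-bound; the full published
  recipe (87k windows × 100 epochs, batch 256) is out of desk scale, though
  expressible through the same configs.
- The R-peak detector is tuned for clean-to-moderately-noisy sinus rhythm;
  heavily pathological morphology would need a different plug-in detector.
- The rule-based classifier covers only rate-defined classes; morphological
  classes require an external trained classifier through the plug-in
  interface.
- The simulator's beat morphology is stationary within a record; models
  trained on it see less variability than real corpora provide.
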