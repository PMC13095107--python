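# Methods

This note records the scientific and numerical decisions behind the
package, in the spirit of a model-description appendix: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Signal model and preprocessing

A recording is a time-major µV matrix over the fixed 19-electrode 10-20
subset (Fp1, F3, C3, P3, O1, F7, T3, T5, Fz, Cz, Pz, Fp2, F4, C4, P4, O2,
F8, T4, T6), sampled at 256 or 1024 Hz. All analysis happens at 256 Hz;
1024 Hz input is reduced with a polyphase FIR low-pass (scipy's
`resample_poly`) and the output trimmed to `floor(n/4)` samples so the
length contract is exact for every input length.

Denoising assumes the diagnostically useful content lies in 0.5–32 Hz.
At 256 Hz an 8-level stationary wavelet transform (SWT, `sym9`) tiles the
spectrum so that the final approximation is exactly 0–0.5 Hz
(256/2⁹ = 0.5) and the two finest detail levels cover 32–64 and
64–128 Hz; those three bands are zeroed and the signal reconstructed.
Each channel is processed independently, symmetric-padded to a multiple of
2⁸ and truncated back after reconstruction. The operator is linear and
shape-preserving.

Two numerical facts worth knowing about the redundant SWT:

* zero-and-reconstruct is **not** an orthogonal projection. Applying the
  denoiser twice is identity to ~10⁻⁵ relative RMS for content well
  inside the pass-band, but content in the transition strips around
  0.5 Hz and 32 Hz is attenuated again on a second pass (percent-level
  changes). Tests therefore probe idempotence with core-band tones.
* stop-band suppression is limited by `sym9`'s transition width: on
  broadband noise the 32–128 Hz band retains ≈0.6% of its power and the
  0–0.4 Hz interior ≈0.05%, but the full 0–0.5 Hz band measures ≈2%
  because of the strip just below 0.5 Hz. Narrowband artifacts (50 Hz
  mains, sub-0.5 Hz drift) are attenuated by well over 20 dB, which is
  the behaviour the pipeline actually depends on.

Denoising quality is summarised per recording as MSE (µV²) and PSNR (dB),
with the PSNR peak defined as the maximum absolute amplitude of the raw
signal; identical signals report infinite PSNR. 1024 Hz recordings are
down-sampled before denoising.

## Windowing and image encoding

Denoised recordings are cut into contiguous, non-overlapping 5 s windows
(1280×19); a trailing partial window is discarded. Each window is min–max
quantized independently to 8 bits (`round(255·(v−min)/(max−min))`;
a constant window maps to 0), making the encoding invariant to affine
amplitude changes of the window — deliberate, since clinical gain varies
by subject and session. The quantization scale is kept for audit, and
images are stored as PNG by default (bit-exact) with a maximum-quality
JPEG dialect for compatibility; the grey plane is replicated to three
identical channels on disk and collapsed on load. The classifier consumes
the single-plane image as a float tensor mapped to [−1, 1]; centring the
input speeds early convergence and loses no information.

## Classifier

The network is four feature-extraction blocks of [valid 3×3 convolution
with 32 filters, stride 1 → ReLU → 2×1 max-pool], dropout 0.25 after
blocks 2 and 4, then flatten → dropout 0.5 → dense softmax over 3 classes.
With a 1280×19×1 input the pool only halves the time axis, so the
electrode axis survives all four blocks (19→17→15→13→11 by convolution
margins alone); a 2×2 pool would exhaust it. Valid padding and stride 1
are used throughout; all shapes and parameter counts are exposed by the
architecture descriptor.

Training is Adam (lr 10⁻³ default) on categorical cross-entropy, batch
size configurable (the reference operating point is 128; small scaled-down
datasets use smaller batches so an epoch still contains a useful number of
gradient updates). A fraction (default 10%) of the *training* data — never
an external test fold — is held out to monitor validation loss; training
stops when the loss fails to improve by ≥0.001 for 15 consecutive epochs
and the best-validation weights are restored. No class weighting is
applied. Given identical data, config and seed, training histories are
bitwise reproducible.

The engine is pure NumPy/BLAS: convolutions run as im2col matmuls with
per-layer buffers reused across batches; the first layer skips the input
gradient; gradients were validated against an exact float64 reference
implementation. Inference applies no dropout and is batch-size invariant
up to float reordering of the argmax-irrelevant kind.

## Evaluation

Class order is fixed (HS, MCI, AD). For one target class the 3×3
confusion matrix collapses to TP (diagonal cell), FN (row remainder), FP
(column remainder), TN (all other cells), and

    ACC = (TP+TN)/total·100   SEN = TP/(TP+FN)·100
    SPE = TN/(TN+FP)·100      FPR = FP/(FP+TN)·100

FPR is computed as `100 − SPE`, which is algebraically identical and keeps
the identity exact in floating point. "Multiclass" values are unweighted
macro averages; a class absent from a fold propagates as a flagged
undefined value, never as a silent zero. Fold summaries report the mean,
sample SD (n−1) and a t-based 95% CI. ROC/AUC is one-vs-rest per class
with trapezoidal integration (verified against the Mann–Whitney identity).

The 10-fold split is uniformly shuffled and **not** stratified (fold
class-composition follows the hypergeometric law, and the tests check
that). The subject-wise protocol removes *all* segments of one subject
from training and scores that subject by the fraction of their own
segments predicted correctly; train/test identity disjointness is asserted
at run time in both protocols rather than assumed.

Model comparison over paired fold values uses (a) the classical paired
t-test with n−1 degrees of freedom and (b) an exact two-sided Wilcoxon
signed-rank test: zero differences dropped, midranks for tied absolute
differences, and the null distribution of the signed-rank sum built by
convolution over doubled ranks — arithmetic identical to enumerating all
2ⁿ sign assignments, feasible for n ≤ 25 and verified against brute-force
enumeration. Ten same-signed pairs give the familiar floor p = 2/1024 =
0.001953. (scipy's exact mode declines ties; this implementation is the
package's own and is cross-checked against scipy when no ties exist.)

## Synthetic data

The generator emulates the statistical structure of clinical three-class
EEG. Each subject's clean signal is a sum over the canonical rhythm bands
(delta 0.5–4, theta 4–8, alpha 8–12, beta 13–32 Hz) of band-pass-filtered
white noise (8th-order Butterworth, filtfilt), normalized to unit variance
per channel and scaled by `amplitude_µV × band_amp × channel_weight`. The
default class signatures follow the EEG slowing gradient of dementia:

| class | delta | theta | alpha | beta | spatial emphasis |
|-------|------:|------:|------:|-----:|------------------|
| HS    | 0.5   | 0.7   | 3.0   | 0.8  | alpha posterior (O/P ×1.5) |
| MCI   | 0.8   | 3.0   | 1.0   | 0.5  | — |
| AD    | 3.0   | 1.2   | 0.4   | 0.3  | delta frontal (×1.3) |

with a base amplitude of 10 µV and a single lognormal gain per subject
(σ = 0.2) so subjects are internally coherent — the property that makes
leave-one-subject-out genuinely harder than segment-wise k-fold.
Artifacts are added on top: a common-phase 50 Hz mains sinusoid (20 µV),
sub-0.5 Hz drift (50 µV at 0.2 Hz, per-channel phase), raised-cosine blink
transients (100 µV, 0.4 s, 12/min, spatially dominated by Fp1/Fp2), and
white sensor noise (3 µV SD). Recordings default to 300 s at 256 Hz;
sampling rates can be cycled per subject to exercise down-sampling.

What the generator does **not** emulate: non-stationarity within a
recording, inter-channel correlation structure beyond shared band
spectra, age/sex-conditional EEG differences (demographics are manifest
metadata only), and pathological transients. Passing the end-to-end tests
therefore demonstrates that the pipeline recovers class-conditional
spectral structure when present and finds nothing when absent — not that
it attains any particular accuracy on clinical data.

## Study-scale choices in the test suite

The full separable-data run uses 12 subjects per class × 60 s recordings
(432 windows) with batch size 12 and 3 training epochs per fold — on this
cleanly separable data the network converges within 2–3 epochs, and an
epoch contains ~32 gradient updates, comparable per-update exposure to the
reference operating point on the full-size data. The null-data control
uses the same training settings with 30 s recordings; chance-level
behaviour is insensitive to recording length. Unit tests for training
mechanics run on reduced input shapes (e.g. 64×19) for speed; the
full-size behaviour is covered by the end-to-end runs.

## I/O conventions

The matrix dialect is a whitespace-delimited grid (one row per sample, 19
canonical columns, `%.6f`) plus a JSON sidecar (subject, label, fs,
channels); round-trips are exact to 10⁻⁶ µV. The EDF dialect reads
through mne and writes with a minimal built-in encoder (1 s records,
16-bit quantization over each channel's floor/ceil-rounded physical
range), so EDF round-trips are exact to the quantization step
(range/65535) and recordings must contain whole seconds. Channel order is
permuted to canonical on every read; mismatched electrode sets fail with
the offending labels named.
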