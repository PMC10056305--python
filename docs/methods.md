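# Methods

## Pipeline overview

The package implements single-beat ECG biometric identification in five
stages: (1) band-limiting, (2) QRS detection and beat verification,
(3) fixed-length cycle segmentation, (4) time-delay phase-portrait
construction, (5) CNN classification, plus a factorial experiment over
the portrait hyperparameters (time delay τ, grid partition r).

## Signal conditioning

Two zero-phase Butterworth filters are applied forward and backward
(`scipy.signal.sosfiltfilt`): a 1 Hz high-pass removing baseline wander
and a 40 Hz low-pass suppressing noise. Each pass is order 2, so the
effective magnitude order is 4. Zero-phase ("anti-causal") filtering is
used so R-peak timing is not shifted; a symmetric pulse keeps its peak
to within one sample.

QRS detection follows the Pan-Tompkins chain — 5–15 Hz band-pass,
derivative, squaring, 150 ms moving-window integration — with adaptive
signal/noise thresholds (running estimates updated at 0.125/0.875), a
200 ms refractory period, and a search-back pass at half threshold when
the gap since the last beat exceeds 1.66× the recent average RR. The
detector output is snapped to the local absolute maximum of the
band-limited ECG within ±50 ms, so the fiducial is the R peak and the
35%/65% cycle split is reproducible.

Beat verification keeps a fiducial iff both adjacent RR intervals are
within ±20% of the record's median RR and its ±100 ms QRS window
correlates ≥ 0.8 with the median QRS template. The first and last
fiducials lack one adjacent RR and are always dropped. These thresholds
are package defaults (exposed as module constants), chosen as common
ectopy/false-positive screens; they are deliberately conservative on
clean data.

Cycle segmentation uses one fixed cycle length per record — the median
RR in samples — rather than per-beat RR, so all of a subject's portraits
derive from equal-length segments. Each window spans
`[f − round(0.35·L), f + L − round(0.35·L))`; windows that overrun the
record are dropped. A recording is screened in iff it lasts ≥ 100 s and
retains ≥ 125 verified beats.

## Phase portraits

Order of operations: upsample ×10 (Gaussian interpolation) → min-max
normalize to [0, 1] → delay-embed → rasterize → block-resize.

* **Gaussian interpolation**: kernel σ = 0.5 original sample periods,
  truncated at ±4σ, weights renormalized to sum to 1 at each query
  point. The signal is extended past both ends by linear extrapolation
  of the terminal sample pairs, which makes the interpolator exact for
  affine signals (and therefore harmless at beat boundaries); constant
  input maps to constant output.
* **Delay conversion**: τ in ms is converted to samples at the upsampled
  rate, `tau_samples = round(τ · fs · 10 / 1000)`, so all sweep delays
  (2–36 ms at 1 kSa/s) are exactly representable.
* **Rasterization** marks only the sample points (no line segments
  between consecutive points): at the ×10-upsampled rate consecutive
  embedded points are near-adjacent, and gap cells can appear only on
  the steepest QRS slopes. This is accepted and documented; its visible
  consequence is that at high grid densities the outer QRS loop may be
  locally broken while the slower P/T loops stay closed.
* **Conventions**: column = `min(floor(x·r), r−1)`; row 0 is the top of
  the image (`row = r−1 − min(floor(y·r), r−1)`). Classification is
  orientation-invariant as long as the convention is consistent.
* **Resize** is nearest-neighbour block replication (each cell becomes a
  (p/r)² block), keeping portraits strictly binary and preserving the
  occupied fraction exactly. `p` must be a multiple of `r`.

Useful invariants (all tested): portraits are invariant to affine
amplitude transforms of the beat; reversing the beat in time transposes
and reflects the grid; refining the partition never uncovers an occupied
cell; rasterization agrees with a brute-force point-in-cell oracle.

## Networks and training

Two architectures are described declaratively (`NetworkSpec`) and
instantiated by a compact NumPy backend written for this package
(im2col convolution, max pooling, fully connected layers, inverted
dropout, softmax/cross-entropy head, Adam). Backpropagation is verified
against central finite differences in the test suite, and the parameter
totals of the instantiated models are enumerated independently of the
counting formula.

* Original network (256 × 256 × 1 input): conv 12×12/s4 → pool 2×2/s2 →
  conv 5×5/p2 → pool 3×3/s2 → three 3×3/p1 convs (384, 384, 256
  channels) → pool 3×3/s2 → FC 12544-4096-4096-classes. At 115 classes:
  72,362,963 weights. The published layer table lists the fifth conv's
  input as 256 channels while the preceding layer emits 384; this is
  treated as a typo (the fifth conv is 384→256, the AlexNet convention),
  the only reading that reproduces the printed weight total.
* Scaled-down network (32 × 32 × 1 input): conv 5×5 → pool 2×2/s2 →
  conv 2×2 → FC 5408-1024-1024-classes. At 115 classes: 6,711,251
  weights.
* Blank padding cells in the published tables are read as padding 0, and
  the first pooling layer follows the table (2×2 stride 2) rather than
  canonical AlexNet (3×3).
* Softmax is folded into the loss during training; inference applies it
  explicitly so probability rows sum to 1.

Training: Adam (lr 1e-3, batch 32 — unspecified upstream, standard
small-image defaults), cross-entropy, dropout 0.5 on the FC hidden
layers, 75 epochs by default, He initialization. All randomness (init,
per-epoch shuffling, dropout) draws from streams derived from the
experiment seed, so whole sweeps are bit-reproducible. The chronological
100/25 per-subject split is never shuffled across the boundary.

The sweep runs one training per (τ, grid) cell — 10 × 5 = 50 cells by
default — regenerating portraits per cell; a failing cell is recorded
with its reason and never aborts the sweep. Accuracy traces are
summarized over epochs 16–30, 31–45, 46–60 and 61–75 (1-based,
inclusive; each stage average is the arithmetic mean of its 15 epochs).

## Synthetic cohort generator

Each subject's beat is a sum of five Gaussians (P, Q, R, S, T); there is
no U wave, which matches the loop structure the portraits are expected
to show. Per-subject parameters are drawn once from plausible lead-I
ranges (not fitted to any dataset): R amplitude 0.8–1.5 mV, P 0.05–0.2,
T 0.1–0.4, Q and S −0.3 to −0.05 mV; Gaussian σ 5–14 ms for the QRS
waves and 20–45 ms for P/T; mean RR 0.7–1.0 s. Wave centers are spaced
so adjacent waves overlap negligibly at each other's peaks (< 1% of the
R amplitude), which makes the noiseless-beat contracts exact by
construction. A record adds per-beat RR jitter (Normal, sd 30 ms),
respiration-like amplitude modulation (depth 0.05 at 0.25 Hz), a 0.2 Hz
sinusoidal baseline (0.1 mV) and white noise (sd 0.02 mV). A global
cohort seed splits into per-subject sub-seeds through a counter scheme,
so cohorts are reproducible and extensible.

What the generator emulates: per-subject morphology differences,
beat-to-beat loop scaling/shifting, baseline wander, broadband noise,
and exact ground-truth R locations for scoring detection. What it does
not emulate: pathological beats (ectopy, bigeminy), realistic HRV
spectra, electrode artifacts, drifting morphology, or the inter-subject
similarity structure of a real clinical population. Synthetic subjects
are substantially easier to separate than real ones, so a passing
end-to-end test demonstrates that the pipeline is wired correctly and
can recover known structure — not that real-database accuracy is
reproduced.

## Problem sizes

The default test and acceptance runs are sized for a single CPU: the
end-to-end identification check uses 10 subjects × 125 beats (100 train
/ 25 validation), the scaled-down network, τ = 24 ms, r = 32 and 30
epochs; the delay/grid ordering check uses 8 subjects with a 15/10
split, 2 epochs, averaged over 3 seeds; QRS recovery is scored on
10 × 125 beats. The full 50-cell sweep at 75 epochs and the original
256-px network are supported but are long-running configurations meant
for real experiments.

## Known limitations

* The point-only rasterization can break the fastest QRS loop at high
  grid densities (see above).
* The WFDB reader/writer covers the format-16 dialect (text header,
  int16 samples, gain/baseline in physical mV, case-insensitive lead
  match) — enough to round-trip this package's records and read
  typical single-file records, not the full format family.
* Screening implements only the objective duration + beat-count rule;
  judging "serious corruption" of real recordings is left to the user.
* The scaled-down network requires 32 × 32 images and the original
  network 256 × 256; the experiment config validates the pairing rather
  than adapting layer sizes.
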