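# Methods

## The detection problem

Post-HI seizures (HAS) are defined clinically and preclinically as
repetitive stereotypic discharge trains of duration ≥ 10 s and amplitude
> 20 µV in at least one EEG channel. The pipeline classifies fixed-length
EEG segments (canonically 51,302 samples at 256 Hz ≈ 3.34 min, centered on
the seizure) as HAS vs. non-HAS, where non-HAS deliberately includes
everything else the electrode sees: background activity, movement
artifacts, and electronic noise. Three detectors share this task and differ
only in their input representation (scalogram image, dominant-feature
matrix, raw signal).

## Synthetic cohorts

The original recordings are not deposited, so `hasdetect.synth` generates
cohorts that reproduce the statistical features the classifiers exploit.

**Background.** Gaussian noise shaped in the frequency domain to
1/f^β above a 0.5 Hz knee. Term: β = 1.0, band edge 30 Hz, continuous.
Preterm: β = 1.6, band edge 15 Hz, multiplied by a burst/interburst gate
(bursts 4–10 s at gain 1, interburst 3–8 s at gain 0.25, 0.5 s raised-cosine
transitions) modeling discontinuous immature EEG. Default RMS 12 µV, well
below the 20 µV seizure floor.

**HAS events.** A sharpened quasi-sinusoid (0.7·sin + 0.3·sin³, which keeps
the fundamental dominant while peaking the discharges) whose instantaneous
frequency drifts from the upper to the lower part of a delta band (term
0.5–4 Hz, preterm 0.5–2.5 Hz) with slow seeded jitter. Two envelope modes:
`waxing` (default) — Tukey window times a sinusoidal modulation, the
classic waxing/waning seizure profile; `peaked` — a single Gaussian
crescendo–decrescendo (σ = duration/5) whose maximum defines an
unambiguous center (used by the centering-recovery tests, see below).
Waveform peak equals the requested amplitude exactly. Durations 10–60 s,
amplitudes 60–300 µV by default; a `contrast` factor scales amplitudes as
the separability dial.

**Hypothermia and sham.** Brain cooling is modeled purely as multiplicative
suppression (factor 0.6) of HAS amplitude and rate in G2 — no temperature
simulation. G3 (sham) receives no seizures, ever; a config requesting them
is rejected.

**Artifacts.** Movement: integrated noise detrended to a slow (< 2 Hz)
non-rhythmic lurch. Electronic: broadband noise plus a 50 Hz mains
component. Amplitudes 50–250 µV — deliberately overlapping the seizure
range so that segment energy alone cannot separate the classes.

**Composition.** Per-group segment targets are the reference cohort's
per-channel counts (7/14/5/14 animals; 3955 HAS and 27,060 non-HAS in
total) scaled by a single `size_factor`; the 1:6.84 class ratio is thereby
preserved at any scale. The desk default (0.032) yields ≈ 994 segments.
Generation is a pure function of (config, seed): seed sequences are spawned
per (group, animal, channel).

**What the generator does not emulate:** spatial structure across
electrodes, sleep-state cycling, post-insult time course of seizure rate,
amplitude nonstationarities of real dural recordings, or realistic artifact
morphology beyond the two stylized kinds. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the detectors
learn the intended spectral/morphological contrasts — not clinical-grade
performance on real EEG.

## Power trend and centering

The monitoring trend is one rectangular-window periodogram per complete
minute, power summed over 1–20 Hz inclusive, reported as 20·log₁₀(power)
dB (the convention used for long-term EEG intensity plots); trailing
partial minutes are dropped. Seizures are marked at this 1-min granularity,
so centering refines the location: the ±1 min excerpt around the marked
minute's midpoint is zero-meaned, normalized to unit peak (a scale-
equivariant step that keeps the 10th power in floating range without moving
the argmax), raised elementwise to the 10th power, and swept with a moving
median absolute deviation of window 8000 samples (centered windows,
shrinking at the edges; even-window medians average the two middle order
statistics). The argmax — earliest index on ties, excerpt midpoint if the
trace is globally flat — is the seizure's center of weight. Segments are
cut as [center − ⌊L/2⌋, center + ⌈L/2⌉), zero-padded and flagged at record
edges; with L = 51,302 this reconciles "100 s either side" with the printed
segment length by treating the latter as authoritative.

The movmad is computed exactly by an incremental sorted-window algorithm
(numba): binary-search insert/remove per slide, median from the middle of
the sorted buffer, MAD by an outward two-pointer merge around the median.
It agrees bit-for-bit with direct per-window recomputation (enforced in the
tests) and processes a 2-min excerpt in under a second.

**Localization precision.** Empirically — and confirmed against the
brute-force oracle, so it is a property of the procedure, not of the
implementation — the 10th power concentrates the excerpt's mass so strongly
that the movmad trace saturates (exact ties) over every window position
fully covering a burst shorter than the 8000-sample (31 s) window: such
bursts are localized only to window scale (a few seconds), which is
immaterial for 3.34-min segments but matters for ±1 s checks. Bursts whose
high-amplitude span exceeds the window, with a single envelope maximum, are
recovered to well within ±1 s at ≥ 10× contrast; the recovery tests
therefore use 60–90 s `peaked`-envelope seizures, and a separate test pins
the short-burst behavior (center inside the burst core).

Non-HAS segments are sampled uniformly over all window positions that lie
inside the record and intersect no annotated HAS interval; artifacts are
allowed by design.

## Front-ends

* **Scalogram**: Morlet ("morl") CWT of the zero-meaned segment over scales
  1:5:500 (100 scales). The pseudo-frequency map F_c·f_s/scale with
  F_c = 0.8125 reproduces the 0.42–208 Hz endpoints at 256 Hz. Magnitudes
  are min–max normalized per image, mapped through a fixed colormap (jet),
  and resampled to 500×333 RGB (bilinear; 300 dpi metadata) — identical
  inputs give byte-identical PNGs. Sign is discarded in images only.
* **Wavelet–Fourier matrix**: columns are signed CWT coefficients at scale
  80 (≈ 2.6 Hz, mid-delta), the 0.2–4.5 Hz band-limited reconstruction
  (real-FFT masking, inclusive band edges, conjugate symmetry by
  construction), and the untouched raw segment.
* **Raw**: the segment itself.

## Classifiers

The architecture language (`hasdetect.arch`) records conv/pool/dense
stacks and propagates spatial sizes with the floor rule
out = ⌊(in + 2·pad − k)/stride⌋ + 1, erroring with the offending layer when
a dimension collapses. The 17-layer WS-CNN (7 conv blocks of 32–256
filters, kernel 3/stride 1/pad 1, each with batch-norm and ReLU; 7 pools of
kernels [3,2], 2, 3, [3,2], [2,3], [4,5], 2 at stride 2; flatten 1536;
dense 24; dense 2; softmax) reproduces every published layer size. The
14-layer WF and 1D schedules are this package's designs (the original
appendix tables are not available): 6 conv blocks with 5 time-axis pools of
kernel/stride 4 — never more than a 4× reduction per pool, and the 3-column
feature axis of the WF input is preserved until the dense head.

Training (`hasdetect.nn`) is a numpy CNN engine written for this package:
im2col convolution, batch normalization with running statistics,
overlapping max-pooling, dense layers, softmax cross-entropy, and RMSProp
(lr 1·10⁻³, squared-gradient decay 0.9, ε 1·10⁻⁸), float32 throughout,
bit-reproducible under a fixed seed. Validation uses a stratified 90/10
split of the training partition (the original split fraction is unstated);
batch size defaults to 32 (unstated); no denoising and no augmentation
anywhere. Inputs are scaled once by a constant estimated from the training
set (1/255 for image rasters, the global standard deviation for
time-series) — a numerical-conditioning step, not preprocessing of the EEG.
Gradient correctness is enforced by finite-difference tests, and the conv
forward pass against an independent 2-D correlation oracle.

**Scale profiles.** `paper`: 51,302-sample segments, 500×333 images, full
filter counts, 60 epochs. `desk`: 2560-sample (10 s) segments, 32 scales
rendered at 64×48, reduced filter counts, and for the scalogram net a
4-conv-block schedule (the full 7-pool schedule cannot propagate through a
48-pixel raster); six epochs suffice on the synthetic cohorts. Desk
problem sizes — ~1000 segments, 5 folds, 3 detectors — keep a full
cross-validated comparison within minutes on one CPU.

## Evaluation

Leave-one-group-out schemes test on G4, G2, G1 in turn, training on the
remaining groups with (study #1) or without (study #2) the sham controls;
study #3 is class-stratified 5-fold cross-validation with a fixed seed so
folds are identical across detectors (the original used a proprietary
generator reset; we guarantee our own seeded reproducibility, which is what
reproducibility requires functionally). With the reference composition the
builders reproduce the published partition sizes exactly (e.g. training
20,491 at ratio 1.95; per-fold test 6203/791/5412). Precision is
implemented as TP/(TP+FP): the published tables satisfy this definition
throughout, against the prose's "TPs among TP + FN". Zero-denominator
ratios are NaN, never 0 or 100. ROC curves sweep the unique scores;
AUC is trapezoidal and equals the pairwise Mann–Whitney statistic (property
test); mean ± SD bands average vertically over a fixed FPR grid.

A trivial energy-threshold baseline (best training-accuracy RMS threshold)
anchors the scaled-down learning tests: the synthetic artifacts give it a
ceiling the CNNs must reach or beat.

## Known limitations

* The 14-layer WF/1D schedules are plausible reconstructions, not the
  original appendix architectures.
* The Morlet centre frequency is fixed at 0.8125 to match the printed
  0.42–208 Hz endpoints; the "2.56 Hz at scale 80" remark would imply 0.8
  and is reported by `morlet_pseudo_frequency(80)` as 2.6 Hz.
* Scalogram images are rendered from coefficient magnitudes; whether the
  original images used signed coefficients is unknown.
* The engine is CPU-only and desk-scale by design; full-scale (51,302 ×
  333×500 × 60-epoch) training is expressible but not practical without
  hardware acceleration.
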