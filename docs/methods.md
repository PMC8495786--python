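# Methods

## The pipeline

`tinamou` turns long autonomous-recorder (ARU) soundscape audio into a
per-species vocal-event database and survey-effort statistics.  The
processing chain is:

1. **Ingest.**  Survey WAV files (16 kHz mono, nominally 30-min sessions
   recorded 5:00–7:30 and 16:00–18:30) are preprocessed by (a) zeroing the
   first 5 s of each session-initial file — the recorder firmware writes a
   high-amplitude spike on wake, and muting must precede gain estimation —
   then (b) peak-normalizing to −2 dBFS, then (c) cutting overlapping 2-s
   analysis windows advanced by 0.25 s.  Trailing audio shorter than one
   window is dropped; the classifier needs fixed-length inputs.
2. **Spectrogram.**  Each window becomes a single-channel square image:
   magnitude STFT (Hann, 1,024-sample frames, 64-sample stride), a
   64-filter triangular Mel bank built *directly on the 900–2,900 Hz band*
   (the band that contains every tinamou fundamental at the study site),
   log compression `log(power + 1e-6)`, bilinear rescale to 512×512 px
   native, downsample to 256×256 for the CNN, per-image min–max
   normalization to [0,1].
3. **Classifier.**  Two identically structured CNNs — five conv blocks
   (32×7×7 stride 2, then 64×5×5, 128×3×3, 256×3×3, 512×3×3; bias-free,
   L2 1e-6 kernel+activity regularization, batch norm momentum 0.01, ReLU,
   2×2 max-pool after blocks 1–4), flatten → dense(256) → dropout(0.5) →
   softmax over the 12 classes (11 species + junk) — differing only in
   whether Gaussian-noise augmentation is applied.  Deployed models use a
   width divisor of 2 (half-width conv layers).  Class probabilities of
   the two submodels are arithmetically averaged ("the ensemble").
4. **Detection.**  Per recording, the probability sequence is smoothed
   (weights 1 / 0.5 / 0.5 over each window and its neighbours, boundary
   weights renormalized), windows with smoothed max probability < 0.85
   are dropped, the rest take the argmax label, and retained same-species
   windows whose intervals lie closer than 0.75 s merge into vocal
   events.  Junk-labelled windows are retained for review bookkeeping but
   never become events.
5. **Two-pass retraining.**  Reviewed positive windows from pass 1
   supplement the training set (per class the larger of a 2,000-clip cap —
   4,000 for junk — sampled without replacement, or the whole pool);
   pass 2 retrains with the same architecture and hyperparameters, the
   sole change being class-balanced batch generation; pass-1 confirmed
   windows are grandfathered and never re-queued for review.
6. **Ecology.**  Events chain into independent captures per species and
   site while consecutive gaps are under 1 h; capture rate is
   `captures / (recording_hours / 24) × 1000` (per 1,000 24-h trap-days);
   effort and cost multipliers compare total rates and total
   cost-per-capture between survey methods; occurrence frequencies are
   the element-wise mean of the terra firme and floodplain distributions;
   eBird comparisons filter checklists (stationary ≤ 150 min, traveling
   ≤ 0.5 km) and resample pseudo-checklists whose durations bootstrap the
   filtered empirical distribution.

## Interpretations where the design was open

* **"−2 dB maximum gain"** is read as peak normalization to −2 dBFS —
  the only reading consistent with "maximum".
* **Smoothed vs raw threshold.**  The 0.85 cut is applied to the
  *smoothed* maximum; smoothing is described as preceding the cut.
* **Eventization wording.**  Grouping is implemented as: runs of retained
  windows closer than 0.75 s merge; clusters at least 0.75 s from all
  others are separate events.  The gap is measured from end of one
  window-interval to the start of the next, treating each retained
  window as a 2-s interval.
* **Mel variant.**  HTK-style Mel (2595·log10(1+f/700)), filters built on
  the band edges; the 64 bins and ~485 STFT frames are stretched to the
  square image by bilinear interpolation, since a square 512-px image from
  64 bins admits no other consistent reading.
* **Output layer.**  The architecture table's final dense size is set to
  the number of classes (12); a 4-unit output cannot produce the 12-class
  probability vectors the detector consumes.
* **Width scale.**  The divisor applies to conv filter counts; the dense
  width is an explicit field.
* **Augmentation units.**  The dB offset (uniform in [0, −40] dB) is a
  pre-normalization intensity offset: on the [0,1]-normalized log image
  it subtracts `|o|/D` where `D` = 80 dB is the assumed image dynamic
  range, clipping at the floor — emulating a fainter call.  Gaussian
  noise intensity is likewise in dB of log-spectrogram jitter
  (std = intensity/D in image units).  Noise std 0.8 *in raw image units*
  is untenable: it reduces the noise-augmented submodel to near-chance
  and drags ensemble confidence below the 0.85 operating threshold,
  whereas the deployed noise submodel performed on par with its
  sibling.  A dB scale also makes the [0, 20] search range meaningful.
* **Epoch under balanced resampling** is defined as
  `ceil(largest class size × n_classes / batch_size)` batches; balanced
  batching has no natural epoch and this recovers the plain epoch length
  for a balanced dataset.
* **Optimizer** is Adam at the configured learning rate (0.0075); loss is
  categorical cross-entropy (single-label multiclass softmax).
* **Padding** is "same" everywhere, so the five-block stack maps
  256 → 8 px cleanly (trace: 256→128→64→64→32→32→16→16→8→8).
* **Ties** in argmax break toward the lowest class index, with a warning.
* **Zero-denominator metrics** (a class never predicted, or absent from
  the validation set) contribute 0 to the affected macro metric, with a
  warning; prAUC for a class with no positives is reported missing.
* **prAUC** uses the step-wise (interpolation-free) area
  `Σ (R_i − R_{i−1}) P_i`; linear interpolation in PR space is biased.
* **Capture-rate basis.**  The per-1,000-trap-day convention
  (`captures/(hours/24)×1000`) reproduces every printed per-species rate
  and total of the published effort table, so it is normative; the
  alternative "per 1,000 hr" phrasing found alongside it does not.
* **Lumping across sessions** treats the survey as continuous time; only
  the < 1 h criterion decides chain membership.

## The neural-network layer

No deep-learning framework ships with this package's environment, so the
network is a compact numpy implementation (`tinamou.nn`): im2col-based
strided convolution, batch normalization (moving-average decay
convention, momentum 0.01 ⇒ running statistics track the current batch
almost entirely), inverted dropout, 2×2 max pooling, dense layers, a
softmax cross-entropy head, and Adam.  All randomness flows through
explicit `numpy.random.Generator` objects, so training is bit-for-bit
reproducible from a seed.  Analytic gradients are verified against
central finite differences in the test suite.  It is deliberately
compact rather than fast, and targets the band-limited spectrogram
images of this pipeline at study scale.

One consequence of the published batch-norm momentum (0.01, in the
moving-average-decay convention) is that the running statistics used at
inference track the *last training batch* — a batch of augmented images
— which makes validation and deployment inference unstable at small
batch sizes.  After each epoch the trainer therefore recalibrates every
batch-norm layer's moving statistics over the clean (unaugmented)
training images ("precise BN"); the momentum value itself is left at
0.01 during training.

## The synthetic soundscape generator

The generator emulates the statistical structure the pipeline assumes,
not tinamou vocal anatomy:

* **Calls** are 2-s harmonic stacks (fundamental + 1–2 overtones) whose
  fundamental follows a piecewise-linear contour inside 900–2,900 Hz,
  under a raised-cosine attack/decay envelope.  Bundled templates are
  illustrative; no field measurements of per-species call structure are
  encoded.
* **Noise bed** is 1/f ("pink") broadband noise at −28 dBFS RMS — a
  realistic rainforest ambient level leaving ~25 dB headroom — and call
  SNR is defined in-band (900–2,900 Hz RMS ratio), matching the
  classifier's analysis band.  Scripted SNRs are uniform in [5, 15] dB
  (faint-but-audible to close-range).
* **Schedule**: AM/PM sessions with naive local clock times; event counts
  per recording are Poisson at programmed per-species rates; onsets
  uniform; calls clipped at file end keep their untruncated offset in the
  truth table; session-initial files carry a synthetic wake spike so the
  mute step is exercised.
* **Training clips**: one call per clip over fresh noise at random SNR
  with onset jitter; junk clips are noise at varied levels plus tonal
  distractors kept ≥ 150 Hz away from every template fundamental.

What passing these tests shows — and does not.  The synthetic species are
spectrally well separated, calls are stereotyped, and noise is
stationary; real tinamou choruses have overlapping heterospecific songs,
variable song types (notably *C. soui* and *C. variegatus*), rain and
wind nonstationarity, and distance-dependent degradation.  Recovery of
programmed rate orderings here validates the *plumbing and statistics*
of the pipeline (windowing, spectrograms, training, smoothing,
thresholding, eventization, rate estimation), not field-grade classifier
accuracy.

## Experiment scales

The pipeline-scale experiments (`tinamou.experiments`) use a reduced
problem size chosen as the smallest that leaves the statistics
identifiable: 4 species + junk; 10 sites (5 terra firme, 5 floodplain);
one day of two 360-s sessions per site (2 recorded hours, ≈ 28,660
windows); programmed rates {25, 50, 100, 200} events/hr — geometric
factor-2 spacing, because detected event counts compress at high rates
(calls closer than the 0.75-s gap merge, and a single-label classifier
degrades on windows holding overlapping calls), so tighter ratios do
not give an identifiable ordering with only four species; the lowest
rate still realizes ≥ 50 truth events in expectation.  96 training
clips/class; 32-px spectrograms (fft 256, stride 128, 32 Mel bins on
the same 900–2,900 Hz band); width divisor 4 (conv filters 8–128; a
divisor-8 net showed per-seed single-class training collapse);
augmentation shift ranges scaled by `input_px/256` so shifts keep their
meaning in seconds and Mel bins; ≤ 10 epochs.  Rate-order recovery is
scored by Spearman correlation between programmed rates and detected
vocal-event counts rather than 1-h-lumped captures: a 6-min session is
far shorter than the independence window, so lumped capture counts
saturate at sites × sessions and carry no rate information at this
scale.  The fixture two-pass supplementation uses caps of 300/600
(study caps 2,000/4,000 remain the module defaults) so the supplemented
set stays proportionate to the base set.

## Numerical details

* Spectrogram log floor ε = 1e-6 (of full-scale power), configurable.
* Bilinear interpolation (scikit-image, `order=1`, no anti-aliasing) for
  all image rescaling.
* Boundary smoothing renormalizes weights instead of zero-padding, so
  probability rows still sum to exactly 1 at file edges.
* Max-pool backward splits gradient equally among tied maxima.
* Chi-square expected counts are the comparison distribution scaled to
  the observed total (dof = k − 1); zero-expected cells are pooled with
  a warning.
* Duration-kernel jitter bandwidth is 5 % of the source interquartile
  range, configurable.
* All-zero waveforms are rejected by gain normalization (no finite scale
  factor); files shorter than the mute window are fully zeroed with a
  warning rather than rejected.

## Known limitations

* The numpy CNN is single-threaded BLAS-bound and unsuitable for
  full-resolution (256-px, width-2) training runs at realistic dataset
  sizes; the architecture builder constructs them, and shape/parameter
  accounting is tested, but routine training happens at fixture scale.
* The published first-pass performance tables and the field survey's
  absolute event counts depend on the original field audio and trained
  weights and are not reproducible here; what is reproduced is every
  desk-checkable consistency in the printed tables, plus the *direction*
  of the pass-1 → pass-2 improvement on synthetic data.
* The "estimated camera-trap captures" column of the published effort
  table follows from no stated formula and is not reproduced.
* eBird-style inputs are consumed from a simple tabular export
  (protocol, duration, distance, presence flags); no API access or
  taxonomy handling.
* A Bayesian hyperparameter search is out of scope; configured defaults
  are the deployed values, and a seeded random-search hook would slot
  into `TrainingConfig` without structural change.
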