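# Methods

This note records the model, the numerical conventions, the synthetic
data design and the open choices made while building `melstage`, in the
spirit of a methods appendix.

## Problem and scope

Five-class sleep staging (W, S1, S2, S3, REM; R&K stage 4 merged into
S3) of 30-s PSG epochs from two central EEG channels and one chin EMG.
The package covers feature extraction (MFCC), stream composition,
classification (CNN + peephole LSTM), evaluation, synthetic data
generation and a CLI. It does not attempt artifact rejection, EDF+
annotation parsing beyond stage extraction, class rebalancing, or
GPU-scale training.

## MFCC chain: conventions and their rationale

* **Pre-emphasis** `y(n) = x(n) − 0.97·x(n−1)` with the boundary
  `y(0) = x(0)`: the recurrence leaves n = 0 undefined; identity at the
  boundary is the common convention and keeps output length equal to
  input length.
* **Framing**: frame length `round(w·fs)` and stride `round(s·fs)`
  samples (round-half-to-even, so 0.5 s at 125 Hz gives 62 samples);
  frame k starts at `k·stride`; frames that would overrun the signal
  are not emitted. The emitted count obeys
  `floor((N − T)/stride) + 1` for `N ≥ T`, else 0 — property-tested
  against brute-force enumeration. Framing restarts at every 30-s
  epoch boundary, because streams are assembled per epoch; whether
  frames may straddle epochs is an interpretation choice and this one
  keeps every epoch's frame grid identical.
* **Windowing**: the symmetric Hamming form
  `0.54 − 0.46·cos(2πn/(T−1))`, endpoints 0.08, centre 1 for odd T.
* **Power spectrum**: zero-padded FFT, one-sided bins `k = 0..nfft/2`,
  `|X(k)|²`. The one-sided sum is used inside the filter bank; since
  every triangle lives in `[0, fs/2]` this loses nothing.
* **Filter bank**: M = 40 triangles with Mel-uniform edge frequencies
  snapped to integer FFT bins; filter m rises linearly to exactly 1 at
  its centre bin and falls to 0 at the next edge. Integer-bin edges
  make two properties exact (unit response at the centre frequency,
  and partition of unity on bins strictly between the first and last
  centres) and both are asserted in tests.
* **FFT length**: `nfft = max(256, next power of two ≥ frame length)`.
  A 40-filter bank needs 42 distinct integer bin edges below Nyquist;
  at the 64–128 Hz rates of central-EEG/EMG PSG a 64-point transform
  has only 33 one-sided bins, so the bank would degenerate. 256-point
  zero-padding is the smallest power of two that supports the default
  bank across all three rates, and keeps bank resolution comparable
  between the 125 Hz and 128 Hz layouts.
* **Log floor**: `ln(Σ|X|²H + ε)` with ε = 1e−10, so silent frames map
  to `ln ε` instead of −∞.
* **Cepstrum**: `C(n) = Σ_{m=1..M} s(m)·cos(πn(m−0.5)/M)`, n = 1..L,
  L = 13 (the conventional choice inside the usual 12–20 range). This
  is the standard DCT-II up to a factor 2, computed via `scipy.fft.dct`
  and checked against the direct cosine sum. `C(0)` — the overall log
  energy — is excluded; consequently the cepstra are invariant to a
  global amplitude scaling of the input (tested), and any information
  that only changes the broadband level of a channel is invisible to
  the features. This matters for the synthetic EMG design below.

A naive reference implementation (`melstage.reference`) recomputes the
whole chain from explicit O(N²) DFT sums, the five-case triangle
formula and direct DCT sums, sharing no code with the fast path; the
two agree to better than 1e−8 on random signals, which is asserted in
the test battery and recomputed by `scripts/acceptance.py`.

## Stream composition

Channels are polyphase-resampled (`scipy.signal.resample_poly`) to the
maximum channel rate before feature extraction, so all channels share
one frame grid — the minimal assumption that makes stacking
well-defined for the 128/64 Hz UCDDB layout. Per epoch, the L×frames
maps of the channels are stacked along the coefficient (height) axis in
channel order; a symmetric window of `context_epochs = 3` epochs is
concatenated along the frame (width) axis; the label is the centre
epoch's stage. Boundary epochs replicate the first/last epoch into the
missing context slots by default (keeping stream count equal to
hypnogram length); a drop policy is available. Which axis hosts
channels versus coefficients is not recoverable from the architecture
description alone; the choice here keeps time contiguous along one
axis for the convolutions and is isolated behind `StreamConfig`.
Per-stream standardization exists but is off by default, keeping the
literal feature chain primary (the synthetic study passes either way;
standardization converges faster).

Splitting is subject-wise (70/20/10 by largest-remainder allocation of
subjects, seeded): no subject contributes epochs to two partitions, so
held-out numbers measure cross-subject generalization rather than
within-night memorization.

## Classifier

Input streams are treated as one-channel 2-D images. Four conv units
(6×6, 5×5, 5×5, 2×2 kernels; leaky-ReLU slope 0.1), 'same' padding,
stride 1, 2×2 max-pooling after the first three units; the fourth unit
keeps its map. The conv output's width (time) axis becomes the LSTM
sequence axis and channels×height flatten into the per-step feature
vector — the minimal CNN→LSTM bridge. One 128-unit peephole LSTM layer
(diagonal peephole weights; input and forget gates peek at `C_{t−1}`,
the output gate at the current `C_t`); its final hidden state feeds a
dense softmax over the five stages. The hidden output gates the cell
state `C_t`, not the candidate `c_t`: gating the candidate would leave
the accumulated state write-only, so the conventional peephole
formulation is used.

Everything — im2col convolution, pooling, backprop-through-time, Adam
— is written in NumPy (float32 for training, float64 in
gradient-check tests; all layers verified against central finite
differences). Defaults: filter counts 8/16/16/32 were the first
choice, reduced to 6/12/12/24 to keep a full synthetic study in the
minutes range on one CPU (capacity is far above what the five-class
problem needs — the study reaches >90% held-out accuracy); Adam at
1e−3; batch 64; unweighted cross-entropy (no class weighting);
max_epochs 10 with early stopping patience 3, restoring the
best-validation-accuracy parameters; forget-gate bias initialized
to 1. All randomness (init, shuffling) derives from one config seed.
No dropout or batch normalization is used.

## Metrics

Per-class metrics use one-vs-rest TP/FP/FN/TN. Overall accuracy is the
trace over the total (equal to micro-averaged recall, asserted as an
identity test). Zero-denominator convention: precision/recall/F1 = 0
with a warning for a class never predicted / never present; macro
averages run over classes with nonzero true support, so a cohort
lacking a stage yields interpretable macro figures. κ raises on the
degenerate `p_e = 1` case. The TCI is computed on integer stage codes
of the discrete predictions (the only reading that is computable from
a classifier's output); its value depends on the fixed code order
`W=0..REM=4`, which is therefore part of the package contract.

## Synthetic data: what it emulates and what it does not

Per stage, EEG epochs are sums of band-limited random-phase sinusoids
plus Gaussian broadband noise (level 0.3): W = 10 Hz alpha; S1 = 5 Hz
theta; S2 = 13 Hz spindle bursts (raised-cosine amplitude modulation,
~0.3–0.6 Hz recurrence) over weak theta; S3 = high-amplitude ~1 Hz
delta; REM = mixed theta. EMG is modelled as stage-tone-scaled
first-differenced white noise (a +6 dB/octave muscle-band tilt) over a
fixed white sensor floor (0.25), with tone levels
W 1.0 / S1 0.6 / S2 0.5 / S3 0.3 / REM 0.2. The tilt is essential, not
cosmetic: the cepstra exclude `C(0)`, so a *level-only* EMG change is
mathematically invisible to the features, and the REM/S1 discriminator
(atonia) must appear as a change of spectral shape — which is also the
physiologically right picture, since real chin EMG rides on
stage-independent instrument noise.

Hypnograms follow a first-order Markov chain (per-30-s-epoch) with
mean dwell times of 5–10 epochs and an S2-heavy stationary
distribution; the matrix is a documented constant, not a fitted claim.
Epochs are generated independently (real stage transitions are
discontinuous too). Not emulated: waveform morphology (K-complexes,
sawtooth waves, vertex waves), arousals and apnea events, electrode
artifacts, inter-subject variability of spectral peaks, and
non-stationarity within a stage bout. Passing the end-to-end test
therefore shows that the implementation can learn stage-dependent
*spectral* structure through the full pipeline — it does not certify
clinical-grade performance on real PSG.

A deliberately trivial baseline (log band powers + EMG RMS into
logistic regression, subject-wise split) is bundled; it scores >80% on
the default cohort, guaranteeing the deep model has signal to find and
giving a floor against which the CNN+LSTM's ≥85% criterion is read.

## Reference experiment and problem sizes

`melstage.study.run_synthetic_study` is the packaged end-to-end
experiment: 12 subjects × 120 epochs (1440 streams of 39×357) at
UCDDB-like rates, subject-wise 70/20/10 split, three model seeds,
median held-out metrics. The cohort size was chosen so a full
single-CPU run completes in minutes while every stage keeps
three-digit epoch counts overall; the same sizes are used by
`scripts/acceptance.py` and the test suite (smaller cohorts are used
in unit tests).

## Known limitations

* The NumPy training loop is single-threaded BLAS-bound; it is meant
  for synthetic-scale experiments, not for 100-subject cohorts.
* EDF support covers standard 16-bit EDF with integer
  samples-per-record; EDF+ annotation channels are not parsed.
* The TCI's integer-code reading, the centre-epoch labelling of
  context streams, and the channel-stacking orientation are documented
  interpretation choices; alternatives are configurable or isolated
  behind small interfaces.
* Masked (artifact) epochs are dropped from streams; no imputation.
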