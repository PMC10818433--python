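# Methods

This note records the models implemented in `respvit`, the defaults chosen
where the field leaves room, and what the synthetic benchmark does and does
not demonstrate.

## Signal conventions

The unit of classification is one respiratory cycle, resampled to 4 kHz
(adventitious sounds carry little energy above 2 kHz) and forced to a fixed
6 s duration: shorter cycles are zero-padded at the end so onset timing is
preserved, longer ones are truncated at the end.  Seconds map to samples via
`floor(t · fs)` with half-open `[start, end)` indexing, so adjacent annotated
cycles never share samples.  Resampling uses polyphase FIR filtering, which
anti-aliases the 100–2000 Hz band of interest.  Multichannel recordings are
reduced to channel 0 (auscultation hardware is mono in practice).

## Time–frequency front-ends

All four front-ends produce a nonnegative K×L matrix with frequency and
frame-time metadata, and all default to an 84 ms analysis frame with 50%
overlap (42 ms hop) so their frame grids are comparable.

**STFT.** Hann window, N = 336 samples (84 ms at 4 kHz), magnitude only.
The N/2 + 1 non-redundant rFFT bins are kept; the implementation is tested
against a direct-summation DFT to < 10⁻⁸ absolute error.

**Mel / MFCC.** `Mel(f) = 1127 ln(1 + f/700)`.  M = 64 triangular filters
(peak height 1) whose M + 2 edge points are uniform on the Mel scale between
0 Hz and fs/2; the matched filter/channel count keeps the four
representations visually comparable.  Filterbank energies are floored at
10⁻¹⁰ before the log so silent frames are finite, then decorrelated with the
`√(2/M) cos(πn(m+½)/M)` cosine transform; the first 20 coefficients are
retained.  Both the coefficient matrix (default) and the log-Mel spectrogram
are exposed, since spectrogram-style images are sometimes preferred for
visual front-ends.  Because FFT-bin quantization cannot place a triangle
peak at an arbitrary frequency, the exact design centres are exposed
separately (`mel_centre_frequencies`) and the matrix rows peak at the
nearest bin.

**CQT.** f₁ = 100 Hz, b = 12 bins/octave up to fs/2 — covering the
adventitious band at semitone resolution.  All bins share
Q = 1/(2^{1/b} − 1); atom lengths N_k = ⌈Q·fs/f_k⌉ shrink inversely with
frequency.  Atoms are Hann-windowed complex exponentials scaled by 1/N_k and
correlated directly with the signal on the common 42 ms hop grid; at
4 kHz × 6 s scale a fast factored CQT is unnecessary and direct evaluation
keeps the transform exactly equal to its definition.

**Cochleogram.** K = 64 gammatone channels of order o = 4,
`g(t) = t^{o−1} e^{−2πb(f_c)t} cos(2πf_c t)` with `b(f_c) = 1.019·ERB(f_c)`
and `ERB(f_c) = 24.7(4.37 f_c/1000 + 1)`.  (The growing-exponential form
that sometimes appears in print is divergent; the decaying exponential is
the physical gammatone.)  Centre frequencies are uniform on the ERB-rate
scale — the integral of 1/ERB, `(1000/(24.7·4.37)) ln(4.37f/1000 + 1)` —
between 100 Hz and fs/2; linear spacing is available behind a flag.
Channels below 100 Hz are deliberately unrepresented: heart sounds and
sensor rumble live there.  Filtering is FIR by truncating the analytic
impulse response where its envelope falls below 0.1% of peak (deterministic
and absolutely summable; the envelope peaks at t = (o−1)/(2πb)).  Frames are
Hann-weighted **energy** sums `C(k, m) = Σ X̂² w` — an amplitude sum would be
sign-indefinite and is not what a spectrogram-like map requires.

**Image rendering.**  10·log₁₀ compression floored 80 dB below the matrix
maximum, per-image min–max normalization, bilinear resize to the target
geometry (default 224×224; the desk profile uses 64×64), re-normalization so
the maximum is exactly 1 after interpolation, Viridis colour mapping, low
frequencies at the bottom row.  Per-image normalization makes the rendering
invariant to positive rescaling of the input, so classifier inputs do not
leak absolute recording gain.  Cepstral (MFCC) matrices skip the dB step —
they are already logarithmic and sign-indefinite.

## Synthetic respiratory sounds

The simulator exists so the pipeline can be exercised and tested end-to-end
without clinical data.  It encodes the accepted spectro-temporal bounds:

- **normal breath sound** — Gaussian noise band-passed to 100–2000 Hz
  (≥ 90% of periodogram energy in band, property-tested), amplitude-modulated
  by two raised-cosine lobes (inspiration, then a longer and softer
  expiration);
- **wheeze** — fundamental in 100–1000 Hz with two weaker harmonics
  (dropped near Nyquist), a smoothed ±5% random pitch drift and 10 ms
  raised-cosine ramps; minimum duration 80 ms is enforced;
- **crackle** — damped sinusoid with time constant duration/5, truncated at
  its duration bound (< 15 ms coarse, < 5 ms fine); the pitch ranges split at
  600 Hz, the midpoint of the shared 100–2000 Hz band, since only
  "low pitch" vs "high pitch" is conventionally specified.

Labelled cycles superpose 1–3 events per present sound kind over the base
sound.  SNR is defined on the event's own support (event energy over base
energy within that window), which makes per-event difficulty independent of
cycle length.  Everything derives from one integer seed; identical configs
are byte-identical, and a manifest records every event.

These recipes are package inventions constrained by the published bounds;
they do **not** model airway physics, stethoscope transfer functions,
sensor noise, inter-patient variability of breath spectra, or the label
noise of real corpora.  A classifier that separates this benchmark has been
shown to read tonal/transient structure out of the chosen representation —
no more.  In particular, per-patient acoustic signatures are absent, so
patient-wise splitting here guards the protocol rather than removing a real
confounder.

## Vision Transformer

Encoder-only: square RGB image → non-overlapping patches (row-major,
default 16 px) → linear embedding to d_model → learnable class token at
index 0 → learnable position embeddings → N identical layers → linear
softmax head on the class token.  Each layer is the post-norm form
`LayerNorm(x + Sublayer(x))` with multi-head scaled dot-product
self-attention and a position-wise ReLU feed-forward network; post-norm (and
ReLU) follow the original transformer description rather than the pre-norm
/ GELU variant common in later ViT code.  Reference defaults are
d_model = 512, N = 6 layers; heads and FFN width are not conventionally
fixed by those two numbers, so the package pairs them with 8 heads and
d_ff = 2048.  Weights are truncated-normal (σ = 0.02, clipped at 2σ),
biases zero, all seeded.  Dropout is available but defaults to 0 — the
desk-scale models are small enough that determinism is worth more than
regularization.

Forward and backward passes are hand-written numpy; the analytic gradients
are verified against central differences (relative error < 10⁻⁴ on a
2×2-patch toy model).  Training is Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸)
at lr 10⁻³, batch 16, 30 epochs, early-stopped when validation loss fails to
improve for 10 consecutive epochs (the plain-patience reading of the usual
ambiguously-worded rule); the parameters kept are those of the best
validation epoch.  The desk-scale profile — 64×64 images, patch 16
(17 tokens), d_model 64, 2 layers, 4 heads, d_ff 256 — trains in seconds on
one CPU.  The capacity check (memorizing 32 random-labelled images to 100%)
uses full-batch Adam: with labels that are pure noise, minibatch gradient
noise at this scale prevents convergence while the full-batch objective is
driven to zero.

## Evaluation protocol

Metrics: Acc, Sen, Spe, Pre, and Sco = (Sen + Spe)/2, computed from
confusion counts with positive = adventitious.  Zero-denominator cells are
reported as NaN with a warning — silent zeros would corrupt averages.  For
the 4-class task the full 4×4 matrix is kept; Acc is exact-match multiclass
accuracy while Sen/Spe/Pre use the adventitious-vs-normal reduction (a
cycle predicted as the wrong adventitious class still counts as a detected
adventitious event in the reduction; the 4×4 matrix is available when the
stricter per-class view is wanted).

Cross-validation partitions *patients* into k near-equal folds (sizes differ
by at most one; 126 patients at k = 10 give six folds of 13 and four of 12)
with a seeded shuffle per repetition; five repetitions of 10 folds give the
conventional 50 evaluation points.  From each fold's training side, 10% of
patients (at least one) are carved out for early stopping.  Two aggregations
are reported because they differ in general and both appear in practice:
metrics of the summed confusion matrix (headline) and the mean of per-fold
metrics.

Model comparison uses the two-sided Mann–Whitney U and Wilcoxon signed-rank
tests at α = 0.05, delegated to scipy with exact p-values for n ≤ 12 without
ties and the tie-corrected normal approximation otherwise; the test suite
checks the exact branch against full permutation/sign-flip enumeration.
The score-identity checker recomputes Sco from printed (Sen, Spe) pairs at
the printing precision (±0.05 for one-decimal tables) and flags cells that
fail the identity instead of forcing them.

## Acceptance-script problem sizes

`scripts/acceptance.py` uses 25 synthetic patients × 8 cycles (200 cycles)
per binary task at 10 dB SNR, 64×64 cochleogram images, the desk-scale ViT,
and 5-fold patient-wise cross-validation — sizes chosen so the whole run
completes in a few minutes on one CPU while every quantity is still computed
by the full pipeline.  The STFT oracle uses 50 random signals of up to 1024
samples.

## Known limitations

- Wheeze detection on the synthetic benchmark is strong (cross-validated
  accuracy well above 90% at 10 dB); crackle detection at the same settings
  is near chance.  A single < 15 ms transient contributes almost nothing to
  an 84 ms energy frame once the image is normalized and resized, so the
  desk-scale crackle task is genuinely hard by construction — consistent
  with crackles being the harder class in clinical studies, though more
  extreme.  Higher image resolution, shorter frames, or denser crackle
  trains would ease it; the defaults are left at the stated study
  conditions.
- The CQT is exact but O(K·L·N_k); it is sized for 6 s cycles at 4 kHz, not
  for long recordings.
- No data augmentation, pre-training, or class-imbalance correction is
  applied by default (inverse-frequency class weights are intentionally out
  of scope for the reference protocol; imbalance handling is left to the
  caller's sampling).
- The simulator's independence across cycles means reported cross-validation
  variance understates the patient-level correlation found in real corpora.
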