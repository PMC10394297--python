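# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic experiments do and do
not establish.

## Signal model and preprocessing

Input is multichannel EEG, nominally 22 channels at 250 Hz (any channel
count and rate ≥ 2× the top analysis band work).  Each recording is
min-max normalized **per channel, per recording, before windowing** — so
overlapping windows stay mutually consistent and no segment-level
statistics leak across the train/test boundary — then cut into
250-sample windows with 50 % overlap (hop 125).  Windows are half-open
`[start, start+250)` with 0-based starts; the trailing remainder shorter
than one window is dropped, giving `⌊(T−250)/125⌋+1` windows.  Constant
channels normalize to zeros rather than erroring (padded clinical files
produce them).  A window's label is the majority state of the samples it
covers; a window over an annotation gap is an error, not a guess.
Channel order follows the file header; no re-montaging or filtering is
applied beyond the transform below.

## Wavelet front-end

The spectral branch computes a five-level Db4 pyramid as a stride-2
convolution.  Before each level the current approximation is extended
circularly: the last `R/2−1` samples are prepended and the first `R/2−1`
appended (`R = 8` taps), which makes the strided correlation *exactly*
the orthonormal circular DWT — it equals `pywt`'s `periodization` mode
with zero index offset and conserves energy per level to machine
precision (both are asserted in tests).  Odd-length approximations are
extended by one repeated trailing sample, the periodization convention.
Padding is reapplied at every level (a flag can restrict it to the first
level; the stride arithmetic then only works for special lengths).

Band mapping at 250 Hz: the dyadic sub-bands are D1 ≈ 62–125 Hz,
D2 ≈ 31–62, D3 ≈ 16–31, D4 ≈ 8–16, D5 ≈ 4–8, A5 ≈ 0–4 — the last five
are the conventional γ/β/α/θ/δ edges almost exactly, so the mapping is
γ=[D1|D2] (the supra-γ D1 content stays with the fastest band rather
than being discarded), β=D3, α=D4, θ=D5, δ=A5.  A 6 Hz rhythm maximizes
the θ band under this mapping, as it should.

Per band, the **squared** coefficients are flattened over channels and
linearly projected to a common width W (default 32).  Energies rather
than raw coefficients: oscillatory class structure lives in sub-band
power, and energies are invariant to the phase at which a rhythm enters
a particular window — with raw-coefficient projections the features were
phase-sensitive and transferred poorly across windows and patients.

The temporal branch applies five independent conv→BN→ELU stacks with
kernel lengths {32, 32, 16, 8, 4} (the two length-32 stacks are separate
parameter sets, as specified) along time, each EEG channel filtered
independently (channels folded into the batch), with stride
`max(2, S/4)`, adaptive average pooling to 4 bins, and a linear
projection to W.  The embedding block (conv k=15, zero same-padding, BN;
width E, default 8) runs first and its output is channel-concatenated
with the raw window; both branches consume the concatenation.

The five [band | temporal] pairs (each 2W wide) are gated by a
squeeze-and-excitation step — mean over each pair, bottleneck of ratio 4,
sigmoid — and flattened to `f_all` of dimension 10·W (even by
construction, as the downstream half-split requires).

## Separation and invariance

`f_all` splits exactly in half by index; G_c1 (category) and G_p
(patient) are single-hidden-layer MLPs (hidden = half dimension, ELU) —
the smallest nontrivial probes.  The max-divergence loss is the negated
summed squared distance between halves.  It is unbounded below; the
training protocol clips the per-sample squared distance at 5 × the
half-dimension by default (`max_divergence_clip="auto"`, `None`
disables).  Without a ceiling, long full-batch runs inflate the feature
scale without limit (observed: |L_md| ~ 10⁶ within 60 epochs) and the
monitoring-only stance is untenable.

The discriminators (two hidden layers 64/32, ELU, n_patients outputs)
see the recombined features through the GRL; the local discriminators
receive features scaled per sample by the true one-hot class indicator —
non-members contribute zero vectors, keeping the 1/N normalization and
static shapes.  A soft variant using predicted class probabilities is
available for ablations.  The center loss operates on G_c2's penultimate
ELU layer (width 64); centers start at zero.

## Optimization

Full batch, one step per epoch (the centers and discriminators see every
training sample each step), Adam lr 0.005 for all network parameters
including the auxiliary heads, 200 epochs by default, no early stopping.
The reported loss follows

    L_sum = L_cls2 + λ(L_cent + L_cls1 + L_p + L_md) − λ(L_global + L_local),  λ = 0.1.

Two deliberate deviations between the reported quantity and the
backpropagated one:

* **Sum-to-mean normalization.**  L_cent and L_md are batch sums; their
  gradient contribution is divided by the batch size so each term's
  per-sample scale matches the 1/N-averaged cross-entropies.  With raw
  sums the effective weight of those terms grows linearly with cohort
  size and λ = 0.1 loses meaning (empirically the classifier stalls).
  Reported values keep the summed definitions.
* **GRL realization of the minimax.**  The discriminator cross-entropies
  enter the backward objective with weight +1 (descent trains the
  discriminators) while the GRL multiplies the gradient flowing into the
  features by −λ.  This reproduces exactly the stated update directions:
  discriminators maximize L_sum (coefficient −λ ⇒ minimizing their CE),
  the extractor receives the −λ-scaled reversed gradient.  The
  equivalence is asserted on a toy linear model in the tests.  An
  explicit alternating-update mode exists for stability experiments.

Centers use the class-count-normalized center-loss update
`Δc_k = Σ_{i: y_i=k}(c_k − x_i)/(1 + n_k)` with lr 0.05: plain SGD on the
raw summed gradient has an effective step of `lr · n_k` and diverges for
any full batch with more than ~40 samples per class.  Feature gradients
of L_cent flow into the network normally.

One master seed fans out (via `SeedSequence.spawn`) to parameter
initialization and minibatch shuffling; full-batch runs are
bit-reproducible, and a saved model reloads to bit-identical predictions.

## Synthetic cohort

The generator emulates the target recording conditions: per patient,
`seconds_per_class_per_patient` (default 250 s) of normal background
followed by the same duration of seizure activity, annotated exactly, at
250 Hz.  Background is 1/f-shaped Gaussian noise (so wavelet sub-bands
are non-degenerate) plus a patient-specific baseline rhythm
(U(3.5, 12) Hz, amplitude 2.5 × noise sd, log-normally spread).  Seizure
intervals add a patient-jittered theta-band rhythm (U(4, 8) ± 1 Hz) with
a half-amplitude first harmonic, amplitude 2 × noise sd scaled by a
per-patient log-normal intensity (sd 0.4), plus Poisson spike-wave
transients (0.8 Hz, amplitude 3).  Per-channel log-normal gains
(sd 0.4), a per-patient noise multiplier (sd 0.3) and a random ictal
topography complete the confounds.  Two independent streams separate
patient identity from noise, so identities are stable when noise is
resampled.

These defaults were chosen so that, as a *distributional tendency*:
a bandpower threshold detects the class within patient almost perfectly
(and is at chance when the class amplitude is zeroed); patients are
identifiable from raw segment statistics; and class models fitted across
patients measurably lose accuracy on an unseen patient (mean gap ≈ +0.16
over seeds, with individual cohorts ranging from no gap to near-total
transfer failure — mirroring the clinical situation where some patients
are simply harder).  What the synthetic experiments do **not** show:
performance on real ictal morphology, artifacts, montage effects, or
seizure-type diversity; absolute accuracies here do not transfer to any
clinical corpus.

## Study sizes used by tests and the acceptance script

Library defaults stay at the full protocol (14 patients, 22 channels,
250 s per class, W=32, 200 epochs).  The test suite and
`scripts/acceptance.py` run a scaled-down model (3 channels, E=2, W=8,
4 temporal filters) on cohorts of 3–5 patients with 6–15 s per class and
40–100 epochs — sizes chosen so every behavioral property remains
measurable while a full multi-seed ablation stays within minutes on one
CPU.  Behavioral checks aggregate over ≥ 5 seeds with majority criteria;
the ablation comparison scores a held-out patient of a strong-confound
cohort (baseline rhythm amplitude 1.8) and a zero-confound control in
which all variants should be indistinguishable.

The disentanglement direction is measured by *transfer* probes: a linear
class probe fitted on training-patient features must score higher on a
held-out patient from the category half than from the patient half
(class information residing in the patient half is patient-specific and
collapses on transfer), while a patient-identity probe within the
training patients favors the patient half.  On pooled training data both
halves approach ceiling class accuracy, so the in-sample comparison is
uninformative — transfer is where "category-related" has meaning.

## Numerical details and degenerate inputs

Everything runs in float64 on a compact reverse-mode autodiff engine
written for this package (the networks are small and full-batch; the
engine is finite-difference-checked in the tests).  Ties in the argmax
prediction resolve to class 0 (normal).  Rates with zero denominators
(SN with no positives, SP with no negatives) are reported as undefined,
never as 0.  ROC sweeps the unique scores and integrates by trapezoid;
ties in scores contribute half, matching the Mann–Whitney statistic
exactly.  Fold averages report the sample standard deviation (ddof 1).
BatchNorm uses momentum 0.1 and eps 1e-5; evaluation mode uses running
statistics.  t-SNE exports use perplexity 30 (reduced automatically for
small batches) with a fixed seed.

## Known limitations

* Adversarial balance is delicate: a saturated discriminator stops
  informing the features, so long runs drive the variants toward the
  same solution; the discriminator-accuracy diagnostics in the training
  history are the first thing to inspect.
* The 1/N-normalized loss combination and the center-update rule are
  scale conventions; results at very different batch sizes are not
  directly comparable to the defaults.
* The EDF writer is minimal (16-bit, single rate, 1-s records) — enough
  to round-trip the synthetic cohorts through the `mne` reader, not a
  general EDF+ exporter.
* With `minibatch` mode the full-batch premises of the center update and
  of the discriminators weaken; it exists for large cohorts and is not
  the reference protocol.
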