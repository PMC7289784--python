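# Methods

## The scoring problem

Overnight polysomnography (PSG) is scored by technicians in 30-s epochs,
each assigned one of five stages — W (wake), N1, N2, N3 (NREM, light to
deep) and R (REM) — from a five-channel staging montage: two referential EEG
derivations (C3/A2, C4/A1), left and right EOG, and EMG, sampled at 200 Hz.
Clinical recordings are messy: electrodes shed, amplifiers saturate, and
broadband artifacts intrude, so a scorer built for the clinic must stay
usable when part of the montage is garbage.  `polystage` implements an
automated scorer designed around that constraint: five convolutional
networks, each fed a different channel group, whose per-epoch stage
probabilities are fused by a weighted average in which any model whose
channels are flagged as noisy gets weight zero for that epoch, followed by a
REM-continuity post-processing rule.

## Preprocessing

Stage-relevant EEG content lives below ~35 Hz.  Each channel is low-pass
filtered and decimated by 3 from 200 Hz to exactly 200/3 Hz (kept as a
rational number so sample bookkeeping is exact; 30 s of signal is always
2000 samples).  The anti-alias filter is a 101-tap linear-phase FIR with a
33 Hz cutoff run through `filtfilt`, giving a zero-phase response and far
more than 40 dB of stop-band attenuation at 45 Hz.  The cutoff sits just
below the target Nyquist (100/3 Hz) — filtering *at* the new sampling
frequency itself would alias, and the point of the step is that no aliasing
occurs.

Because stage scoring is contextual (a technician reads neighbouring epochs
when one is ambiguous), the record is re-divided into 90-s windows of three
epochs with a 30-s stride: one window per scored epoch, labelled by its
centre epoch (configurable to first/last).  At the record boundaries the
edge epoch is replicated so the window count always equals the epoch count.
Each channel is z-scored per record before model input to remove
inter-subject gain differences.

## The staging networks

Each group's network is a stack of two block types over the
(channels × 6000)-sample window:

* **conv block** — two convolutions (each + batch norm + ReLU), a shortcut
  that concatenates the block input with the two-convolution output along
  the channel axis, then average pooling that halves the temporal length
  (output channels = input channels + second-conv filters);
* **trans block** — two convolutions with strides 2 and 1 (each + batch
  norm + ReLU), halving the temporal length;

then flatten and a dense layer to five logits with softmax.  Temporal
length after any halving block is ⌈L/2⌉.  The reference stack is six
halving blocks (trans, trans, conv, trans, trans, conv with 6/8/8/12/12/12
filters, kernels 7→3), taking 6000 samples down to 47; for multi-channel
inputs the first two blocks' widths are doubled, since the all-channel
model must represent every channel's bands in its earliest feature maps
(without this the all-channel model underfits and scores below the
single-channel models).

The channel groups are: 1 — EEG C3/A2, 2 — EEG C4/A1, 3 — EOG left,
4 — EOG right, 5 — all five channels.  A variant with a single two-channel
EOG group is available (`default_groups(paired_eog=True)`).  EMG appears
only inside group 5.

Training: mini-batch Adam (batch 64, learning rate 3 × 10⁻³) on
cross-entropy with inverse-frequency class weights (N3 is rare in an OSA
population; unweighted training collapses its recall), early stopping on
validation accuracy (patience 3, up to 10 passes), best-validation snapshot
restored.  Splits are always by recording, never by epoch.  Everything —
initialization, batch order, the training loop — is plain numpy driven by
one seed, so training is bit-reproducible on a fixed BLAS/thread
configuration.  The reference model set (five networks, ~1.6 k windows)
trains in roughly 6–8 minutes on one CPU core.

## Noise detection

Three transparent per-epoch, per-channel statistics stand in for the
falloff detector (the heuristics and thresholds are this package's own
engineering choices):

| detector   | statistic                                   | default threshold |
|------------|---------------------------------------------|-------------------|
| flatline   | epoch standard deviation                    | < 0.5 µV          |
| saturation | fraction of samples within 1 µV of ±rail    | ≥ 0.2 (rail 250 µV) |
| hf_noise   | epoch power above 25 Hz / total epoch power | ≥ 0.5             |

A channel group is flagged in an epoch iff any member channel trips any
detector there, so one bad channel silences exactly the models that consume
it — including, by default, the all-channel group (configurable).  Flags
are local (they depend only on the epoch's own samples) and monotone
(adding an artifact never unflags an epoch).

Detection runs on the **source-rate** record, before decimation.  This is
deliberate: the 33 Hz anti-alias filter destroys precisely the broadband
evidence the hf detector needs — after decimation, white noise can place at
most ~25% of its power above 25 Hz, so no sensible threshold exists there,
while at 200 Hz broadband noise puts ~75% of its power above 25 Hz and
clean EEG well under 10%.  EMG is exempt from the hf detector because
physiological EMG is intrinsically broadband (10–100 Hz); a clean EMG epoch
would trip any threshold that still catches artifacts.

## Integration and expert rules

Per epoch, the five probability vectors are combined as Σ wᵢpᵢ with the
masked models' weights set to zero and the rest renormalized.  Weights are
uniform by default; a validation-accuracy-proportional mode exists.  If
every model is masked the fusion falls back to a uniform average and marks
the epoch low-confidence rather than emitting nothing.  Argmax ties break
to the lowest stage index in the fixed order W, N1, N2, N3, R.

The REM-continuity rule addresses tonic REM: epochs inside a REM period
without visible rapid eye movements are easily mis-scored as N1/N2.  Two
modes are implemented:

* **gap_fill** (default) — non-R runs of length ≤ 8 epochs lying strictly
  between two R epochs are converted to R.  This is the reading consistent
  with the rule's purpose (preserving the continuity of an ongoing REM
  bout) and it is idempotent.
* **literal** — one simultaneous pass converting any epoch whose next 8
  epochs contain an R prediction.  This follows the written procedure
  exactly but would also convert long pre-REM wake runs, and it is *not*
  idempotent (a second pass would recruit epochs ahead of the Rs the first
  pass created); it is retained for fidelity experiments only.

Both modes only ever change labels *to* R, so the R count is non-decreasing
under the rule.

## Evaluation

The report computes: the 5×5 confusion matrix (rows = expert, columns =
model); per-stage precision, recall and F1; count-weighted averages —
weighting per-stage precision by predicted-stage counts reproduces overall
accuracy exactly (Σ TPᵢ/N), which is the identity behind the benchmark
table's "weighted average" row; Cohen's κ from the matrix marginals; top-k
accuracy with ties broken in fixed stage order, and the top-2 − top-1
increase rate; the second-choice table, cell (i, j) counting epochs with
top-1 = i and runner-up = j as a percentage of all epochs predicted i;
OSA-severity stratification from AHI (thresholds 5/15/30, upper categories
left-closed); and total sleep time as non-wake epochs × 30 s.  Display
rounding is 4 decimal places, round-half-even; all stored values are
unrounded.

## The synthetic test bench

No clinical recordings ship with the package; the generator produces
records carrying exactly the structure the pipeline exploits, and its
defaults are the study conditions for every end-to-end check:

* **Stage dynamics** — a first-order Markov chain over the five stages.
  The `severe_osa` preset emulates a fragmented OSA night: stationary mass
  ≈ 33% W, 17% N1, 37% N2, 0.7% N3, 13% R (scarce N3, plentiful wake —
  the class imbalance that makes N3 recall hard and motivates class
  weighting).  A `normal` preset with consolidated sleep exists for
  contrast.  Chains start in W (nights begin awake).
* **Signals** — per epoch and channel, Gaussian noise shaped to textbook
  AASM band signatures (alpha-dominant W, theta N1, spindle-bearing N2
  with 11–16 Hz bursts, ≥ 75% relative delta power at high amplitude in
  N3, theta R), a 4% white-noise floor, 0.25-s crossfades between epochs,
  plus stage-specific transients: N2 spindles on the EEG channels,
  anti-phase saccadic deflections on the two EOG channels in R, and
  stage-scaled EMG tone (30 µV RMS in W down to 2.5 µV atonia in R).
  EEG/N1 and EEG/R spectra are deliberately similar, so R is only
  separable through EOG and EMG — the property that makes the multi-group
  design meaningful.
* **Arousals** — 3–15 s alpha + EMG bursts overlaid on uniformly chosen
  sleep epochs, relabelling the epoch to N1 with probability 0.5.  Arousal
  count is independent of AHI, enabling the arousal-sensitivity analysis.
* **Falloff artifacts** — flatline (near-zero + jitter), saturation
  (signal driven into ±250 µV rails) and broadband hf noise (150 µV),
  confined to one channel and epoch span.
* **Population** — the reference study is 12 records × 160 epochs, split
  7/2/3 by recording; per-record AHI drawn across the four severity
  classes weighted toward severe (a sleep-clinic case mix), arousal counts
  growing with severity.

What the generator does **not** emulate: real EEG's 1/f background,
K-complex morphology, sweat/movement artifacts with physiological
structure, inter-scorer label noise, apnea/desaturation waveforms (AHI is
metadata only), and inter-subject spectral variability beyond gain.
Passing end-to-end checks therefore demonstrates that the pipeline's
machinery — preprocessing, training, fusion, masking, rules, metrics — is
correct and that the architecture can learn stage signatures from
plausible spectra; it does not certify clinical-grade accuracy, which the
original study established on ~150 k expert-scored epochs.

## Numerical and design choices

* Decimated output length is ⌈n/3⌉ (sample 0 kept); window sample counts
  are exact by the rational-rate bookkeeping.
* Probability fusion renormalizes at use; integrated vectors sum to 1
  within 10⁻⁹.
* The EDF writer quantizes to 16 bits over a per-channel symmetric range
  (error ≤ range/2¹⁶); EDF+ annotation tracks are read but hypnograms are
  written as one-label-per-line text.
* Degenerate inputs fail loudly: single-class training sets, records
  shorter than one epoch, mismatched record/hypnogram lengths, transition
  matrices that are not row-stochastic, subjects appearing in two splits.
* Scale: the desk-scale defaults (12 × 160-epoch records, six-block
  networks, ≤ 10 training passes) were chosen so the full study — generate,
  train five models, score, ablate — completes in roughly ten minutes on a
  single CPU core while leaving comfortable margins on the end-to-end
  accuracy checks.

## Known limitations

* The noise-detector thresholds are engineering defaults tuned to the
  synthetic artifact models; clinical deployment would re-tune them.
* hf falloff on the EMG channel is invisible to the hf detector (see
  above); flatline and saturation still cover EMG.
* The literal expert-rule mode is intentionally not idempotent; use
  gap_fill unless reproducing the written procedure matters.
* Training determinism is per-BLAS-configuration; different threading or
  BLAS builds may differ in final bits while remaining statistically
  equivalent.
* The generator's Markov chain has no time-of-night structure (no sleep
  cycles); REM bouts arise only from the chain's self-transition.
* On noise-corrupted records the gap_fill rule's benefit varies with the
  realization: when masked epochs produce scattered false R predictions,
  gap filling can amplify them and cost accuracy at desk scale.  A
  production deployment would anchor the rule on R bouts of a minimum
  length rather than single R epochs; that variant is deliberately not the
  default because it departs from the procedure as stated.
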