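# Methods

## The comparison framework

The scientific question the package operationalises is whether learned
(neural) feature representations of electrodermal activity beat carefully
hand-crafted skin-conductance statistics for recognising heat-induced pain.
A fair comparison requires that everything *except* the feature extractor be
fixed: one pre-processing chain, one classifier, one evaluation protocol.
`painfeat` therefore fixes per-window min–max normalisation, a 100-tree
random forest, and leave-one-subject-out (LOSO) cross-validation repeated
five times, and lets feature extractors — the 38-dimensional hand-crafted
vector, an MLP, a CNN, a ConvLSTM and a convolutional autoencoder (CAE), or
any extractor registered by a third party — compete under that harness.

## Generative model of a heat-pain study

Because the benchmark recordings are gated, the package generates synthetic
studies whose structure matches the two acquisition protocols. The generator
is first-class, tested code: its defaults *are* the study conditions, not
tuning knobs.

**Calibration.** Each subject has a pain threshold TP ~ U[40, 46] °C and a
tolerance TT = TP + U[2, 4] °C capped at 49 °C (the calibration staircase
maximum). The level range is R = (TT − TP)/4; PMDB-style levels are
NP = TP − R and Pi = TP + i·R (P4 = TT), BVDB-style levels
Ti = TP + (i − 1)·R, with a 32 °C baseline in both schemes. The staircase
procedure itself is not simulated step by step — downstream stages consume
only TP/TT, so profiles draw them directly.

**Protocols.** PMDB scheme: each of NP, P1..P4 applied 8× for 10 s with
rests uniform in [20, 30] s, order randomised per subject. BVDB scheme: each
of T0..T4 applied 20× for 4 s with pauses uniform in [8, 12] s (100 stimuli
per subject). Events never overlap and are sorted by onset.

**Electrodermal signal.** EDA = tonic + phasic + noise, clipped at zero:

* *Tonic*: a per-subject baseline level (U[2, 10] arbitrary conductance
  units) plus slow drift — three sinusoids with frequencies in
  [0.002, 0.02] Hz, i.e. strictly below the 0.05 Hz decomposition cutoff.
* *Phasic*: one stimulus-evoked SCR per painful event, a bi-exponential
  kernel `exp(−t/3.0) − exp(−t/0.75)` (unit peak ≈ 1.2 s after response
  onset, several-second recovery), delayed by the subject's response latency
  (U[1, 2.5] s). The amplitude is `scr_gain · w(level) · h^rep · jitter`
  with level weights w = 0 for B/NP/T0 and 0.25/0.5/0.75/1.0 for the four
  painful levels, habituation h per repetition, and log-normal per-event
  jitter. Spontaneous (non-specific) SCRs occur as a Poisson process with
  small amplitudes, so baseline windows contain realistic activity.
* *Noise*: additive Gaussian.

**CoVAS rating.** The rating trace is zero outside painful stimuli; during a
painful event it ramps up after a ~1 s reaction lag over ~2 s to a plateau
`100 · min(1, covas_gain · drive · jitter)` and returns to zero within ~2 s
of stimulus offset, clipped to [0, 100]. Crucially the *drive* is the same
per-event quantity that scales the evoked SCR, drawn once per event — the
subjective label is thereby coupled to the physiology, which is what makes
rating-derived classes (C1..C4) group windows by the response that actually
occurred. This is the mechanism behind the observed subjective-label
advantage in classification.

**Effect presets.** Two named parameter sets describe the population:
`default` (evoked gain 0.5 units at the top level, event jitter σ=0.4
log-scale, noise SD 0.03, habituation 0.97/repetition, 2 spontaneous
SCRs/min, drift 0.3 units) approximates a realistic noisy study and yields
graded task difficulty; `clean` (gain 1.0, jitter 0.15, noise 0.02,
habituation 0.99, 1/min, drift 0.2) is a strong, low-noise effect used by
the recovery suite, chosen on signal-to-noise grounds: a top-level SCR of
~1 unit against 0.02-unit noise is unambiguous, while the weakest painful
level (0.25 units) still competes with drift and jitter. All values are in
the same arbitrary conductance units as the signal.

**What the generator does not emulate.** Real EDA nonstationarities
(electrode drift and detachment, motion artefacts, sensor-site
repositioning mid-session), thermal sensitisation, between-channel coupling
(only EDA plus temperature/CoVAS are emitted), and the heavy-tailed
between-subject variability of real cohorts. Passing recovery tests
therefore demonstrate that the pipeline finds a monotone electrodermal
effect when one exists and reports chance when none does — they do not
predict absolute accuracies on real recordings.

## Pre-processing and labels

All channels are linearly interpolated onto a uniform 256 Hz grid spanning
the recording. Windows are cut half-open `[start, start + T)` with
`start = round(start_s · fs)`: PMDB-style 2560 samples from stimulus onset
plus a 2560-sample pre-stimulus baseline window (class B); BVDB-style 1408
samples starting 3 s after onset (taken literally from the published window
geometry even though it extends past the 4-s stimulus). Windows that would
cross a recording boundary are dropped with a logged warning rather than
zero-padded — padding would distort both min–max normalisation and SCR
statistics. Each window is normalised per channel to [0, 1]; a constant
channel maps to zeros (keeps the codomain, avoids 0/0).

CoVAS window sums are computed on the common 256 Hz grid (the per-subject
scaling cancels any rate dependence), scaled by the subject's maximum sum,
and binned: 0 → C0, ]0, .25] → C1, ]0.25, .5] → C2, ]0.5, .75] → C3,
]0.75, 1] → C4. The bins partition ]0, 1]; at least one window per rated
subject attains the top of the scale.

## Hand-crafted features

The window is normalised, then decomposed by a zero-phase (forward-backward,
cascaded second-order sections) second-order Butterworth filter with a
0.05 Hz cutoff — low-pass output = tonic, high-pass output = phasic. The
cutoff is read as 0.05 **Hz**: a normalised cutoff of 0.05 at 256 Hz would
be 6.4 Hz, far above tonic dynamics. Because filtering is applied twice, the
amplitude gain is the squared Butterworth magnitude, `1/(1 + (f/fc)^4)` for
the low-pass — this closed form is the test oracle for the filter.

SCRs are detected on the phasic trace in normalised per-window units
(normalisation precedes decomposition, so the published thresholds live on
that scale): an event opens where the trace rises through 0.01, peaks at the
subsequent maximum, closes where the trace falls back through its onset
value, and is kept if peak − onset ≥ 0.05. The onset threshold applies to
the phasic *value*, not its derivative. Half-recovery is the first sample
after the peak below onset + amplitude/2, absent if not reached in-window.

The 38 features are: RMS; mean of strict 3-point local maxima and minima
(plateaus contribute their first sample); mean absolute value; mean absolute
first and second differences, each also on the z-standardised signal;
coefficients of variation of the signal and of its squared values (the
"variation of the first and second moment", reconstructed); argmin/argmax
indices; last − first value; mean and SD of each of {phasic, tonic, SCR
amplitudes, SCR rise times, SCR half-recovery times, tonic recovery range
per SCR (tonic(offset) − tonic(onset))}; SCR count; amplitude sum; first
amplitude; phasic maximum; mean/SD/variance of the unit-normalised signal;
and an auxiliary block documented as such — max, min, median, interquartile
range, least-squares slope (per second), and trapezoidal area under the
window — bringing the enumeration to the published dimensionality of 38,
which the source feature list does not reach unambiguously on its own.
SCR-dependent statistics are zero when no SCR is detected; every feature
carries a name so downstream analyses are auditable.

Note an intended consequence of per-window normalisation: absolute SCR
amplitude is discarded, so level information survives in relative terms
(phasic spread, noise-to-response ratio) rather than raw amplitude. On
unnormalised windows the mean detected SCR amplitude is strictly monotone
in the painful level; after normalisation the monotone carrier is the
phasic SD. Both facts are asserted by tests.

## Learned features

The four architectures follow their published layer recipes exactly (the
test suite audits them layer by layer): the MLP's hidden dense layers have
no activation listed and are therefore linear; the CAE uses ReLU
convolutions (kernels 7/11/11 encoder, mirrored decoder) with pool/upsample
factor 4 and a linear 1-kernel reconstruction layer; the CNN uses two
Conv(16, k7, s2, ReLU) → MaxPool(4) → Dropout(0.1) blocks; the ConvLSTM net
processes the window split into 4 equal time segments through three
ConvLSTM blocks (32/16/8 filters, kernels 11/7/3, input-conv strides 8/8/2,
tanh cell activation, hard-sigmoid gates — the tanh is assumed for the
blocks whose activation column is blank).

Three interpretation choices were genuinely open:

* *Pooling in the ConvLSTM net*: a pool of 4 over all non-channel axes
  would collapse the 4-segment axis immediately and drive the temporal axis
  below the pool size (640 → 80 → 20 → 3 with the printed strides), which a
  valid pool cannot accept. Pooling therefore acts on the within-segment
  temporal axis only, with ceil (same-padding) semantics.
* *Feature layers*: the penultimate Dense(100) for the classifiers, the
  flattened post-encoder representation for the CAE (640 values for a
  2560-sample window, 352 for 1408).
* *Padding*: same-padding everywhere, so the CAE's pool/upsample chain
  restores the input length exactly (2560 = 4³·40, 1408 = 4³·22).

The layer stack itself (dense, strided same-padded 1-D convolution, ceil
max-pooling, nearest-neighbour upsampling, dropout, batch normalisation,
convolutional LSTM, Adam) is implemented directly on numpy with explicit
backpropagation. This keeps the dependency footprint to the scientific
Python core and makes every gradient auditable; the backward passes are
validated against central-difference numerical gradients at tiny sizes in
float64 (worst relative error ~1e-10), and training runs in float32 for
speed. Weight initialisation is Glorot-uniform from a seeded generator;
dropout is active only during training; repeated runs with one seed are
bit-identical. Training follows the published recipe: Adam at learning rate
1e-4, batch size 8, 50 epochs by default (no early stopping), categorical
cross-entropy for classifiers and MSE for the CAE; the five LOSO
repetitions use seeds `base_seed + 0 .. + 4`.

## Evaluation conventions

**Tasks.** Binary: a baseline level (B, T0 or C0) against one pain level,
selected from the temperature or CoVAS labels. Tasks are balanced by
deterministic per-subject undersampling of the majority class (seeded,
default on). This is a substantive choice: the PMDB segmentation yields one
baseline window per stimulus, so B outnumbers any single level 5:1, and an
unbalanced evaluation would let a majority-class classifier score 83% on a
task that is actually uninformative; the chance floor of every task is
pinned to 50% instead, which is the scale on which graded pain results are
interpretable (and on which a response-free task reads as a random guess).

**Cross-validation.** For each of 5 runs and each subject: train a
100-tree random forest (run-specific seed, other hyperparameters at library
defaults) on all other subjects, test on the held-out subject. Extractors
that require fitting (all deep methods, including the unsupervised CAE) are
re-trained inside each fold on the training subjects' task rows only —
anything else would leak test subjects into feature learning. The CAE sees
the same rows as the supervised nets (without labels) for comparability.

**Aggregation.** Reported values are the per-run mean over subjects,
averaged over runs; the ± value is the per-run SD over subjects, averaged
over runs. Method pairs are compared by a two-sided paired t-test on
subject-aligned accuracies averaged over runs (α = 0.05, direction
reported; zero-variance zero-mean differences are not significant,
zero-variance nonzero-mean differences are, with p reported as 0). No
multiple-testing correction is applied across the method-pair grid.
Degenerate confusion denominators (0/0) yield 0 for precision, recall
and F1.

## Problem sizes and seeds in the verification runs

The recovery suite uses a 12-subject PMDB-scheme dataset with the `clean`
preset at 256 Hz — 960 windows, 192 rows per balanced temperature task —
with 5 LOSO runs for the hand-crafted path. The deep-path smoke runs train
the MLP and CAE at 10 epochs per fold with a single LOSO run; these sizes
give stable accuracy estimates while keeping per-fold autoencoder training
(the dominant cost) to a few seconds each. The empirical chance reference
re-runs the identical harness with labels permuted within subject, using
the hand-crafted features: chance level is a property of the label
distribution, not of the feature set, so re-training deep extractors on
shuffled labels would add compute without information. All randomness in
`scripts/acceptance.py` derives from `--seed`.

## Known limitations

* Synthetic physiology only; absolute accuracies are not comparable to real
  benchmark numbers (the clean preset deliberately saturates the easy
  tasks).
* The SCR detector is the simple threshold scheme, not a deconvolution
  method; superposed responses within one window merge into single events.
* dPhEDA / TVSymp / MTVSymp features are out of scope; the extractor
  registry provides the seam where such methods plug in, and
  `hcf_combined` concatenates whatever is registered.
* The numpy layer stack targets these four small architectures; it is not a
  general-purpose autodiff framework (each layer implements its own
  backward pass).
* BVDB-style recordings carry no CoVAS channel, so subjective-label tasks
  exist only for the PMDB scheme.
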