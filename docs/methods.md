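# Methods

This note records the models, estimators, and numerical choices behind
`renyifs`, and what the synthetic experiments do and do not demonstrate.

## Signal chain

**Preprocessing.** The chain is notch → band-pass → channel subset →
resample → epoch; filters run at the native rate and epoching happens last.
Both filters are applied forward–backward (zero phase), so trial timing is
not smeared: a 2nd-order IIR notch (quality 30) at the mains frequency
(default 50 Hz) and a Butterworth band-pass of order 2 per section (4th
order overall, default 0.5–100 Hz).  IIR over FIR because epochs are short
(hundreds of samples) and linear-phase FIR filters of comparable selectivity
would spend a large fraction of each epoch on transients.  Downsampling is
polyphase with the built-in anti-alias filter (default 250 → 100 Hz).  The
default channel subset keeps indices 1–5 and 7–11 of a 25-channel montage
(the central/frontal scalp rows); recordings that already contain exactly
the reduced montage pass through unchanged.  Epochs are half-open windows
`[onset + 3.0 s, onset + 6.0 s)` — the imagery period that follows the cue
in a cue-paced paradigm — giving exactly 300 samples at 100 Hz.  The window
is configurable; nothing downstream assumes its length beyond the
decomposition-depth constraint.

**EDF I/O.** EDF is written directly against the 16-bit field layout with
one-second records and a per-channel symmetric physical range rounded
outward so the 8-character header value still covers the data; worst-case
quantization error is `span / 2^15` for a channel of peak-to-peak `span`.
Reading goes through MNE.  The delimited text dialect is lossless
(`repr`-precision floats) and is the format used by the test fixtures.
GDF, annotation channels, and streaming input are out of scope; recordings
in other formats are expected to be converted to EDF externally.

## Wavelet packet features

A level-`J` wavelet packet transform recursively splits both the
approximation and the detail branch, producing `2^J` terminal sub-bands of
equal width.  Nodes are kept in natural (Paley) order — the recursion
order, with children `(j+1, 2k)` and `(j+1, 2k+1)` of node `(j, k)` — and
feature names record channel, level, node index, and statistic
(`ch3.j5.k17.energy`).  The ascending-frequency position of node `k` is the
binary-reflected Gray decode of `k`; the package does not relabel nodes.

Defaults: level 5, Daubechies `db4` (a common choice for EEG work; any
orthogonal family is accepted), and **periodization boundary handling**.
Periodization keeps the discrete transform exactly orthogonal, so
terminal-node energies sum to the signal energy (Parseval) and
reconstruction is exact to rounding — both verified to 1e-6 relative and
1e-8 absolute for `db1`/`db4` at `J = 1..5` on dyadic-length signals.  With
padding modes (symmetric etc.) the coefficient count grows at each level
and energy is conserved only approximately (errors of several percent at
`J = 5`), which is why periodization is the default.  For lengths not
divisible by `2^J` (the 300-sample default epoch) the transform remains
invertible but tiles the spectrum only approximately; the observed effect
is ±1–2 nodes of leakage around a narrow-band component.

Per-node statistics: energy `Σc²`, population variance (divide by `n` —
the convention is stated because both conventions appear in the
literature), its square root, and waveform length `Σ|c_i − c_{i−1}|`.
Channels are processed independently and concatenated channel-major:
`n_channels × 2^J × 4` candidate features per trial (1280 for 10 channels
at level 5).  Averaging or pooling across channels would discard the
channel provenance that selection later exploits.

## Discrete estimation

Continuous features are discretized by equal-frequency binning (default 8
bins), fit on training rows only and then frozen — never refit at
evaluation.  Equal-frequency is the default because WPT energies are
heavy-tailed and equal-width bins would starve.  The joint `p(class, cell)`
is the empirical relative frequency over the Cartesian product of the
selected columns' bins, restricted to occupied cells; optional Laplace
smoothing adds mass only to retained cells (default off).  All entropies
are in bits.

In-sample Bayes risk is optimistically biased once cells become sparse
(mean occupancy below 5 triggers a warning): in the limit of one row per
cell the empirical risk is 0 regardless of signal.  This is the overfitting
mode of any in-sample greedy criterion.  The default mirrors the in-sample
procedure; a stratified two-fold cross-estimate of the risk is available
for the stopping rule (`SelectionConfig(cross_validate_risk=True)`).

The Rényi entropy is evaluated through the largest probability
(`H_δ = δ/(1−δ)·log2 p_max + …`) so that large orders neither overflow nor
underflow; the implementation is exercised at δ up to 1000, where the gap
to min-entropy obeys the exact envelope `0 ≤ H_δ − H_∞ ≤ H_∞/(δ−1)`.

## Selection

The greedy recursion, its Shannon variant, and univariate MI ranking share
one configuration: risk tolerance ε (default 0.05, i.e. stop at training
accuracy 0.95), subset cap `k_max` (default 16), and the binning rule.
Ties in the per-step arg-min are broken toward the lowest column index
(deterministic; column order is otherwise irrelevant and a permutation test
verifies it).  The reported risk trace is the running minimum of the
subset risk, starting from the prior risk of the empty set; for the
in-sample estimator the trace is non-increasing anyway because refining a
partition cannot lower the sum of cell maxima.

The equivalence of min-entropy minimization and `I_∞` maximization is not
assumed: `equivalence_check` runs both formulations and compares the
selected sequences.

Degenerate inputs: selection refuses single-class labels and all-constant
tables; individual constant columns are allowed (they collapse to one bin
and can never win a step).

## Synthetic data

**Sessions.** 6 runs × 12 trials per class per run × 4 classes = 288
trials, 72 per class, at 250 Hz on 10 channels; trials are 6 s with a 1 s
gap, and the class-specific oscillation is active during the 3–6 s imagery
window.  Each class drives one disjoint channel pair at its own centre
frequency (8, 14, 20, 26 Hz; 2 Hz bandwidth; 20 µV RMS — chosen as a
strong, clearly supra-threshold effect) as band-limited filtered noise with
a Tukey envelope, superposed on 1/f-amplitude background noise of 10 µV
RMS on every channel.  All randomness derives from one seed via
`SeedSequence` spawning with per-trial substreams, so sessions are
bit-reproducible.  The model omits volume conduction, ERD/ERS temporal
dynamics, ocular artifacts, and non-stationarity: passing tests demonstrate
that the pipeline recovers planted band-power structure, not that it
handles real-EEG confounds.

**Planted tables.** Informative column `j` elevates the mean of class
`j mod n_classes` by the effect size `d` (default 3) over unit-variance
noise — a one-vs-rest code in which every informative column is needed to
separate all classes, so self-stopping selection must take all of them.
Redundant columns are informative columns plus N(0, 0.1²) jitter.  The XOR
construction is two-class: columns 0 and 1 are fair coin flips and the
label is their XOR, so each member is marginally independent of the label.
Two XOR variants are used deliberately: with *binary* noise candidates all
features share one discretization cardinality, isolating the conditioning
behaviour of the greedy criteria (which must complete the pair immediately
after either member enters the subset); with *continuous* 8-bin noise the
noise columns carry a larger univariate MI estimation bias
(≈ (B−1)(|C|−1)/(2N ln 2)), which pushes the zero-MI pair to the bottom of
the univariate ranking — the redundancy/interaction blindness the baseline
is documented to have.  The binary-noise variant is not used to grade the
MI baseline, nor vice versa, because the in-sample greedy criterion
preferentially absorbs high-cardinality noise cells (the sparse-cell
optimism above), which is a property of discretization granularity rather
than of the conditioning structure under study.

## Problem sizes

The shipped experiments use the generator defaults throughout: full
288-trial sessions for the paradigm and end-to-end checks (two sessions
play the train/test days), 50 seeded tables of 50 features at 400 rows for
recovery, 1000 random joints for the identity suite, and 50 random
10-feature tables at 60 rows for the brute-force-oracle comparison (the
oracle enumerates every remaining candidate at every step, so modest tables
keep it exhaustive).  The ground-truth provenance test uses 3-run sessions;
channel provenance of the top selections is unaffected by session length.

## Known limitations

* Headline metric is accuracy only; kappa and per-class recall appear only
  through the confusion matrix diagnostics.
* The in-sample stopping rule inherits the sparse-cell optimism described
  above; with many high-cardinality features and few trials, enable the
  cross-estimated risk.
* Binning is per-feature (axis-aligned); jointly rotated structure is
  invisible until at least one axis carries signal.
* The EDF writer requires integer sampling rates and whole-second
  recordings.
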