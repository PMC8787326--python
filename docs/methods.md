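# Methods

This note records what each component computes, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a user should know about before trusting the output.

## 1. Sequence codec

Each of the 20 standard amino acids gets a digit value by alphabetical
one-letter order: A=1, C=2, …, Y=20. A sequence `r_1 r_2 … r_L` maps to the
base-21 integer

    code = Σ_{i=1..L} value(r_i) · 21^(L−i)

Digit 0 is never assigned, so codes of different lengths occupy disjoint
ranges and the map is injective over all sequences up to the supported
maximum length of 20. Codes are exact Python integers (21^20 exceeds 64-bit
range); the log transform `log_code = ln code` is what the models consume,
computed with `math.log`, which accepts big integers. Within a fixed length,
code order equals lexicographic sequence order — verified exhaustively for
all 400 dipeptides and 8,000 tripeptides in the test suite.

## 2. Conjugate series

Given records `(sequence, EC50)`, two series are built over the *same* data:

- **by_code** — records sorted by code; target `y = ln EC50`, input
  `u = ln code`. The input is smooth and monotone, the target inherits no
  order and behaves like noise.
- **by_activity** — records sorted by EC50; target `y = ln EC50` is now a
  sorted (monotone, strongly autocorrelated) profile, input `u = ln code`.

Ties are broken by the secondary key and then the original record index via
`numpy.lexsort`, making construction deterministic. Diagnostics
(`describe`, `autocorrelation`, `cross_correlation`) use scipy/biased
divide-by-n ACF conventions; the lag-0 ACF is always 1 and constant series
are rejected.

## 3. Fractal analysis

**Haar multiresolution analysis** is iterated single-level `pywt.dwt`
("haar" filters). Default boundary handling is `symmetric`; perfect
reconstruction holds for any length and mode. Energy conservation
(orthonormality) additionally requires `periodization` *and* an even signal
length at every level — odd lengths force a padding sample that adds
energy. The tests and acceptance script only assert energy conservation in
that regime.

**Hurst estimation** regresses `log2 Var(d_j)` of Haar detail coefficients
on scale `j` with counts as weights, then maps the slope to H. For a raw
(nonstationary) FBM path the map is `H = (slope − 1)/2`; for increments
(fGn) it is `H = (slope + 1)/2`. Default scales for FBM input are 2–9: the
finest scale is systematically biased for nonstationary input, and dropping
it reduces the measured bias at H = 0.3/0.5/0.7 from ≈ −0.13 to
≤ 0.06 in absolute value at n = 4096. Explicitly requested scale ranges are
always honored. Estimates are clipped to (0, 1).

**FBM simulation** uses Davies–Harte circulant embedding: the fGn
autocovariance is embedded in a circulant matrix, its FFT eigenvalues
(clipped at zero against round-off) drive an exact Gaussian synthesis, and
the path is the cumulative sum with `B(0) = 0`. This is exact, not
approximate: measured lag-1 increment autocorrelation at H = 0.5 is ≈ 0.001
(|ρ| < 0.05 asserted), and the across-path variance log-log slope at
H = 0.7 is ≈ 1.40 against the theoretical 2H = 1.4. Envelopes
(`fbm_envelope`) summarize many seeded paths by pointwise quantiles and can
place an observed profile among them.

## 4. NARX models

The model is series-parallel (open-loop) NARX:

    y(t) = f[ y(t−1…t−n_y), u(t−1…t−n_u) ]

with `f` a 10-unit tanh hidden layer and linear output. Presets:
`(n_y, n_u) = (3, 3)` for the code-sorted series, `(2, 2)` for the
activity-sorted series. Inputs and target are standardized on the training
partition.

**Training** is Levenberg–Marquardt implemented as damped Gauss–Newton with
an analytic Jacobian: damping μ starts at 1e-3, ×10 on a rejected step,
÷10 on acceptance; stopping on gradient < 1e-12, μ overflow (1e10), a goal
MSE, an epoch cap (200), or validation early stopping (patience 6, best
parameters restored). Fits are bit-reproducible given a seed.

**Data division** defaults to a *random* interleaved 0.70/0.15/0.15
train/validation/test split (seeded). On sorted profiles a contiguous
final-block test partition is pure extrapolation and measures a different
quantity than interpolative fit quality; the random split is also the
default division in the standard neural time-series tooling this design
follows. A contiguous split remains available (`random_split=False`).

**Prediction** offers one-step open-loop (`predict_open_loop`, measured
lags) and multi-step closed-loop (`predict_closed_loop`, predictions fed
back, exogenous future supplied).

## 5. Classification and the two-stage predictor

**Segments** cut the ln-EC50 axis at EC50 = 1 (ln = 0) and the panel
median: k = 2 uses the median only, k = 3 uses both. Intervals are
half-open with boundary values assigned to the upper class.

**Descriptors.** Each sequence yields 8 features: distinct-residue
fraction, maximum residue frequency, digit mean, digit standard deviation
(population), ln code, leading digit, length, terminal digit. The SVM is an
RBF `SVC(C=1, gamma="scale")` behind a `StandardScaler`, trained on a
stratified 70/30 split.

**Two-stage prediction.** A query sequence is (1) classified into a
segment, then (2) assigned a *coarse* estimate by inserting its ln code
into the code-sorted series and running the code-sorted NARX at the
insertion point, and (3) *refined* by one step of the activity-sorted NARX
between the two segment members bracketing the coarse estimate (or the two
nearest same-side members). The refined value is clipped to the segment
range ± the mean neighbor spacing; segments with fewer than two members
fall back to the coarse estimate with a warning. Classifier/coarse
disagreements trust the classifier and warn.

**Evaluation protocol** (`evaluate_method`): an outer contiguous split in
code order holds out `n − n_train` records (≈ 31 of 231 by default at the
panel scale); the segment scheme and both series come from the training
records only; classification can be `oracle` (true segment), `svm`
(trained on the training block) or `random`. MSE is reported in ln-EC50
units per seed with the median across seeds.

**BPNN baseline**: a 3–10–1 network (inputs digit mean, ln code, length;
logistic hidden layer) trained with the same LM optimizer, 1000-iteration
cap, goal MSE 1e-5; test MSEs over seeded random resamples are reported
as median/mean. On the default benchmark the two-stage predictor's median
test MSE is roughly a third of the baseline's.

## 6. Synthetic generator

`SyntheticSpec` produces a panel of unique di/tripeptides (default n = 231,
length mix 45% / 55%) with ln EC50 values generated by one of three links:

- `fbm_profile` (default): draw one FBM path with Hurst `hurst` (0.7),
  scale it by `profile_sd / n^hurst` so its spread is length-independent,
  and assign its values to records *in random order*; the *sorted* activity
  profile of the panel is then exactly the sorted FBM sample. Observation
  noise N(0, `noise_sd`²) (default 0.3) is added on the ln scale.
- `monotone_code`: ln EC50 = `code_slope` × standardized ln code — a fully
  classifiable regime for stress-testing classifiers and predictors.
- `independent`: activity is N(0, `profile_sd`²) independent of sequence —
  a null regime in which no method should beat the variance floor.

`ground_truth` regenerates and returns the noiseless activities, the
generating path and the true segment labels, verifying the records match
the spec that made them.

What this emulates: a right-skewed EC50 marginal (ln-normal-like), the
smooth persistent activity-sorted profile vs the random-like code-sorted
series, and a benchmark size of 231 with ≈ 31-record test blocks. What it
does **not** emulate: real ACE-inhibitory biochemistry — there is no
physicochemical model linking residues to activity; `fbm_profile` activity
is *independent* of sequence by construction, so sequence-based
classification is only informative under `monotone_code`.

Two statistical caveats worth stating plainly:

- The Hurst index of a *sorted* sample is not the Hurst index of its
  generating process: sorting produces a smooth monotone profile whose
  wavelet-variance estimate is ≈ 0.9 regardless of the generating H. The
  generator's H is recoverable from the generating path (exposed via
  `ground_truth`), not from the sorted panel profile.
- On sorted profiles, held-out blocks at the series edge are extrapolation;
  error there is dominated by saturation of the network outside the
  training range, not by interpolative model quality. Interior held-out
  queries on a noiseless monotone panel are recovered with MSE < 0.05.

## 7. Reproducibility and I/O

All stochastic components take explicit seeds (`numpy.random.default_rng`;
sub-streams via `SeedSequence` spawning in scripts). The pipeline runner
writes every artifact with a `config_hash` — a 16-hex-digit SHA-256 prefix
of the analysis configuration, excluding presentation-only fields
(output directory, log level) — so identical analyses produce identical
hashes wherever they are written. Tables are TSV with columns
`id, sequence, ec50`; FASTA input is supported with a separate id→EC50
activity table.

## 8. Limitations

- The NARX "insertion point" coarse estimate depends on the local density
  of the code-sorted series; in sparse code regions it degrades gracefully
  toward the segment fallback but is not calibrated.
- LM training is full-batch and dense; it is intended for the
  hundreds-of-records regime, not large panels.
- The SVM features are simple order/composition statistics; they carry no
  physicochemical information (hydrophobicity, charge).
- Energy conservation of the Haar transform is only exact in the
  even-length periodized regime (see §3).
- EC50 values must be strictly positive; all modeling is on the ln scale
  and back-transformed point estimates carry no uncertainty.
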