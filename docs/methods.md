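# Methods

This note documents the models implemented in `ecognet`, the defaults and
their rationale, the synthetic study conditions used by the test suite and
`scripts/acceptance.py`, and the numerical and design decisions that were
genuinely open.

## State-space conditional Granger causality

### Model

Multichannel trial data `y_t` (ROI-averaged, ensemble-normalised) are modeled
in innovations form

    x_{t+1} = A x_t + K e_t        (state transition)
    y_t     = C x_t + e_t          (observation)

with latent state dimension `m` (the model order), steady-state Kalman gain
`K` and innovations covariance `Sigma`. Validity requires stability
(`rho(A) < 1`), the minimum-phase property (`rho(A - KC) < 1`) and
`Sigma > 0`. The state-space form is preferred over direct VAR modeling
because downsampled, ROI-averaged signals are generically VARMA rather than
finite-order VAR, and because the frequency-domain causality quantities come
out of closed-form algebra on `(A, C, K, Sigma)`.

### Identification

A canonical-variate (CVA) subspace method. Per trial, past and future stacked
vectors `p_t = (y_{t-1}, ..., y_{t-h})`, `f_t = (y_t, ..., y_{t+h-1})` are
formed with horizon `h = max(20, 2 * order)` by default (no cross-trial
wraparound); the implementation accumulates one Gram matrix per trial so that
a model can be fitted to any subset of trials by summing per-trial Grams —
this is what makes the trial-permutation tests affordable. Canonical
correlations between whitened past and future give the state basis; `(A, C)`
follow from least squares on consecutive state estimates, and `(K, Sigma)`
from the steady-state filtering Riccati equation applied to the state/output
residual covariances. An unstable `A` (rare, borderline data) is shrunk
radially with a warning.

Order selection counts the principal angles between the past and future
subspaces that are significantly below pi/2: the observed canonical
correlations are compared with the `1 - alpha` quantile (alpha = 0.05) of the
largest canonical correlation after randomly permuting future columns
against past columns (20 surrogates by default), which destroys temporal
alignment while preserving marginal covariances.

### Spectral quantities

Transfer function `H(f) = I + C (e^{i 2 pi f / fs} I - A)^{-1} K` and CSD
`S(f) = H Sigma H*`, evaluated over 0–50 Hz at 0.5 Hz by default (the
analysis ceiling; recordings destined for connectivity analysis are
downsampled to 100 Hz). The resolvent is evaluated through the
eigendecomposition of `A` (with a direct solve fallback for
ill-conditioned eigenvector bases), shared between the full and all reduced
models.

For a source `j` and target `a`, conditional on all remaining modeled
channels, the reduced model omitting `j` is obtained by solving the discrete
algebraic Riccati equation (DARE) for the subsystem observation; with
`G(f) = H_R(f)^{-1} H_{full,R}(f)` (the reduced-model innovations expressed
in full-model innovations) the spectral conditional GC is

    f_{j->a|rest}(f) = ln( S^u_aa / (S^u_aa - |G_aj|^2 sigma^2_{j|rest}) )

where `S^u = G Sigma G*` and `sigma^2_{j|rest}` is the source innovations
variance partialled on all other channels. The subtracted term is a variance
of a projection, so the denominator is nonnegative by construction; values in
`(-1e-8, 0)` are clipped to zero and anything more negative raises (it
indicates a broken factorization). The DARE is solved by a structure-
preserving doubling iteration (tolerance 1e-12, residual-checked), with the
scipy QZ solver and a plain fixed-point iteration (tolerance 1e-10, 10^4
iterations) as fallbacks.

Band aggregation is the unweighted mean over in-band frequency bins
(inclusive bounds): theta 4–8, alpha 9–12, beta 13–30, gamma 31–50 Hz for
connectivity; ERSP reporting additionally splits gamma into low (31–69) and
high (70–150) gamma.

### The independent VAR route

`ecognet.varref` computes the same quantities along a completely different
path: exact autocovariances from the companion-form Lyapunov equation,
reduced models by explicit multivariate Yule–Walker regression truncated at
high order (128–160 lags), and transfer functions by VAR polynomial
inversion. It shares no identification, Riccati or resolvent code with
`ecognet.ssgc` and serves as the cross-check oracle in the tests; on
stable systems the two routes agree to near machine precision.

### A caveat on the spectral/time-domain identity

The frequency average of spectral GC equals the time-domain log-variance
ratio only when the target's intrinsic (source-partialled) spectral factor is
an outer (minimum-phase) function. This is not automatic: unconstrained
random VAR draws violate it, in which case the spectral mean falls genuinely
below the time-domain value — on one bivariate draw both computational routes
give a spectral mean of 0.215 against a time-domain value of 0.481, which a
long-simulation regression confirms. The identity checks in the test suite
therefore draw diagonal-dominant random systems and screen them with the VAR
route (redraw when the oracle itself deviates by more than 1%, conditional
trivariate systems being the fragile case), then hold the state-space
implementation to a 5% tolerance.

## Surrogate and permutation inference

* **Phase randomisation** replaces the Fourier phases of every trial and
  channel independently with i.i.d. uniform phases (DC and Nyquist kept
  real), preserving amplitude spectra to machine precision and destroying
  cross-channel dependence. Used to build the per-(pair, frequency) null for
  thresholding observed CGC: threshold at the 95th percentile of 2000
  surrogates by default (each surrogate re-identified at the observed model
  order — order re-selection under phase randomisation is unstable), subtract
  and trim at zero.
* **Pre/post permutation test**: statistic per (ordered pair, band) is the
  sum over in-band frequencies of |CGC_pre - CGC_post|; the null reassigns
  trials to conditions (sizes preserved) with full re-identification, 2000
  permutations by default; p = count(null >= observed) / n_perm (no +1
  correction; a `plus_one` variant exists in `ecognet.stats`), BH-FDR at
  q = 0.05 across pairs x bands, change direction from the sign of the
  (post - pre) band mean. Permutation and surrogate iterations use
  per-iteration seeds spawned from the caller's seed, so results do not
  depend on execution order.

Calibration note: with label permutation plus re-identification, the null for
an unaffected edge is exact only under full exchangeability. When the two
conditions genuinely differ somewhere in the network, small finite-sample
bias differences between the homogeneous observed groups and the permuted
mixtures can push a null edge's observed statistic past all permuted values;
the effect shrinks with trial length and with a model order generous enough
for the (generally VARMA) dynamics. This is why the planted-edge study in the
acceptance suite uses 2-s trials and order 26, and why occasional
granularity-floor false positives (probability ~ 1/n_perm per null test)
remain an irreducible feature of the `count/n_perm` convention.

## Hub centrality

Hub strength is weighted degree: `HS(i) = sum_j w(i->j) + w(j->i)` on a
band-aggregated CGC matrix (zero diagonal). The hub hypothesis for a target
node is `HS(target) > median(HS(others))`; the null permutes the off-diagonal
weight multiset over off-diagonal positions (full random permutation; a
pairwise-swap chain of 10 E transpositions is selectable and mixes to the
same distribution), 100,000 surrogates by default, `p = count/n_swaps`,
BH-FDR across the four bands. The statistic is invariant to global rescaling
of the matrix; the median makes it robust to extreme surrogates.

## Evoked responses

* **ERSP**: Morlet decomposition (7 cycles by default) on a log- or
  user-spaced grid; value = `10 log10(power / mean baseline power at that
  frequency)` with the trial average taken on power before dB conversion
  (`average="db"` flag for the alternative); default baseline is the
  pre-stimulus −150–0 ms silent interval. The baseline-window mean is 0 dB by
  construction up to Jensen-gap and sampling noise; at low frequencies the dB
  trace carries few independent samples per second (the wavelet is ~0.56 s
  long at 20 Hz), so stationarity checks are posed on time-means.
* **Mismatch difference wave**: congruent and incongruent trials (short-VOT
  /b/-bias and long-VOT /p/-bias words vs the reversed combinations; middle
  VOT steps excluded) are matched by VOT step before subtraction — unequal
  per-step counts are an error, not silently subsampled. Condition ERPs are
  band-pass filtered with the Kaiser FIR specification (0.5–50 Hz, 3624
  taps, beta = 5.65) applied forward-backward (zero phase, squared
  magnitude response).
* **VOT peak measures**: Peak 1 is the most negative point of the
  trial-averaged ERP in a window centered on 250 ms (+/- 75 ms), Peak 2 the
  most positive near 350 ms; flat windows resolve ties to the earliest
  extremum and are flagged. Pre/post latency comparisons go through the
  Wilcoxon signed-rank test.

## Shared statistics

* **Cluster-based permutation test** (1-D over time): pointwise two-sided
  Welch t, cluster-forming threshold at cluster_alpha = 0.05 with pointwise
  Welch degrees of freedom, cluster mass = summed t over contiguous
  same-sign supra-threshold runs, null = maximum |mass| over relabelings
  (exact enumeration when feasible), p = count/n_perm. Significant clusters
  shorter than 25 ms are discarded *after* p evaluation (they remain visible
  in `all_clusters`).
* **Wilcoxon signed-rank**: exact null for n <= 25 without rank ties, normal
  approximation with continuity correction otherwise (scipy backend; the
  tests verify the exact branch against full sign-pattern enumeration).
* **BH-FDR**: statsmodels step-up backend, verified against the brute-force
  `max{k : p_(k) <= k q / m}` definition.

## Behavior

The psychometric model is logistic in centered VOT (step − 3.5), bias
(/b/ = −0.5, /p/ = +0.5), disconnection (pre = −0.5, post = +0.5) and the two
disconnection interactions, fitted by IRLS (statsmodels GLM). The
by-word-pair grouping of the study design is honored through cluster-
bootstrap standard errors (resampling word pairs with replacement, 2000
resamples by default) rather than a mixed model: with seven clusters the
random-slope machinery is poorly identified, while the cluster bootstrap
targets the same inferential question. Trial-level bootstrap and Wald SEs are
selectable; complete separation triggers a ridge-penalized refit with a
warning. The reliable change index is the Jacobson–Truax form
`RCI = (post - pre) / (sd sqrt(2) sqrt(1 - r))` with externally supplied
norm SD and test-retest reliability, flagged at |RCI| >= 1.96.

## Synthetic study conditions

The generator emulates the structure of the study's data, with known ground
truth:

* **Task roster**: 6-step VOT grid fixed at {0, 8, 16, 24, 32, 40} ms (the
  endpoints and step count are given; even spacing is assumed). Extended
  design: 7 word pairs x 6 VOT x 2 biases x 6 repetitions = 504 experimental
  trials plus 126 filler and 63 catch (693 total). Intraoperative design:
  4 word pairs x 6 x 2 x 6 = 288 experimental (24 per bias x VOT cell) plus
  72 filler; congruency labeling yields 96 congruent and 96 incongruent
  trials for the mismatch contrast. Repetition counts are inferred from the
  printed totals jointly with the cell grid and are config-exposed.
* **Network trials**: nodes are damped stochastic oscillators (AR(2) with
  poles at `(1 - damping) exp(+-i 2 pi f0 / fs)`) so that couplings act in
  nameable bands; directed couplings are lagged cross-coefficients, and a
  coupling may optionally run through a noiseless resonant relay
  (`relay_damping`), which confines the directed influence sharply to its
  carrier band at the cost of making the observed process VARMA. Condition
  deltas add/remove/rescale couplings between "pre" and "post". Connectivity
  epochs default to 0–2 s at 100 Hz. Stability of the (extended) companion
  matrix is checked before simulation.
* **Evoked trials**: white noise plus a negative peak near 250 ms and a
  positive peak near 350 ms, both latency-shifted by 8 ms per VOT step; an
  extra mismatch component (Gaussian bump in 270–350 ms) on incongruent
  trials with per-phase amplitude; optional per-phase band-limited
  oscillatory power effects (dB change applied post-stimulus).
* **Behavioral responses**: Bernoulli draws from the logistic model above.

What the generator does **not** emulate: volume conduction and shared
reference artifacts, non-stationary background (anesthesia recovery drift),
1/f broadband structure, word-pair random effects, lapse/guess asymptotes in
the psychometric curves, and electrode displacement between recordings.
Passing tests therefore demonstrate correctness and calibration of the
algorithms under the modeled conditions, not robustness to every property of
real intracranial data.

## Problem sizes in the test and acceptance runs

Chosen so the full suite and the acceptance script each run in minutes on a
single CPU: connectivity trials of 100–200 samples at 100 Hz with 60–100
trials per condition; 500 phase-randomisation surrogates and 500 label
permutations where the routine-profile counts are exercised (the package
defaults remain 2000); hub nulls of 2,000–10,000 swaps (default 100,000);
cluster tests at 250 Hz with 96 + 96 trials and 250 permutations;
psychometric recovery at 504 trials with 150 bootstrap resamples per fit.
The planted-edge study uses the 5-node network above with the gamma edge
relay-mediated, identification order 26 and horizon 28 (generous relative to
the 13-dimensional minimal state of the VARMA generator, which keeps
underfitting bias from inflating null-edge permutation statistics).

## Known limitations

* Conditional spectral GC is reported per direction without symmetrization;
  pre and post conditions are identified independently (same maximum order),
  and surrogate thresholds are computed separately per condition.
* The permutation test's null is exact only under exchangeability; see the
  calibration note above.
* The band-limited relay coupling has no finite VAR representation over the
  observed nodes, so `NetworkSpec.var_coefficients` refuses it; use
  `extended_var_coefficients` (latent relay states) or the identification
  pipeline itself.
* The exact Wilcoxon branch declines to handle rank ties (falls back to the
  corrected normal approximation), matching its enumeration oracle's domain.
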