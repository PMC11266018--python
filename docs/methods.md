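# Methods

## Problem and model

`cvte` infers the direction of coupling between two complex-valued time
series, each given as a magnitude series and a phase series (the polar
decomposition z = a·e^{jθ}).  The motivating data are complex-valued fMRI
ROI time series, where the phase channel carries information that
magnitude-only analyses discard; any paired magnitude/phase (or more
generally, any paired two-channel) signals fit the same interface.

The directed-coupling measure from signal z₁ = (a, θ) to z₂ = (b, φ) is a
sum of four plug-in information quantities at a single conditioning lag τ:

    C(z₁→z₂) = R_{a→b} + R_{θ→φ} + R_{a→b|θ} + R_{θ→φ|a}

where R_{x→y} is transfer entropy — the conditional mutual information
I(y_t ; x_{t−τ} | y_{t−τ}) of the empirical distribution — and
R_{x→y|w} is partial transfer entropy, the same quantity additionally
conditioned on w_{t−τ}.  The two partial terms capture cross-channel
(magnitude↔phase) effects that the two within-channel terms miss.  The
simplified variant (`scte`) drops the partial terms; real-valued baselines
use the magnitude channel only, either symbolized (`ste`) or histogram-
binned (`hte`); an ablation variant (`cte_direct`) replaces the partial
terms by plain cross transfer entropies R_{b→θ} + R_{a→φ}.

Assumptions: weak stationarity over the analysis window, a single dominant
coupling lag (no multi-lag embedding), and enough samples (T ≳ 100) for the
4^d-cell categorical tables behind the symbolic estimators.

## Symbolization

Every sample is mapped to one of four codes using thresholds at μ_p and
(1±β)·μ_p, where μ_p is the mean of the positive samples (negative samples
use the mirrored rule around the negative-sample mean μ_n).  β defaults to
0.05.  Because the thresholds scale with the data, the encoding — and every
estimator built on it — is invariant to positive rescaling of a series,
which is the source of the method's noise robustness relative to raw-value
histograms.  Exact zeros are treated as non-negative and fall in the
innermost band (code 3).  Probabilities are exact categorical frequencies
over the four-letter alphabet; the width-based histogram (bin width =
joint range / T, overridable via `hte_bins`) is used only for the raw-value
HTE baseline, since symbols are already discrete.

## Delay selection

τ is the lag in 1..max_lag (default 10) maximizing the |Pearson
correlation| between source and lagged target.  By default one τ is scanned
from the magnitude pair (per ordered pair, in argument order) and reused
for all four terms; a per-term override (`tau_phase`) lets the phase terms
carry the delay scanned from the phase pair, which the simulation benchmark
uses — with nonlinear (quadratic) magnitude coupling the magnitude scan is
only intermittently informative and the phase channel must find its own
lag.  Absolute correlation is the default (`delay_mode="abs"`) so negative
couplings are found; ties break toward the smallest lag; constant inputs
fall back to τ = 1 with a warning.

## Significance and the direction verdict

For each of R = 100 repetitions the source signal is permuted in time
(magnitude and phase by the same permutation, preserving the per-sample
pairing and all marginals) and the surrogate-corrected difference

    ΔC(r) = [C(1→2) − C_sh(1→2; r)] − [C(2→1) − C_sh(2→1; r)]

is recorded.  A two-sided one-sample t-test of the R values against zero
gates the three-way verdict: significant and positive mean → z₁→z₂,
significant and negative → z₂→z₁, otherwise none.  Symbol codes are
permuted directly (symbolization commutes with permutation), so the
surrogate loop costs only the entropy evaluations.

**Calibration caveat.**  The t-test treats the R differences as independent
draws, but they share the single unshuffled difference; under the null of
independent signals the unshuffled causality is one draw from the same
distribution as its surrogates, so the t statistic scales like √R times a
standard normal and the test rejects far above the nominal rate (~80% of
independent white-noise pairs receive a direction).  We keep this form as
the default because it is the published procedure and it is what the
published benchmark numbers reflect (the histogram baseline's ~50%
benchmark accuracy is exactly forced-choice behaviour).  A calibrated
alternative, `p_method="surrogate"`, compares the unshuffled difference
against the quantiles of the shuffled differences (permutation p-value) and
holds the nominal false-direction rate; use it when "no coupling" must be a
credible outcome.

## Granger baseline

Order-J autoregressions without intercept are fitted by OLS in both
prediction directions; whether the candidate source's lags significantly
reduce the target's residual variance is judged by the nested-model F-test
at p < 0.05 (a raw variance comparison, which always declares some
direction, is available via `method="raw"`).  J defaults to the scanned
delay.  The F-test form is what makes the baseline collapse on quadratic
coupling: a² is uncorrelated with every lag of a for symmetric innovations,
so neither direction's test fires and the verdict is "none".

## Simulated benchmark

Six families of signal pairs with known z₁→z₂ causality are generated from
AR(2) recurrences with coefficients 0.952 and −0.9025 (stable complex roots,
modulus 0.95, period ≈ 6 samples), standard-normal innovations, coupling
coefficient 0.5, zero initial conditions and a 100-sample burn-in:
linear (L1–L3) or quadratic (N1–N3) magnitude coupling at lag 1, with
phases fully driven by the source magnitude (L1/N1, innovations shared with
the magnitude equations), forming their own coupled AR pair (L2/N2), or
independent white series (L3/N3).  T defaults to 146 points, a typical
fMRI run length.

Two representation details matter and are deliberate:

* The generated "magnitude" channels are signed AR series.  The entropy
  estimators consume the magnitude of the assembled complex signal — |a| —
  while the delay scans and the Granger baseline see the raw generated
  series (`SimulatedPair.observed()` implements the estimator view).  This
  observation model is what makes quadratic coupling visible to the
  symbolic estimators (b ≈ 0.5a² is monotone in |a|) while leaving the
  linear-correlation machinery blind to it.
* Generated phase series are used directly as real-valued series; no
  wrapping to (−π, π] is applied.

Noise for robustness sweeps is zero-mean Gaussian added independently to
each of the four component series at a specified per-series SNR
(10·log₁₀(var(signal)/var(noise)) dB); magnitudes are clipped at zero only
when the noiseless series is itself non-negative.  A complex-plane noise
mode exists behind `mode="complex"`.

The benchmark harness scores a method's verdict correct iff it equals
"forward" and reports group-wise accuracy (default 10 groups).  Its default
verdict is the **sign of the surrogate-corrected mean ΔC** — the three-way
verdict with the significance gate always passing — because the conservative
t-test mode converts noise-dominated cells (notably HTE) into "none"
verdicts and cannot reproduce the published forced-choice accuracies;
`verdict_mode="significance"` applies the full gate.

What passing benchmark tests does and does not show: the simulators share
the estimators' stationarity and single-lag structure, innovations are
Gaussian, and ground truth is unidirectional — so benchmark accuracy says
nothing about bidirectional coupling, hemodynamic convolution, slow drifts,
or non-stationary real fMRI data.

## Group analysis

Per-ROI complex series are arithmetic voxel means of magnitude and of phase
within each atlas label (phase averaging is arithmetic, not circular,
matching how the estimators consume the series; with preprocessed,
referenced phase data the values are far from the wrap point).  All-pairs
connectivity is the antisymmetric matrix of ΔC̄ values with BH-FDR across
the N(N−1)/2 edges; two-group comparison applies edge-wise two-sample
t-tests with BH-FDR, returning t-values on surviving edges and zero
elsewhere, with optional aggregation into the ten canonical resting-state
networks (the ROI→network table is user-supplied configuration).

## Numerical choices

* Entropies are computed in nats internally; reported values default to
  bits.  Direction verdicts are unit-invariant.
* 0·log 0 := 0; zero-probability cells contribute nothing.
* Lag alignment: tuples (v_t, v_{t−τ}) for t = τ+1..T, giving T−τ counted
  tuples.
* The partial terms use the joint-probability-weighted conditional-MI form,
  which is non-negative and reduces to plain transfer entropy when the
  conditioner is constant; a literal conditional-probability weighting
  (`literal_eq=True`) is retained for comparison only.
* Degenerate inputs: constant targets give exactly zero estimates;
  zero-variance ΔC with zero mean yields verdict "none" (p = 1), with
  non-zero mean it is treated as significant with a warning; rank-deficient
  Granger designs fall back to a small ridge with a warning.
* Reproducibility: every stochastic step flows from explicit seeds
  (`numpy.random.SeedSequence` spawning); `delta_c` accepts a seed pair so
  the antisymmetry ΔC(z₁,z₂) = −ΔC(z₂,z₁) is exact under mirrored seeds.

## Problem sizes used in the test suite

The acceptance tests run the benchmark at 200 pairs per cell (100 per SNR
point) with R = 100 shuffles; the acceptance script uses the full 1,000
pairs per cell.  At 200 pairs the Monte-Carlo standard error of a cell
accuracy is ≈ 3 points, well inside the 5-point comparison tolerance.

## Known limitations

* Plug-in estimators only; no kernel/k-NN (KSG) estimators and no
  embedding dimensions beyond a single conditioning lag.
* The published t-test verdict is anti-conservative under the null (see
  the calibration caveat); edge-wise FDR downstream inherits this.
* On linear full-causality signals the partial cross terms can slightly
  dilute rather than sharpen the verdict; the measure's advantage is on
  signals with genuine magnitude–phase cross effects.
* Shuffle surrogates destroy all temporal structure, not only cross-
  coupling; block or phase-randomized surrogates are not implemented.
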