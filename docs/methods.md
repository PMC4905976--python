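# Methods

## Model and procedure

The estimator follows the Granger logic — a source X "causes" a target
Y when X's past improves prediction of Y beyond Y's own past — but the
predictive models are nonparametric.  The two nested models of Y are
leave-one-out local-mean (Nadaraya–Watson-style) regressions on
delay-embedded predictors, with one Gaussian kernel per predictor
column and the per-column weights combined **multiplicatively**:

1. embed every channel with delay τ and dimension d, producing the lag
   columns z(t−τ), …, z(t−dτ) (strictly past; lag 0 would make the
   prediction problem trivial and the causal question empty);
2. fit Y on its own lags (plus conditioning lags, if any), and again
   with the source's lags added;
3. C = log of the ratio of the two leave-one-out error variances.
   Negative values mean the added predictors worsened the
   cross-validated fit; they are clipped to zero for reporting while
   the raw value is kept for statistics.

Multiplicative weighting is what makes one estimator serve the
pairwise, bivariate and fully conditional cases unmodified: a sample
that is distant from the query on *any* predictor column receives a
vanishing product weight regardless of the other columns.

### Significance

The null ("X's past carries no aligned information about Y") is
emulated by circularly rotating the source channel by an offset drawn
uniformly from [⌈L/3⌉, L−1].  The rotation preserves the source's
marginal distribution and (circular) autocorrelation but destroys its
temporal alignment with the target.  S = ⌈1/α − 1⌉ surrogates are
generated (19 at α = 0.05) and the real estimate is significant iff it
exceeds the maximum surrogate estimate — under exchangeability of the
real and surrogate statistics this max-threshold test has size exactly
α, which the suite verifies by Monte-Carlo calibration on decoupled
noise.  Only the source is surrogated; the restricted model is shared
between the real and surrogate estimates so the comparison is
like-with-like.

### Sensitivity Q

Within a fitted model, predictor column j is probed by moving each
query coordinate x_tj up and down by δ_j = Δ·(max_j − min_j) and
averaging the absolute prediction change, normalised by
2·T·|y_max − y_min|·Δ.  Only the query coordinate moves; moving the
stored sample coordinates together with it would cancel inside every
kernel distance and force Q ≡ 0.  (Moving *only* the stored samples is
algebraically identical to moving only the query, since the kernel
depends on the difference.)  Q = 0 means the predictor has no
detectable local influence.  Q is reported only for links that passed
the surrogate test, so it needs no separate significance machinery.
Whether Δ is an absolute nudge or a fraction of the predictor's range
is a genuine ambiguity of the normalisation; we use fraction-of-range,
which makes Q dimensionless and invariant to affine rescaling of the
predictor, and matches the magnitude of the published benchmark
sensitivities far better than the absolute reading (which is ~an order
of magnitude off for these systems).

## Parameters

| parameter | default | meaning |
|---|---|---|
| σ_j (kernel tolerance) | 1 for every column | Gaussian bandwidth per predictor, in the predictor's units.  `tolerance_from_range` offers the data-driven alternative (range/6). |
| τ (embedding delay) | 1 sample | spacing of the lags |
| d (embedding dimension) | 3 | number of lags per channel (6 for the Hénon benchmark, matching the BIC-selected linear order there) |
| α | 0.05 | surrogate-test level; sets S = ⌈1/α − 1⌉ |
| Δ | 0.05 | sensitivity nudge, as a fraction of the predictor column's range |
| window | none | optional non-overlapping window length for long records |

A fixed σ interacts with the amplitude of the data: channels whose
spread is much larger than σ produce sharply localised weights, fewer
effective neighbours, and in the extreme, query points whose weight
denominator underflows to zero.  Such points are flagged invalid and
excluded; both fits of a ratio are evaluated over the intersection of
their valid points so the two variances always describe the same
samples.  When channels live on very different scales, z-score first
(`cnpmr.zscore`); the suite verifies the exact equivalence "z-scored
data at σ = 1" ≡ "raw data with σ_j set to each channel's sd".

Residual variances use the sample (n−1) divisor; the choice cancels in
the log ratio.  Ties and degenerate inputs (constant channels, constant
predictor columns, fewer than two valid points) raise errors rather
than returning silent NaNs.

## Simulated benchmark systems

The five generators cover the canonical ground-truth situations:
purely nonlinear unidirectional drive (squared coupling), a linear
chain with an indirect edge, mixed linear/nonlinear coupling among
bounded noisy maps, deterministic chaos with tunable coupling
(non-identical Hénon maps), and saturation nonlinearity (the
unidirectional pair clamped into [0, 20] — "clamp" meaning pointwise
max/min against the band edges, not rounding).  Innovations are
standard normal (scaled by the printed 0.4 in the mixed-coupling
system); stochastic models start from zero initial conditions and
discard a 500-sample burn-in, the Hénon pair starts from uniform
(−0.1, 0.1) draws, discards 1000 transient iterations and retries
escaping orbits with fresh initial conditions.  Every realization
draws from an independent stream keyed by (seed, realization index),
so batches are reproducible element-by-element.

What the generators do *not* emulate: measurement noise separate from
process noise, nonstationarity, trends, line noise, or multi-trial
structure.  Passing benchmarks therefore demonstrates correctness of
the estimator on stationary systems with known coupling, not
performance on raw physiological recordings, which additionally need
normalisation, filtering and windowing choices.

## Reproduction scope and known discrepancies

With the standard settings (no normalisation, σ = 1, τ = 1, d = 3) the
package reproduces the published benchmark behaviour of this estimator
family in all qualitative respects, and quantitatively where the
conventions are unambiguous: the driving-direction causality of the
unidirectional nonlinear pair (0.35 vs 0.357 published), the
mixed-coupling sensitivities (within ~10%), the indirect-edge
suppression by conditioning, the exact conditional edge set of the
mixed-coupling system, and the Hénon pattern of a dominant x→y at
every coupling with reverse-direction significance emerging around
c = 0.5 (in our runs the onset sits *at* c = 0.5 rather than strictly
above it).  Under amplitude limiting the reverse direction is flagged
at roughly the nominal 5% test size — occasionally slightly above it,
consistent both with binomial noise and with a genuinely nonzero
effect, since the clamped source channel is no longer Markov and the
driven channel carries information about its latent past.

Several published magnitudes are, however, sensitive to conventions the
benchmark protocol leaves unstated, and we could find no single
convention that reproduces all of them simultaneously.  The non-driving
direction of the unidirectional pair comes out near −0.10 rather than
the published −0.003: adding three wide-amplitude (sd ≈ 3.9) irrelevant
lag columns at σ = 1 shrinks the median effective neighbourhood of the
model of x2 from ~350 to ~34 points, a real variance penalty of the
multiplicative kernel.  Z-scoring removes that penalty (−0.007) but
then the driving direction overshoots (0.46) and the sensitivity
lag-decay shapes degrade, so the unnormalised convention is kept.  For
the same reason the sensitivity magnitudes of the wide-amplitude
systems deviate (≈1.3× high for the unidirectional pair, ≈2.5× for the
near-resonant linear chain, ≈0.5× for the amplitude-limited pair whose
clamp at 0 zeroes half of the source channel) while their lag-decay
*shapes* match closely.  The linear-GC direction-misidentification
reported for weakly coupled Hénon maps also does not reproduce with a
plain nested-OLS F-test baseline, which detects the true direction
already at c = 0.05; no numeric linear-GC target is asserted.

## Problem sizes

Monte-Carlo sizes follow the benchmark protocol: 50 realizations of
1000 samples (100 for the amplitude-limited system), and a Hénon sweep
of 5 non-overlapping 750-sample windows per coupling value — the
windowed protocol at a reduced window count.  The leave-one-out fit is
computed as a dense T×T log-weight accumulation per predictor block
with per-block caching (the restricted model's block is reused across
all surrogate re-fits), which keeps a full 50-realization experiment
with surrogate testing in the tens of seconds on one CPU.
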