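# Methods

This note documents the models and procedures implemented in `rampasym`,
the choices made where the design was genuinely open, and what the
synthetic data do and do not establish.

## Stimuli

One battery per sound quality: seven 250 ms constant sounds (50, 55, 60,
65, 70, 80, 85 dB SPL) and sixteen linear-in-dB intensity ramps (50–85 and
60–85 dB, durations 0.1/0.25/1/2 s, both directions). Envelopes are
rendered at the imaging frame rate (31.5 Hz) with the onset on a frame
boundary and `round(duration × rate)` stimulus frames; ramps interpolate
linearly in dB between both endpoints inclusive. The silence floor defaults
to 0 dB SPL; the sigmoid intensity channels map it to ≈0 by construction,
so its exact value is immaterial downstream. Envelopes are piecewise linear
with abrupt edges (no onset/offset gating); `render_battery` pads all
stimuli onto one common grid (0.5 s pre-pad, total 5 s) so batteries stack
into rectangular tensors.

## Encoding models

All four models act on the dB envelope through one or two static sigmoid
intensity channels `amplitude / (1 + exp(−slope (s − midpoint)))` — a
"quiet" channel saturating at low levels (defaults 1, 50 dB, 0.25 dB⁻¹)
and a "loud" channel rising only at high levels (1, 72 dB, 0.25 dB⁻¹).
Three parameters per channel; brute-force grids where fitted.

- **Linear**: causal kernel on [0, 1] s applied to a monotone scaling of
  the envelope; fitted by minimum-norm least squares (Moore–Penrose
  pseudo-inverse via SVD).
- **Adaptation**: synaptic depression `d′ = −d/τ_a + u·s·(1 − d)`,
  `d(0) = 0`, `s_d = s(1 − d)`, then a fitted linear kernel. `(u, τ_a)` by
  brute-force grid search, kernel by pseudo-inverse at each grid point.
  The ODE is integrated with a fixed-step 4th-order Runge–Kutta scheme
  whose sub-steps align with frame boundaries (the input is held piecewise
  constant per frame, so the ODE is smooth within each step); the
  full-support integral of `s_d` is accumulated with a Simpson-consistent
  rule inside the same loop. An integrating-factor argument shows
  `∫ s·d dt` is a double integral symmetric under time reversal of `s`,
  so `∫ s_d` is exactly reversal-invariant for the continuous dynamics;
  numerically the residual sits at the floating-point floor for any step
  and the refinement test verifies it never grows under halving. The
  explicit scheme assumes inputs of order unity (channel outputs) and
  raises if the depression variable leaves [0, 1] grossly.
- **LN**: two kernels on [0, 2] s applied to the two channels, summed,
  then a monotone piecewise-linear output nonlinearity
  (`a(x−x₀)+c` below the kink, `b(x−x₀)+c` above, `a, b ≥ 0`). Kernels are
  fitted first (pseudo-inverse, before the nonlinearity), then the kink is
  grid-searched over output quantiles with `(a, b, c)` solved in closed
  form per candidate; negative slopes are clipped to preserve
  monotonicity.
- **Multilayer**: six feature detectors from the two channels — tonic
  (`s_c` itself) and ON/OFF per channel. ON (OFF) rectifies the positive
  (negative) part of the forward-difference channel derivative, smooths it
  with a causal exponential of time constant τ_f = 0.05 s (truncated at
  5 τ, normalized to unit discrete sum, so constants pass unchanged and
  discrete integrals are preserved exactly), and applies the shared
  rectifier `G(x) = x − θ` for `x > θ`, else 0. The order is
  rectify → smooth → threshold. The response is
  `a·tonic_Q + b·tonic_L + Σ h_{p,q} ⊗ feature_{p,q}` with transient-feature
  kernels on [0, 1] s; weights and kernels come from one pseudo-inverse
  solve per candidate θ, and θ from a brute-force grid (0–8 in steps of
  0.5) or fixed at zero.

**Why θ matters.** With θ = 0 the ON/OFF features integrate to the total
positive/negative variation of the channel, which is identical for a ramp
and its reversal; tonic features are pointwise functions of the envelope,
whose value multiset reversal preserves. Every feature integral — hence
every full-support response integral of the θ = 0 model — is exactly
reversal-invariant, and the normalized asymmetry is zero at every ramp
duration. With θ > 0 the threshold is subtracted for as long as a feature
is active: fast onset/offset transients (whose smoothed derivative exceeds
θ) survive while slow within-ramp derivatives are suppressed entirely, and
the durations of supra-threshold episodes differ between a ramp and its
reversal. This is the one mechanism in the model family that makes
integrated responses direction-selective.

**Train/test split.** Training: 0.25 s constants at 50/60/70/85 dB plus all
50–85 dB ramps (12 stimuli); test: constants at 55/65/80 dB plus all
60–85 dB ramps (11). Model comparison uses the fraction of unexplained
variance, `Σ residual² / Σ (target − mean)²`, pooled over clusters,
stimuli and frames of the named set.

**Reversal-integral oracle.** For a model and an envelope set, the oracle
returns `max |I_fwd − I_rev| / (|I_fwd| + |I_rev|)` with integrals over the
whole padded trace (stimulus + kernel tails + relaxation). The
onset→offset+500 ms window is reserved for data analysis; the invariance
theorem holds only over full support.

## Synthetic data

The generator's purpose is to produce surrogate sessions with the
statistical structure the analyses assume, with known ground truth.

- **Archetypes.** Six responsive families (quiet-ON 18%, loud-OFF 30%,
  quiet-OFF 4%, tonic 18%, ON+OFF 15%, loud-OFF+tonic 15% of responsive
  cells; 37% of all cells responsive) are rows of one generative
  multilayer model with θ = 2 s⁻¹ and exponential readout kernels
  (τ = 0.15 s). Selectivity outside a family's preferred range is produced
  by negative weights on the opposite channel's transient (e.g. quiet-ON =
  1.3·ON_Q − 1.55·ON_L), and the readout is rectified at zero when rates
  are generated. Down-ramp preference is carried by quiet-OFF and ON+OFF,
  so the population integral asymmetry for 2 s ramps is positive by
  construction. Per-family amplitudes are scaled so the deconvolved
  profile energy is comparable across families (in vivo, all cluster types
  show comparable response amplitudes); exact amplitudes and time
  constants are only qualitative in the source data and are configurable.
- **Fluorescence.** `F = F₀(1 + g·(rate ⊗ k)) + 0.7·F_np + η` with
  `k(t) = (1 − e^{−t/τ_rise}) e^{−t/τ_decay}` (unit peak, τ_rise = 0.1 s,
  τ_decay = 2 s), calcium gain g = 0.02 (peak transients ≈ 1.5 ΔF/F,
  GCaMP6s-like), and i.i.d. Gaussian frame noise of sd 0.10 ΔF/F per
  trial. τ_rise is set so the deconvolved signal lags a smooth rate
  transient by ~70–100 ms, the known consequence of the indicator rise.
  The neuropil trace is the population-average calcium signal low-pass
  filtered with a 200 ms Gaussian — a shared, slow, stimulus-locked
  contaminant — rather than a pixel-level simulation; a small pixel-frame
  fixture exercises the fill-in operator directly.
- **Gains.** Per-neuron lognormal gain (sd 0.5 in log space), giving the
  long-tailed SNR distribution the selection stage expects.
- **Layouts and behaviour.** Positions are uniform in 550 × 540 µm; with
  clumping `c`, each cell is instead drawn around its label's Gaussian
  center (sd 40 µm) with probability `c`. Learning curves are logistic,
  `0.5 + (plateau − 0.5)/(1 + e^{−k(t − t₀)})`, with per-mouse `k` and `t₀`.

**What the generator does not emulate.** Spontaneous activity, correlated
trial-to-trial response variability, indicator supralinearity, and pixel
geometry. Because the first two are absent, single-trial population
reproducibility on synthetic data (~0.9) is far higher than in vivo
(~0.2); passing tests therefore establish the correctness and calibration
of the procedures, not their statistical power on real recordings.

## Preprocessing

Neuropil fill-in uses a spatial Gaussian of σ = 170 µm (reflective
boundaries, truncated at 4σ — conventions shared by every Gaussian filter
in the package). Correction weight 0.7. Baseline F₀ is the minimum of the
per-block Gaussian-filtered trace over 42 s blocks (smoothing σ = 1 s, a
package default chosen longer than transient rise times and shorter than a
block; the trailing partial block uses its own minimum). Deconvolution uses
the raw forward difference times the frame rate plus `f/τ`, τ = 2 s, with
no pre-smoothing; the exponential `e^{−t/τ}` is annihilated up to a
forward-difference residual of relative size `dt/2τ ≈ 0.8%` at 31.5 Hz.
Nonpositive baselines raise and flag the neuron. The tensor-level chain
treats each rendered stimulus trace (≈5 s) as one baseline unit and
processes neurons in chunks to bound memory.

## Population statistics

Similarity between conditions `(stimulus j, frame t)` is the mean Pearson
correlation across the neuron dimension over all single-trial vector
pairs, computed after temporal smoothing (σ = 60 ms); for a condition
against itself, same-trial pairs are excluded, making the diagonal a
cross-trial reproducibility strictly below 1 under noise. Zero-variance
vectors are skipped and logged. Integrals use the trapezoid rule on the
frame grid over [onset, offset + 500 ms]. The asymmetry index defaults to
the mean-normalized form `2(I_up − I_down)/(I_up + I_down)` (bounded in
[−2, 2]); the down-normalized alternative `(I_up − I_down)/I_down` is
available. Across sessions: per-condition one-sided tests (rank-sum on
integral pairs, or signed-rank of indices against zero), BH step-up across
conditions, and a pooled one-sided signed-rank test.

## Clustering

Selection keeps neurons whose pooled per-trial response means differ from
the preceding 0.5 s baselines (paired Wilcoxon signed-rank, P < 0.05) and
differ across stimuli (Kruskal–Wallis, P < 0.05); response windows run
onset→offset+0.5 s, matching the integral convention. The SNR of the
concatenated trial-resolved profile is the std over time of the trial mean
divided by the mean over time of the across-trial std (the source
definition is not recoverable verbatim; this default is pluggable and
produces the expected long-tailed distribution), capped for noiseless
input. The top 30% by SNR are clustered: z-scored concatenated trial-mean
profiles (smoothed, σ = 31 ms; z-scoring per cell over the whole profile),
Euclidean distance, complete linkage, tree cut to `n_cut` clusters,
clusters under 10 cells dropped, remaining selected cells assigned to the
highest-correlating surviving centroid when ρ > 0.1 (ties to the lowest
cluster id). For z-scored length-L profiles, squared Euclidean distance is
`2L(1 − ρ)`, so the metric and the reassignment criterion are two views of
the same similarity.

`cluster_pipeline` defaults `n_cut` to `min(50, n_clustered // 14)`. The
reference procedure cuts ~700 clustered cells into 50 clusters — about 14
cells per pre-prune cluster — and it is that granularity, not the absolute
count, that transfers across dataset sizes: forcing a 50-cut on a much
smaller set shatters it into pieces below the minimum size and the prune
deletes everything. `hierarchical_cluster` itself keeps the explicit
`n_cut = 50` default.

## Spatial statistics

The homogeneity index of a cluster is the mean, over its cells with at
least one neighbour, of the fraction of same-label cells within 30 µm
(self excluded, no edge correction; a radius-sweep utility is provided).
The null permutes labels within each animal; `p = (1 + #{null ≥ obs}) /
(1 + n_shuffles)` with the 2.5–97.5 percentile null band, BH-corrected
across clusters. Only labelled (clustered) cells enter the shuffle. Under
a uniform layout the uncorrected per-cluster rejection rate calibrates to
α = 5%; after BH, with all nulls true, the family-wise error is controlled
at α, so the corrected per-cluster rate is necessarily below 5% — the
package's calibration check asserts both facts separately.

## Behaviour

Day-level lick ratios are Σpost/Σpre per mouse (zero pre-stimulus counts
yield a logged missing value). Learning curves are fitted with the
logistic family above by bounded least squares; "sigmoid" is not otherwise
specified in the source, and an initial delay phase is absorbed by t₀. The
rise duration is the time from 20% to 80% of plateau-above-chance,
`2 ln 4 / k`, invariant to rescaling of the effect size; curves whose
fitted plateau is within 0.05 of chance return a missing value. Groups are
compared by the two-sample Kolmogorov–Smirnov test on individual rise
durations; the plateau estimate is the fitted asymptote, not the empirical
maximum.

## Problem sizes and numerical conventions

The shipped tests and the acceptance script use: 1,000 random kernels for
the linear reversal oracle; a 10 × 10 logarithmic `(u, τ_a)` grid with
1/2/4 sub-steps per frame for the adaptation check; six archetype targets
with 5% additive noise for model fitting; one 1,000-neuron, 20-trial
session for clustering recovery; 200 replicate 300-cell maps with 200
shuffles each for spatial calibration; and twelve 150-neuron sessions for
the end-to-end asymmetry sign. These sizes make every property measurable
with comfortable margins on a single CPU. Least squares is solved by SVD
with numpy's default rank tolerance (minimum-norm solution on
rank-deficient designs). Known limitations: the generator's archetype
amplitudes are qualitative; the quiet-OFF family (4% of responsive cells)
is too small to seed its own core cluster at the 1,000-neuron scale and is
absorbed by correlated clusters during reassignment, which bounds
archetype recovery near 96%; and the θ-grid resolution (0.5) limits
threshold recovery accuracy to half a grid step.
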