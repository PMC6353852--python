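# Methods

## Model

The observer estimates a latent scalar (e.g. the timbre a percussion
instrument will produce) with a Gaussian prior N(η, s_p).  An event supplies
n samples of per-sample variance σ², i.e. a Gaussian likelihood for the
sample mean x̄ with variance s_l = σ²/n.  Conjugate updating yields the
posterior with precision 1/s_p + 1/s_l and precision-weighted mean.  All
logarithms are natural; every entropy and divergence is reported in nats
(this makes the closed forms below exact, with no base-conversion factor).

**Arousal = information gain.**  The KL divergence of the posterior from the
prior has the closed form

    G(δ, s_p, s_l) = ½ [ s_p δ²/(s_p+s_l)² + ln((s_p+s_l)/s_l) − s_p/(s_p+s_l) ],

δ = x̄ − η.  We adopt the sign convention δ = reality − expectation; only δ²
enters G, so the choice is cosmetic but documented.  G decomposes as
α δ² + β with α = s_p/(2(s_p+s_l)²) and β = ½[ln((s_p+s_l)/s_l) − s_p/(s_p+s_l)];
the package computes `gain` as α δ² + β so the decomposition identity holds
bitwise.  ∂β/∂s_p = s_p/(2(s_p+s_l)²) is strictly positive — the test suite
asserts the strict increase of β in s_p on dense grids.

**Crossover.**  Two gain curves at uncertainties s_p1 ≠ s_p2 with shared s_l
intersect at positive δ iff s_p1·s_p2 > s_l².  On the exact boundary the
quadratic coefficients coincide (parallel curves, distinct intercepts): the
package reports "no crossover" rather than raising, because the input is
valid, merely measure-zero.  Asking for the crossover of two *equal*
uncertainties is a degenerate-input error.  Only the non-negative root δ\*
is reported; the mirrored negative root is implied by evenness.

**Valence.**  Reward and aversion are sigmoids of G with thresholds G_r <
G_a, asymptotes h_r < h_a and gradients c_r, c_a; valence is their sum.  The
thresholds enter the exponent unscaled (exponent = −c·G + threshold), so each
sigmoid's midpoint sits at G = threshold/gradient.  No numeric values for
the six parameters are established empirically; the shipped defaults
(G_r = 2, G_a = 6, h_r = 1, h_a = 1.5, c_r = c_a = 1) were chosen once to
satisfy both ordering constraints and to give a clear inverse-U with an
interior optimum (≈ 3.733 nats); all are overridable via config.  Valence at
G = 0 is slightly nonzero for finite thresholds; we follow the formula and do
not subtract a baseline to force neutrality.  The inverse-U is asserted for
the shipped defaults, not claimed universally: with both constraints
satisfied but midpoints close together the positive lobe can vanish.

**Desensitization.**  Repeated exposure is formalised as posterior-becomes-
prior iteration against a fixed stimulus with constant s_l per step (whether
s_l should itself shrink with familiarity is an open modelling question; we
hold it fixed).  Noise-free dynamics are exact: variance after k updates is
1/(1/s_p0 + k/s_l) and δ shrinks geometrically by s_l/(s_p,k + s_l).
Optional Gaussian observation noise requires an explicit seed; there is no
hidden global random state anywhere in the package.

## Synthetic experiment generator

The generator emulates a within-subject 2×2 design: familiarity (A familiar
/ B unfamiliar) × congruity (X congruent / Y incongruent), 8 stimuli (2 per
cell), presented in randomized sets with ISIs uniform on 1000–2000 ms.  The
main session uses 20 sets (160 trials/subject), the sound-only session 5
sets (40 trials/subject), 9 subjects by default.

**Condition mapping.**  The design maps onto the model as s_p(A) = 0.2,
s_p(B) = 1.0, s_l = 0.1, δ(X) = 0, δ(Y) = 2.0.  The scale is a modelling
choice (the canonical gain-curve family is plotted over s_p 0.2–1.0 at
s_l = 0.1); the essential requirements, enforced at validation, are
s_p(B) > s_p(A), δ(Y) > δ(X) ≥ 0, and δ(Y) beyond the crossover point
(δ\* ≈ 0.870) — the regime in which the interaction reverses sign.  Cell
gains: AX 0.216, BX 0.744, AY 4.660, BY 2.397 nats, i.e. BX > AX but
AY > BY.

**Likert ratings.**  Latent surprise = 1 + 1·G + subject effect
(sd 0.3) + response noise (sd 0.5), cut at 1.5/2.5/3.5 into ratings 1–4.
Noise-free, the four cells land exactly on ratings 1 (AX), 2 (BX), 3 (BY),
4 (AY).  Slope and cut points were chosen so the noise-free mapping uses the
full 4-point range; the noise levels are plausible single-trial rating
variability, set once.

**ERP epochs.**  500 Hz, −200 to +1500 ms around video onset (half-open
grid: sample i at −200 + 2i ms, i = 0…849; the +1500 ms endpoint is
excluded), sound event at +500 ms, channel Pz (the dominant P300 site; the
forward model synthesizes one channel).  Each epoch is a Gaussian bump of
width 50 ms centred at sound onset + latency (latency ~ N(350, 20²) ms,
clipped inside the search window), amplitude

    A = 4 + 2·G + subject offset (sd 1 μV) + subject×condition offset (sd 0.8 μV)  [μV]

plus band-limited background noise: white Gaussian noise smoothed with an
8 ms Gaussian kernel and rescaled to sd 2 μV (a qualitative stand-in for
low-pass-filtered EEG background; the acquisition chain's 0.1–20 Hz bandpass
and 3 s time constant are not modelled).  These values give single-subject
P300 effects of a few μV over a ~2 μV noise floor — physiologically
plausible and set once, not tuned per run.

**P300 extraction.**  Baseline = mean of the 200 ms pre-onset window,
subtracted; any raw sample beyond ±100 μV rejects the epoch (ocular-artifact
rule); amplitude = maximum of the corrected signal 250–600 ms after sound
onset; latency = time of that maximum, earliest sample winning ties.  The
noise-free synthesize→extract round trip is exact because the default peak
latency (350 ms) falls on the 2 ms sample grid.

**What passing tests do and do not show.**  The generator realises the
model's own assumptions (Gaussian bumps, linear gain→amplitude, additive
Gaussian effects), so the end-to-end detection of the crossover interaction
demonstrates internal consistency and adequate statistical power at the
design's size — not empirical validity on real EEG.  Real data add overlapping
components, non-Gaussian artifacts, drifting baselines, and an unknown
gain→amplitude law, none of which are simulated.

## Statistics

Two-way repeated-measures ANOVA with subject-by-effect error strata;
multiple trials per subject×cell are averaged first (standard ERP practice).
No sphericity correction: both factors have 2 levels (1 df), so the
correction is moot.  Simple main effects are per-slice one-way
within-subject ANOVAs (per-slice error strata, not pooled — a deliberate
choice where conventions differ).  Degenerate strata are reported explicitly:
zero error SS with positive effect SS gives F = ∞, p = 0; zero effect and
zero error gives F = NaN.  Unbalanced tables raise; nothing is imputed.
The crossover-pattern detector returns true iff mean(BX) > mean(AX) and
mean(AY) > mean(BY), with ties flagged and treated as "not detected".

The sums of squares partition the total exactly (asserted to 1e-8 against a
loop-based definitional computation), and the engine's F and p values are
cross-checked against pingouin in the test suite.  Under null simulations
the interaction test's rejection rate at α = 0.05 is calibrated (asserted
within [0.04, 0.06] over 2000 replicates).

## Numerical choices

- Variances must be finite and strictly positive; never clamped.  Flat-prior
  behaviour is exercised with large finite s_p.
- Posterior mean computed in convex-combination form η + w(x̄−η), which is
  exact when x̄ = η (keeps noise-free exposure trajectories at δ ≡ 0).
- Sigmoids via `scipy.special.expit` (no overflow at extreme arguments).
- Valence optimum: 10 001-point grid scan then bounded golden-section
  refinement, tolerance 1e-8 in G; a numerically flat objective raises a
  no-unique-optimum error.
- Algebraic identities are tested at 1e-10; quadrature comparisons at 1e-6
  (quadrature error dominates).
- Batch ERP synthesis and extraction are vectorized over trials; the
  replicate studies in the acceptance script (200 end-to-end sessions, 2000
  null ANOVAs) run in well under a minute each at the default sizes.

## Known limitations

- Gaussian-conjugate beliefs only; no hierarchical or non-Gaussian filtering.
- The valence parameters are illustrative defaults, not fitted to behaviour.
- The ERP forward model is a single-component abstraction; it supports
  testing the extraction and analysis pipeline, not waveform realism.
- The condition→(s_p, δ) mapping is a declared modelling scale, not a
  measured quantity; conclusions from the synthetic experiment are about the
  model's internal predictions.
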