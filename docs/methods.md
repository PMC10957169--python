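# Methods

## Model

N binary units s_i(t) ∈ {0, 1} are conditionally independent given N_F
latent variables h_μ(t):

    P(s_i = 1 | h(t)) = 1 / (1 + exp(η (J h(t))_i / √N_F + ε)),
    J_iμ ~ N(0, 1)  i.i.d.

Because the units are conditionally independent, the normalisation of the
joint distribution factorises into per-neuron logistic terms and is never
computed explicitly. Two conventions deserve note:

* **Sign of ε.** ε is a bias *towards silence*: P(s=1) decreases with ε.
  Equivalently P(s_i = 0) = 1/(1 + exp(−η(Jh)_i/√N_F − ε)), which is the
  per-neuron factor of the silence probability used throughout the theory
  module.
* **Drive normalisation.** The latent drive is scaled by 1/√N_F so that the
  per-neuron input variance equals η² (for stationary unit-variance
  latents) however many fields carry it. This makes η directly comparable
  between single- and multi-variable populations — the statistics of a
  five-field population at given η differ from a one-field population only
  through the slower decorrelation of the total drive, not through its
  scale. For N_F = 1 the drive is exactly η J_i h.

**Latent dynamics.** In OU mode each h_μ follows the exact stationary
discretisation

    h(t+1) = h(t) e^(−1/τ_F) + sqrt(1 − e^(−2/τ_F)) ξ(t),  ξ ~ N(0,1),

initialised from N(0, 1), so the marginal distribution and the
autocorrelation e^(−Δ/τ_F) are exact at every τ_F (no Euler bias; the
recursion is evaluated as a vectorised AR(1) filter). In quasi-static mode
h is piecewise constant: a fresh N(0, 1) value per segment, with segment
boundaries recorded so that detection never joins activity across a
redraw. Fresh replicates redraw couplings, latents, and spikes.

**Parameters and defaults.** The study conditions are: N = 1024 neurons,
T = 2×10⁶ time steps, η = 4, and (N_F = 5, ε = 12) or (N_F = 1, ε = 8),
with τ_F ∈ [10³, 10⁵] steps; the quasi-static characterisation uses
N = 128, η ∈ 1…10, ε ∈ 2…14. `bin_seconds` is pure metadata declaring the
real-time duration of one bin (3–10 ms is typical of experimental
binning); no computation depends on it.

## Avalanche detection

Bins with population count strictly above a threshold (default 0) are
active; each maximal active run is one avalanche with duration D = run
length and size S = summed count. Runs touching a recording edge or a
quasi-static segment boundary have unknown true extent and are discarded
(counted separately); at T ≫ D this removes O(segments/T) of events and
biases nothing measurable. Thresholding is exposed because real recordings
of modest size have no silent bins; in this model raising the threshold is
equivalent to raising ε.

## Power-law inference

Sizes and durations are integers, so the discrete (Hurwitz-zeta-normalised)
power law is fitted throughout. The MLE solves
ζ'(α, x_min)/ζ(α, x_min) = −⟨ln x⟩ by bracketed root finding on α ∈ (1, 6]
for x_min ≤ 6, and uses the continuous-tail approximation
α = 1 + n/Σ ln(x_i/(x_min−½)) above (the two agree to <0.01 for
x_min ∈ [7, 50] on large samples). ζ and its α-derivatives come from
scipy's Hurwitz zeta with central finite differences (steps 1e−5/1e−4);
the standard error is the inverse root of the observed log-likelihood
curvature, n·d²lnζ/dα².

The lower cutoff scans every integer value present in the sample that
leaves ≥100 tail observations, scoring each by the KS distance between
empirical and fitted CDFs over its tail; the selected cutoff is the
*smallest* whose KS is within 10% of the global minimum (resolving
two-local-minima KS curves in favour of the longer power law). Candidates
whose MLE falls outside (1, 6] are inadmissible — this matters for
thin-tailed samples, which otherwise evade rejection by retreating into a
steep far-tail pocket of ~100 observations. No upper cutoff is fitted.

Goodness of fit uses semi-parametric surrogates: each surrogate matches
the sample size, drawing each observation from the fitted power law above
x_min with probability n_tail/n and uniformly from the empirical values
below x_min otherwise; every surrogate is refit from scratch and the
p-value is the fraction of surrogate KS distances at or above the
empirical one (pass at p ≥ 0.1, the conventional level; 1000 surrogates by
default, configurable). Samples beyond 500,000 observations are randomly
subsampled to that cap before fitting and surrogate analysis, so the test
retains comparable power across simulations of very different length. The
power-law sampler used for surrogates (and as a test oracle) inverts the
exact discrete CDF over a 10⁵-value table and falls back to the rounded
continuous inverse beyond it, where discreteness is negligible.

## Size–duration scaling and the crackling relation

γ is fitted on log₁₀ S̄(D) vs log₁₀ D (unweighted least squares on
per-duration means). Durations are linearly sampled, so a single global
fit over-weights short durations; the range is instead selected by decade
scanning: (1) on a quarter-decade grid of candidate lower cutoffs, fit one
decade at a time and keep the cutoff whose slope is consistent (±0.05)
with the largest number of subsequent decade windows (ties → smallest
cutoff); (2) grow the upper cutoff on the same grid until the first-decade
residuals acquire a significant sign bias (two-sided sign test at 0.05 —
distribution-free on log residuals; residuals below 1e−9 count as zeros so
exact tables are never flagged); (3) refit over the selected range with a
95% t-interval. A fit requires at least one avalanche of size ≥500 and a
table spanning ≥1 decade; runs enter cross-parameter comparisons only when
the selected range spans ≥2 decades. The prediction is
γ_pred = (α−1)/(τ−1) with first-order error propagation, and the crackling
check is |γ_fit − γ_pred| ≤ 0.1. Window consistency compares slopes only,
not intercepts.

## Avalanche-probability theory (quasi-static)

Conditioned on h, bins are i.i.d., so an avalanche initiates exactly when
a silent bin precedes an active one: P_ava(h) = P_sil(h)(1 − P_sil(h)) ≤ ¼
with P_sil computed in log space. At h = 0, P_sil = (1+e^(−ε))^(−N)
independent of couplings, maximised at ε₀ = −log(2^{1/N} − 1) ~ ln N. The
expected avalanche count is T·∫P_ava(h)φ(h)dh; it counts initiations and
matches detected catalogs up to boundary discards, provided enough
segments sample the latent space (10³ segments in the validation runs —
with far fewer, the realised latent values under-sample the narrow
avalanche-productive region at large η and the observed count fluctuates
well beyond counting noise). For OU latents the same integral is only an
approximation (bins are correlated over τ_F) and is treated as such.

**Numerical integration.** P_ava(h) is a pair of bumps centred where
P_sil crosses ½, of width ~1/(η max|J_i|) — far narrower than the latent
prior at large η. Fixed Gauss–Hermite rules under-resolve them (order 201
shows ~2×10⁻³ relative error at η ≈ 4), so the default integrator is
adaptive quadrature on [−60, 60] with the P_sil = ½ crossings supplied as
break points (relative error <10⁻⁸ against panel-integration oracles); a
Gauss–Hermite path of configurable order remains available for broad
integrands. Regime classification: below an integrated probability of
10⁻³ a point is avalanche-free — silent if P_sil(0) ≥ ½, else
high-activity (the population-level silence probability discriminates
correctly where per-neuron rates would not, e.g. ε = 3, N = 128: every
neuron fires rarely yet the population never falls silent); otherwise
Type 1 (ε < ε₀, avalanches from rare latent excursions, high fit cutoffs)
or Type 2 (ε ≥ ε₀, low cutoffs).

## Latent-variable information

For a single quasi-static latent observed through T bins, the MLE h* of h
solves a concave scoring equation (unique root, found by expanding-bracket
root finding; recordings that are entirely silent or saturated carry no
latent estimate and return NaN). The Fisher information

    1/σ² = Σ_i T (η J_i)² / (4 cosh²((η J_i h + ε)/2))

is exactly linear in T, and the mutual information in the Gaussian-MLE
approximation is I = ½⟨ln(1/σ²_h)⟩ over h ~ N(0, 1) (Gauss–Hermite order
101 by default — the log-Fisher integrand is smooth and broad — or Monte
Carlo), reported in nats; scaling T multiplies σ⁻² uniformly, so I grows
by exactly ½ ln(T₂/T₁). The approximation fails at activity extremes; the
validity flag is a package heuristic, not a closed-form boundary: a point
is invalid when the population mean firing probability exceeds 0.45
anywhere in |h| ≤ 2, or when the decoder at h = 0 is less precise than the
N(0, 1) prior (1/σ² < 1). Both thresholds are configurable module
constants.

## Sweeps and reproducibility

Every run is bit-reproducible from its config (one integer seed feeds
couplings → latents → spikes → fit subsampling in a fixed order). Sweep
records derive their seeds from SHA-256 of (base seed, parameter values,
replicate) — keyed by values, not grid position, so reordering a sweep
changes nothing. Failed fits yield missing-value records rather than
aborting, mirroring how non-power-law parameter combinations drop out of
comparisons.

## What the synthetic data does and does not emulate

The generator *is* the study's data source: all results are statements
about this model. It reproduces the features that matter for avalanche
analysis — conditional independence given shared slow inputs, logistic
single-neuron nonlinearity, Gaussian coupling heterogeneity, stationary
latent dynamics. It omits direct neuron–neuron coupling, place-field-like
tuned inputs, refractoriness, non-stationarity of the latent statistics,
and measurement effects (spike sorting, subsampling, imaging forward
models). Passing tests therefore validate the mechanism — latent drive
suffices for avalanche criticality — not any claim about a specific
biological recording.

## Problem sizes

The validation suite regenerates the three full-length recordings
(2×10⁶ steps × 1024 neurons, ~40 s each) and a 3×3 quasi-static sweep with
3 replicates at N = 128 (~2.5 min); estimator checks use 10⁵-observation
synthetic samples, and surrogate-test power is assessed at 10³
observations × 100 surrogates × 100 trials. These sizes give sampling
error comfortably below every tolerance asserted while keeping the whole
suite in the ten-minute range on one CPU.

## Known limitations

* The avalanche-count theory and the information calculation are derived
  for a single latent field; multi-field behaviour is studied by
  simulation only.
* The KS-cutoff selection is a discrete argmin: on distributions that are
  only approximately power law (notably the one-variable model at fast
  τ_F, which the analysis itself flags as a poor fit), nearly-tied KS
  minima at very different cutoffs can flip the selected exponent between
  samples.
* The surrogate test's power depends on the tail size; with the 500,000
  cap it is deliberately strong, and marginal distributions near the
  pass/fail boundary should be read together with their KS values.
* OU-mode avalanche counts have no exact closed form; the quasi-static
  integral over- or under-counts depending on τ_F relative to typical
  avalanche durations.
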