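# latent-avalanches

Avalanche criticality in neural populations driven by latent dynamical
variables: simulation, avalanche statistics, crackling-noise scaling, and
latent-variable information.

## The scientific problem

Power-law distributed "neuronal avalanches" — bouts of contiguous population
activity bounded by silent time bins — are widely reported in neural
recordings and often read as evidence that cortical networks sit at a
critical point. An alternative explanation is that a population of neurons
coupled to a few slow, unobserved inputs produces the same statistics
without any tuning of network parameters. This package implements that
latent-variable model end to end and asks: under which parameters does it
produce avalanche criticality, and how much information does the activity
then carry about the latent inputs?

The model: N binary neurons fire conditionally independently given N_F
latent variables h_μ(t),

    P(s_i = 1 | h) = 1 / (1 + exp(η (J h)_i / √N_F + ε)),   J_iμ ~ N(0, 1),

where η scales the latent input, ε biases neurons towards silence, and each
h_μ is a stationary unit-variance Ornstein–Uhlenbeck process with
correlation time τ_F (or a quasi-static variable redrawn from N(0,1) every
segment). The 1/√N_F factor keeps the per-neuron input variance at η²
regardless of how many fields carry it.

An avalanche is a maximal run of bins with population activity above a
threshold (default: at least one spike); size S is the summed activity,
duration D the run length. The analysis chain fits

* P(S) ∝ S^(−τ) and P(D) ∝ D^(−α) by discrete maximum likelihood (the
  Hurwitz-zeta equation, with KS-minimising lower cutoffs and a
  semi-parametric surrogate goodness-of-fit test),
* S̄(D) ∝ D^γ over the longest consistent range (decade-scanning selection),

and tests the crackling relation γ_fit ≈ γ_pred ≡ (α−1)/(τ−1) — the
stringent signature of avalanche criticality. A theory module computes the
avalanche-probability phase diagram P_ava = P_sil(1−P_sil) in closed form
for quasi-static latents, including the boundary ε₀ = −log(2^{1/N}−1)
between the two avalanche regimes, and an information module computes the
Gaussian-MLE mutual information I ≈ ½⟨ln(T/σ²_h)⟩ between activity and the
latent variable via its Fisher information.

## Worked example

```python
import latent_avalanches as la

cfg = la.SimulationConfig(
    n_neurons=1024, n_fields=5, eta=4.0, epsilon=12.0,
    tau_F=1e4, n_steps=2_000_000, seed=101,
)
res = la.run_experiment(cfg)
sf, df, cr = res.size_fit, res.duration_fit, res.crackling
print(f"tau   = {sf.exponent:.3f} (S_min={sf.xmin})")
print(f"alpha = {df.exponent:.3f} (D_min={df.xmin})")
print(f"gamma_fit = {cr.gamma_fit:.3f}, gamma_pred = {cr.gamma_pred:.3f}")
print("crackling satisfied:", res.crackling_passed)
```

prints (≈40 s on one CPU):

```
tau   = 1.877 (S_min=3)
alpha = 2.096 (D_min=3)
gamma_fit = 1.205, gamma_pred = 1.251
crackling satisfied: True
```

i.e. this five-latent-variable population produces power-law avalanche
statistics whose three exponents satisfy the crackling relation — with no
tuning of η or ε.

The numbered scripts under `analysis/` run the full study: the flagship
recording (01), the one-vs-five latent-variable comparison (02), the
quasi-static (η, ε) sweep showing crackling without fine-tuning (03), the
analytic regime map with the ε₀ boundary and ε*(η) ridge (04), and the
latent-information surface (05). Each writes its tables under `results/`.

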