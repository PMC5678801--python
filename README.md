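# qbnoise

Point-process analysis of noise in early invertebrate vision: how much of
a photoreceptor's estimation error is **extrinsic** (random photon
arrival times) and how much is **intrinsic** (the phototransduction
cascade — quantum-bump latency, shape variability, quantum efficiency)?

The package is for computational neuroscientists and point-process
modellers.  It simulates Markov-modulated Poisson light, transduces
photons into summed quantum-bump (QB) current with a configurable
stochastic cascade surrogate, and reconstructs the hidden light state
causally with exact Bayesian filters, so that the mean squared error of
each reconstruction chain quantifies one noise component.

## The model and estimators

Light is a finite-state continuous-time Markov chain with generator `R`
over normalised intensities `x(t)`; photons form a Poisson process of
rate `α·x(t)` (ms⁻¹).  Two dimensionless parameters classify a stimulus:
`β = α/k` (mean photons per "on" sojourn — relative intensity) and
`γ = (1/k)/100` (sojourn length in 100 ms reference bump widths —
relative flicker slowness), where `k` is the smallest death rate of the
chain.

* **Snyder filter** (`snyder.general_filter`): the exact causal MMSE
  estimator `x̂(t) = E[x(t) | photons up to t]`.  Between events the
  un-normalised posterior evolves through `exp(Δt (R − Λ))` with
  `Λ = diag(α·xᵢ)`; at an event it is reweighted by the emission rates.
  For the 2-state on-off (telegraph) model there is a closed form with
  `A = β⁻¹ + ½`, `B = √(β⁻² + ¼)`, `C = artanh((A−1)/B)`:
  `x̂(t) = A − B·tanh(Bαt + C)` between events and `x̂(s⁺) = 1` at each
  event, decaying to the floor `A − B ∈ [0, ½]`.
* **Delayed Snyder filter** (`delayed_snyder.delayed_filter`): optimal
  causal estimate of the *current* state when events are observed after
  a known lag τ, via the Chapman–Kolmogorov correction
  `P(x(t)|M₀ᵗ) = P(x(t−τ)|M₀ᵗ)·e^{τR}`.  For the telegraph model the
  post-event value is `½(1 + e^{−2τk}) < 1`.
* **Integrate-fire-Snyder** (`integrate_fire`): recovers estimated
  photon times from the QB current by integrating charge and firing at
  multiples of a threshold `ζ = m·⟨Q_a⟩` trained on a split stream with
  the Victor-Purpura spike distance (whose small-shift-cost limit is the
  photon-count cost `μ = |1−m|·#Pₐ`, minimised at `m = 1`); the fired
  stream is then Snyder-filtered.
* **Linear baselines** (`baselines`): the closed-form optimal-linear
  MMSE for the telegraph model, `mse_lin(β) = (1/β)(√(1+β/2) − 1)`, and
  a least-squares causal FIR filter on the raw current.

## Worked example

```python
import numpy as np
from qbnoise import SweepConfig, run_sweep, summarize, linear_mmse_closed_form

cfg = SweepConfig(gamma_list=(20.0,), beta_grid=(1.0, 14.1, 200.0),
                  n_reps=3, photons_per_stream=2000,
                  curves=("photon_floor", "delayed_optimal", "if_full_noise"),
                  master_seed=101)
print(summarize(run_sweep(cfg)).round(4).to_string(index=False))
```

prints

```
 gamma  beta           curve   mean    min    max  count
  20.0   1.0 delayed_optimal 0.2229 0.2216 0.2238      3
  20.0   1.0   if_full_noise 0.2290 0.2270 0.2309      3
  20.0   1.0    photon_floor 0.2205 0.2192 0.2213      3
  20.0  14.1 delayed_optimal 0.0944 0.0837 0.1085      3
  20.0  14.1   if_full_noise 0.1086 0.0958 0.1270      3
  20.0  14.1    photon_floor 0.0816 0.0727 0.0936      3
  20.0 200.0 delayed_optimal 0.0345 0.0238 0.0420      3
  20.0 200.0   if_full_noise 0.0498 0.0362 0.0623      3
  20.0 200.0    photon_floor 0.0131 0.0087 0.0154      3
```

Read vertically per β: at low intensity (β=1) all three curves sit near
the uninformed error 0.25 — photon noise dominates and the cascade adds
almost nothing.  At high intensity (β=200) the photon-noise floor
(`photon_floor`, 0.013) separates sharply from the integrate-fire bound
on full cascade noise (`if_full_noise`, 0.050), and most of that gap is
already present in `delayed_optimal` (0.035), the optimal filter with
*only* a fixed 43.3 ms delay: the mean QB delay, not bump shape noise or
jitter, is the dominant intrinsic noise source.  For comparison,
`linear_mmse_closed_form(14.1) = 0.1303` exceeds the integrate-fire
value 0.1086 there — a nonlinear point-process estimator on noisy bumps
beats the optimal *linear* estimator on perfect photons.

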