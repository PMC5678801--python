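# Methods

## Light models

The stimulus is a continuous-time Markov chain over normalised
intensities `x ∈ [0, 1]` emitting photons at rate `α·x(t)` ms⁻¹.  The
canonical source is the symmetric on-off switch (random telegraph) with
both transition rates `k`: states {0, 1}, mean sojourn 1/k ms,
stationary law (½, ½), mean inter-photon time 2/α at stationarity.  The
pair `(β, γ)` with `β = α/k` and `γ = (1/k)/100` fully specifies a
telegraph condition; `k` is defined in general as the smallest death
rate of the chain, and the mapping `(β, γ) ↔ (α, k)` is used throughout
(time in ms, rates in ms⁻¹).

The multi-state bimodal source generalises the telegraph to a
nearest-neighbour birth-death chain over `n` equally spaced intensity
levels, plus a direct modal switch `ε` between two designated mode
states.  Only the topology of this model is canonical; the rates are a
design choice here.  We target a stationary law that is an equal mixture
of two discretised Gaussian lobes (width `spread` index units) centred
on the modes, and set birth/death rates by a Metropolis detailed-balance
recipe — `aᵢ = c·min(1, πᵢ₊₁/πᵢ)`, `bᵢ₊₁ = c·min(1, πᵢ/πᵢ₊₁)` — then
rescale `c` so the smallest death rate equals `k`.  Because the mixture
assigns equal mass to the two modes, adding the symmetric modal switch
preserves detailed balance exactly, so the stationary law *is* the
target mixture (this is asserted in the tests).  State values are
equally spaced on [0, 1] to preserve the `x = λ/α` convention.

Trajectories are simulated exactly (Gillespie; exponential holding
times), started from the stationary law so that long-run MSE averages
carry no start-up transient.  Photons are sampled per constant-rate
segment as Poisson counts with uniform order-statistic times — no
thinning approximation.

## Snyder filtering

Between events the un-normalised posterior row vector obeys
`q' = q (R − Λ)`, `Λ = diag(α·xᵢ)`; at an event, `qᵢ ← qᵢ·α·xᵢ` followed
by normalisation.  The implementation diagonalises `G = R − Λ` once per
model and evaluates whole inter-event intervals in one vectorised step;
the exponent is shifted by the largest real eigenvalue before
exponentiation and the posterior renormalised at every output time, so
arbitrarily long photon-free gaps cannot underflow.  If the eigenvector
basis is ill-conditioned (condition number > 1e10) the filter falls
back to stepwise `scipy.linalg.expm`.  A completely independent path —
direct `solve_ivp` integration of the normalised Snyder ODE
`pᵢ' = [pR]ᵢ − pᵢ(λᵢ − Σⱼ pⱼλⱼ)` — is kept as a numerical oracle and the
two agree to ≤ 1e-6 on random streams, as does the telegraph closed
form.

Conventions: the prior is the stationary law unless a photon at t = 0
is asserted (the closed form's convention; both are exposed).  Output
grids duplicate every event time into a pre-jump and a post-jump row so
discontinuities are stored losslessly.  An event arriving when the
total emitting posterior mass is below 1e-300 raises a degeneracy error
rather than silently renormalising — such a stream is inconsistent with
the model.

MSE is the trapezoidal time average of `(x(t) − x̂(t))²` over an
evaluation window.  The grid always contains the truth's change times
plus the filter's event rows, so both discontinuity families are
represented exactly; the remaining trapezoid error is O(dt²) in the
smooth parts.

## Delayed observations

For a known deterministic lag τ the observed stream has unchanged
inter-event statistics, so the standard filter applied to it yields the
posterior of `x(t − τ)`; right-multiplying by `e^{τR}` (computed once
per model-τ pair and cached) propagates it to the current time.
Timestamps in the output refer to wall-clock t — the causal, real-time
estimate of the present state from lagged data.  Randomly jittered
delays admit no tractable optimal filter; the evaluation instead
applies the *standard* filter to empirically delayed streams, which
yields an upper bound rather than an optimum.

## Cascade surrogate

The cascade model is phenomenological: it reproduces the statistics the
noise decomposition depends on — per-photon capture (QE), latency
(mean + jitter), amplitude/width variability, linear superposition —
without simulating the underlying reaction network.  Defaults, all
config-exposed:

| parameter | default | why |
|---|---|---|
| latency mean | 43.3 ms | physiological mean QB delay |
| latency SD | 15 ms | representative jitter; latencies span ~15–100 ms, truncated-normal at 0 |
| amplitude mean / CV | 1 / 0.3 | unit bumps; skewed (log-normal) variability |
| width mean / CV | 15 ms / 0.3 | bump support ≲ 100 ms, the reference width behind γ |
| QE | 1 | near-unity capture at the intensities studied; 0.66 used for robustness runs |
| waveform dt | 1 ms | resolves tens-of-ms bumps |

The bump kernel is the fixed gamma-shaped pulse `g(s) = s²e^{2−2s}`
(unit peak at s = 1, effective support ≲ 8 widths, unit-width area
e²/4).  Latency is drawn independently of amplitude and width, matching
the experimental finding that QB timing and waveform are uncorrelated.
The analysis results depend on bump area, amplitude, width and latency
statistics, not on the exact pulse shape.  What the surrogate does NOT
model: dark (spontaneous) events, adaptation (intensity-dependent bump
shrinkage), saturation of the microvillus population — so passing tests
bound noise under linear superposition and stationary bump statistics,
not under strong light adaptation.

## Integrate-fire training

The threshold is `ζ = m·⟨Q_a⟩` with `⟨Q_a⟩` the mean bump charge per
photon on the training half of a time-based 50/50 split.  `m` is chosen
on a grid (0.5–1.5, step 0.05) by minimising the Victor-Purpura
distance between the true and fired training streams; ties resolve
towards m = 1.  The count cost `μ = |1−m|·#Pₐ` (the q → 0 limit of the
spike distance) has its unique zero at m = 1 by construction.

The default shift cost is q = 0.002 /ms.  The spike-distance training
is only count-dominated when q·(typical displacement) ≪ 1; fired events
lag true photons by the systematic bump latency (~45 ms plus rise
time), so q = 0.01 already prices each matched pair at ~0.5 and biases
the minimiser to m ≈ 1.05, while q = 0.002 (pair cost ~0.1) recovers
the count-dominated regime with a clear minimum at m = 1 for both
deterministic and stochastic cascades.  Fired timestamps are the first
waveform sample where the cumulative trapezoid charge crosses `n·ζ` (no
sub-sample interpolation — counts, not positions, dominate
performance); if several thresholds are crossed within one sample the
events are spread by sub-sample offsets to keep times strictly
increasing.  The integrator is perfect (non-leaky) and assumes zero
baseline current.

## Evaluation protocol

A sweep cell is (γ, β, curve, rep).  Streams are generated to a fixed
photon count (default 8000; duration adaptive, truncated just past the
nth photon) rather than fixed duration.  Within a rep, every curve
shares the same trajectory and photon stream — only cascade noise is
redrawn — which removes between-curve sampling variance from the
ordering comparisons.  Seeds are a pure CRC32 hash of (master seed,
cell labels), so any cell can be recomputed independently and re-runs
are bit-identical.

All curves are scored on the second half of the stream: the first half
is the integrate-fire training window, and it simultaneously serves as
filter warm-up (it always exceeds 1/k at the defaults).  The MSE grid
resolution is `dt = max(1 ms, min(0.25/α, 0.02/k))` unless a fixed dt
is configured: a few samples per mean photon gap and ≥ 50 per sojourn,
which keeps the grid size bounded as β or γ make streams span 10⁶–10⁷
ms.  The reduced-scale acceptance sweep uses γ = 20, five β values on
[1, 200], 3 reps of 2000 photons; the curve ordering and the
delay-dominance gap structure are stable at this size while keeping the
suite fast.  The FIR comparator uses a 5·(2/α) window on the bump
current, down-binned so the design matrix stays ≤ ~10⁵ × 64.

## Known limitations

* The bimodal rate recipe is a documented stand-in; quantitative MSE
  curves for bimodal models depend on it and are not asserted against
  reference values.
* The delayed filter is exact only for deterministic lags; jittered
  delays are handled by bounding.
* Victor-Purpura training is O(n²) per grid point (numba-compiled);
  streams much beyond ~10⁴ training photons get slow.
* The closed-form linear MMSE applies to the telegraph model only; for
  other chains use the FIR comparator.
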