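"""Markov-modulated Poisson light sources.

A light stimulus is a finite-state continuous-time Markov chain with
generator ``R`` (ms^-1) over normalised intensity levels ``x_i``; photons
are emitted as an inhomogeneous Poisson process with rate ``alpha * x(t)``
(ms^-1).  Two dimensionless descriptors summarise a model:

* ``beta = alpha / k`` — mean photons emitted per "on" sojourn (relative
  intensity; more photons per state means more usable information);
* ``gamma = (1/k) / 100`` — sojourn time in units of a 100 ms reference
  quantum-bump width (relative flicker slowness).

``k`` is the characteristic switch rate, defined as the smallest death
rate of the chain.  Time is in ms throughout, rates in ms^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MarkovLightModel",
    "DimensionlessSetting",
    "StateTrajectory",
    "EventStream",
    "build_interrupted",
    "build_bimodal",
    "simulate_trajectory",
    "sample_photons",
    "stationary_distribution",
]

_ROW_SUM_TOL = 1e-12

# Reference maximum quantum-bump width (ms) used to normalise flicker speed.
QB_REFERENCE_WIDTH_MS = 100.0


@dataclass(frozen=True)
class DimensionlessSetting:
    """Dimensionless (beta, gamma) description of a light model.

    ``beta = alpha/k`` and ``gamma = (1/k)/QB_REFERENCE_WIDTH_MS``; the
    mapping to physical rates ``(alpha, k)`` is a bijection.
    """

    beta: float
    gamma: float

    def __post_init__(self):
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")

    @property
    def k(self) -> float:
        """Characteristic switch rate (ms^-1)."""
        return 1.0 / (QB_REFERENCE_WIDTH_MS * self.gamma)

    @property
    def alpha(self) -> float:
        """Photon scale (ms^-1)."""
        return self.beta * self.k

    @classmethod
    def from_rates(cls, alpha: float, k: float) -> "DimensionlessSetting":
        if alpha <= 0 or k <= 0:
            raise ValueError("alpha and k must be positive")
        return cls(beta=alpha / k, gamma=1.0 / (QB_REFERENCE_WIDTH_MS * k))


@dataclass(frozen=True)
class MarkovLightModel:
    """Finite-state CTMC light source with per-state photon emission.

    ``state_values`` are normalised intensities x_i = lambda_i / alpha, so
    the emission rate in state i is ``alpha * state_values[i]``.
    """

    state_values: np.ndarray
    rate_matrix: np.ndarray
    alpha: float
    k: float
    epsilon: float | None = None

    def __post_init__(self):
        x = np.asarray(self.state_values, dtype=float)
        R = np.asarray(self.rate_matrix, dtype=float)
        object.__setattr__(self, "state_values", x)
        object.__setattr__(self, "rate_matrix", R)
        n = x.size
        if R.shape != (n, n):
            raise ValueError(f"rate matrix shape {R.shape} incompatible with {n} states")
        if self.alpha <= 0 or self.k <= 0:
            raise ValueError("alpha and k must be positive")
        if np.any(x < 0):
            raise ValueError("state_values must be non-negative")
        off = R - np.diag(np.diag(R))
        if np.any(off < 0):
            raise ValueError("off-diagonal generator entries must be non-negative")
        if np.any(np.abs(R.sum(axis=1)) > _ROW_SUM_TOL * max(1.0, np.abs(R).max())):
            raise ValueError("generator rows must sum to zero")

    @property
    def n_states(self) -> int:
        return self.state_values.size

    @property
    def emission_rates(self) -> np.ndarray:
        """Per-state photon rates alpha * x_i (ms^-1)."""
        return self.alpha * self.state_values

    @property
    def setting(self) -> DimensionlessSetting:
        return DimensionlessSetting.from_rates(self.alpha, self.k)

    @property
    def beta(self) -> float:
        return self.setting.beta

    @property
    def gamma(self) -> float:
        return self.setting.gamma


@dataclass(frozen=True)
class StateTrajectory:
    """Piecewise-constant hidden state x(t) on [0, T).

    ``change_times[0] == 0``; segment i holds state ``states[i]`` on
    ``[change_times[i], change_times[i+1])``.
    """

    change_times: np.ndarray
    states: np.ndarray
    T: float

    def __post_init__(self):
        t = np.asarray(self.change_times, dtype=float)
        s = np.asarray(self.states, dtype=int)
        object.__setattr__(self, "change_times", t)
        object.__setattr__(self, "states", s)
        if t.size != s.size:
            raise ValueError("change_times and states must have equal length")
        if t.size == 0 or t[0] != 0.0:
            raise ValueError("trajectory must start at t=0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("change_times must be strictly increasing")
        if t[-1] >= self.T:
            raise ValueError("last change_time must precede T")

    def states_at(self, times: np.ndarray) -> np.ndarray:
        """Cadlag state index at each query time."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.change_times, times, side="right") - 1
        return self.states[np.clip(idx, 0, self.states.size - 1)]

    def values_at(self, times: np.ndarray, state_values: np.ndarray) -> np.ndarray:
        return np.asarray(state_values, dtype=float)[self.states_at(times)]

    def truncated(self, T_new: float) -> "StateTrajectory":
        if T_new <= 0 or T_new > self.T:
            raise ValueError("truncation time outside trajectory support")
        keep = self.change_times < T_new
        return StateTrajectory(self.change_times[keep], self.states[keep], T_new)


@dataclass(frozen=True)
class EventStream:
    """Ordered point-event times (ms) on [0, T)."""

    times: np.ndarray
    T: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("event times must be strictly increasing")
            if t[0] < 0 or t[-1] >= self.T:
                raise ValueError("event times must lie in [0, T)")

    def __len__(self) -> int:
        return self.times.size

    def shifted(self, delay: float, T_new: float | None = None) -> "EventStream":
        """Shift all events by a constant delay (ms)."""
        T_new = self.T + delay if T_new is None else T_new
        t = self.times + delay
        return EventStream(t[t < T_new], T_new)

    def windowed(self, t0: float, t1: float) -> "EventStream":
        """Events within [t0, t1), timestamps kept absolute, T set to t1."""
        t = self.times[(self.times >= t0) & (self.times < t1)]
        return EventStream(t, t1)


def build_interrupted(alpha: float, k: float) -> MarkovLightModel:
    """Symmetric on-off (random telegraph) light switch.

    State values are exactly {0, 1}; both switch rates are ``k`` so the
    mean sojourn in either state is 1/k ms and the stationary law is
    (1/2, 1/2).  Photons appear at rate ``alpha`` in the on state only.
    """
    if alpha <= 0 or k <= 0:
        raise ValueError("alpha and k must be positive")
    R = np.array([[-k, k], [k, -k]], dtype=float)
    return MarkovLightModel(np.array([0.0, 1.0]), R, alpha=alpha, k=k)


def _bimodal_target(n_states: int, mode_indices: tuple[int, int], spread: float) -> np.ndarray:
    i = np.arange(n_states, dtype=float)
    m1, m2 = mode_indices
    pi = np.exp(-0.5 * ((i - m1) / spread) ** 2) + np.exp(-0.5 * ((i - m2) / spread) ** 2)
    return pi / pi.sum()


def build_bimodal(
    n_states: int,
    mode_indices: tuple[int, int],
    k: float,
    epsilon: float,
    alpha: float,
    spread: float = 1.0,
) -> MarkovLightModel:
    """Multi-state bimodal flickering light model.

    A nearest-neighbour birth-death chain over ``n_states`` equally spaced
    intensity levels on [0, 1], whose stationary distribution is a
    symmetric mixture of two discretised Gaussian lobes (width ``spread``
    in index units) centred on ``mode_indices``, plus a direct modal
    switch at rate ``epsilon`` between the two mode states.  Birth/death
    rates follow a Metropolis detailed-balance recipe against the target
    mixture and are rescaled so the smallest death rate equals ``k``;
    because the two modes carry equal stationary mass, the symmetric modal
    switch preserves detailed balance and the stationary distribution is
    exactly the target mixture.
    """
    if n_states < 4:
        raise ValueError("bimodal model needs at least 4 states")
    m1, m2 = sorted(int(m) for m in mode_indices)
    if m1 == m2 or not (0 <= m1 < n_states and 0 <= m2 < n_states):
        raise ValueError("mode indices must be distinct and in range")
    if spread <= 0:
        raise ValueError("spread must be positive")
    if epsilon < 0 or k <= 0 or alpha <= 0:
        raise ValueError("rates must be non-negative (k, alpha positive)")

    pi = _bimodal_target(n_states, (m1, m2), spread)
    if np.any(pi <= 0):
        raise ValueError("spread produced a degenerate target distribution")

    births = np.minimum(1.0, pi[1:] / pi[:-1])       # a_i: i -> i+1
    deaths = np.minimum(1.0, pi[:-1] / pi[1:])       # b_{i+1}: i+1 -> i
    scale = k / deaths.min()
    births *= scale
    deaths *= scale

    R = np.zeros((n_states, n_states))
    idx = np.arange(n_states - 1)
    R[idx, idx + 1] = births
    R[idx + 1, idx] = deaths
    R[m1, m2] += epsilon
    R[m2, m1] += epsilon
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))

    return MarkovLightModel(
        np.linspace(0.0, 1.0, n_states), R, alpha=alpha, k=k, epsilon=epsilon
    )


def stationary_distribution(model: MarkovLightModel) -> np.ndarray:
    """Stationary probability vector pi with pi @ R = 0, sum(pi) = 1."""
    R = model.rate_matrix
    n = model.n_states
    if n == 1:
        return np.ones(1)
    adj = (R > 0).astype(int)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("chain is reducible; no unique stationary distribution")
    # solve pi R = 0 with sum constraint appended
    A = np.vstack([R.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_trajectory(model: MarkovLightModel, T: float, seed) -> StateTrajectory:
    """Exact (Gillespie) realisation of the hidden chain on [0, T).

    Holding time in state i is exponential with rate -R_ii; the initial
    state is drawn from the stationary distribution so that long-run MSE
    averages carry no start-up transient.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    rng = np.random.default_rng(seed)
    R = model.rate_matrix
    exit_rates = -np.diag(R)
    pi = stationary_distribution(model)
    state = int(rng.choice(model.n_states, p=pi))

    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = exit_rates[state]
        if rate <= 0:  # absorbing (1-state chains)
            break
        t += rng.exponential(1.0 / rate)
        if t >= T:
            break
        probs = R[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(model.n_states, p=probs))
        times.append(t)
        states.append(state)
    return StateTrajectory(np.array(times), np.array(states), T)


def sample_photons(model: MarkovLightModel, traj: StateTrajectory, seed) -> EventStream:
    """Photon stream from a trajectory: exact per-segment Poisson sampling.

    Within each constant-rate segment the event count is Poisson with mean
    rate*duration and event times are order statistics of uniforms — no
    thinning approximation.
    """
    rng = np.random.default_rng(seed)
    rates = model.emission_rates[traj.states]
    starts = traj.change_times
    ends = np.append(traj.change_times[1:], traj.T)
    out = []
    for r, t0, t1 in zip(rates, starts, ends):
        if r <= 0:
            continue
        n = rng.poisson(r * (t1 - t0))
        if n:
            out.append(t0 + np.sort(rng.random(n)) * (t1 - t0))
    if out:
        times = np.concatenate(out)
        # ties have probability zero but guard against float coincidence
        times = np.unique(times)
    else:
        times = np.empty(0)
    return EventStream(times, traj.T)
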