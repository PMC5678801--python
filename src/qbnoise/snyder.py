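"""Exact causal MMSE (Snyder) filtering of a Markov-modulated Poisson process.

The Snyder filter is the point-process analogue of the Kalman filter: for
a hidden CTMC x(t) observed through a Poisson process of rate
``alpha * x(t)``, it propagates the exact posterior P(x(t) | events up to
t).  Between events the un-normalised posterior evolves linearly,
``q'(t) = q(t) (R - Lambda)`` with ``Lambda = diag(alpha * x_i)``; at an
event each component is reweighted by its emission rate and the vector is
renormalised.  The conditional mean ``x_hat = E[x(t) | data]`` minimises
the mean squared error among all causal estimators.

For the 2-state interrupted (telegraph) model the filter collapses to a
closed form: with A = 1/beta + 1/2, B = sqrt(1/beta^2 + 1/4) and
C = arctanh((A-1)/B),

    x_hat(t) = A - B tanh(B alpha t + C)   between events (local clock),
    x_hat(s+) = 1                          immediately after any event,

decaying towards the floor A - B in [0, 1/2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eig, expm, inv
from scipy.integrate import solve_ivp

from .light_models import EventStream, MarkovLightModel, StateTrajectory, \
    stationary_distribution

__all__ = [
    "FilterOutput",
    "InterruptedFilterConstants",
    "SnyderDegeneracyError",
    "interrupted_closed_form",
    "general_filter",
    "general_filter_ode",
    "mse",
]


class SnyderDegeneracyError(RuntimeError):
    """Raised when an event arrives while every emitting state has
    (numerically) zero posterior mass, so the Bayes update is 0/0."""


@dataclass(frozen=True)
class InterruptedFilterConstants:
    """Closed-form constants of the interrupted-model filter."""

    beta: float

    @property
    def A(self) -> float:
        return 1.0 / self.beta + 0.5

    @property
    def B(self) -> float:
        return np.sqrt(1.0 / self.beta**2 + 0.25)

    @property
    def C(self) -> float:
        return np.arctanh((self.A - 1.0) / self.B)

    @property
    def floor(self) -> float:
        """Inter-event decay floor A - B = lim_{t->inf} x_hat(t), in [0, 1/2]."""
        # A - B rewritten to avoid catastrophic cancellation at large beta
        return 0.25 / (self.A + self.B) * (4.0 / self.beta)


@dataclass(frozen=True)
class FilterOutput:
    """Posterior trajectory of a Snyder filter run.

    ``t`` contains the evaluation grid with each event time duplicated
    (pre-jump and post-jump rows), so discontinuities are represented
    losslessly.  ``posterior`` rows sum to one; ``x_hat`` is the
    conditional-mean normalised intensity.
    """

    t: np.ndarray
    posterior: np.ndarray
    x_hat: np.ndarray
    event_times: np.ndarray
    state_values: np.ndarray

    def post_event_values(self) -> np.ndarray:
        """x_hat immediately after each processed event."""
        idx = np.searchsorted(self.t, self.event_times, side="right") - 1
        return self.x_hat[idx]


def _merge_grid(t_grid: np.ndarray, events: np.ndarray, T: float):
    """Evaluation times with events duplicated (pre/post); returns the
    merged array and the row index of each event's pre-jump row."""
    t_grid = np.asarray(t_grid, dtype=float)
    keep = ~np.isin(t_grid, events)
    base = t_grid[keep]
    merged = np.sort(np.concatenate([base, events, events]))
    pre_rows = np.searchsorted(merged, events, side="left")
    return merged, pre_rows


def interrupted_closed_form(
    beta: float,
    alpha: float,
    photons: EventStream,
    t_grid: np.ndarray,
    assume_event_at_zero: bool = True,
) -> FilterOutput:
    """Closed-form interrupted-model Snyder filter.

    The local clock resets at every event; immediately after an event
    x_hat jumps to exactly 1.  With ``assume_event_at_zero`` (the
    convention of the analytic solution) the trajectory starts at
    x_hat(0) = 1; otherwise it starts from the stationary value 1/2,
    which corresponds to shifting the local clock so that
    tanh(B alpha t0 + C) = (A - 1/2)/B.
    """
    if beta <= 0 or alpha <= 0:
        raise ValueError("beta and alpha must be positive")
    c = InterruptedFilterConstants(beta)
    A, B, C = c.A, c.B, c.C
    events = photons.times
    merged, _ = _merge_grid(np.asarray(t_grid, float), events, photons.T)

    if assume_event_at_zero:
        offset0 = C
    else:
        # start at the stationary mean 1/2: A - B tanh(u0) = 1/2
        offset0 = np.arctanh((A - 0.5) / B)

    # local time since the last event (or 0), with post-jump rows getting 0
    last_idx = np.searchsorted(events, merged, side="left")
    # rows exactly at an event time: first (pre) row belongs to previous
    # segment, second (post) row restarts the clock.  searchsorted 'left'
    # assigns both rows to the previous segment; fix the post rows.
    is_event = np.isin(merged, events)
    if np.any(is_event):
        ev_pos = np.flatnonzero(is_event)
        # within each duplicated pair the second row is post-jump
        post_rows = ev_pos[1::2]
        pre_rows = ev_pos[0::2]
        last_idx[post_rows] = np.searchsorted(events, merged[post_rows], side="right")
        last_idx[pre_rows] = np.searchsorted(events, merged[pre_rows], side="left")

    if events.size:
        seg_start = np.where(last_idx > 0,
                             events[np.clip(last_idx - 1, 0, None)], 0.0)
        offset = np.where(last_idx > 0, C, offset0)
    else:
        seg_start = np.zeros_like(merged)
        offset = np.full_like(merged, offset0)
    local = merged - seg_start
    x_hat = A - B * np.tanh(B * alpha * local + offset)
    x_hat = np.clip(x_hat, 0.0, 1.0)
    posterior = np.column_stack([1.0 - x_hat, x_hat])
    return FilterOutput(merged, posterior, x_hat, events,
                        np.array([0.0, 1.0]))


class _Propagator:
    """exp(dt * G) applied to row vectors, via eigendecomposition with an
    expm fallback when the eigenvector basis is ill-conditioned."""

    def __init__(self, G: np.ndarray):
        self.G = G
        d, V = eig(G)
        try:
            Vinv = inv(V)
            ok = np.linalg.cond(V) < 1e10
        except np.linalg.LinAlgError:
            ok = False
            Vinv = None
        self.eig_ok = ok
        if ok:
            self.d, self.V, self.Vinv = d, V, Vinv

    def propagate(self, p: np.ndarray, dts: np.ndarray) -> np.ndarray:
        """Rows p @ exp(dt G) for each dt, renormalised to sum 1."""
        dts = np.asarray(dts, dtype=float)
        if self.eig_ok:
            coef = p.astype(complex) @ self.V
            shift = np.max(self.d.real)
            E = np.exp(np.outer(dts, self.d - shift))
            out = np.real((E * coef) @ self.Vinv)
        else:
            out = np.empty((dts.size, p.size))
            order = np.argsort(dts)
            last_dt, M = None, None
            for i in order:
                if last_dt is None or dts[i] != last_dt:
                    M = expm(dts[i] * self.G)
                    last_dt = dts[i]
                out[i] = p @ M
        out = np.clip(out, 0.0, None)
        sums = out.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise SnyderDegeneracyError(
                "posterior mass underflowed during inter-event propagation; "
                "use a finer grid or check model rates")
        return out / sums


def _run_point_process_filter(model, photons, t_grid, assume_event_at_zero):
    lam = model.emission_rates
    G = model.rate_matrix - np.diag(lam)
    prop = _Propagator(G)
    events = photons.times
    merged, _ = _merge_grid(np.asarray(t_grid, float), events, photons.T)
    n_t = merged.size
    posterior = np.empty((n_t, model.n_states))

    p = stationary_distribution(model)
    if assume_event_at_zero:
        w = p * lam
        if w.sum() <= 0:
            raise SnyderDegeneracyError("no emitting state has prior mass")
        p = w / w.sum()

    is_event = np.isin(merged, events)
    ev_rows = np.flatnonzero(is_event)
    pre_rows = ev_rows[0::2]
    post_rows = ev_rows[1::2]

    seg_start = 0.0
    row = 0
    for j, s in enumerate(events):
        pre = pre_rows[j]
        # rows strictly inside the segment plus the pre-event row
        block = merged[row:pre + 1]
        posterior[row:pre + 1] = prop.propagate(p, block - seg_start)
        p_pre = posterior[pre]
        w = p_pre * lam
        total = w.sum()
        if total < 1e-300:
            raise SnyderDegeneracyError(
                f"event at t={s} ms arrived with ~zero emitting posterior "
                "mass; the stream is inconsistent with the model (e.g. an "
                "event during a certain off state)")
        p = w / total
        posterior[post_rows[j]] = p
        seg_start = s
        row = post_rows[j] + 1
    if row < n_t:
        posterior[row:] = prop.propagate(p, merged[row:] - seg_start)

    x_hat = posterior @ model.state_values
    return FilterOutput(merged, posterior, x_hat, events, model.state_values)


def general_filter(
    model: MarkovLightModel,
    photons: EventStream,
    t_grid: np.ndarray,
    assume_event_at_zero: bool = False,
) -> FilterOutput:
    """Exact Snyder filter for any finite-state Markov light model.

    Between events the un-normalised posterior is propagated through
    ``exp(dt (R - Lambda))`` (evaluated spectrally and renormalised at
    every output time, which removes the underflow risk of long gaps);
    at an event the posterior is reweighted by the emission rates.  The
    prior is the stationary distribution unless ``assume_event_at_zero``
    asserts a photon at t = 0, matching the closed form's convention.
    """
    return _run_point_process_filter(model, photons, t_grid, assume_event_at_zero)


def general_filter_ode(
    model: MarkovLightModel,
    photons: EventStream,
    t_grid: np.ndarray,
    assume_event_at_zero: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> FilterOutput:
    """Cross-validation path: integrate the normalised Snyder ODE.

    dp_i/dt = [p R]_i - p_i (lambda_i - sum_j p_j lambda_j) between
    events, with the same Bayes update at events.  Slower than
    :func:`general_filter`; used as an independent numerical oracle.
    """
    lam = model.emission_rates
    R = model.rate_matrix

    def rhs(_t, p):
        mean_rate = p @ lam
        return p @ R - p * (lam - mean_rate)

    events = photons.times
    merged, _ = _merge_grid(np.asarray(t_grid, float), events, photons.T)
    posterior = np.empty((merged.size, model.n_states))

    p = stationary_distribution(model)
    if assume_event_at_zero:
        w = p * lam
        p = w / w.sum()

    is_event = np.isin(merged, events)
    ev_rows = np.flatnonzero(is_event)
    pre_rows = ev_rows[0::2]
    post_rows = ev_rows[1::2]

    def integrate(p0, t0, ts):
        if ts.size == 0:
            return np.empty((0, p0.size))
        if ts[-1] == t0:
            return np.tile(p0, (ts.size, 1))
        sol = solve_ivp(rhs, (t0, ts[-1]), p0, t_eval=ts, rtol=rtol, atol=atol,
                        method="LSODA")
        out = np.clip(sol.y.T, 0.0, None)
        return out / out.sum(axis=1, keepdims=True)

    seg_start = 0.0
    row = 0
    for j, s in enumerate(events):
        pre = pre_rows[j]
        posterior[row:pre + 1] = integrate(p, seg_start, merged[row:pre + 1])
        w = posterior[pre] * lam
        p = w / w.sum()
        posterior[post_rows[j]] = p
        seg_start = s
        row = post_rows[j] + 1
    if row < merged.size:
        posterior[row:] = integrate(p, seg_start, merged[row:])

    x_hat = posterior @ model.state_values
    return FilterOutput(merged, posterior, x_hat, events, model.state_values)


def mse(
    truth: StateTrajectory,
    estimate: FilterOutput,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> float:
    """Time-averaged squared error between the true normalised intensity
    and an estimate, by trapezoidal integration on the estimate's grid.

    The truth is piecewise constant; each grid segment is assumed to lie
    within one truth segment (pass a grid containing the trajectory's
    change times to make this exact).  ``t_start`` lets callers discard a
    warm-up or training window.
    """
    t = estimate.t
    if t_end is None:
        t_end = min(truth.T, t[-1])
    if t_start >= t_end:
        raise ValueError("empty evaluation window")
    if t[0] > t_start or t[-1] < t_end - 1e-9:
        raise ValueError("estimate grid does not cover the evaluation window")
    m = (t >= t_start) & (t <= t_end)
    tt = t[m]
    xh = estimate.x_hat[m]
    seg_states = truth.values_at(tt[:-1], estimate.state_values)
    dt = np.diff(tt)
    e_l = seg_states - xh[:-1]
    e_r = seg_states - xh[1:]
    num = np.sum(dt * 0.5 * (e_l**2 + e_r**2))
    den = np.sum(dt)
    if den <= 0:
        raise ValueError("degenerate evaluation window")
    return float(num / den)
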