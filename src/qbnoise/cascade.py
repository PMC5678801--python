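"""Phenomenological quantum-bump (QB) cascade simulator.

Converts a photon stream into the summed QB current a photoreceptor would
report.  Each captured photon (quantum efficiency QE) produces one bump
with a random latency (truncated normal), amplitude and width (log-normal,
positive support, skewed) — latency independent of shape, matching the
experimental observation that bump timing and waveform are uncorrelated.
Bumps superpose linearly.

This is a surrogate for a full stochastic phototransduction reaction
network: it reproduces the statistics the noise decomposition rests on
(mean delay, latency jitter, shape variability, QE) without modelling the
underlying Rhodopsin/G-protein/PLC/TRP kinetics.  The bump kernel is a
fixed gamma-shaped unimodal pulse ``g(s) = s^2 exp(2 - 2s)`` with unit
peak at s = 1 and effective support within a few widths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .light_models import EventStream

__all__ = [
    "CascadeParams",
    "BumpWaveform",
    "apply_qe",
    "sample_bumps",
    "render_waveform",
    "simulate_cascade",
    "empirical_delay",
]

# kernel support cut-off in units of the width parameter; g(8) ~ 2e-5
_KERNEL_SUPPORT = 8.0
# area of the unit-amplitude, unit-width kernel: int_0^inf s^2 e^{2-2s} ds = e^2/4
KERNEL_UNIT_AREA = np.e**2 / 4.0


@dataclass(frozen=True)
class CascadeParams:
    """Tunable statistics of the QB surrogate.

    latency_mean/_sd (ms): truncated-normal photon-to-bump delay; the
    default mean 43.3 ms matches the physiological latency distribution.
    amplitude/width: log-normal with the given means and coefficients of
    variation (width in ms).  qe: probability a photon yields a bump.
    dt (ms): waveform sampling step.  deterministic: all variances forced
    to zero (fixed-shape, fixed-delay bumps).
    """

    latency_mean: float = 43.3
    latency_sd: float = 15.0
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.3
    width_mean: float = 15.0
    width_cv: float = 0.3
    qe: float = 1.0
    dt: float = 1.0
    deterministic: bool = False

    def __post_init__(self):
        if self.latency_mean <= 0:
            raise ValueError("latency_mean must be positive")
        if not (0.0 < self.qe <= 1.0):
            raise ValueError("qe must be in (0, 1]")
        if self.dt <= 0 or self.width_mean <= 0 or self.amplitude_mean <= 0:
            raise ValueError("dt, width_mean, amplitude_mean must be positive")
        if min(self.latency_sd, self.amplitude_cv, self.width_cv) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.deterministic:
            object.__setattr__(self, "latency_sd", 0.0)
            object.__setattr__(self, "amplitude_cv", 0.0)
            object.__setattr__(self, "width_cv", 0.0)

    def as_deterministic(self) -> "CascadeParams":
        return replace(self, deterministic=True, latency_sd=0.0,
                       amplitude_cv=0.0, width_cv=0.0)


@dataclass(frozen=True)
class BumpWaveform:
    """Uniformly sampled summed QB current plus per-bump metadata.

    ``bump_table`` has one row per QE-surviving photon with columns
    (photon_time, latency, amplitude, width); ``current`` is in charge
    units per ms and is non-negative everywhere.
    """

    t_grid: np.ndarray
    current: np.ndarray
    bump_table: np.ndarray  # (n, 4): photon_time, latency, amplitude, width

    def __post_init__(self):
        object.__setattr__(self, "t_grid", np.asarray(self.t_grid, dtype=float))
        object.__setattr__(self, "current", np.asarray(self.current, dtype=float))
        tbl = np.asarray(self.bump_table, dtype=float).reshape(-1, 4)
        object.__setattr__(self, "bump_table", tbl)
        if self.t_grid.shape != self.current.shape:
            raise ValueError("t_grid and current must have equal shape")
        if np.any(self.current < -1e-12):
            raise ValueError("current must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t_grid[1] - self.t_grid[0])

    @property
    def bump_areas(self) -> np.ndarray:
        """Charge of each bump: amplitude * width * kernel unit area."""
        return self.bump_table[:, 2] * self.bump_table[:, 3] * KERNEL_UNIT_AREA

    def windowed(self, t0: float, t1: float) -> "BumpWaveform":
        i0 = int(np.searchsorted(self.t_grid, t0, side="left"))
        i1 = int(np.searchsorted(self.t_grid, t1, side="right"))
        tbl = self.bump_table
        keep = (tbl[:, 0] >= t0) & (tbl[:, 0] < t1)
        return BumpWaveform(self.t_grid[i0:i1], self.current[i0:i1], tbl[keep])


def apply_qe(photons: EventStream, qe: float, seed) -> EventStream:
    """Thin a photon stream: each photon retained independently w.p. qe."""
    if not (0.0 < qe <= 1.0):
        raise ValueError("qe must be in (0, 1]")
    if qe == 1.0:
        return photons
    rng = np.random.default_rng(seed)
    keep = rng.random(len(photons)) < qe
    return EventStream(photons.times[keep], photons.T)


def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) conditioned on positivity, by resampling."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out <= 0
    return out


def _lognormal(rng, mean, cv, size):
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def sample_bumps(photons: EventStream, params: CascadeParams, seed) -> np.ndarray:
    """Draw per-photon bump metadata (photon_time, latency, amplitude, width).

    Latency is truncated-at-zero normal; amplitude and width log-normal
    with the configured means and CVs; all three independent.  In
    deterministic mode every bump has exactly the mean latency, amplitude
    and width, regardless of seed.
    """
    n = len(photons)
    t = photons.times
    if params.deterministic or (
        params.latency_sd == 0 and params.amplitude_cv == 0 and params.width_cv == 0
    ):
        lat = np.full(n, params.latency_mean)
        amp = np.full(n, params.amplitude_mean)
        wid = np.full(n, params.width_mean)
    else:
        rng = np.random.default_rng(seed)
        lat = (_truncated_normal(rng, params.latency_mean, params.latency_sd, n)
               if params.latency_sd > 0 else np.full(n, params.latency_mean))
        amp = (_lognormal(rng, params.amplitude_mean, params.amplitude_cv, n)
               if params.amplitude_cv > 0 else np.full(n, params.amplitude_mean))
        wid = (_lognormal(rng, params.width_mean, params.width_cv, n)
               if params.width_cv > 0 else np.full(n, params.width_mean))
    return np.column_stack([t, lat, amp, wid])


def bump_kernel(s: np.ndarray) -> np.ndarray:
    """Unit-peak gamma-shaped pulse g(s) = s^2 exp(2-2s) for s >= 0."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    pos = s > 0
    out[pos] = s[pos] ** 2 * np.exp(2.0 - 2.0 * s[pos])
    return out


def render_waveform(bump_table: np.ndarray, T: float, dt: float) -> BumpWaveform:
    """Linearly superpose bump pulses on a uniform grid over [0, T].

    Bump j contributes ``A_j * g((t - t_j - L_j) / w_j)``; contributions
    are accumulated only over each bump's effective support.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tbl = np.asarray(bump_table, dtype=float).reshape(-1, 4)
    t_grid = np.arange(0.0, T + 0.5 * dt, dt)
    current = np.zeros_like(t_grid)
    for t0, lat, amp, wid in tbl:
        onset = t0 + lat
        i0 = max(0, int(np.ceil(onset / dt)))
        i1 = min(t_grid.size, int(np.floor((onset + _KERNEL_SUPPORT * wid) / dt)) + 1)
        if i0 >= i1:
            continue
        s = (t_grid[i0:i1] - onset) / wid
        current[i0:i1] += amp * bump_kernel(s)
    return BumpWaveform(t_grid, current, tbl)


def simulate_cascade(photons: EventStream, params: CascadeParams, seed,
                     T: float | None = None) -> BumpWaveform:
    """Full photon-to-current pipeline: QE thinning, bump draws, rendering.

    ``T`` defaults to the stream horizon plus enough margin for the last
    bump's delayed tail to be represented.
    """
    rng = np.random.default_rng(seed)
    effective = apply_qe(photons, params.qe, rng.integers(2**31))
    tbl = sample_bumps(effective, params, rng.integers(2**31))
    if T is None:
        margin = params.latency_mean + 5 * params.latency_sd \
            + _KERNEL_SUPPORT * params.width_mean * (1 + params.width_cv)
        T = photons.T + margin
    return render_waveform(tbl, T, params.dt)


def empirical_delay(photons: EventStream, params: CascadeParams, seed) -> EventStream:
    """Shift each photon by an independent latency draw, then re-sort.

    With zero jitter this is a pure time shift that preserves inter-event
    spacing; with jitter, delays may reorder events.  Models a cascade
    whose only action is the physiological latency.
    """
    n = len(photons)
    if n == 0:
        return EventStream(np.empty(0), photons.T)
    rng = np.random.default_rng(seed)
    lat = (_truncated_normal(rng, params.latency_mean, params.latency_sd, n)
           if params.latency_sd > 0 else np.full(n, params.latency_mean))
    t = np.sort(photons.times + lat)
    T_new = max(photons.T, t[-1] + 1e-9)
    # degenerate float ties after sorting: nudge apart by ulp-scale steps
    for i in range(1, t.size):
        if t[i] <= t[i - 1]:
            t[i] = np.nextafter(t[i - 1], np.inf)
    return EventStream(t, T_new)
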