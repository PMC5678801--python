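"""Sweep orchestration: MSE curve families across intensity and flicker.

Reproduces the headline experiment: for each (gamma, beta) cell of an
interrupted (or bimodal) light model, generate independent photon-bump
streams of a fixed photon count and score a family of reconstruction
chains against the true hidden intensity:

* ``photon_floor``     — Snyder filter on the true photons (the MMSE
                         noise floor; extrinsic noise only);
* ``delayed_optimal``  — delay-corrected Snyder filter on photons lagged
                         by the mean bump latency tau (lower bound with
                         all cascade variability removed);
* ``if_deterministic`` — integrate-fire-Snyder on bumps from the
                         deterministic cascade (mean delay only);
* ``if_full_noise``    — integrate-fire-Snyder on fully stochastic bumps
                         (upper bound on photon + cascade distortion);
* ``empirical_delay``  — standard Snyder filter on photons randomly
                         delayed by the latency distribution;
* ``pure_threshold``   — current-threshold photon estimator, then Snyder;
* ``fir``              — least-squares FIR directly on the bump current;
* ``eq3``              — closed-form optimal-linear MMSE on true photons.

Within a rep all curves share the same light trajectory and photon
stream (matched randomness); only cascade noise is redrawn per curve.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .baselines import fit_fir, linear_mmse_closed_form
from .cascade import CascadeParams, empirical_delay, simulate_cascade
from .delayed_snyder import delayed_filter
from .integrate_fire import (fire_photons, pure_threshold_estimator,
                             split_stream, train_threshold)
from .light_models import (DimensionlessSetting, EventStream, MarkovLightModel,
                           StateTrajectory, build_bimodal, build_interrupted,
                           sample_photons, simulate_trajectory,
                           stationary_distribution)
from .snyder import general_filter, mse

__all__ = [
    "CURVES",
    "SweepConfig",
    "SweepResult",
    "cell_seed",
    "generate_stream",
    "evaluation_grid",
    "run_condition",
    "run_sweep",
    "summarize",
    "plot_sweep",
    "bimodal_factory",
]

CURVES = ("photon_floor", "delayed_optimal", "if_deterministic",
          "if_full_noise", "empirical_delay", "pure_threshold", "fir", "eq3")

_DEFAULT_BETAS = tuple(np.round(np.logspace(0, np.log10(200.0), 8), 4))


@dataclass(frozen=True)
class SweepConfig:
    """Study conditions for a full sweep.

    Defaults follow the reference protocol: flicker settings gamma in
    {5, 10, 20, 30}, relative intensity beta log-spaced on [1, 200],
    10 independent streams of 8000 photons per cell, and a deterministic
    observation lag tau = 43.3 ms matching the mean bump latency.
    """

    gamma_list: tuple = (5.0, 10.0, 20.0, 30.0)
    beta_grid: tuple = _DEFAULT_BETAS
    n_reps: int = 10
    photons_per_stream: int = 8000
    tau: float = 43.3
    qe: float = 1.0
    cascade: CascadeParams = field(default_factory=CascadeParams)
    curves: tuple = ("photon_floor", "delayed_optimal",
                     "if_deterministic", "if_full_noise")
    dt: float | None = None  # None -> adaptive grid resolution
    q_shift: float = 0.002
    m_grid: tuple | None = None
    split_fraction: float = 0.5
    threshold_level_fraction: float = 0.5
    master_seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1 or self.photons_per_stream < 10:
            raise ValueError("n_reps >= 1 and a non-trivial photon count required")
        if min(self.gamma_list) <= 0 or min(self.beta_grid) <= 0:
            raise ValueError("gamma and beta values must be positive")
        if self.tau < 0 or not (0 < self.qe <= 1):
            raise ValueError("tau >= 0 and qe in (0, 1] required")
        unknown = set(self.curves) - set(CURVES)
        if unknown:
            raise ValueError(f"unknown curves: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cascade" in raw:
            raw["cascade"] = CascadeParams(**raw["cascade"])
        for key in ("gamma_list", "beta_grid", "curves", "m_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class SweepResult:
    """Tidy per-rep table: columns gamma, beta, curve, rep, mse, seed."""

    table: pd.DataFrame
    config: SweepConfig

    def aggregate(self) -> pd.DataFrame:
        g = self.table.groupby(["gamma", "beta", "curve"])["mse"]
        agg = g.agg(["mean", "min", "max", "count"]).reset_index()
        return agg


def cell_seed(master: int, *keys) -> int:
    """Deterministic per-cell seed from the master seed and cell labels."""
    tag = "|".join([str(int(master))] + [f"{k:.8g}" if isinstance(k, float)
                                         else str(k) for k in keys])
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


def generate_stream(model: MarkovLightModel, n_photons: int, seed
                    ) -> tuple[StateTrajectory, EventStream]:
    """Simulate until ``n_photons`` photons are observed, then truncate
    both trajectory and stream just past the nth photon.

    The horizon is grown geometrically; because the Gillespie and Poisson
    samplers consume randomness in time order, re-running with a larger
    horizon under the same seed extends the same realisation.
    """
    pi = stationary_distribution(model)
    mean_rate = float(model.emission_rates @ pi)
    if mean_rate <= 0:
        raise ValueError("model never emits photons")
    T_guess = 1.3 * n_photons / mean_rate + 10.0 / model.k
    for _ in range(14):
        traj = simulate_trajectory(model, T_guess, seed)
        photons = sample_photons(model, traj, seed + 1)
        if len(photons) >= n_photons:
            t_n = photons.times[n_photons - 1]
            T_cut = t_n + max(1e-9, 1e-12 * t_n)
            return traj.truncated(T_cut), EventStream(photons.times[:n_photons], T_cut)
        T_guess *= 1.6
    raise RuntimeError("failed to accumulate the requested photon count")


def evaluation_grid(traj: StateTrajectory, model: MarkovLightModel,
                    dt: float | None) -> np.ndarray:
    """Uniform grid over [0, T] merged with the truth's change times.

    The adaptive default resolves both the inter-photon decay of the
    filter (a few samples per mean photon gap 2/alpha) and the switching
    dynamics (many samples per sojourn 1/k), never finer than 1 ms.
    """
    T = traj.T
    if dt is None:
        dt = max(1.0, min(0.25 / model.alpha, 0.02 / model.k))
    base = np.arange(0.0, T, dt)
    return np.union1d(np.union1d(base, [T]), traj.change_times)


def _if_chain_mse(model, config, traj, photons, grid, params, seed) -> float:
    """Train threshold on the first window, fire over the whole waveform,
    Snyder-filter the estimated photons, score on the test window."""
    wave = simulate_cascade(photons, params, seed)
    split = split_stream(photons, wave, config.split_fraction)
    m_grid = None if config.m_grid is None else np.asarray(config.m_grid)
    thr, _ = train_threshold(split, m_grid, config.q_shift)
    est = fire_photons(wave, thr.zeta)
    out = general_filter(model, est, grid)
    return mse(traj, out, t_start=split.split_time, t_end=traj.T)


def _fir_mse(model, config, traj, photons, params, seed) -> float:
    """Least-squares FIR on the (possibly down-binned) bump current."""
    wave = simulate_cascade(photons, params, seed)
    window = 5.0 * (2.0 / model.alpha)
    T = traj.T
    dt_fir = max(wave.dt, window / 64.0, T / 1e5)
    stride = max(1, int(round(dt_fir / wave.dt)))
    keep = wave.t_grid <= T
    t = wave.t_grid[keep][::stride]
    sig = wave.current[keep][::stride]
    truth = traj.values_at(t, model.state_values)
    n_train = int(np.searchsorted(t, config.split_fraction * T))
    fir = fit_fir(sig[:n_train], truth[:n_train], window, float(t[1] - t[0]))
    pred = fir.predict(sig)
    test = slice(n_train, None)
    return float(np.mean((truth[test] - pred[test]) ** 2))


def _curve_mse(model: MarkovLightModel, config: SweepConfig, curve: str,
               traj: StateTrajectory, photons: EventStream,
               noise_seed: int) -> float:
    grid = evaluation_grid(traj, model, config.dt)
    t_start = config.split_fraction * traj.T
    cascade_params = replace(config.cascade, qe=config.qe)

    if curve == "photon_floor":
        out = general_filter(model, photons, grid)
        return mse(traj, out, t_start=t_start)
    if curve == "delayed_optimal":
        delayed = photons.shifted(config.tau)
        out = delayed_filter(model, delayed, config.tau, grid)
        return mse(traj, out, t_start=t_start, t_end=traj.T)
    if curve == "empirical_delay":
        stream = empirical_delay(photons, cascade_params, noise_seed)
        out = general_filter(model, stream, grid)
        return mse(traj, out, t_start=t_start, t_end=traj.T)
    if curve == "if_full_noise":
        return _if_chain_mse(model, config, traj, photons, grid,
                             cascade_params, noise_seed)
    if curve == "if_deterministic":
        return _if_chain_mse(model, config, traj, photons, grid,
                             config.cascade.as_deterministic(), noise_seed)
    if curve == "pure_threshold":
        wave = simulate_cascade(photons, cascade_params, noise_seed)
        level = config.threshold_level_fraction * cascade_params.amplitude_mean
        est = pure_threshold_estimator(wave, level)
        out = general_filter(model, est, grid)
        return mse(traj, out, t_start=t_start, t_end=traj.T)
    if curve == "fir":
        return _fir_mse(model, config, traj, photons, cascade_params, noise_seed)
    if curve == "eq3":
        return float(linear_mmse_closed_form(model.beta))
    raise ValueError(f"unknown curve {curve!r}")


def _model_for(config: SweepConfig, gamma: float, beta: float) -> MarkovLightModel:
    setting = DimensionlessSetting(beta=beta, gamma=gamma)
    return build_interrupted(setting.alpha, setting.k)


def bimodal_factory(n_states: int = 16, mode_indices: tuple = (4, 11),
                    epsilon_over_k: float = 1.0, spread: float = 1.0):
    """Model factory for sweeping a multi-state bimodal light source.

    ``epsilon_over_k`` sets the modal switch rate as a multiple of the
    characteristic rate k implied by each (gamma, beta) cell, so e.g.
    1.0 and 3.0 reproduce the reference bimodal configurations.
    """
    def factory(config: SweepConfig, gamma: float, beta: float):
        s = DimensionlessSetting(beta=beta, gamma=gamma)
        return build_bimodal(n_states, mode_indices, k=s.k,
                             epsilon=epsilon_over_k * s.k, alpha=s.alpha,
                             spread=spread)
    return factory


def run_condition(model: MarkovLightModel, config: SweepConfig, curve: str,
                  reps: int | None = None) -> np.ndarray:
    """MSE of one estimator chain over ``reps`` matched streams."""
    if curve not in CURVES:
        raise ValueError(f"unknown curve {curve!r}; choose from {CURVES}")
    reps = config.n_reps if reps is None else reps
    gamma, beta = model.gamma, model.beta
    out = np.empty(reps)
    for rep in range(reps):
        s_stream = cell_seed(config.master_seed, gamma, beta, "stream", rep)
        traj, photons = generate_stream(model, config.photons_per_stream, s_stream)
        s_noise = cell_seed(config.master_seed, gamma, beta, curve, "noise", rep)
        out[rep] = _curve_mse(model, config, curve, traj, photons, s_noise)
    return out


def run_sweep(config: SweepConfig, progress: bool = False,
              model_factory=None) -> SweepResult:
    """Full factorial gamma x beta x curve x rep sweep.

    ``model_factory(config, gamma, beta)`` may override the default
    interrupted-model constructor (e.g. to sweep a bimodal model).
    Streams are generated once per (gamma, beta, rep) and shared across
    curves; the seed schedule is a pure function of the master seed and
    the cell labels, so re-runs are bit-identical.
    """
    factory = model_factory or _model_for
    rows = []
    for gamma in config.gamma_list:
        for beta in config.beta_grid:
            model = factory(config, gamma, beta)
            for rep in range(config.n_reps):
                s_stream = cell_seed(config.master_seed, gamma, beta,
                                     "stream", rep)
                traj, photons = generate_stream(
                    model, config.photons_per_stream, s_stream)
                for curve in config.curves:
                    s_noise = cell_seed(config.master_seed, gamma, beta,
                                        curve, "noise", rep)
                    val = _curve_mse(model, config, curve, traj, photons,
                                     s_noise)
                    rows.append((gamma, beta, curve, rep, val, s_stream))
                if progress:
                    import sys
                    print(f"gamma={gamma} beta={beta} rep={rep} done",
                          file=sys.stderr)
    table = pd.DataFrame(rows, columns=["gamma", "beta", "curve", "rep",
                                        "mse", "seed"])
    return SweepResult(table, config)


def summarize(result: SweepResult) -> pd.DataFrame:
    """Per-(gamma, beta, curve) mean/min/max MSE aggregates."""
    return result.aggregate()


def plot_sweep(result: SweepResult, path) -> None:
    """One panel per gamma: mean MSE vs beta with min-max error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = result.aggregate()
    gammas = sorted(agg["gamma"].unique())
    fig, axes = plt.subplots(1, len(gammas), figsize=(4 * len(gammas), 3.2),
                             squeeze=False, sharey=True)
    for ax, gamma in zip(axes[0], gammas):
        sub = agg[agg["gamma"] == gamma]
        for curve in sorted(sub["curve"].unique()):
            c = sub[sub["curve"] == curve].sort_values("beta")
            yerr = np.vstack([c["mean"] - c["min"], c["max"] - c["mean"]])
            ax.errorbar(c["beta"], c["mean"], yerr=yerr, marker="o",
                        capsize=2, label=curve)
        ax.set_xscale("log")
        ax.set_xlabel(r"$\beta$")
        ax.set_title(rf"$\gamma={gamma:g}$")
    axes[0][0].set_ylabel("MSE")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
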