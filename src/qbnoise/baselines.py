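"""Linear-filtering comparators for the nonlinear Snyder estimators.

Two baselines: the closed-form optimal-linear MMSE for the interrupted
model (from a continuity approximation of the telegraph state — an
Ornstein-Uhlenbeck surrogate with relaxation 2k and stationary variance
1/4 observed through Gaussian-approximated counts), and an ordinary
least-squares causal FIR filter trained on sampled signal/truth pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FIRFilter", "linear_mmse_closed_form", "fit_fir"]


def linear_mmse_closed_form(beta: float | np.ndarray) -> float | np.ndarray:
    """Optimal-linear MMSE for the interrupted model.

        mse_phl(beta) = (1/beta) (sqrt(1 + beta/2) - 1)

    This is the positive root of the steady-state Riccati equation
    2 alpha P^2 + 4 k P - k = 0 of the continuity-approximated filter,
    divided through by k.  Limits: 1/4 as beta -> 0 (the uninformed
    estimator's error for a symmetric 0/1 state) and 0 as beta -> inf;
    monotone decreasing throughout.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    out = (np.sqrt(1.0 + beta / 2.0) - 1.0) / beta
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FIRFilter:
    """Causal finite-impulse-response estimator.

    ``coefficients[l]`` weights the input ``l`` samples in the past;
    ``intercept`` absorbs the signal/truth means.  The window (number of
    lags times dt) is the filter's fading memory.
    """

    coefficients: np.ndarray
    intercept: float
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "coefficients",
                           np.asarray(self.coefficients, dtype=float))
        if self.coefficients.size == 0 or self.dt <= 0:
            raise ValueError("need at least one coefficient and positive dt")

    @property
    def window(self) -> float:
        return self.coefficients.size * self.dt

    def predict(self, signal: np.ndarray) -> np.ndarray:
        """Causal convolution: output at sample t uses signal[t-L+1 .. t]
        only (zero padding before the start)."""
        s = np.asarray(signal, dtype=float)
        full = np.convolve(s, self.coefficients, mode="full")[: s.size]
        return full + self.intercept

    def to_dict(self) -> dict:
        return {"coefficients": self.coefficients.tolist(),
                "intercept": self.intercept, "dt": self.dt}

    @classmethod
    def from_dict(cls, d: dict) -> "FIRFilter":
        return cls(np.asarray(d["coefficients"], float),
                   float(d["intercept"]), float(d["dt"]))


def _lagged_design(signal: np.ndarray, n_lags: int) -> np.ndarray:
    s = np.asarray(signal, dtype=float)
    X = np.zeros((s.size, n_lags))
    for l in range(n_lags):
        X[l:, l] = s[: s.size - l]
    return X


def fit_fir(signal: np.ndarray, truth: np.ndarray, window: float,
            dt: float) -> FIRFilter:
    """Least-squares causal FIR fit of ``truth`` from lagged ``signal``.

    ``window`` (ms) sets the number of lags, window/dt.  A rank-deficient
    design falls back to a small ridge penalty with a warning.  For
    photon inputs pass binned counts at dt; for bump inputs the raw
    sampled current.
    """
    s = np.asarray(signal, dtype=float)
    y = np.asarray(truth, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("signal and truth must be equal-length 1-D arrays")
    if window <= 0 or dt <= 0:
        raise ValueError("window and dt must be positive")
    n_lags = max(1, int(round(window / dt)))
    if s.size <= 3 * n_lags:
        raise ValueError("training series much shorter than the window")
    X = _lagged_design(s, n_lags)
    Xc = np.column_stack([X, np.ones(s.size)])
    coef, residuals, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
    if rank < Xc.shape[1]:
        warnings.warn("singular FIR design; falling back to ridge solution",
                      RuntimeWarning, stacklevel=2)
        lam = 1e-8 * np.trace(Xc.T @ Xc) / Xc.shape[1]
        coef = np.linalg.solve(Xc.T @ Xc + lam * np.eye(Xc.shape[1]), Xc.T @ y)
    return FIRFilter(coef[:-1], float(coef[-1]), dt)
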