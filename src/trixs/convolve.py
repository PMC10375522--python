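"""Closed-form convolutions with a Gaussian instrument response.

The pump-probe time resolution is modeled as a Gaussian IRF of given
FWHM. Step, exponential-decay and saturating-rise kinetics convolved
with that Gaussian all have closed forms built on the (scaled
complementary) error function; using them avoids discretization error
on the coarse, non-uniform time grids typical of TR-XSS scans.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, erfc, erfcx

__all__ = ["sigma_from_fwhm", "step_conv", "exp_conv", "rise_conv"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def sigma_from_fwhm(fwhm: float) -> float:
    return fwhm * _FWHM_TO_SIGMA


def step_conv(t, sigma: float, t0: float = 0.0) -> np.ndarray:
    """Heaviside step at t0 convolved with a Gaussian of width sigma."""
    t = np.asarray(t, dtype=float)
    if sigma <= 0:
        return (t >= t0).astype(float)
    return 0.5 * (1.0 + erf((t - t0) / (sigma * np.sqrt(2.0))))


def exp_conv(t, tau: float, sigma: float, t0: float = 0.0) -> np.ndarray:
    """Causal exponential decay exp(-t/tau) convolved with a Gaussian.

    Evaluated through erfcx to stay stable when sigma^2/tau >> t.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float) - t0)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if sigma <= 0:
        return np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau), 0.0)
    s = sigma / tau
    z = (s - t / sigma) / np.sqrt(2.0)
    # 0.5 exp(s^2/2 - t/tau) erfc(z); for z >= 0 rewrite via erfcx to
    # avoid overflow of exp, for z < 0 (t >> sigma) evaluate directly
    # since the exponential itself is then small.
    out = np.empty_like(t)
    pos = z >= 0
    out[pos] = 0.5 * erfcx(z[pos]) * np.exp(-(t[pos] ** 2) / (2.0 * sigma**2))
    out[~pos] = 0.5 * np.exp(0.5 * s**2 - t[~pos] / tau) * erfc(z[~pos])
    return out


def rise_conv(t, tau: float, sigma: float, t0: float = 0.0) -> np.ndarray:
    """Saturating rise (1 - exp(-t/tau)) * step, convolved with a Gaussian."""
    return step_conv(t, sigma, t0) - exp_conv(t, tau, sigma, t0)
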