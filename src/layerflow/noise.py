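"""Instrument-noise simulation for FD-DOS and DCS measurements.

FD-DOS noise is Gaussian: multiplicative-relative on the amplitude
(``sigma = AC / SNR`` per source-detector distance) and additive on the
phase (standard deviation in degrees), independent across distances and
of each other.

DCS noise follows the photon-statistics correlation noise model of
Koppel (Phys. Rev. A 10, 1938 (1974)), in the single-exponential form
commonly used for diffuse correlation spectroscopy (e.g. C. Zhou et al.,
Opt. Express 14, 1125 (2006), Eq. (17)): the per-lag standard deviation of
g2 is parameterized by the correlator bin time, the integration time T,
the mean photon count per bin, the coherence factor beta, and the decay
rate of the (noise-free) correlation curve.  Noise is Gaussian,
zero-mean, and independent across lags.

The delay-time grid mimics a hardware multi-tau correlator: a linear
block at the base bin time followed by stages in which the bin width
doubles every few lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TauGrid",
    "FdNoiseSpec",
    "DcsNoiseSpec",
    "multitau_grid",
    "add_fd_noise",
    "estimate_decay_rate",
    "dcs_noise_sigma",
    "add_dcs_noise",
]


@dataclass(frozen=True)
class TauGrid:
    """Strictly increasing delay-time grid (s) plus a layout descriptor."""

    taus: np.ndarray
    scheme: str = "multitau"

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        if taus.ndim != 1 or taus.size < 2:
            raise ValueError("need at least two delay times")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("delay times must be strictly increasing")
        object.__setattr__(self, "taus", taus)

    def __len__(self) -> int:
        return self.taus.size


@dataclass(frozen=True)
class FdNoiseSpec:
    """Amplitude SNR (mu/sigma) and phase standard deviation (degrees)."""

    amplitude_snr: float = 100.0
    phase_sigma_deg: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.amplitude_snr > 0:
            raise ValueError("amplitude_snr must be positive")
        if self.phase_sigma_deg < 0:
            raise ValueError("phase_sigma_deg must be >= 0")


@dataclass(frozen=True)
class DcsNoiseSpec:
    """Photon count rate, integration time and correlator parameters that
    set the correlation-noise magnitude."""

    count_rate: float            # detected photon rate (Hz)
    integration_time: float      # T (s)
    beta: float = 0.5
    bin_time: float = 0.6e-6     # correlator base bin (s)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.count_rate > 0:
            raise ValueError("count_rate must be positive")
        if not self.integration_time > 0:
            raise ValueError("integration_time must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if not self.bin_time > 0:
            raise ValueError("bin_time must be positive")


def multitau_grid(
    tau_min: float = 0.6e-6,
    tau_max: float = 3.7e-3,
    count: int = 100,
    *,
    linear_lags: int = 16,
    lags_per_stage: int = 8,
) -> TauGrid:
    """Build a multi-tau delay grid of exactly ``count`` lags.

    The first ``linear_lags`` lags are linear at the base bin
    ``tau_min``; afterwards the bin width doubles every
    ``lags_per_stage`` lags.  When continuing to double would overshoot
    ``tau_max`` before reaching ``count`` lags, the doubling stops and the
    remaining lags are spread linearly up to ``tau_max`` (a truncated
    multi-tau layout that spans the full requested range).
    """
    if not 0 < tau_min < tau_max:
        raise ValueError("need 0 < tau_min < tau_max")
    if count < 2:
        raise ValueError("count must be >= 2")
    if count * tau_min > tau_max + 1e-30:
        raise ValueError(
            f"count={count} lags at base bin {tau_min} cannot fit below "
            f"tau_max={tau_max}"
        )
    taus = []
    bin_w = tau_min
    t = 0.0
    while len(taus) < count:
        at_boundary = len(taus) >= linear_lags and (
            (len(taus) - linear_lags) % lags_per_stage == 0
        )
        if at_boundary:
            remaining = count - len(taus)
            if t + remaining * 2.0 * bin_w > tau_max:
                # final linear fill to tau_max
                taus.extend(t + (tau_max - t) * np.arange(1, remaining + 1) / remaining)
                break
            bin_w *= 2.0
        t += bin_w
        if t > tau_max * (1 + 1e-12):
            raise ValueError("multi-tau layout cannot stay within tau_max")
        taus.append(t)
    return TauGrid(np.asarray(taus[:count]), scheme="multitau")


def add_fd_noise(amplitudes, phases, spec: FdNoiseSpec, rng=None):
    """Add FD-DOS instrument noise to amplitude/phase curves.

    ``AC' = AC (1 + eps / SNR)`` with ``eps ~ N(0,1)`` i.i.d. per
    distance; ``theta' = theta + eta`` with ``eta ~ N(0, sigma_theta^2)``
    (``phases`` in radians, sigma specified in degrees).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ac = np.asarray(amplitudes, dtype=float)
    th = np.asarray(phases, dtype=float)
    ac_noisy = ac * (1.0 + rng.standard_normal(ac.shape) / spec.amplitude_snr)
    th_noisy = th + np.deg2rad(spec.phase_sigma_deg) * rng.standard_normal(th.shape)
    return ac_noisy, th_noisy


def estimate_decay_rate(curve, tau_grid, *, beta: float | None = None) -> float:
    """Decay rate (1/s) of the best single-exponential fit ``g1 ~ exp(-G tau)``.

    ``curve`` may be a g1 curve (values in (0, 1]) or a g2 curve (values
    near 1 + beta); g2 input is converted through the Siegert relation
    using ``beta`` (defaulting to the observed intercept).  The rate is
    fit by least squares of ``ln g1`` against tau on the early lags
    (g1 >= 0.3), where the single-exponential approximation holds.
    """
    taus = np.asarray(tau_grid.taus if isinstance(tau_grid, TauGrid) else tau_grid,
                      dtype=float)
    vals = np.asarray(curve, dtype=float)
    if vals.shape != taus.shape:
        raise ValueError("curve and tau grid lengths differ")
    if vals[0] > 1.05:  # intensity autocorrelation
        b = beta if beta is not None else max(vals[0] - 1.0, 1e-6)
        g1 = np.sqrt(np.clip((vals - 1.0) / b, 0.0, None))
    else:
        g1 = vals
    mask = g1 >= 0.3
    if mask.sum() < 3:
        mask = np.zeros_like(mask)
        mask[:3] = True
    slope, _ = np.polyfit(taus[mask], np.log(np.clip(g1[mask], 1e-12, None)), 1)
    gamma = -slope
    if not gamma > 0:
        raise ValueError("curve does not decay; cannot estimate a decay rate")
    return float(gamma)


def dcs_noise_sigma(tau_grid, gamma: float, spec: DcsNoiseSpec) -> np.ndarray:
    """Per-lag standard deviation of g2 from the correlation noise model.

    Koppel-derived expression (D. E. Koppel, Phys. Rev. A 10, 1938
    (1974); in the single-exponential DCS form of C. Zhou et al., Opt.
    Express 14, 1125 (2006), Eq. (17)) with bin time ``t``, integration
    time ``T``, mean photons per bin ``<n> = count_rate * t``, lag index
    ``m = tau / t``, coherence factor ``beta`` and single-exponential
    decay rate ``gamma``:

    ``sigma(tau) = sqrt(t/T) * [ beta^2 ( (1+e^-2Gt)(1+e^-2Gtau)
    + 2m(1-e^-2Gt)e^-2Gtau ) / (1-e^-2Gt) + 2<n>^-1 beta (1+e^-2Gtau)
    + <n>^-2 (1 + beta e^-Gtau) ]^(1/2)``

    For a multi-tau grid, ``t`` is each lag's own accumulation bin (the
    local lag spacing, ``spec.bin_time`` in the linear block): a hardware
    multi-tau correlator averages late lags over its widened bins, which
    suppresses the shot-noise terms there.  The noise scales exactly as
    ``1/sqrt(T)`` and decreases with count rate; at late lags it
    approaches a floor set by beta and ``<n>``.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    taus = np.asarray(tau_grid.taus if isinstance(tau_grid, TauGrid) else tau_grid,
                      dtype=float)
    T = spec.integration_time
    beta = spec.beta
    # local bin width per lag; constant grids reduce to spec.bin_time
    t = np.diff(taus, prepend=0.0)
    t[0] = min(taus[0], spec.bin_time)
    n_mean = spec.count_rate * t
    m = np.maximum(taus / t, 1.0)
    e2t = np.exp(-2.0 * gamma * t)
    e2tau = np.exp(-2.0 * gamma * taus)
    e1tau = np.exp(-gamma * taus)
    var = (
        beta**2 * ((1 + e2t) * (1 + e2tau) + 2 * m * (1 - e2t) * e2tau) / (1 - e2t)
        + 2 / n_mean * beta * (1 + e2tau)
        + (1 + beta * e1tau) / n_mean**2
    )
    return np.sqrt(t / T * var)


def add_dcs_noise(g2_curve, sigma_curve, seed=None, rng=None) -> np.ndarray:
    """Add zero-mean Gaussian noise with per-lag standard deviation
    ``sigma_curve`` to a g2 curve, independently per lag."""
    g2 = np.asarray(g2_curve, dtype=float)
    sigma = np.asarray(sigma_curve, dtype=float)
    if g2.shape != sigma.shape:
        raise ValueError("g2 and sigma curves must have the same length")
    if rng is None:
        rng = np.random.default_rng(seed)
    return g2 + sigma * rng.standard_normal(g2.shape)
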