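"""Sequential constrained inversion for layered FD-DOS / DCS data.

The three-step scheme assumes a priori knowledge of the superficial-layer
thickness and homogeneous reduced scattering across layers:

1. fit multidistance FD-DOS amplitude and phase to the two-layer cylinder
   model for ``(mu_a1, mu_a2, mu_s')``;
2. fit the short-separation DCS curve to the semi-infinite correlation
   model for the superficial flow index ``F1``, using the stage-1 optics;
3. fit the long-separation DCS curve to the two-layer correlation model
   for the cerebral flow index ``F2``, using all previous outputs.

Both FD-DOS cost terms are built from differences relative to the
shortest distance (log-amplitude ratios and phase differences), which
removes instrumental amplitude/phase scale factors from the problem.  The
homogeneous semi-infinite baseline fits (long distances only) and the
coherence-factor (beta) estimation fit are also provided here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from . import models as M

__all__ = [
    "FddosData",
    "DcsData",
    "FitConfig",
    "FlowFitResult",
    "SIFitResult",
    "TwoLayerFitResult",
    "FitError",
    "fit_fddos_2L",
    "fit_dcs_si",
    "fit_dcs_2L",
    "fit_fddos_si",
    "fit_beta",
    "fit_hybrid_2L",
]


class FitError(RuntimeError):
    """Raised when a fit cannot be set up or produces no usable lags."""


# ---------------------------------------------------------------------------
# measured-data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FddosData:
    """Multidistance FD-DOS measurement: amplitudes and phases (radians)."""

    distances: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    modulation_frequency: float

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        p = np.asarray(self.phases, dtype=float)
        if not (d.shape == a.shape == p.shape) or d.ndim != 1:
            raise ValueError("distances, amplitudes, phases must be 1-D and equal length")
        if d.size < 3:
            raise ValueError("need at least 3 source-detector distances")
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError("amplitudes must be positive")
        if not self.modulation_frequency > 0:
            raise ValueError("modulation_frequency must be positive")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "phases", p)

    def restricted(self, dmin: float, dmax: float) -> "FddosData":
        """Sub-measurement with distances in [dmin, dmax]."""
        m = (self.distances >= dmin) & (self.distances <= dmax)
        return FddosData(
            self.distances[m], self.amplitudes[m], self.phases[m],
            self.modulation_frequency,
        )


@dataclass(frozen=True)
class DcsData:
    """Single-distance DCS measurement: intensity autocorrelation g2(tau)."""

    distance: float
    taus: np.ndarray
    g2: np.ndarray
    wavelength: float            # cm
    integration_time: float = 10.0

    def __post_init__(self) -> None:
        t = np.asarray(self.taus, dtype=float)
        g = np.asarray(self.g2, dtype=float)
        if t.shape != g.shape or t.ndim != 1:
            raise ValueError("taus and g2 must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("taus must be strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ValueError("g2 contains non-finite values")
        if not self.distance > 0:
            raise ValueError("distance must be positive")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive (cm)")
        object.__setattr__(self, "taus", t)
        object.__setattr__(self, "g2", g)


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS = {
    "mu_a1": (0.005, 0.6),
    "mu_a2": (0.005, 0.6),
    "mu_s_prime": (4.0, 20.0),
    "F1": (1e-11, 1e-5),
    "F2": (1e-11, 1e-5),
}
_DEFAULT_GUESS = {"mu_a1": 0.1, "mu_a2": 0.1, "mu_s_prime": 10.0, "F1": 1e-8, "F2": 1e-8}


@dataclass
class FitConfig:
    """Bounds, initial guesses and geometry for the sequential inversion.

    ``thickness`` is the assumed superficial-layer thickness (cm) -- the
    algorithm's single piece of prior anatomical knowledge.
    """

    thickness: float = 1.2
    radius: float = 30.0
    refractive_index: float = 1.4
    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    initial_guess: dict = field(default_factory=lambda: dict(_DEFAULT_GUESS))
    beta_short: float = 0.5
    beta_long: float = 0.5
    g2_floor_2L: float = 1.0
    g2_floor_SI: float = 1.25
    lag_selection: str = "prefix"     # 'prefix' | 'all'
    si_distances: tuple = (2.8, 3.2, 3.6, 4.0)
    ftol: float = 1e-9
    xtol: float = 1e-7

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("thickness must be positive")
        for name, (lo, hi) in self.bounds.items():
            init = self.initial_guess.get(name)
            if init is not None and not (lo < init < hi):
                raise ValueError(f"initial guess for {name} not inside bounds")
        if self.lag_selection not in ("prefix", "all"):
            raise ValueError("lag_selection must be 'prefix' or 'all'")


@dataclass(frozen=True)
class FlowFitResult:
    flow_index: float
    residual: float
    converged: bool
    bounds_hit: bool
    n_lags: int


@dataclass(frozen=True)
class SIFitResult:
    mu_a_SI: float
    mu_s_prime_SI: float
    F_SI: float | None = None
    beta: float | None = None
    residuals: dict = field(default_factory=dict)
    converged: dict = field(default_factory=dict)
    bounds_hit: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TwoLayerFitResult:
    mu_a1: float
    mu_a2: float
    mu_s_prime: float
    F1: float | None = None
    F2: float | None = None
    residuals: dict = field(default_factory=dict)
    converged: dict = field(default_factory=dict)
    bounds_hit: dict = field(default_factory=dict)


def _near_bound(x: float, lo: float, hi: float, tol: float = 1e-6) -> bool:
    span = hi - lo
    return (x - lo) <= tol * span or (hi - x) <= tol * span


# ---------------------------------------------------------------------------
# stage 1: FD-DOS two-layer fit
# ---------------------------------------------------------------------------


def _fd_cost_parts(amplitudes, phases):
    """Relative representation: log-amplitude and phase w.r.t. rho_1."""
    log_ac = np.log(amplitudes)
    return log_ac - log_ac[0], phases - phases[0]


def fit_fddos_2L(data: FddosData, cfg: FitConfig) -> TwoLayerFitResult:
    """Recover ``(mu_a1, mu_a2, mu_s')`` from multidistance FD-DOS data.

    Minimizes the sum of the squared log-amplitude-ratio and
    phase-difference misfits (both relative to the shortest distance)
    over the three optics with ``mu_s1' = mu_s2' = mu_s'`` enforced.
    """
    if data.distances.size < 4:
        raise FitError("the two-layer FD-DOS fit needs at least 4 distances")
    src = M.SourceSpec("FD", modulation_frequency=data.modulation_frequency)
    meas_logac, meas_ph = _fd_cost_parts(data.amplitudes, data.phases)
    dists = data.distances

    def residuals(x):
        mua1, mua2, mus = x
        med = M.TwoLayerMedium(
            M.TissueLayer(mua1, mus), M.TissueLayer(mua2, mus),
            thickness=cfg.thickness, radius=cfg.radius,
            refractive_index=cfg.refractive_index,
        )
        ac, th = M.fd_amp_phase_2L(med, src, dists)
        th_logac, th_ph = _fd_cost_parts(ac, th)
        return np.concatenate([meas_logac - th_logac, meas_ph - th_ph])

    lo = [cfg.bounds["mu_a1"][0], cfg.bounds["mu_a2"][0], cfg.bounds["mu_s_prime"][0]]
    hi = [cfg.bounds["mu_a1"][1], cfg.bounds["mu_a2"][1], cfg.bounds["mu_s_prime"][1]]
    x0 = [cfg.initial_guess["mu_a1"], cfg.initial_guess["mu_a2"],
          cfg.initial_guess["mu_s_prime"]]
    res = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        ftol=cfg.ftol, xtol=cfg.xtol, diff_step=1e-4,
        x_scale=[0.1, 0.1, 10.0],
    )
    names = ["mu_a1", "mu_a2", "mu_s_prime"]
    bounds_hit = {
        n: _near_bound(v, l, h) for n, v, l, h in zip(names, res.x, lo, hi)
    }
    return TwoLayerFitResult(
        mu_a1=res.x[0], mu_a2=res.x[1], mu_s_prime=res.x[2],
        residuals={"fddos": float(2 * res.cost)},
        converged={"fddos": bool(res.success)},
        bounds_hit=bounds_hit,
    )


# ---------------------------------------------------------------------------
# DCS lag selection and single-parameter flow fits
# ---------------------------------------------------------------------------


def _select_lags(g2: np.ndarray, floor: float, scheme: str) -> np.ndarray:
    """Boolean mask of lags entering the DCS cost."""
    above = g2 >= floor
    if scheme == "all":
        mask = above
    else:  # contiguous prefix up to the first crossing below the floor
        mask = np.zeros_like(above)
        if above[0]:
            first_below = np.argmin(above) if not above.all() else above.size
            mask[:first_below] = True
    if not mask.any():
        raise FitError(f"no delay times with g2 >= {floor}")
    return mask


def _fit_flow(g2_meas, taus, model_g1, beta, cfg: FitConfig, bounds_key: str) -> FlowFitResult:
    """Bounded single-parameter flow fit, run in log10(F) space."""
    lo, hi = cfg.bounds[bounds_key]
    u0 = np.log10(cfg.initial_guess[bounds_key])

    def residuals(u):
        g1 = model_g1(10.0 ** u[0])
        return g2_meas - (1.0 + beta * g1**2)

    res = least_squares(
        residuals, [u0], bounds=([np.log10(lo)], [np.log10(hi)]),
        method="trf", ftol=cfg.ftol, xtol=cfg.xtol, diff_step=1e-4,
    )
    u = res.x[0]
    return FlowFitResult(
        flow_index=float(10.0 ** u),
        residual=float(2 * res.cost),
        converged=bool(res.success),
        bounds_hit=_near_bound(u, np.log10(lo), np.log10(hi)),
        n_lags=g2_meas.size,
    )


def fit_dcs_si(
    data: DcsData,
    mu_a: float,
    mu_s_prime: float,
    beta: float,
    cfg: FitConfig,
    g2_floor: float | None = None,
) -> FlowFitResult:
    """Fit a flow index to one DCS curve with the semi-infinite model.

    Used both as stage 2 of the layered scheme (short separation,
    superficial optics from stage 1, ``g2 >= 1``) and as the homogeneous
    baseline (long separation, SI optics, ``g2 >= 1.25``).
    """
    floor = cfg.g2_floor_2L if g2_floor is None else g2_floor
    mask = _select_lags(data.g2, floor, cfg.lag_selection)
    taus = data.taus[mask]
    g2m = data.g2[mask]
    src = M.SourceSpec("DCS", wavelength=data.wavelength)

    def model_g1(F):
        med = M.SemiInfiniteMedium(
            M.TissueLayer(mu_a, mu_s_prime, F), cfg.refractive_index
        )
        return M.si_g1(med, src, data.distance, taus)

    return _fit_flow(g2m, taus, model_g1, beta, cfg, "F1")


def fit_dcs_2L(
    data: DcsData,
    mu_a1: float,
    mu_a2: float,
    mu_s_prime: float,
    F1: float,
    cfg: FitConfig,
) -> FlowFitResult:
    """Stage 3: fit the deep-layer flow index ``F2`` to the long-separation
    DCS curve with the two-layer model, all other parameters fixed."""
    mask = _select_lags(data.g2, cfg.g2_floor_2L, cfg.lag_selection)
    taus = data.taus[mask]
    g2m = data.g2[mask]
    src = M.SourceSpec("DCS", wavelength=data.wavelength)

    def model_g1(F2):
        med = M.TwoLayerMedium(
            M.TissueLayer(mu_a1, mu_s_prime, F1),
            M.TissueLayer(mu_a2, mu_s_prime, F2),
            thickness=cfg.thickness, radius=cfg.radius,
            refractive_index=cfg.refractive_index,
        )
        return M.g1_2L(med, src, data.distance, taus)

    return _fit_flow(g2m, taus, model_g1, cfg.beta_long, cfg, "F2")


# ---------------------------------------------------------------------------
# homogeneous baselines
# ---------------------------------------------------------------------------


def fit_fddos_si(data: FddosData, cfg: FitConfig) -> SIFitResult:
    """Homogeneous-baseline FD-DOS fit at the long distances.

    Same relative log-amplitude + phase-difference cost as the layered
    stage-1 fit, with the semi-infinite forward model and two free
    parameters ``(mu_a, mu_s')``.
    """
    if data.distances.size < 3:
        raise FitError("the SI FD-DOS fit needs at least 3 distances")
    src = M.SourceSpec("FD", modulation_frequency=data.modulation_frequency)
    meas_logac, meas_ph = _fd_cost_parts(data.amplitudes, data.phases)

    def residuals(x):
        med = M.SemiInfiniteMedium(M.TissueLayer(x[0], x[1]), cfg.refractive_index)
        R = M.si_reflectance_fd(med, src, data.distances)
        ac, th = np.abs(R), np.unwrap(-np.angle(R))
        th_logac, th_ph = _fd_cost_parts(ac, th)
        return np.concatenate([meas_logac - th_logac, meas_ph - th_ph])

    lo = [cfg.bounds["mu_a1"][0], cfg.bounds["mu_s_prime"][0]]
    hi = [cfg.bounds["mu_a1"][1], cfg.bounds["mu_s_prime"][1]]
    x0 = [cfg.initial_guess["mu_a1"], cfg.initial_guess["mu_s_prime"]]
    res = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        ftol=cfg.ftol, xtol=cfg.xtol, diff_step=1e-4, x_scale=[0.1, 10.0],
    )
    return SIFitResult(
        mu_a_SI=res.x[0], mu_s_prime_SI=res.x[1],
        residuals={"fddos": float(2 * res.cost)},
        converged={"fddos": bool(res.success)},
        bounds_hit={
            "mu_a_SI": _near_bound(res.x[0], lo[0], hi[0]),
            "mu_s_prime_SI": _near_bound(res.x[1], lo[1], hi[1]),
        },
    )


def fit_si_baseline(fd: FddosData, dcs_long: DcsData, cfg: FitConfig) -> SIFitResult:
    """Full homogeneous baseline: SI optics from the long FD-DOS
    distances, then the SI flow index from the long DCS curve restricted
    to its early lags (``g2 >= g2_floor_SI``)."""
    sub = fd.restricted(min(cfg.si_distances) - 1e-9, max(cfg.si_distances) + 1e-9)
    si_fd = fit_fddos_si(sub, cfg)
    flow = fit_dcs_si(
        dcs_long, si_fd.mu_a_SI, si_fd.mu_s_prime_SI, cfg.beta_long, cfg,
        g2_floor=cfg.g2_floor_SI,
    )
    return SIFitResult(
        mu_a_SI=si_fd.mu_a_SI,
        mu_s_prime_SI=si_fd.mu_s_prime_SI,
        F_SI=flow.flow_index,
        residuals={**si_fd.residuals, "dcs": flow.residual},
        converged={**si_fd.converged, "dcs": flow.converged},
        bounds_hit={**si_fd.bounds_hit, "F_SI": flow.bounds_hit},
    )


def fit_beta(
    data: DcsData,
    mu_a: float,
    mu_s_prime: float,
    cfg: FitConfig | None = None,
    g2_floor: float = 1.25,
) -> tuple[float, FlowFitResult]:
    """Estimate the Siegert coherence factor beta jointly with a flow
    index from the early lags (``g2 >= g2_floor``) of one curve, using
    the semi-infinite model.  Returns ``(beta, flow_result)``."""
    cfg = cfg or FitConfig()
    mask = _select_lags(data.g2, g2_floor, cfg.lag_selection)
    taus = data.taus[mask]
    g2m = data.g2[mask]
    src = M.SourceSpec("DCS", wavelength=data.wavelength)

    def residuals(x):
        beta, u = x
        med = M.SemiInfiniteMedium(
            M.TissueLayer(mu_a, mu_s_prime, 10.0**u), cfg.refractive_index
        )
        g1 = M.si_g1(med, src, data.distance, taus)
        return g2m - (1.0 + beta * g1**2)

    lo_f, hi_f = cfg.bounds["F1"]
    res = least_squares(
        residuals, [0.5, np.log10(cfg.initial_guess["F1"])],
        bounds=([1e-3, np.log10(lo_f)], [1.0, np.log10(hi_f)]),
        method="trf", ftol=cfg.ftol, xtol=cfg.xtol, diff_step=1e-4,
    )
    beta = float(res.x[0])
    flow = FlowFitResult(
        flow_index=float(10.0 ** res.x[1]),
        residual=float(2 * res.cost),
        converged=bool(res.success),
        bounds_hit=_near_bound(res.x[1], np.log10(lo_f), np.log10(hi_f)),
        n_lags=g2m.size,
    )
    return beta, flow


# ---------------------------------------------------------------------------
# the full sequential scheme
# ---------------------------------------------------------------------------


def fit_hybrid_2L(
    fd: FddosData,
    dcs_short: DcsData,
    dcs_long: DcsData,
    cfg: FitConfig,
) -> TwoLayerFitResult:
    """Run the three sequential stages and thread their outputs.

    Stage failures propagate as ``FitError`` carrying the stage name;
    optimizer non-convergence is reported in the ``converged`` flags
    rather than raised.
    """
    if dcs_short.distance >= dcs_long.distance:
        raise FitError("dcs_short must have a smaller distance than dcs_long")
    try:
        stage1 = fit_fddos_2L(fd, cfg)
    except FitError as exc:
        raise FitError(f"stage 1 (FD-DOS 2L): {exc}") from exc
    try:
        stage2 = fit_dcs_si(
            dcs_short, stage1.mu_a1, stage1.mu_s_prime, cfg.beta_short, cfg,
            g2_floor=cfg.g2_floor_2L,
        )
    except FitError as exc:
        raise FitError(f"stage 2 (DCS SI short): {exc}") from exc
    try:
        stage3 = fit_dcs_2L(
            dcs_long, stage1.mu_a1, stage1.mu_a2, stage1.mu_s_prime,
            stage2.flow_index, cfg,
        )
    except FitError as exc:
        raise FitError(f"stage 3 (DCS 2L long): {exc}") from exc
    return TwoLayerFitResult(
        mu_a1=stage1.mu_a1, mu_a2=stage1.mu_a2, mu_s_prime=stage1.mu_s_prime,
        F1=stage2.flow_index, F2=stage3.flow_index,
        residuals={**stage1.residuals, "dcs_short": stage2.residual,
                   "dcs_long": stage3.residual},
        converged={**stage1.converged, "dcs_short": stage2.converged,
                   "dcs_long": stage3.converged},
        bounds_hit={**stage1.bounds_hit, "F1": stage2.bounds_hit,
                    "F2": stage3.bounds_hit},
    )
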