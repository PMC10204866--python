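"""Simulation-study harness: truth sampling, noisy forward data, accuracy
metrics and the secondary error studies.

The default instrument mirrors a hybrid FD-DOS/DCS probe on an adult
head: eight FD-DOS distances from 0.8 to 4.0 cm at 110 MHz, DCS at
0.8 cm (200 kHz detected) and 2.5 cm (40 kHz) at 785 nm, a 100-lag
multi-tau grid from 0.6 us to 3.7 ms, coherence factor beta = 0.5,
cylinder radius 30 cm, refractive index 1.4.

Truths are drawn uniformly from adult-head ranges: mu_a in
[0.08, 0.18] 1/cm for both layers, mu_s' in [6, 15] 1/cm with the
fractional difference between layers below 20%, F1 in [1e-9, 2e-8] and
F2 in [1e-9, 1e-7] cm^2/s, superficial thicknesses {1.0, 1.2, 1.4,
1.6} cm.  Truths have heterogeneous scattering; the fits assume it
homogeneous, which is part of what the study quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import models as M
from . import noise as N
from . import fitting as F

__all__ = [
    "Instrument",
    "SamplingRanges",
    "MetricsSummary",
    "sample_forward_dataset",
    "simulate_record",
    "mape_iqr",
    "recovery_regression",
    "sensitivity_profiles",
    "cnr",
    "run_recovery_study",
    "run_perturbation_study",
    "summarize_records",
]


@dataclass(frozen=True)
class Instrument:
    """Probe geometry and acquisition settings of the simulated system."""

    fd_distances: tuple = (0.8, 1.2, 1.6, 2.0, 2.8, 3.2, 3.6, 4.0)
    dcs_short: float = 0.8
    dcs_long: float = 2.5
    modulation_frequency: float = 110e6        # Hz
    wavelength: float = 785e-7                 # cm
    count_rate_short: float = 200e3            # Hz
    count_rate_long: float = 40e3              # Hz
    beta: float = 0.5
    radius: float = 30.0                       # cm
    refractive_index: float = 1.4
    amplitude_snr: float = 100.0
    phase_sigma_deg: float = 0.1


DEFAULT_INSTRUMENT = Instrument()


@dataclass(frozen=True)
class SamplingRanges:
    mu_a_range: tuple = (0.08, 0.18)
    mu_s_range: tuple = (6.0, 15.0)
    scatter_mismatch_cap: float = 0.20
    F1_range: tuple = (1e-9, 2e-8)
    F2_range: tuple = (1e-9, 1e-7)
    thicknesses: tuple = (1.0, 1.2, 1.4, 1.6)
    combos_per_thickness: int = 2030

    def __post_init__(self) -> None:
        for r in (self.mu_a_range, self.mu_s_range, self.F1_range, self.F2_range):
            if not r[0] < r[1]:
                raise ValueError("ranges must be ordered")
        if not 0 < self.scatter_mismatch_cap < 1:
            raise ValueError("scatter_mismatch_cap must lie in (0, 1)")


@dataclass(frozen=True)
class MetricsSummary:
    """Per-parameter MAPE (%), IQR of absolute percent errors, optional
    OLS slope/intercept of recovered vs actual, and Wilcoxon p-values for
    the layered-vs-homogeneous comparisons."""

    mape: dict
    iqr: dict
    regression: dict = field(default_factory=dict)
    wilcoxon_p: dict = field(default_factory=dict)
    n_records: int = 0
    n_failed: int = 0


def sample_forward_dataset(
    ranges: SamplingRanges,
    seed: int,
    combos_per_thickness: int | None = None,
) -> list[M.TwoLayerMedium]:
    """Draw uniform truths within the stated ranges, one flow pair per
    optics combination, rejecting scattering mismatches above the cap."""
    rng = np.random.default_rng(seed)
    n = combos_per_thickness or ranges.combos_per_thickness
    truths = []
    for ell in ranges.thicknesses:
        for _ in range(n):
            mua1 = rng.uniform(*ranges.mu_a_range)
            mua2 = rng.uniform(*ranges.mu_a_range)
            while True:
                mus1 = rng.uniform(*ranges.mu_s_range)
                mus2 = rng.uniform(*ranges.mu_s_range)
                if abs(mus1 - mus2) / mus1 < ranges.scatter_mismatch_cap:
                    break
            f1 = rng.uniform(*ranges.F1_range)
            f2 = rng.uniform(*ranges.F2_range)
            truths.append(
                M.TwoLayerMedium(
                    M.TissueLayer(mua1, mus1, f1),
                    M.TissueLayer(mua2, mus2, f2),
                    thickness=ell,
                    radius=DEFAULT_INSTRUMENT.radius,
                    refractive_index=DEFAULT_INSTRUMENT.refractive_index,
                )
            )
    return truths


def simulate_record(
    truth: M.TwoLayerMedium,
    rng: np.random.Generator,
    *,
    integration_time: float = 10.0,
    instrument: Instrument = DEFAULT_INSTRUMENT,
    tau_grid: N.TauGrid | None = None,
    noiseless: bool = False,
):
    """Generate one noisy (or noiseless) synthetic measurement set:
    multidistance FD-DOS plus short- and long-separation DCS."""
    ins = instrument
    grid = tau_grid or N.multitau_grid()
    fd_src = M.SourceSpec("FD", modulation_frequency=ins.modulation_frequency)
    dcs_src = M.SourceSpec("DCS", wavelength=ins.wavelength)
    rhos = np.asarray(ins.fd_distances, dtype=float)

    ac, th = M.fd_amp_phase_2L(truth, fd_src, rhos)
    if not noiseless:
        spec = N.FdNoiseSpec(ins.amplitude_snr, ins.phase_sigma_deg)
        ac, th = N.add_fd_noise(ac, th, spec, rng=rng)
    fd = F.FddosData(rhos, ac, th, ins.modulation_frequency)

    dcs = {}
    for rho, rate in ((ins.dcs_short, ins.count_rate_short),
                      (ins.dcs_long, ins.count_rate_long)):
        g1 = M.g1_2L(truth, dcs_src, rho, grid.taus)
        g2 = M.siegert(g1, ins.beta)
        if not noiseless:
            gamma = N.estimate_decay_rate(g1, grid)
            spec = N.DcsNoiseSpec(rate, integration_time, beta=ins.beta)
            sigma = N.dcs_noise_sigma(grid, gamma, spec)
            g2 = N.add_dcs_noise(g2, sigma, rng=rng)
        dcs[rho] = F.DcsData(rho, grid.taus, g2, ins.wavelength,
                             integration_time=integration_time)
    return fd, dcs[ins.dcs_short], dcs[ins.dcs_long]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def mape_iqr(recovered, actual):
    """Median and interquartile range of the absolute percent errors
    ``100 |actual - recovered| / actual`` (quartiles by linear
    interpolation)."""
    rec = np.asarray(recovered, dtype=float)
    act = np.asarray(actual, dtype=float)
    if rec.shape != act.shape:
        raise ValueError("recovered and actual must have equal length")
    if np.any(act == 0):
        raise ValueError("actual values must be nonzero")
    ape = 100.0 * np.abs((act - rec) / act)
    q1, med, q3 = np.percentile(ape, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def recovery_regression(recovered, actual):
    """Ordinary least-squares slope and intercept of recovered on actual."""
    rec = np.asarray(recovered, dtype=float)
    act = np.asarray(actual, dtype=float)
    if rec.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(act) == 0:
        raise ValueError("actual values are degenerate (zero variance)")
    fit = stats.linregress(act, rec)
    return float(fit.slope), float(fit.intercept)


def cnr(baseline_F_samples, stepped_F_samples) -> float:
    """Contrast-to-noise ratio: median paired flow change divided by the
    standard deviation of the baseline recoveries."""
    base = np.asarray(baseline_F_samples, dtype=float)
    step = np.asarray(stepped_F_samples, dtype=float)
    if base.size == 0 or step.size == 0:
        raise ValueError("need nonempty samples")
    if base.shape != step.shape:
        raise ValueError("paired samples must have equal length")
    sd = np.std(base, ddof=1)
    if sd == 0:
        raise ValueError("zero baseline variance")
    return float(np.median(step - base) / sd)


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

_PARAM_SETTERS = {
    "mu_a1": lambda m, x: _rebuild(m, mu_a1=x),
    "mu_a2": lambda m, x: _rebuild(m, mu_a2=x),
    "mu_s1": lambda m, x: _rebuild(m, mu_s1=x),
    "mu_s2": lambda m, x: _rebuild(m, mu_s2=x),
}
_PARAM_GETTERS = {
    "mu_a1": lambda m: m.layer1.mu_a,
    "mu_a2": lambda m: m.layer2.mu_a,
    "mu_s1": lambda m: m.layer1.mu_s_prime,
    "mu_s2": lambda m: m.layer2.mu_s_prime,
}


def _rebuild(m: M.TwoLayerMedium, **kw) -> M.TwoLayerMedium:
    l1 = M.TissueLayer(
        kw.get("mu_a1", m.layer1.mu_a),
        kw.get("mu_s1", m.layer1.mu_s_prime),
        m.layer1.flow_index,
    )
    l2 = M.TissueLayer(
        kw.get("mu_a2", m.layer2.mu_a),
        kw.get("mu_s2", m.layer2.mu_s_prime),
        m.layer2.flow_index,
    )
    return M.TwoLayerMedium(l1, l2, m.thickness, m.radius, m.refractive_index)


def sensitivity_profiles(
    base: M.TwoLayerMedium,
    source: M.SourceSpec,
    rho_grid: Sequence[float],
    param_list: Sequence[str] = ("mu_a1", "mu_a2", "mu_s1", "mu_s2"),
    rel_step: float = 1e-3,
) -> dict:
    """Central finite-difference derivatives of log-amplitude and phase of
    the layered FD model with respect to each optical property (layers
    varied independently).

    Returns ``{param: (dlogAC_drho_grid, dtheta_drho_grid)}``.
    """
    rhos = np.asarray(rho_grid, dtype=float)
    out = {}
    for p in param_list:
        x = _PARAM_GETTERS[p](base)
        h = rel_step * x
        ac_hi, th_hi = M.fd_amp_phase_2L(_PARAM_SETTERS[p](base, x + h), source, rhos)
        ac_lo, th_lo = M.fd_amp_phase_2L(_PARAM_SETTERS[p](base, x - h), source, rhos)
        out[p] = (
            (np.log(ac_hi) - np.log(ac_lo)) / (2 * h),
            (th_hi - th_lo) / (2 * h),
        )
    return out


# ---------------------------------------------------------------------------
# recovery study
# ---------------------------------------------------------------------------


def run_recovery_study(
    truths: Sequence[M.TwoLayerMedium],
    *,
    integration_time: float = 10.0,
    seed: int = 0,
    instrument: Instrument = DEFAULT_INSTRUMENT,
    noiseless: bool = False,
    si_baseline: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate and invert every truth; return one tidy row per record.

    Columns: truth parameters (suffix ``_act``), the layered recoveries,
    and (optionally) the homogeneous-baseline recoveries.  Records whose
    fit raises are excluded; the count is attached as ``df.attrs['n_failed']``.
    """
    grid = N.multitau_grid()
    rows = []
    n_failed = 0
    for idx, truth in enumerate(truths):
        rng = np.random.default_rng([seed, idx])
        fd, ds, dl = simulate_record(
            truth, rng, integration_time=integration_time,
            instrument=instrument, tau_grid=grid, noiseless=noiseless,
        )
        cfg = F.FitConfig(
            thickness=truth.thickness, radius=truth.radius,
            refractive_index=truth.refractive_index,
            beta_short=instrument.beta, beta_long=instrument.beta,
        )
        row = {
            "mu_a1_act": truth.layer1.mu_a, "mu_a2_act": truth.layer2.mu_a,
            "mu_s1_act": truth.layer1.mu_s_prime,
            "mu_s2_act": truth.layer2.mu_s_prime,
            "F1_act": truth.layer1.flow_index, "F2_act": truth.layer2.flow_index,
            "thickness": truth.thickness, "T": integration_time,
        }
        try:
            hyb = F.fit_hybrid_2L(fd, ds, dl, cfg)
            row.update(
                mu_a1=hyb.mu_a1, mu_a2=hyb.mu_a2, mu_s_prime=hyb.mu_s_prime,
                F1=hyb.F1, F2=hyb.F2,
            )
            if si_baseline:
                si = F.fit_si_baseline(fd, dl, cfg)
                row.update(
                    mu_a_SI=si.mu_a_SI, mu_s_prime_SI=si.mu_s_prime_SI,
                    F_SI=si.F_SI,
                )
        except (F.FitError, M.SeriesConvergenceError):
            n_failed += 1
            continue
        rows.append(row)
        if progress and (idx + 1) % 50 == 0:
            print(f"  {idx + 1}/{len(truths)} records done")
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = n_failed
    return df


# (recovered column, actual column) per reported parameter; the SI-model
# recoveries are judged against the deep-layer truth, as in the primary
# comparison.
_METRIC_PAIRS = {
    "mu_a1": ("mu_a1", "mu_a1_act"),
    "mu_a2": ("mu_a2", "mu_a2_act"),
    "mu_s_prime": ("mu_s_prime", "mu_s2_act"),
    "F1": ("F1", "F1_act"),
    "F2": ("F2", "F2_act"),
    "mu_a_SI": ("mu_a_SI", "mu_a2_act"),
    "mu_s_prime_SI": ("mu_s_prime_SI", "mu_s2_act"),
    "F_SI": ("F_SI", "F2_act"),
}

_FLOW_SCALE = 1e-8  # flows regressed in units of 1e-8 cm^2/s


def summarize_records(df: pd.DataFrame) -> MetricsSummary:
    """Reduce a tidy record table to the headline accuracy metrics."""
    mape, iqr, reg = {}, {}, {}
    for name, (rec_col, act_col) in _METRIC_PAIRS.items():
        if rec_col not in df.columns:
            continue
        m, q = mape_iqr(df[rec_col], df[act_col])
        mape[name], iqr[name] = m, q
    for name, rec_col, act_col, scale in (
        ("mu_a2", "mu_a2", "mu_a2_act", 1.0),
        ("F2", "F2", "F2_act", _FLOW_SCALE),
        ("mu_a_SI", "mu_a_SI", "mu_a2_act", 1.0),
        ("F_SI", "F_SI", "F2_act", _FLOW_SCALE),
    ):
        if rec_col in df.columns and len(df) >= 3:
            reg[name] = recovery_regression(df[rec_col] / scale, df[act_col] / scale)
    wilc = {}
    for name, (col_2l, col_si) in (
        ("mu_a2_vs_SI", ("mu_a2", "mu_a_SI")),
        ("F2_vs_SI", ("F2", "F_SI")),
    ):
        if col_si in df.columns:
            act = df[_METRIC_PAIRS[col_2l][1]] if col_2l != "F2" else df["F2_act"]
            ape_2l = np.abs((act - df[col_2l]) / act)
            ape_si = np.abs((act - df[col_si]) / act)
            wilc[name] = float(stats.wilcoxon(ape_2l, ape_si).pvalue)
    return MetricsSummary(
        mape=mape, iqr=iqr, regression=reg, wilcoxon_p=wilc,
        n_records=len(df), n_failed=df.attrs.get("n_failed", 0),
    )


# ---------------------------------------------------------------------------
# perturbation studies
# ---------------------------------------------------------------------------


def _sample_with_ratio(rng, ranges, ratio_lo, ratio_hi, ell):
    """One truth whose scattering ratio mu_s2'/mu_s1' lies in a bin."""
    mua1 = rng.uniform(*ranges.mu_a_range)
    mua2 = rng.uniform(*ranges.mu_a_range)
    lo, hi = ranges.mu_s_range
    while True:
        mus1 = rng.uniform(lo, hi)
        mus2 = mus1 * rng.uniform(ratio_lo, ratio_hi)
        if lo <= mus2 <= hi:
            break
    return M.TwoLayerMedium(
        M.TissueLayer(mua1, mus1, rng.uniform(*ranges.F1_range)),
        M.TissueLayer(mua2, mus2, rng.uniform(*ranges.F2_range)),
        thickness=ell, radius=DEFAULT_INSTRUMENT.radius,
        refractive_index=DEFAULT_INSTRUMENT.refractive_index,
    )


def _signed_errors(df: pd.DataFrame) -> pd.DataFrame:
    """Signed percent errors 100 (actual - recovered) / actual."""
    out = pd.DataFrame(index=df.index)
    for name, (rec, act) in _METRIC_PAIRS.items():
        if rec in df.columns:
            out[name] = 100.0 * (df[act] - df[rec]) / df[act]
    return out


def run_perturbation_study(
    kind: str,
    *,
    seed: int = 0,
    n_per_bin: int = 30,
    integration_time: float = 10.0,
    ranges: SamplingRanges = SamplingRanges(),
    instrument: Instrument = DEFAULT_INSTRUMENT,
    ratio_bins: Sequence[float] | None = None,
    thicknesses: Sequence[float] = (1.2,),
    delta_ell_grid: Sequence[float] = (-0.2, -0.1, 0.0, 0.1, 0.2),
    mu_a2_grid: Sequence[float] | None = None,
    noiseless: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """One of the three secondary error studies.

    ``scattering_mismatch``
        signed errors binned by the actual scattering ratio
        mu_s2'/mu_s1' (default 20 bins over [0.8, 1.2]);
    ``thickness_mismatch``
        signed errors vs the thickness error delta_ell used in the fit;
    ``homogeneous_optics``
        deep-flow recovery when all optics are forced to the
        homogeneous-SI values, vs the actual deep absorption.

    Returns one row per (grid point, record) with the signed errors; use
    groupby on ``bin`` for medians and IQRs.
    """
    rng_root = np.random.default_rng(seed)
    grid_ = N.multitau_grid()
    rows = []

    def _one(truth, cfg, rng, forced_optics=None):
        fd, ds, dl = simulate_record(
            truth, rng, integration_time=integration_time,
            instrument=instrument, tau_grid=grid_, noiseless=noiseless,
        )
        if forced_optics is None:
            return F.fit_hybrid_2L(fd, ds, dl, cfg)
        # homogeneous-optics variant: optics fixed from the SI fit
        si_fd = F.fit_fddos_si(
            fd.restricted(min(cfg.si_distances) - 1e-9, max(cfg.si_distances) + 1e-9),
            cfg,
        )
        mua, mus = si_fd.mu_a_SI, si_fd.mu_s_prime_SI
        f1 = F.fit_dcs_si(ds, mua, mus, cfg.beta_short, cfg,
                          g2_floor=cfg.g2_floor_2L)
        f2 = F.fit_dcs_2L(dl, mua, mua, mus, f1.flow_index, cfg)
        return F.TwoLayerFitResult(
            mu_a1=mua, mu_a2=mua, mu_s_prime=mus,
            F1=f1.flow_index, F2=f2.flow_index,
        )

    if kind == "scattering_mismatch":
        edges = np.asarray(
            ratio_bins if ratio_bins is not None else np.linspace(0.8, 1.2, 21)
        )
        for ell in thicknesses:
            for b in range(len(edges) - 1):
                for j in range(n_per_bin):
                    rng = np.random.default_rng([seed, int(ell * 10), b, j])
                    truth = _sample_with_ratio(rng, ranges, edges[b], edges[b + 1], ell)
                    cfg = F.FitConfig(thickness=ell, radius=truth.radius)
                    try:
                        res = _one(truth, cfg, rng)
                    except (F.FitError, M.SeriesConvergenceError):
                        continue
                    rows.append({
                        "bin": 0.5 * (edges[b] + edges[b + 1]),
                        "thickness": ell,
                        "ratio_act": truth.layer2.mu_s_prime / truth.layer1.mu_s_prime,
                        "mu_a2_err": 100 * (truth.layer2.mu_a - res.mu_a2) / truth.layer2.mu_a,
                        "F2_err": 100 * (truth.layer2.flow_index - res.F2) / truth.layer2.flow_index,
                    })
            if progress:
                print(f"  scattering bins done for thickness {ell}")
    elif kind == "thickness_mismatch":
        truths = sample_forward_dataset(ranges, seed=rng_root.integers(2**31),
                                        combos_per_thickness=n_per_bin)
        truths = [t for t in truths if abs(t.thickness - thicknesses[0]) < 1e-12]
        for dl_ in delta_ell_grid:
            for j, truth in enumerate(truths):
                rng = np.random.default_rng([seed, 1000 + j])
                cfg = F.FitConfig(thickness=truth.thickness + dl_, radius=truth.radius)
                try:
                    res = _one(truth, cfg, rng)
                except (F.FitError, M.SeriesConvergenceError):
                    continue
                rows.append({
                    "bin": dl_, "thickness": truth.thickness,
                    "mu_a2_err": 100 * (truth.layer2.mu_a - res.mu_a2) / truth.layer2.mu_a,
                    "F2_err": 100 * (truth.layer2.flow_index - res.F2) / truth.layer2.flow_index,
                })
    elif kind == "homogeneous_optics":
        grid_mu = np.asarray(
            mu_a2_grid if mu_a2_grid is not None else np.linspace(0.08, 0.18, 6)
        )
        for mua2 in grid_mu:
            for j in range(n_per_bin):
                rng = np.random.default_rng([seed, int(round(mua2 * 1000)), j])
                truth = M.TwoLayerMedium(
                    M.TissueLayer(0.1, 10.0, 1e-8),
                    M.TissueLayer(float(mua2), 10.0, 6e-8),
                    thickness=thicknesses[0],
                    radius=instrument.radius,
                    refractive_index=instrument.refractive_index,
                )
                cfg = F.FitConfig(thickness=truth.thickness, radius=truth.radius)
                try:
                    res_h = _one(truth, cfg, rng, forced_optics="SI")
                    rng2 = np.random.default_rng([seed, int(round(mua2 * 1000)), j])
                    res_2l = _one(truth, cfg, rng2)
                except (F.FitError, M.SeriesConvergenceError):
                    continue
                rows.append({
                    "bin": float(mua2),
                    "F2_homog": res_h.F2, "F2_2L": res_2l.F2,
                    "F2_act": truth.layer2.flow_index,
                    "F2_err": 100 * (truth.layer2.flow_index - res_h.F2) / truth.layer2.flow_index,
                    "mu_a2_err": 100 * (truth.layer2.mu_a - res_2l.mu_a2) / truth.layer2.mu_a,
                })
    else:
        raise ValueError(f"unknown perturbation study kind {kind!r}")
    return pd.DataFrame(rows)
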