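# layerflow

Two-layer head-model analysis for hybrid frequency-domain diffuse optical
spectroscopy (FD-DOS) and diffuse correlation spectroscopy (DCS)
measurements of the adult head.

## The problem

Optical measurements of cerebral blood flow (DCS) and tissue absorption
(FD-DOS) made from the scalp are contaminated by the extracerebral tissues
the light must cross twice.  The conventional analysis treats the head as a
homogeneous semi-infinite (SI) medium and, in adults, can mis-assign most of
the "cerebral" flow signal to the scalp and skull.  `layerflow` implements a
constrained two-layer (2L) alternative: the head is a cylinder of radius *a*
with a superficial layer of thickness *ℓ* (scalp + skull; properties μa,1,
μs,1′, F1) over an infinitely deep cerebral layer (μa,2, μs,2′, F2), with
common refractive index *n* and homogeneous reduced scattering
(μs,1′ = μs,2′ = μs′) assumed during fitting.

## The model and the algorithm

Photon transport is described by the frequency-domain photon diffusion
equation (∇² − K₀²)Φ = −S with K₀² = (vμa + iω)/D, and speckle dynamics by
the correlation diffusion equation, identical in form with
K²(τ) = (vμa + 2vμs′k₀²Fτ)/D.  For the 2L cylinder the Green's function is
a Bessel series over the positive roots sₙ of J₀(a′s) = 0 on the effective
radius a′ = a + z_b (extrapolated-zero boundary), with per-layer wavenumbers

    α_k² = vμa,k/D_k + sₙ² + iω/D_k          (FD-DOS)
    α_k² = vμa,k/D_k + sₙ² + 2vμs,k′k₀²F_kτ/D_k   (DCS)

The measured quantities are the Fick's-law surface reflectance amplitude
AC = |R| and phase θ = −arg R, and the intensity autocorrelation
g₂ = 1 + β|g₁|² (Siegert relation).

The inversion is sequential and constrained, assuming *ℓ* known a priori:

1. **FD-DOS stage** — fit multidistance AC and θ (log-amplitude ratios and
   phase differences relative to the shortest distance) to the 2L model for
   (μa,1, μa,2, μs′);
2. **short-separation DCS stage** — fit g₂ at ρ ≈ 0.8 cm with the SI
   correlation model for F1, using the stage-1 optics;
3. **long-separation DCS stage** — fit g₂ at ρ ≈ 2.5 cm with the 2L
   correlation model for F2, all other parameters fixed.

A homogeneous-SI baseline (long distances only, g₂ ≥ 1.25) is provided for
comparison, along with an instrument-noise simulator (amplitude SNR, phase
σ in degrees, Koppel-type correlation noise on a multi-tau delay grid) and
a study harness that quantifies recovery accuracy over randomized
adult-head tissue properties.

## Worked example

```python
import numpy as np
from layerflow import (
    TissueLayer, TwoLayerMedium, FitConfig,
    fit_hybrid_2L, fit_si_baseline,
)
from layerflow.study import simulate_record

# ground truth: scalp/skull layer over cortex
truth = TwoLayerMedium(
    layer1=TissueLayer(mu_a=0.10, mu_s_prime=10.0, flow_index=1e-8),
    layer2=TissueLayer(mu_a=0.15, mu_s_prime=10.0, flow_index=6e-8),
    thickness=1.2, radius=30.0, refractive_index=1.4,
)

# one noisy hybrid measurement (amplitude SNR 100, phase sigma 0.1 deg,
# DCS count rates 200/40 kHz, T = 10 s)
rng = np.random.default_rng(7)
fd, dcs_short, dcs_long = simulate_record(truth, rng, integration_time=10.0)

cfg = FitConfig(thickness=1.2)            # a-priori layer thickness
res = fit_hybrid_2L(fd, dcs_short, dcs_long, cfg)
si = fit_si_baseline(fd, dcs_long, cfg)

print(f"two-layer: mu_a1={res.mu_a1:.3f}  mu_a2={res.mu_a2:.3f}  "
      f"mu_s'={res.mu_s_prime:.2f} 1/cm")
print(f"           F1={res.F1:.2e}  F2={res.F2:.2e} cm^2/s")
print(f"homogeneous baseline: mu_a_SI={si.mu_a_SI:.3f} 1/cm  "
      f"F_SI={si.F_SI:.2e} cm^2/s")
```

prints

```
two-layer: mu_a1=0.104  mu_a2=0.136  mu_s'=9.89 1/cm
           F1=1.03e-08  F2=5.89e-08 cm^2/s
homogeneous baseline: mu_a_SI=0.120 1/cm  F_SI=1.43e-08 cm^2/s
```

The layered fit recovers the cerebral absorption (0.136 vs 0.15 1/cm under
this noise draw) and cerebral flow index (5.9e-8 vs 6e-8 cm²/s); the
homogeneous baseline collapses the cerebral flow toward the scalp value
(1.4e-8 — a four-fold underestimate) and reads an absorption between the
two layers.

## Command line

```bash
layerflow simulate --out-dir data/           # noiseless + noisy CSV tables
layerflow fit --fd data/fddos_noisy.csv \
    --dcs-short data/dcs_short_noisy.csv \
    --dcs-long data/dcs_long_noisy.csv       # three-stage fit + SI baseline
layerflow sensitivity --out sens.csv         # d logAC / dθ derivative curves
layerflow study --scale ci --out-dir study/  # accuracy table, reduced scale
```

FD-DOS tables are CSV with columns `rho_cm,amplitude,phase_deg` (one file
per measurement, phases in degrees on disk); DCS tables have
`tau_s,g2` (one file per source–detector distance).  Both carry a
`# meta: {...}` JSON header line with instrument metadata, the seed and the
config hash.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the forward-model accuracy batch (600 randomized
truths — 150 per superficial-layer thickness in {1.0, 1.2, 1.4, 1.6} cm —
with instrument noise at T = 10 s, inverted by both the layered scheme and
the SI baseline; median absolute percent errors and the F2 regression
slope), the deterministic amplitude/phase sensitivity ratios of cerebral
vs superficial reduced scattering at ρ = 4 cm, and the median signed
recovery errors in the bin where the true cerebral-to-superficial
scattering ratio is 0.8 at ℓ = 1.2 cm.  Runtime is a few minutes on one
CPU; results are written as JSON keyed by target id.
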