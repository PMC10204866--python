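"""Analytical photon-diffusion and correlation-diffusion forward models.

This module implements the Green's-function solutions used throughout the
package:

* a homogeneous semi-infinite (SI) half-space, solved with the method of
  images under the extrapolated-zero boundary condition, for both
  frequency-domain (FD-DOS) photon diffusion and continuous-wave DCS
  correlation diffusion;
* a two-layer (2L) cylinder -- a superficial (extracerebral) layer of
  thickness ``l`` on top of an infinitely deep (cerebral) layer -- solved as
  a Bessel series over the positive roots of ``J0`` on the effective radius
  ``a' = a + zb``.

The layered kernel is evaluated with exponent-scaled hyperbolic terms so
that every exponential carries a negative real argument; the series is then
numerically stable up to arbitrarily large root index.

Units are CGS throughout: lengths in cm, optical coefficients in 1/cm, flow
indices in cm^2/s, delay times in s, modulation frequency in Hz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "C_LIGHT_CM_S",
    "TissueLayer",
    "TwoLayerMedium",
    "SemiInfiniteMedium",
    "SourceSpec",
    "BesselBasis",
    "SeriesConvergenceError",
    "effective_reflection",
    "extrapolation_length",
    "si_green_fd",
    "si_reflectance_fd",
    "si_g1",
    "bessel_basis",
    "layer_wavenumber",
    "reflectance_2L",
    "fd_amp_phase_2L",
    "g1_2L",
    "siegert",
]

#: speed of light in vacuum (cm/s)
C_LIGHT_CM_S = 2.998e10

# Adaptive series truncation: stop once this many consecutive terms each
# contribute less than SERIES_RTOL relative to the running sum.
SERIES_CONSECUTIVE = 50
SERIES_RTOL = 1e-8
SERIES_MAX_ROOTS = 10_000
_SERIES_BLOCK = 512


class SeriesConvergenceError(RuntimeError):
    """Raised when the Bessel series fails to satisfy the truncation rule."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueLayer:
    """Optical and dynamic properties of one homogeneous tissue layer.

    Parameters
    ----------
    mu_a:
        Absorption coefficient (1/cm).
    mu_s_prime:
        Reduced scattering coefficient (1/cm).
    flow_index:
        DCS blood-flow index ``F`` (cm^2/s); may be ``None`` for
        FD-DOS-only use.
    """

    mu_a: float
    mu_s_prime: float
    flow_index: float | None = None

    def __post_init__(self) -> None:
        if not self.mu_a > 0:
            raise ValueError(f"mu_a must be positive, got {self.mu_a}")
        if not self.mu_s_prime > 0:
            raise ValueError(f"mu_s_prime must be positive, got {self.mu_s_prime}")
        if self.flow_index is not None and self.flow_index < 0:
            raise ValueError(f"flow_index must be >= 0, got {self.flow_index}")


@dataclass(frozen=True)
class TwoLayerMedium:
    """Two-layer cylinder: superficial layer 1 of thickness ``l`` over an
    infinitely deep layer 2, radius ``a``, common refractive index ``n``."""

    layer1: TissueLayer
    layer2: TissueLayer
    thickness: float
    radius: float
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("thickness must be positive")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")

    def check_radius(self, distances: Sequence[float]) -> None:
        """Warn when the cylinder border could influence the probed field."""
        if self.radius < 2.0 * max(distances):
            warnings.warn(
                f"cylinder radius {self.radius} cm is less than twice the "
                f"largest source-detector distance {max(distances)} cm; the "
                "border may affect the solution",
                stacklevel=3,
            )


@dataclass(frozen=True)
class SemiInfiniteMedium:
    """Homogeneous half-space used by the conventional SI analysis."""

    layer: TissueLayer
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")


@dataclass(frozen=True)
class SourceSpec:
    """Source description: FD mode needs ``modulation_frequency`` (Hz);
    DCS mode needs ``wavelength`` (cm)."""

    mode: str
    modulation_frequency: float | None = None
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("FD", "DCS"):
            raise ValueError(f"mode must be 'FD' or 'DCS', got {self.mode!r}")
        if self.mode == "FD":
            if self.modulation_frequency is None or self.modulation_frequency <= 0:
                raise ValueError("FD mode requires modulation_frequency > 0")
        else:
            if self.wavelength is None or self.wavelength <= 0:
                raise ValueError("DCS mode requires wavelength > 0 (cm)")

    @property
    def omega(self) -> float:
        """Angular modulation frequency (rad/s); 0 in DCS (CW) mode."""
        if self.mode == "FD":
            return 2.0 * math.pi * self.modulation_frequency
        return 0.0

    @property
    def k0(self) -> float:
        """Optical wavenumber 2*pi/lambda (1/cm); only defined in DCS mode."""
        if self.wavelength is None:
            raise ValueError("k0 requires a wavelength")
        return 2.0 * math.pi / self.wavelength


@dataclass(frozen=True)
class BesselBasis:
    """Cached roots of ``J0(a's) = 0`` and the Bessel factors entering the
    layered series, shared across forward evaluations with the same
    effective radius and detector set.

    The basis is immutable; within a fit only the layer wavenumbers change
    between optimizer iterations, so the basis is built once per
    ``(a', distances, n_roots)`` and reused.
    """

    effective_radius: float
    roots: np.ndarray          # (n_roots,)  s_n, strictly increasing (1/cm)
    j0_factors: np.ndarray     # (n_dist, n_roots)  J0(s_n * rho_i)
    j1_factors: np.ndarray     # (n_roots,)  J1(a' * s_n)
    distances: tuple = field(default_factory=tuple)

    @property
    def n_roots(self) -> int:
        return self.roots.size


# ---------------------------------------------------------------------------
# boundary condition
# ---------------------------------------------------------------------------


def effective_reflection(n: float) -> float:
    """Effective internal diffuse-reflection fraction ``Reff``.

    Polynomial approximation ``Reff = -1.440 n^-2 + 0.710 n^-1 + 0.668 +
    0.0636 n`` in the relative refractive index ``n`` (tissue over
    surrounding medium).
    """
    if n < 1:
        raise ValueError(f"refractive index ratio must be >= 1, got {n}")
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def extrapolation_length(mu_a: float, mu_s_prime: float, n: float) -> float:
    """Extrapolated-boundary distance ``zb`` (cm).

    ``zb = (2/3) (mu_a + mu_s')^-1 (1 + Reff) / (1 - Reff)`` places the
    virtual zero-fluence plane a distance ``zb`` above the physical surface.
    """
    if mu_a <= 0 or mu_s_prime <= 0:
        raise ValueError("mu_a and mu_s_prime must be positive")
    reff = effective_reflection(n)
    return (2.0 / 3.0) / (mu_a + mu_s_prime) * (1.0 + reff) / (1.0 - reff)


def _derived(layer: TissueLayer, n: float):
    """Return (v, D, z0, zb) for a layer with refractive index n."""
    v = C_LIGHT_CM_S / n
    D = v / (3.0 * (layer.mu_a + layer.mu_s_prime))
    z0 = 1.0 / (layer.mu_a + layer.mu_s_prime)
    zb = extrapolation_length(layer.mu_a, layer.mu_s_prime, n)
    return v, D, z0, zb


# ---------------------------------------------------------------------------
# semi-infinite solutions
# ---------------------------------------------------------------------------


def _si_k(medium: SemiInfiniteMedium, omega: float = 0.0, gamma: float = 0.0):
    """Complex SI wavenumber: K^2 = (v mu_a + gamma + i omega) / D, where
    ``gamma = 2 v mu_s' k0^2 F tau`` in DCS mode and 0 in FD mode."""
    lay = medium.layer
    v, D, _, _ = _derived(lay, medium.refractive_index)
    return np.sqrt((v * lay.mu_a + gamma + 1j * omega) / D)


def si_green_fd(medium: SemiInfiniteMedium, source: SourceSpec, rho: float) -> complex:
    """Frequency-domain fluence of a point source in a half-space.

    ``Phi = v/(4 pi D) [exp(-K r1)/r1 - exp(-K r2)/r2]`` with the real
    source buried at depth ``z0`` and its negative image at ``-z0 - 2 zb``.
    """
    if rho <= 0:
        raise ValueError("rho must be positive (source singularity at rho=0)")
    lay = medium.layer
    v, D, z0, zb = _derived(lay, medium.refractive_index)
    K = _si_k(medium, omega=source.omega)
    r1 = math.hypot(z0, rho)
    r2 = math.hypot(z0 + 2 * zb, rho)
    return v / (4 * math.pi * D) * (np.exp(-K * r1) / r1 - np.exp(-K * r2) / r2)


def _si_reflectance(medium: SemiInfiniteMedium, rho, K):
    """Fick's-law reflectance ``R = D dPhi/dz`` at z=0 for wavenumber K."""
    lay = medium.layer
    v, D, z0, zb = _derived(lay, medium.refractive_index)
    rho = np.asarray(rho, dtype=float)
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt((z0 + 2 * zb) ** 2 + rho**2)
    return v / (4 * math.pi) * (
        z0 * (1 + K * r1) * np.exp(-K * r1) / r1**3
        + (z0 + 2 * zb) * (1 + K * r2) * np.exp(-K * r2) / r2**3
    )


def si_reflectance_fd(medium: SemiInfiniteMedium, source: SourceSpec, rho):
    """Complex FD reflectance of the half-space (Fick's law at the surface)."""
    if np.any(np.asarray(rho) <= 0):
        raise ValueError("rho must be positive")
    return _si_reflectance(medium, rho, _si_k(medium, omega=source.omega))


def si_g1(
    medium: SemiInfiniteMedium,
    source: SourceSpec,
    rho: float,
    tau_grid: Sequence[float],
) -> np.ndarray:
    """Normalized field autocorrelation ``g1(tau)`` of the half-space.

    The correlation-diffusion solution has the CW form of the FD solution
    with ``K(tau)^2 = (v mu_a + 2 v mu_s' k0^2 F tau)/D``; ``g1`` is the
    ratio of the surface (Fick's-law) reflectance at ``K(tau)`` to its
    ``tau = 0`` value, the same observable as the layered model.
    """
    taus = np.asarray(tau_grid, dtype=float)
    if np.any(taus < 0):
        raise ValueError("delay times must be >= 0")
    lay = medium.layer
    if lay.flow_index is None:
        raise ValueError("medium layer needs a flow_index for DCS")
    v, D, _, _ = _derived(lay, medium.refractive_index)
    gamma = 2.0 * v * lay.mu_s_prime * source.k0**2 * lay.flow_index * taus
    K = np.sqrt((v * lay.mu_a + gamma) / D)
    K0 = math.sqrt(v * lay.mu_a / D)
    return np.real(
        _si_reflectance(medium, rho, K) / _si_reflectance(medium, rho, K0)
    )


# ---------------------------------------------------------------------------
# two-layer cylinder
# ---------------------------------------------------------------------------

_J0_ZEROS_CACHE: dict[int, np.ndarray] = {}


def _j0_zeros(n: int) -> np.ndarray:
    """Positive zeros of J0, cached and grown geometrically."""
    have = max(_J0_ZEROS_CACHE, default=0)
    if n > have:
        grow = max(n, 2 * have, 2048)
        _J0_ZEROS_CACHE.clear()
        _J0_ZEROS_CACHE[grow] = special.jn_zeros(0, grow)
    key = max(_J0_ZEROS_CACHE)
    return _J0_ZEROS_CACHE[key][:n]


_BASIS_CACHE: dict[tuple, BesselBasis] = {}
_BASIS_CACHE_MAX = 16


def bessel_basis(
    a_prime: float, distances: Sequence[float], n_roots: int
) -> BesselBasis:
    """Build (or fetch from cache) the Bessel basis for effective radius
    ``a'`` and a fixed set of source-detector distances.

    ``s_n`` are the positive roots of ``J0(a' s) = 0``; the basis caches
    ``J0(s_n rho_i)`` and ``J1(a' s_n)`` which are the only
    geometry-dependent factors of the layered series.
    """
    if a_prime <= 0:
        raise ValueError("a_prime must be positive")
    if n_roots < 1:
        raise ValueError("n_roots must be >= 1")
    distances = tuple(float(r) for r in distances)
    if any(r >= a_prime for r in distances):
        raise ValueError("all distances must be smaller than a_prime")
    key = (round(a_prime, 12), distances, n_roots)
    basis = _BASIS_CACHE.get(key)
    if basis is not None:
        return basis
    roots = _j0_zeros(n_roots) / a_prime
    j1 = special.j1(a_prime * roots)
    j0 = special.j0(np.outer(np.asarray(distances), roots))
    basis = BesselBasis(
        effective_radius=a_prime,
        roots=roots,
        j0_factors=j0,
        j1_factors=j1,
        distances=distances,
    )
    if len(_BASIS_CACHE) >= _BASIS_CACHE_MAX:
        _BASIS_CACHE.pop(next(iter(_BASIS_CACHE)))
    _BASIS_CACHE[key] = basis
    return basis


def layer_wavenumber(
    layer: TissueLayer,
    s_n,
    *,
    mode: str,
    omega: float = 0.0,
    tau=0.0,
    k0: float = 0.0,
    refractive_index: float = 1.4,
):
    """Per-layer wavenumber ``alpha_k`` of the layered solution.

    FD mode:  ``alpha^2 = v mu_a / D + s_n^2 + i omega / D``
    DCS mode: ``alpha^2 = v mu_a / D + s_n^2 + 2 v mu_s' k0^2 F tau / D``
    """
    v, D, _, _ = _derived(layer, refractive_index)
    s2 = np.asarray(s_n, dtype=float) ** 2
    if mode == "FD":
        return np.sqrt(v * layer.mu_a / D + s2 + 1j * omega / D)
    if mode == "DCS":
        if layer.flow_index is None:
            raise ValueError("DCS mode requires the layer's flow_index")
        gamma = 2.0 * v * layer.mu_s_prime * k0**2 * layer.flow_index * np.asarray(tau)
        return np.sqrt(v * layer.mu_a / D + s2 + gamma / D)
    raise ValueError(f"unknown mode {mode!r}")


def _kernel_2l(medium: TwoLayerMedium, a1, a2, D1: float, D2: float, z0: float, zb: float):
    """Bessel-domain surface reflectance of the 2L medium for given layer
    wavenumbers ``a1``, ``a2`` (broadcastable arrays).

    Exponent-scaled form of ``D1 dG1/dz`` at ``z = 0``: the first part is
    the homogeneous image-source pair, the second the layer-interface
    correction proportional to ``D1 a1 - D2 a2``; every exponential has a
    non-positive real argument.
    """
    ell = medium.thickness
    E = np.exp(-2.0 * a1 * (ell + zb))
    den = D1 * a1 * (1.0 + E) + D2 * a2 * (1.0 - E)
    homog = 0.5 * (np.exp(-a1 * z0) + np.exp(-a1 * (z0 + 2 * zb)))
    interface = (
        (D1 * a1 - D2 * a2)
        * np.exp(-a1 * (2 * ell - z0))
        * (1.0 - np.exp(-2.0 * a1 * (z0 + zb)))
        * (1.0 + np.exp(-2.0 * a1 * zb))
        / (2.0 * den)
    )
    return homog + interface


def _series_geometry(medium: TwoLayerMedium):
    v = C_LIGHT_CM_S / medium.refractive_index
    D1 = v / (3.0 * (medium.layer1.mu_a + medium.layer1.mu_s_prime))
    D2 = v / (3.0 * (medium.layer2.mu_a + medium.layer2.mu_s_prime))
    z0 = 1.0 / (medium.layer1.mu_a + medium.layer1.mu_s_prime)
    zb = extrapolation_length(
        medium.layer1.mu_a, medium.layer1.mu_s_prime, medium.refractive_index
    )
    return v, D1, D2, z0, zb


def _sum_series(medium, source, distances, basis, *, gamma2_1=None, gamma2_2=None):
    """Evaluate the layered reflectance series at every distance.

    ``gamma2_k`` are the per-layer additive terms of ``alpha_k^2`` beyond
    ``v mu_a / D + s^2``: ``i omega / D`` in FD mode, or an array
    ``2 v mu_s' k0^2 F tau / D`` over the delay grid in DCS mode.

    Returns an array of shape ``(n_dist,)`` (FD) or ``(n_dist, n_tau)``
    (DCS).  Truncation follows the running-sum rule: accumulation stops
    once ``SERIES_CONSECUTIVE`` successive terms each contribute less than
    ``SERIES_RTOL`` of the running sum (monitored on the slowest-decaying
    component, tau = 0 / the FD term itself).
    """
    v, D1, D2, z0, zb = _series_geometry(medium)
    m1, m2 = medium.layer1, medium.layer2
    base1 = v * m1.mu_a / D1
    base2 = v * m2.mu_a / D2

    tau_like = np.ndim(gamma2_1) > 0
    if tau_like:
        g1_ = np.asarray(gamma2_1)[None, :]
        g2_ = np.asarray(gamma2_2)[None, :]
        out = np.zeros((len(distances), g1_.shape[1]))
    else:
        g1_ = gamma2_1
        g2_ = gamma2_2
        out = np.zeros(len(distances), dtype=complex)

    running = np.zeros(len(distances))
    n_small = np.zeros(len(distances), dtype=int)
    converged = False
    n = basis.n_roots
    for start in range(0, n, _SERIES_BLOCK):
        stop = min(start + _SERIES_BLOCK, n)
        s = basis.roots[start:stop]
        s2 = s**2
        if tau_like:
            a1 = np.sqrt(base1 + s2[:, None] + g1_)
            a2 = np.sqrt(base2 + s2[:, None] + g2_)
        else:
            a1 = np.sqrt(base1 + s2 + (g1_ if g1_ is not None else 0.0))
            a2 = np.sqrt(base2 + s2 + (g2_ if g2_ is not None else 0.0))
        kern = _kernel_2l(medium, a1, a2, D1, D2, z0, zb)
        weight = basis.j0_factors[:, start:stop] / basis.j1_factors[start:stop] ** 2
        if tau_like:
            out += weight @ kern  # (n_dist, n_tau)
            monitor = np.abs(weight * kern[:, 0][None, :])  # tau = 0 column
        else:
            contrib = weight * kern[None, :]
            out += contrib.sum(axis=1)
            monitor = np.abs(contrib)
        # convergence bookkeeping on per-term contributions
        ref = np.abs(out[:, 0]) if tau_like else np.abs(out)
        running = np.maximum(running, ref)
        small = monitor < SERIES_RTOL * np.maximum(running, 1e-300)[:, None]
        for i in range(len(distances)):
            row = small[i]
            if row.all():
                n_small[i] += row.size
            else:
                last_big = np.max(np.nonzero(~row)[0])
                n_small[i] = row.size - 1 - last_big
        if np.all(n_small >= SERIES_CONSECUTIVE):
            converged = True
            break
    if not converged:
        raise SeriesConvergenceError(
            f"layered Bessel series not converged with {n} roots "
            f"(a'={basis.effective_radius:.3f} cm, "
            f"trailing small-term counts {n_small.tolist()}); "
            "increase the basis size"
        )
    # v matches the point-source normalization of the SI closed form
    return v * out / (math.pi * basis.effective_radius**2)


# Largest Bessel-domain frequency kept by a default basis (1/cm); chosen so
# that exp(-s_max * z0) is far below SERIES_RTOL for any in-bounds optics.
_S_TARGET = 650.0


def _basis_for(medium: TwoLayerMedium, distances, n_roots: int | None) -> BesselBasis:
    _, _, _, _, zb = _series_geometry(medium)
    a_prime = medium.radius + zb
    if n_roots is None:
        n_roots = min(SERIES_MAX_ROOTS, int(math.ceil(_S_TARGET * a_prime / math.pi)))
    return bessel_basis(a_prime, distances, n_roots)


def reflectance_2L(
    medium: TwoLayerMedium,
    source: SourceSpec,
    rho,
    basis: BesselBasis | None = None,
    *,
    tau=None,
    n_roots: int | None = None,
):
    """Complex surface reflectance of the 2L cylinder.

    In FD mode the result is the complex reflectance at angular frequency
    ``omega``; in DCS mode ``tau`` (scalar or array) selects the delay
    time(s) and the result is real.

    ``basis`` may be passed explicitly for reuse; it must have been built
    with this medium's effective radius.
    """
    distances = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(distances <= 0):
        raise ValueError("rho must be positive")
    medium.check_radius(distances)
    if basis is None:
        basis = _basis_for(medium, distances, n_roots)
    else:
        _, _, _, _, zb = _series_geometry(medium)
        if abs(basis.effective_radius - (medium.radius + zb)) > 1e-9:
            raise ValueError(
                "basis effective radius does not match the medium; rebuild "
                "the basis for a' = radius + zb"
            )
        if tuple(distances) != basis.distances:
            raise ValueError("rho not in basis.distances; rebuild the basis")
    v, D1, D2, _, _ = _series_geometry(medium)
    m1, m2 = medium.layer1, medium.layer2
    if source.mode == "FD":
        om = source.omega
        res = _sum_series(
            medium, source, distances, basis,
            gamma2_1=1j * om / D1, gamma2_2=1j * om / D2,
        )
    else:
        if tau is None:
            raise ValueError("DCS mode requires tau")
        taus = np.atleast_1d(np.asarray(tau, dtype=float))
        if m1.flow_index is None or m2.flow_index is None:
            raise ValueError("DCS mode requires flow indices on both layers")
        k0 = source.k0
        g1_ = 2.0 * v * m1.mu_s_prime * k0**2 * m1.flow_index * taus / D1
        g2_ = 2.0 * v * m2.mu_s_prime * k0**2 * m2.flow_index * taus / D2
        res = _sum_series(medium, source, distances, basis, gamma2_1=g1_, gamma2_2=g2_)
        if np.ndim(tau) == 0:
            res = res[:, 0]
    if np.ndim(rho) == 0:
        return res[0]
    return res


def fd_amp_phase_2L(
    medium: TwoLayerMedium,
    source: SourceSpec,
    distances: Sequence[float],
    basis: BesselBasis | None = None,
    *,
    n_roots: int | None = None,
):
    """Theoretical FD-DOS amplitude and phase of the 2L cylinder.

    Returns ``(AC, theta)`` with ``AC = |R|`` and ``theta = -arg(R)`` in
    radians, unwrapped along increasing distance.
    """
    R = reflectance_2L(medium, source, np.asarray(distances, float), basis, n_roots=n_roots)
    ac = np.abs(R)
    theta = np.unwrap(-np.angle(R))
    return ac, theta


def g1_2L(
    medium: TwoLayerMedium,
    source: SourceSpec,
    rho: float,
    tau_grid: Sequence[float],
    basis: BesselBasis | None = None,
    *,
    n_roots: int | None = None,
) -> np.ndarray:
    """Normalized field autocorrelation ``g1(tau)`` of the 2L cylinder.

    The numerator is the correlation-diffusion reflectance at each delay,
    the denominator its ``tau = 0`` (CW) value -- the identical code path,
    so ``g1(0) = 1`` exactly.
    """
    taus = np.asarray(tau_grid, dtype=float)
    if np.any(taus < 0):
        raise ValueError("delay times must be >= 0")
    with_zero = np.concatenate(([0.0], taus))
    G = reflectance_2L(medium, source, rho, basis, tau=with_zero, n_roots=n_roots)
    return np.real(G[1:] / G[0])


def siegert(g1_values, beta: float):
    """Siegert relation ``g2 = 1 + beta * g1^2``."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    g1 = np.asarray(g1_values, dtype=float)
    return 1.0 + beta * g1**2
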