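"""Closed-form photon budget and performance limits for mass photometry.

The detection limit and mass resolution of an interferometric mass
measurement are set by how many scattered photons a molecule of mass ``m``
delivers to the peak pixel of its point-spread function, relative to the
shot noise of the attenuated reference light.  This module evaluates that
budget analytically:

* ``scattered_photons`` / ``reflected_photons`` — detected photons per pixel
  and exposure, from the illumination fluence, the Rayleigh scattering
  cross-section of the molecule (mass-proportional polarizability
  ``alpha = delta_alpha * m``), the collection efficiency ``mu``, the
  interface enhancement ``gamma``, and the back-focal-plane geometry.
* ``shot_noise_snr`` — the shot-noise-limited SNR of the ratiometric
  contrast, ``SNR = sqrt(2 * N_sca)``; the factor 2 is interferometric, the
  1/sqrt(2) comes from differencing two frame averages.
* ``detection_limit_mass`` — smallest mass with ``SNR = q``.
* ``qcrlb_resolution`` — quantum Cramér–Rao bound on the mass estimate,
  ``sigma_m = m / (sqrt(2) * SNR(m))``; equivalently the mass at which the
  ratiometric SNR equals 1/sqrt(2).
* ``snr_with_excess`` — adds a non-shot-noise background, expressed as the
  contrast of a mass-equivalent ``sigma_exc_kda`` protein, in quadrature.
* ``interface_enhancement`` — gamma from the emission pattern of an in-plane
  dipole at the glass-water interface (shared kernel with the imaging
  module), with a tabulated fallback.

All inputs are SI base units except masses (kDa) and polarizability slope
(Å^3/kDa), mirroring the way instrument budgets are usually quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import c as _c, h as _h
from scipy.optimize import brentq

from .scatterers import A3_TO_M3

__all__ = [
    "SnrParameters",
    "GAMMA_TABLE",
    "interface_enhancement",
    "collection_efficiency",
    "bfp_area",
    "derived_factors",
    "scattered_photons",
    "reflected_photons",
    "shot_noise_snr",
    "detection_limit_mass",
    "qcrlb_resolution",
    "snr_with_excess",
    "snr_simplified_constant",
    "performance_maps",
]

#: Interface enhancement factors for an oil-immersion objective (n_i = 1.515)
#: at a glass-water interface, usable instead of the numerical integration.
GAMMA_TABLE = {1.2: 1.14, 1.3: 1.21, 1.4: 1.53, 1.5: 1.67}


class IncompleteConfigError(ValueError):
    """A required budget parameter is missing or non-physical."""


@dataclass
class SnrParameters:
    """Every symbol of the analytic photon budget.

    Defaults are the worked-example values of a contrast-enhanced mass
    photometer: 1.42 NA oil objective, 2 % transmission mask, 445 nm.
    """

    illumination: float = 1.0e9      # I_illu [W/m^2]  (0.1 MW/cm^2)
    exposure: float = 0.1            # effective exposure per image Delta_t [s]
    wavelength: float = 445e-9       # lambda [m]
    optical_throughput: float = 0.8  # OT
    quantum_efficiency: float = 0.70 # QE
    reflectivity: float = 0.004      # |r|^2 of the glass-buffer interface
    mask_transmission: float = 0.02  # |tau|^2 of the BFP mask
    mu: float = 0.40                 # collection efficiency asin(NA/n_i)/pi
    gamma: float = 1.58              # interface scattering enhancement
    bfp_area: float = 50e-6          # A_BFP [m^2]
    f_obj: float = 3e-3              # objective focal length [m]
    pixel_size: float = 80e-9        # effective pixel size d_px [m]
    n_medium: float = 1.333
    n_immersion: float = 1.515
    n_glass: float = 1.515
    na: float = 1.42
    delta_alpha: float = 724.0       # polarizability slope [A^3/kDa]
    mass_kda: float = 66.0           # protein mass m [kDa]
    sigma_exc_kda: float = 0.0       # excess background, mass-equivalent [kDa]

    def __post_init__(self) -> None:
        for name in ("illumination", "exposure", "wavelength", "f_obj",
                     "pixel_size", "delta_alpha", "mass_kda", "bfp_area"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise IncompleteConfigError(f"parameter {name!r} must be positive, got {v}")
        for name in ("optical_throughput", "quantum_efficiency",
                     "reflectivity", "mask_transmission"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise IncompleteConfigError(f"parameter {name!r} must be in [0, 1], got {v}")
        if not 0.0 <= self.mu <= 0.5:
            raise IncompleteConfigError(f"mu must be in [0, 1/2], got {self.mu}")
        if self.sigma_exc_kda < 0:
            raise IncompleteConfigError("sigma_exc_kda must be >= 0")


def collection_efficiency(na: float, n_immersion: float) -> float:
    """mu = asin(min(NA/n_i, 1)) / pi; the NA > n_i case is clamped."""
    return float(np.arcsin(min(na / n_immersion, 1.0)) / np.pi)


def bfp_area(f_obj: float, n_immersion: float, n_medium: float, n_glass: float) -> float:
    """Accessible back-focal-plane area, limited by the critical angle:
    A_BFP = pi * f_obj^2 * (n_i * n_m / n_g)^2."""
    return float(np.pi * f_obj**2 * (n_immersion * n_medium / n_glass) ** 2)


def interface_dipole_weights(theta_glass: np.ndarray, n_glass: float,
                             n_medium: float, height: float = 0.0,
                             wavelength: float = 445e-9) -> np.ndarray:
    """Relative power per solid angle radiated into the glass by an in-plane
    dipole sitting ``height`` above the glass-water interface.

    Derived from the Weyl plane-wave expansion of the dipole field in the
    medium, Fresnel transmission of each (possibly evanescent) component into
    the glass, and stationary phase for the far field.  Supercritical angles
    (sin(theta_glass) > n_m/n_g) carry the near-field-coupled emission that
    makes the interface enhancement exceed one.  Normalized such that a free
    dipole in the medium has weight 1 in every direction (its in-plane
    azimuthal/orientation average radiates isotropically).
    """
    s1 = np.sin(theta_glass)
    c1 = np.cos(theta_glass)
    s2 = (n_glass / n_medium) * s1
    c2 = np.sqrt((1.0 - s2**2).astype(complex))
    c2 = np.where(c2.imag < 0, -c2, c2)
    ts = 2 * n_medium * c2 / (n_medium * c2 + n_glass * c1)
    tp = 2 * n_medium * c2 / (n_glass * c2 + n_medium * c1)
    k_m = 2 * np.pi * n_medium / wavelength
    decay = np.exp(1j * k_m * c2 * height)
    pref = n_glass * (n_glass / n_medium) ** 2 * c1**2 / np.abs(c2) ** 2
    w = pref * (np.abs(ts * decay) ** 2 + np.abs(tp * c2 * decay) ** 2) / 2.0
    return w / (n_medium * 2.0 / 3.0)


def interface_enhancement(na: float, n_immersion: float = 1.515,
                          n_medium: float = 1.333, *, from_table: bool = False,
                          n_theta: int = 200_000) -> float:
    """Enhancement factor gamma: extra dipole scattering collected at a
    glass-water interface, relative to a free dipole in the medium collected
    at the same (arcsine-convention) efficiency mu.

    With ``from_table=True`` the tabulated reference values are interpolated
    instead of integrating the radiation pattern.
    """
    if from_table:
        nas = np.array(sorted(GAMMA_TABLE))
        return float(np.interp(na, nas, [GAMMA_TABLE[x] for x in nas]))
    theta_max = np.arcsin(min(na / n_immersion, 1.0))
    theta = (np.arange(n_theta) + 0.5) * theta_max / n_theta
    w = interface_dipole_weights(theta, n_immersion, n_medium)
    # collected power over the cone vs mu * (isotropic total 4*pi)
    collected = 2 * np.pi * np.trapezoid(w * np.sin(theta), theta)
    mu = theta_max / np.pi
    return float(collected / (mu * 4 * np.pi))


def derived_factors(p: SnrParameters) -> tuple[float, float, float]:
    """(mu, A_BFP, gamma) recomputed from the optical geometry."""
    mu = collection_efficiency(p.na, p.n_immersion)
    area = bfp_area(p.f_obj, p.n_immersion, p.n_medium, p.n_glass)
    gamma = interface_enhancement(p.na, p.n_immersion, p.n_medium)
    return mu, area, gamma


def _photon_fluence(p: SnrParameters):
    """Photons per m^2 delivered during one exposure."""
    return p.illumination * p.exposure * p.wavelength / (_h * _c)


def scattered_photons(p: SnrParameters):
    """Detected scattered photons N_sca per pixel and exposure.

    N_sca = Phi * OT * QE * mu * gamma * sigma_sca * A_BFP * d_px^2
            / (lambda^2 * f_obj^2)

    with the Rayleigh cross-section sigma_sca = k_m^4 (delta_alpha*m)^2/(6 pi)
    (polarizability in the alpha/epsilon_0 volume convention, which absorbs
    the medium factor n_m^2 into delta_alpha).  The A_BFP d^2/(lambda f)^2
    factor concentrates the collected power onto the peak pixel of a
    uniformly-filled back focal plane.  Linear in fluence, quadratic in mass.
    """
    alpha = p.delta_alpha * p.mass_kda * A3_TO_M3
    k_m = 2 * np.pi * p.n_medium / p.wavelength
    sigma_sca = k_m**4 * alpha**2 / (6 * np.pi)
    peak_fraction = p.bfp_area * p.pixel_size**2 / (p.wavelength**2 * p.f_obj**2)
    return (_photon_fluence(p) * p.optical_throughput * p.quantum_efficiency
            * p.mu * p.gamma * sigma_sca * peak_fraction)


def reflected_photons(p: SnrParameters):
    """Detected reference photons N_ref per pixel and exposure:
    N_ref = Phi * OT * QE * |r|^2 * |tau|^2 * d_px^2."""
    return (_photon_fluence(p) * p.optical_throughput * p.quantum_efficiency
            * p.reflectivity * p.mask_transmission * p.pixel_size**2)


def shot_noise_snr(p: SnrParameters):
    """Shot-noise-limited ratiometric SNR.

    The contrast is C = 2 sqrt(N_sca/N_ref); the noise of the ratiometric
    frame is sqrt(2/N_ref); hence SNR = sqrt(2 * N_sca), independent of the
    reference level.  Proportional to m and to sqrt(I * Delta_t).
    """
    if np.any(np.asarray(reflected_photons(p)) <= 0):
        raise ZeroDivisionError("zero reflected photons: ratiometric contrast undefined")
    return np.sqrt(2.0 * scattered_photons(p))


def detection_limit_mass(p: SnrParameters, q: float = 3.0) -> float:
    """Smallest detectable mass m_q [kDa]: solves SNR(m) = q for m."""
    if q <= 0:
        raise ValueError("SNR threshold q must be positive")

    def f(m):
        return float(shot_noise_snr(replace(p, mass_kda=m))) - q

    hi = p.mass_kda
    while f(hi) < 0:
        hi *= 4.0
    return float(brentq(f, 1e-9 * hi, hi, xtol=1e-12, rtol=1e-14))


def qcrlb_resolution(p: SnrParameters) -> float:
    """Quantum Cramér–Rao lower bound on the mass estimate [kDa].

    sigma_m = m / (sqrt(2) * SNR(m)); since SNR is linear in m this is
    independent of m, and equals the mass whose ratiometric SNR is 1/sqrt(2).
    """
    return float(p.mass_kda / (np.sqrt(2.0) * shot_noise_snr(p)))


def snr_with_excess(p: SnrParameters):
    """SNR including the dynamic excess background (mass-equivalent
    sigma_exc_kda), added in quadrature to shot noise:

        SNR_exc = [SNR_shot^-2 + (m/sigma_exc)^-2]^(-1/2)

    Reduces to the shot-noise SNR for sigma_exc = 0 and saturates at the
    ceiling SNR_max = m / sigma_exc for unbounded photon flux.
    """
    snr = shot_noise_snr(p)
    if p.sigma_exc_kda == 0:
        return snr
    ceiling = p.mass_kda / p.sigma_exc_kda
    return 1.0 / np.sqrt(1.0 / snr**2 + 1.0 / ceiling**2)


def snr_simplified_constant(p: SnrParameters) -> float:
    """Constant kappa of the condensed SNR expression

        SNR = kappa * sqrt(I_illu * Delta_t) * m / lambda^(5/2)

    computed from the full parameter set at call time (never hard-coded), so
    that unit errors in the budget surface immediately.  kappa has SI units
    of m^(7/2) J^(-1/2) per kDa.
    """
    snr = float(shot_noise_snr(p))
    return snr * p.wavelength**2.5 / (np.sqrt(p.illumination * p.exposure) * p.mass_kda)


def performance_maps(p: SnrParameters, illumination: np.ndarray,
                     exposure: np.ndarray, q: float = 3.0) -> dict[str, np.ndarray]:
    """Vectorized SNR / detection-limit / resolution maps over an
    illumination x exposure grid (rows: exposure, cols: illumination).

    Returns maps with and without the excess-noise term of ``p``.
    """
    ii, tt = np.meshgrid(np.asarray(illumination, float),
                         np.asarray(exposure, float))
    ref = float(shot_noise_snr(replace(p, sigma_exc_kda=0.0)))
    scale = np.sqrt(ii * tt / (p.illumination * p.exposure))
    snr_shot = ref * scale
    maps = {
        "snr_shot": snr_shot,
        "m_q_shot": q * p.mass_kda / snr_shot,
        "sigma_m_shot": p.mass_kda / (np.sqrt(2.0) * snr_shot),
    }
    if p.sigma_exc_kda > 0:
        ceiling = p.mass_kda / p.sigma_exc_kda
        snr_exc = 1.0 / np.sqrt(1.0 / snr_shot**2 + 1.0 / ceiling**2)
        # m_q with excess noise: solve q^2 = [m'^2/(ref*scale*m)^2 ... ] in m'
        # SNR_exc(m') = m' / sqrt((m/ (ref*scale))^2 + sigma_exc^2) -> linear in m'
        denom = np.sqrt((p.mass_kda / snr_shot) ** 2 + p.sigma_exc_kda**2)
        maps.update({
            "snr_exc": snr_exc,
            "m_q_exc": q * denom,
            "sigma_m_exc": denom / np.sqrt(2.0),
        })
    return maps
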