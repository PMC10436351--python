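"""Correlated cover-glass roughness and the static speckle background.

Microscope cover glass is rough on the nanometre scale (~2 nm height
variation over ~100 nm lateral scales).  The reference field reflected off
such a surface picks up a position-dependent phase retardation
``psi(x) = 2 k0 n_g dh(x)`` (round trip of the glass-side wave to the
locally displaced interface), which the attenuating BFP mask converts into
a speckle-like intensity pattern whose contrast far exceeds that of a
single protein — the reason ratiometric background removal is required,
and the origin of the locally varying effective reflectivity ``r(x)``.

Height maps are generated as uniform white noise, low-pass filtered with a
Gaussian frequency kernel set by the lateral correlation length, and peak-
normalized to the requested amplitude bound (the quoted roughness is a
bound, not an RMS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .field_optics import OpticalConfig, InvalidConfigError, image_point_source

__all__ = ["RoughSurface", "generate_height_map", "height_to_phase",
           "speckle_background", "save_surface", "load_surface"]


@dataclass
class RoughSurface:
    """Correlated height map of the glass-water interface."""

    height: np.ndarray            # dh [m], bounded by +-amplitude
    correlation_length: float     # lateral scale [m]
    amplitude: float              # height bound [m]
    pixel_size: float             # [m]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, float)
        if self.amplitude > 0 and np.abs(self.height).max() > self.amplitude * (1 + 1e-9):
            raise InvalidConfigError("height map exceeds its stated amplitude")


def generate_height_map(grid_size: int, pixel_size: float,
                        correlation_length: float = 100e-9,
                        amplitude: float = 0.8e-9,
                        seed: int | None = None) -> RoughSurface:
    """Seeded correlated roughness map.

    Uniform white noise is low-pass filtered with a Gaussian kernel whose
    width is chosen so the autocorrelation FWHM of the result matches the
    requested correlation length, then rescaled so the extrema sit at the
    requested +-amplitude.  ``amplitude = 0`` yields a flat surface.
    """
    if correlation_length < pixel_size:
        raise InvalidConfigError(
            f"correlation length {correlation_length:.3g} m below the pixel "
            f"size {pixel_size:.3g} m cannot be represented on the grid")
    if amplitude == 0:
        return RoughSurface(np.zeros((grid_size, grid_size)), correlation_length,
                            0.0, pixel_size, seed)
    rng = np.random.default_rng(seed)
    white = rng.uniform(-1.0, 1.0, (grid_size, grid_size))
    # real-space Gaussian blur of std sigma_r makes the autocorrelation a
    # Gaussian of std sigma_r*sqrt(2); match its FWHM to correlation_length
    sigma_r = correlation_length / (2 * np.sqrt(2 * np.log(2)) * np.sqrt(2.0))
    k = 2 * np.pi * np.fft.fftfreq(grid_size, pixel_size)
    kx, ky = np.meshgrid(k, k)
    h = np.fft.ifft2(np.fft.fft2(white)
                     * np.exp(-(kx**2 + ky**2) * sigma_r**2 / 2.0)).real
    h *= amplitude / np.abs(h).max()
    return RoughSurface(h, correlation_length, amplitude, pixel_size, seed)


def height_to_phase(surface: RoughSurface, config: OpticalConfig) -> np.ndarray:
    """Phase retardation map psi = 2 k0 n_g dh of the reflected field.

    The factor is the glass-side round trip to the locally displaced
    interface; it is strictly linear in the height map.  The (unknown)
    additional coverslip phase seen by the transmitted/scattered path can be
    added downstream as an extra phase term and is off by default.
    """
    if surface.pixel_size != config.pixel_size:
        raise InvalidConfigError("surface and optical grids must share a pitch")
    return 2.0 * config.k0 * config.n_glass * surface.height


def speckle_background(surface: RoughSurface, config: OpticalConfig,
                       z_sample: float = 0.0) -> np.ndarray:
    """Detector intensity of the bare rough interface (no scatterer),
    normalized to unit illumination intensity.  Deterministic given the
    surface; a zero-roughness surface reproduces the flat-interface
    reflectivity |r|^2 |tau|^2 exactly."""
    flat = surface.amplitude == 0 or not np.any(surface.height)
    return image_point_source(config, 0.0, z_sample, None if flat else surface)


def save_surface(surface: RoughSurface, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("height", data=surface.height)
        d.attrs.update({
            "correlation_length": surface.correlation_length,
            "amplitude": surface.amplitude,
            "pixel_size": surface.pixel_size,
            "seed": -1 if surface.seed is None else surface.seed,
        })


def load_surface(path) -> RoughSurface:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["height"]
        seed = int(d.attrs["seed"])
        return RoughSurface(d[...], float(d.attrs["correlation_length"]),
                            float(d.attrs["amplitude"]), float(d.attrs["pixel_size"]),
                            None if seed < 0 else seed)
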