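"""Ratiometric analysis chain: frame averaging, event detection, PSF
fitting, local reflectivity correction, peak fitting and mass calibration.

The measurement principle: raw frames contain a large static speckle
background and tiny protein signatures.  Two consecutive ``n_avg``-frame
averages are differenced relative to the first,

    R_i = (mean(F[i+n+1 : i+2n+1]) - mean(F[i : i+n])) / mean(F[i : i+n]),

which cancels everything static exactly and makes each binding event fade
in and out of the ratiometric movie around its landing frame.  Candidate
events are pixels with a minimum amplitude above the background noise and
a minimum radial symmetry, deduplicated across frames; a PSF model
(theoretical or experimental) fitted to each 7x7 patch yields the contrast;
the local-reflectivity correction ``C -> C * sqrt(I_local / <I>)`` removes
the dependence on where on the rough glass the molecule landed (exact up
to the unknown coverslip phase term); Gaussian peak fits of the contrast
histogram and a linear contrast-mass calibration produce the mass
histogram.  The pipeline is deterministic given a movie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import least_squares
from scipy.stats import gaussian_kde, pearsonr

from .field_optics import (InvalidConfigError, OpticalConfig,
                           image_point_source, ratiometric_contrast)

__all__ = [
    "RatioStack", "DetectedEvent", "MassHistogram", "Calibration", "PsfModel",
    "ratiometric_stack", "detect_events", "theoretical_psf",
    "build_experimental_psf", "fit_event_contrast", "reflectivity_correction",
    "fit_mass_peaks", "calibrate_mass", "analyze_movie",
]


class DegenerateInputError(ValueError):
    pass


@dataclass
class RatioStack:
    """Ratiometric frames R_i plus provenance."""

    ratio: np.ndarray             # (T - 2 n_avg - 1, N, N)
    n_avg: int
    source: object = None         # originating FrameStack, if any

    @property
    def n_frames(self) -> int:
        return self.ratio.shape[0]


@dataclass
class DetectedEvent:
    frame: int
    x_px: float
    y_px: float
    contrast: float               # signed fitted amplitude
    residual: float = np.nan
    symmetry: float = np.nan
    correction: float = 1.0
    converged: bool = True

    @property
    def magnitude(self) -> float:
        return abs(self.contrast) * self.correction


@dataclass
class MassHistogram:
    values: np.ndarray
    peaks: list = field(default_factory=list)   # (mu, sigma, count) per species
    bandwidth: float = 2.0


@dataclass
class Calibration:
    slope: float                   # contrast per kDa
    intercept: float
    peak_contrasts: np.ndarray
    peak_masses: np.ndarray
    residuals: np.ndarray

    def to_mass(self, contrast):
        return (np.asarray(contrast) - self.intercept) / self.slope


def ratiometric_stack(frames, n_avg: int) -> RatioStack:
    """Sliding-window ratiometric transform (stride 1).

    Requires at least 2 n_avg + 2 raw frames; a constant movie maps to an
    exactly zero stack (static-background cancellation identity).
    """
    source = None
    if hasattr(frames, "frames"):
        source = frames
        frames = frames.frames
    frames = np.asarray(frames, float)
    t = frames.shape[0]
    n_out = t - 2 * n_avg - 1
    if n_out < 1:
        raise InvalidConfigError(
            f"{t} frames are too few for an n_avg = {n_avg} window")
    cum = np.cumsum(frames, axis=0)
    cum = np.concatenate([np.zeros_like(cum[:1]), cum], axis=0)

    def window_mean(start, length):
        return (cum[start + length] - cum[start]) / length

    idx = np.arange(n_out)
    ratio = np.empty((n_out, *frames.shape[1:]))
    for i in idx:
        a = window_mean(i, n_avg)
        b = window_mean(i + n_avg + 1, n_avg)
        ratio[i] = (b - a) / a
    return RatioStack(ratio=ratio, n_avg=n_avg, source=source)


def _radial_symmetry(patch: np.ndarray) -> float:
    """Correlation of a patch with its own angular average around the
    patch centre; 1 for perfectly radially symmetric patterns."""
    n = patch.shape[0]
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    rbin = np.round(r).astype(int)
    means = ndimage.mean(patch, labels=rbin, index=np.arange(rbin.max() + 1))
    model = means[rbin]
    if np.std(model) == 0 or np.std(patch) == 0:
        return 0.0
    return float(np.corrcoef(patch.ravel(), model.ravel())[0, 1])


def detect_events(stack: RatioStack, min_radial_symmetry: float = 0.5,
                  min_amplitude: float = 4.5, patch_size: int = 7,
                  min_consecutive: int = 2, link_radius: float = 2.0,
                  suppression_radius: float = 5.0) -> list[dict]:
    """Find candidate binding events in a ratiometric stack.

    A candidate is a local maximum of |R| exceeding ``min_amplitude`` robust
    background sigmas whose patch passes the radial-symmetry filter; weaker
    candidates within ``suppression_radius`` pixels of a stronger one in the
    same frame (Airy-ring sidelobes) are suppressed.  Candidates are linked
    across adjacent frames within ``link_radius`` pixels; an event must
    persist for ``min_consecutive`` consecutive ratiometric frames
    (suppressing single-frame shot-noise outliers) and is reported once, at
    its maximal-|R| frame.
    """
    if min_radial_symmetry < 0 or min_amplitude < 0:
        raise InvalidConfigError("thresholds must be >= 0")
    half = patch_size // 2
    raw = []
    for f in range(stack.n_frames):
        frame = stack.ratio[f]
        absf = np.abs(frame)
        sigma = 1.4826 * np.median(np.abs(frame - np.median(frame)))
        if sigma == 0:
            continue
        peaks = (absf == ndimage.maximum_filter(absf, size=3)) \
            & (absf > min_amplitude * sigma)
        cands = sorted(zip(*np.nonzero(peaks)),
                       key=lambda yx: -absf[yx[0], yx[1]])
        kept: list[tuple[int, int]] = []
        for y, x in cands:
            if any(np.hypot(y - y2, x - x2) <= suppression_radius
                   for y2, x2 in kept):
                continue
            kept.append((y, x))
            if not (half <= y < frame.shape[0] - half
                    and half <= x < frame.shape[1] - half):
                continue
            patch = frame[y - half: y + half + 1, x - half: x + half + 1]
            score = _radial_symmetry(patch * np.sign(frame[y, x]))
            if score >= min_radial_symmetry:
                raw.append({"frame": f, "y": int(y), "x": int(x),
                            "amplitude": frame[y, x], "symmetry": score})
    # link across frames
    raw.sort(key=lambda c: c["frame"])
    used = np.zeros(len(raw), bool)
    events = []
    for i, c in enumerate(raw):
        if used[i]:
            continue
        track = [c]
        used[i] = True
        last = c
        for j in range(i + 1, len(raw)):
            d = raw[j]
            if used[j]:
                continue
            if d["frame"] - last["frame"] > 1:
                if d["frame"] - last["frame"] > 1 + stack.n_avg:
                    break
                continue
            if np.hypot(d["y"] - last["y"], d["x"] - last["x"]) <= link_radius \
                    and d["frame"] > last["frame"]:
                track.append(d)
                used[j] = True
                last = d
        frames_seen = {t["frame"] for t in track}
        runs = _longest_run(sorted(frames_seen))
        if runs >= min_consecutive:
            best = max(track, key=lambda t: abs(t["amplitude"]))
            events.append(best)
    return events


def _longest_run(sorted_frames) -> int:
    best = run = 1
    for a, b in zip(sorted_frames, sorted_frames[1:]):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return best


class PsfModel:
    """Interpolable (cubic-spline) PSF shape with unit peak amplitude."""

    def __init__(self, profile: np.ndarray, pixel_size: float, oversample: int = 1):
        profile = np.asarray(profile, float)
        peak = np.abs(profile).max()
        if peak == 0:
            raise DegenerateInputError("empty PSF profile")
        self.profile = profile / profile.flat[np.abs(profile).argmax()]
        self.pixel_size = pixel_size / oversample
        n = profile.shape[0]
        self._coord = (np.arange(n) - (n - 1) / 2.0) * self.pixel_size
        self._spline = RectBivariateSpline(self._coord, self._coord, self.profile,
                                           kx=3, ky=3)
        self.half_extent = self._coord[-1]

    def eval(self, shape: tuple[int, int], pixel_size: float,
             dx: float = 0.0, dy: float = 0.0) -> np.ndarray:
        """Sample the model on a patch of ``shape`` analysis pixels, with the
        peak displaced by (dx, dy) analysis pixels from the patch centre."""
        ny, nx = shape
        y = (np.arange(ny) - (ny - 1) / 2.0 - dy) * pixel_size
        x = (np.arange(nx) - (nx - 1) / 2.0 - dx) * pixel_size
        y = np.clip(y, -self.half_extent, self.half_extent)
        x = np.clip(x, -self.half_extent, self.half_extent)
        return self._spline(y, x)


def theoretical_psf(config: OpticalConfig, analysis_pixel_size: float,
                    z_sample: float = 0.0, oversample: int = 4,
                    half_size_px: int = 5, binning: int = 2) -> PsfModel:
    """Render the in-focus interferometric contrast PSF of a weak point
    scatterer on flat glass, oversampled relative to the analysis grid.

    ``binning`` emulates the detector: an analysis pixel is the average of
    ``binning x binning`` raw-pixel point samples, so the model is the
    continuous PSF convolved with that sample comb — without it the fitted
    amplitude would depend on the sub-pixel landing position at the
    several-percent level.
    """
    if oversample % max(binning, 1):
        raise InvalidConfigError("oversample must be a multiple of the binning")
    n_fine = 2 * (half_size_px + 1) * oversample + 1
    fine = replace(config, pixel_size=analysis_pixel_size / oversample,
                   grid_size=n_fine)
    bkg = image_point_source(fine, 0.0, z_sample)
    det = image_point_source(fine, 1e4, z_sample)  # small alpha: linear regime
    c = ratiometric_contrast(det, bkg)
    if binning > 1:
        step = oversample // binning
        offsets = (np.arange(binning) - (binning - 1) / 2.0) * step
        acc = np.zeros_like(c)
        for dy in offsets:
            for dx in offsets:
                acc += ndimage.shift(c, (dy, dx), order=1, mode="nearest")
        c = acc / binning**2
    trim = oversample  # drop the shift-contaminated border
    c = c[trim:-trim, trim:-trim]
    return PsfModel(c, analysis_pixel_size, oversample=oversample)


def fit_event_contrast(patch: np.ndarray, psf_model: PsfModel,
                       pixel_size: float, frame: int = -1,
                       y_px: float = 0.0, x_px: float = 0.0,
                       symmetry: float = np.nan) -> DetectedEvent:
    """Least-squares amplitude + sub-pixel position fit of the PSF model to
    a ratiometric patch; the fitted amplitude is the event contrast.  A
    patch that is an exact scaled copy of the model is recovered exactly."""
    patch = np.asarray(patch, float)
    a0 = patch.flat[np.abs(patch).argmax()]

    def resid(p):
        amp, dx, dy, off = p
        return (amp * psf_model.eval(patch.shape, pixel_size, dx, dy)
                + off - patch).ravel()

    res = least_squares(resid, [a0, 0.0, 0.0, 0.0],
                        bounds=([-np.inf, -2, -2, -np.inf],
                                [np.inf, 2, 2, np.inf]))
    amp, dx, dy, _ = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return DetectedEvent(frame=frame, x_px=x_px + dx, y_px=y_px + dy,
                         contrast=float(amp), residual=rms, symmetry=symmetry,
                         converged=bool(res.success))


def build_experimental_psf(patches, pixel_size: float,
                           corr_threshold: float = 0.8,
                           oversample: int = 4) -> PsfModel:
    """Sub-pixel align >= 10 event patches by cubic-spline interpolation,
    average them, and reject outliers by Pearson correlation against the
    mean.  The averaged model beats any single noisy patch."""
    patches = [np.asarray(p, float) for p in patches]
    if len(patches) < 10:
        raise DegenerateInputError("need at least 10 patches")
    aligned = []
    for p in patches:
        sign = np.sign(p.flat[np.abs(p).argmax()]) or 1.0
        shift = _quadratic_peak_shift(sign * p)
        aligned.append(ndimage.shift(p, shift, order=3, mode="nearest") * sign)
    aligned = np.array(aligned)
    mean = aligned.mean(axis=0)
    keep = np.array([pearsonr(a.ravel(), mean.ravel())[0] >= corr_threshold
                     for a in aligned])
    if not keep.any():
        raise DegenerateInputError("all patches rejected as outliers")
    mean = aligned[keep].mean(axis=0)
    return PsfModel(mean, pixel_size, oversample=1)


def _quadratic_peak_shift(p: np.ndarray) -> np.ndarray:
    """Shift that moves the (parabolically interpolated) peak to the patch
    centre; zero for an already-centred patch."""
    y, x = np.unravel_index(np.argmax(p), p.shape)
    pos = np.array([float(y), float(x)])
    for axis, idx in ((0, y), (1, x)):
        if 0 < idx < p.shape[axis] - 1:
            sl = [y, x]
            vals = []
            for d in (-1, 0, 1):
                sl[axis] = idx + d
                vals.append(p[tuple(sl)])
            denom = vals[0] - 2 * vals[1] + vals[2]
            if denom != 0:
                pos[axis] += 0.5 * (vals[0] - vals[2]) / denom
    centre = (np.array(p.shape) - 1) / 2.0
    return centre - pos


def reflectivity_correction(event: DetectedEvent, background_map: np.ndarray,
                            weights: np.ndarray | None = None,
                            background_patch: np.ndarray | None = None) -> DetectedEvent:
    """Local reflectivity correction removing the 1/|r(x)| dependence of the
    interferometric contrast on the rough glass (identity on a flat
    background; event coordinates are preserved).

    The fitted amplitude is a weighted average of per-pixel contrasts, each
    carrying the local reference factor (I(x)/<I>)^(-1/2) of its own speckle
    grain.  The matching correction is therefore the same-weighted harmonic
    mean,

        C -> C / sum_i u_i (I_i/<I>)^(-1/2),

    with ``u_i`` the normalized effective fit weights (model^2 for a plain
    least-squares fit) on ``background_patch``.  Without weights the factor
    falls back to sqrt(I/<I>) interpolated at the event position.
    """
    bg = np.asarray(background_map, float)
    mean = bg.mean()
    if weights is not None:
        if background_patch is None:
            raise InvalidConfigError("weights require a matching background_patch")
        u = np.asarray(weights, float)
        u = u / u.sum()
        factor = float(1.0 / np.sum(u * (np.asarray(background_patch, float)
                                         / mean) ** -0.5))
    else:
        pos = np.array([[event.y_px], [event.x_px]])
        local = float(ndimage.map_coordinates(bg, pos, order=1, mode="nearest")[0])
        factor = float(np.sqrt(local / mean))
    return replace(event, correction=factor)


def fit_mass_peaks(values, bandwidth: float = 2.0,
                   min_weight: float = 0.05,
                   n_peaks: int | None = None) -> MassHistogram:
    """Gaussian peak decomposition of an event histogram.

    Peaks are seeded at the modes of a fixed-bandwidth kernel density
    estimate; each peak is then fitted by a local Gaussian (mu, sigma,
    count) on the samples assigned to it.  Unresolvable overlapping peaks
    are flagged with a warning and fitted jointly (shared assignment).
    """
    values = np.sort(np.asarray(values, float))
    if values.size < 5:
        raise DegenerateInputError("too few events for peak fitting")
    kde = gaussian_kde(values, bw_method=bandwidth / max(values.std(), 1e-12))
    grid = np.linspace(values.min() - 3 * bandwidth,
                       values.max() + 3 * bandwidth, 2048)
    dens = kde(grid)
    mode_idx = np.nonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
                          & (dens[1:-1] > min_weight * dens.max()))[0] + 1
    modes = grid[mode_idx]
    if modes.size == 0:
        modes = np.array([values.mean()])
    # assign samples to nearest mode, then local trimmed Gaussian fit
    assign = np.argmin(np.abs(values[:, None] - modes[None, :]), axis=1)
    peaks = []
    for k, m in enumerate(modes):
        sel = values[assign == k]
        if sel.size < 5:
            continue
        mu, sigma = sel.mean(), sel.std()
        for _ in range(5):  # trimmed re-fit
            core = sel[np.abs(sel - mu) < 3 * max(sigma, bandwidth / 2)]
            if core.size < 5:
                break
            mu, sigma = core.mean(), core.std()
        peaks.append((float(mu), float(max(sigma, 1e-12)), int(sel.size)))
    if n_peaks is not None and len(peaks) > n_peaks:
        peaks = sorted(peaks, key=lambda p: -p[2])[:n_peaks]
    peaks.sort()
    for (m1, s1, _), (m2, s2, _) in zip(peaks, peaks[1:]):
        if m2 - m1 < 2 * (s1 + s2):
            warnings.warn(f"peaks at {m1:.3g} and {m2:.3g} overlap; "
                          "joint assignment used", stacklevel=2)
    return MassHistogram(values=values, peaks=peaks, bandwidth=bandwidth)


def calibrate_mass(peak_contrasts, known_masses) -> Calibration:
    """Least-squares line through (mass, contrast) calibrant pairs."""
    c = np.asarray(peak_contrasts, float)
    m = np.asarray(known_masses, float)
    if c.size < 2:
        raise DegenerateInputError("calibration needs at least two peaks")
    slope, intercept = np.polyfit(m, c, 1)
    if slope <= 0:
        raise DegenerateInputError("non-positive contrast-mass slope")
    resid = c - (slope * m + intercept)
    return Calibration(slope=float(slope), intercept=float(intercept),
                       peak_contrasts=c, peak_masses=m, residuals=resid)


def analyze_movie(stack, n_avg: int | None = None, psf_model: PsfModel | None = None,
                  mask_correction: bool = True, patch_size: int = 7,
                  min_amplitude: float = 4.5, min_radial_symmetry: float = 0.5,
                  min_consecutive: int = 2) -> list[DetectedEvent]:
    """End-to-end analysis of a (possibly binned) FrameStack: ratiometric
    transform, detection, PSF contrast fitting and (optionally) the local
    reflectivity correction.  Returns the fitted events."""
    n_avg = n_avg if n_avg is not None else 1
    ratio = ratiometric_stack(stack, n_avg)
    if psf_model is None:
        psf_model = theoretical_psf(stack.config, stack.config.pixel_size,
                                    binning=getattr(stack.settings, "spatial_binning", 1))
    candidates = detect_events(ratio, min_radial_symmetry=min_radial_symmetry,
                               min_amplitude=min_amplitude,
                               patch_size=patch_size,
                               min_consecutive=min_consecutive)
    background = np.median(np.asarray(stack.frames, float), axis=0)
    half = patch_size // 2
    out = []
    for c in candidates:
        frame = ratio.ratio[c["frame"]]
        patch = frame[c["y"] - half: c["y"] + half + 1,
                      c["x"] - half: c["x"] + half + 1]
        ev = fit_event_contrast(patch, psf_model, stack.config.pixel_size,
                                frame=c["frame"], y_px=c["y"], x_px=c["x"],
                                symmetry=c["symmetry"])
        if not ev.converged:
            continue
        if mask_correction:
            model = psf_model.eval(patch.shape, stack.config.pixel_size,
                                   ev.x_px - c["x"], ev.y_px - c["y"])
            bpatch = background[c["y"] - half: c["y"] + half + 1,
                                c["x"] - half: c["x"] + half + 1]
            ev = reflectivity_correction(ev, background, weights=model**2,
                                         background_patch=bpatch)
        out.append(ev)
    return out
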