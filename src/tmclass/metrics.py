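"""Aberration separation and image-quality metrics.

The solver's input correction converges to φ_i + g (input aberration
entangled with acquisition drift) and cannot split the two from a single
dataset.  The two-configuration procedure does: in the ordinary geometry
the recovered output correction is θ_o = φ_o, while with a test target at
the conjugate image plane before the input lens both pupils act after the
object and θ'_o = φ_i + φ_o.  The wrapped difference θ'_o - θ_o is the
pure input aberration, independent of both drift realizations.

The remaining functions quantify optical quality: PSF synthesis from a
residual pupil phase, Strehl ratio (aberrated peak over ideal peak of the
same aperture), FWHM with sub-pixel peak interpolation, a least-squares
Airy-pattern fit over the central lobe and first ring, the Siemens-star
azimuthal-contrast resolution read-out, and the coherent synthetic-aperture
diffraction limit Δ = λ/(NA_ill + NA_col).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit
from scipy.special import j1

from .core import Grid, fit_wrapped_tilt, ifft2c, support_mask, wrap_phase

__all__ = [
    "PSFProfile",
    "separate_input",
    "compute_psf",
    "fwhm",
    "airy_fit",
    "siemens_resolution",
    "register_center",
    "diffraction_limit",
    "circular_rms_phase_error",
    "UNRESOLVED",
]

UNRESOLVED = math.inf
"""Sentinel returned by :func:`siemens_resolution` when no circle reaches
the contrast threshold (coarser than anything measurable)."""


# --------------------------------------------------------------------------
# separation of the input aberration
# --------------------------------------------------------------------------

def separate_input(
    theta_o_main: NDArray,
    theta_o_conjugate: NDArray,
    mask: NDArray | None = None,
    remove_tilt: bool = True,
) -> NDArray:
    """Pure input-aberration estimate from the two measurement geometries:
    wrapped difference θ'_o - θ_o on the shared output support,
    gauge-normalized (piston at the origin removed and, by default, the
    tilt gauge difference of the two independent solver runs — a relative
    translation of the two reconstructions — subtracted)."""
    a = np.asarray(theta_o_main, dtype=float)
    b = np.asarray(theta_o_conjugate, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"support mismatch: {a.shape} vs {b.shape}")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    elif mask.shape != a.shape:
        raise ValueError("mask shape does not match the phase maps")
    diff = wrap_phase(b - a)
    c = a.shape[0] // 2
    if remove_tilt:
        iy, ix = np.nonzero(mask)
        kvecs = np.stack([ix - c, iy - c], axis=1)
        tilt = fit_wrapped_tilt(diff[iy, ix], kvecs)
        diff = diff - tilt[0] * (np.arange(a.shape[1]) - c)[None, :] \
                    - tilt[1] * (np.arange(a.shape[0]) - c)[:, None]
    diff = wrap_phase(diff - diff[c, c])
    return np.where(mask, diff, 0.0)


# --------------------------------------------------------------------------
# PSF synthesis and metrics
# --------------------------------------------------------------------------

@dataclass
class PSFProfile:
    """Point-spread function of a unit-amplitude pupil carrying a phase map."""

    grid: Grid
    intensity: NDArray
    peak_value: float
    peak_pos: tuple  # (y, x) sub-pixel indices
    strehl: float
    fwhm: float | None = None
    airy_fit: dict | None = None


def _subpixel_peak(img: NDArray) -> tuple[float, float, float]:
    """Quadratic (3-point parabola per axis) refinement of the brightest
    pixel; returns (y, x, value)."""
    iy, ix = np.unravel_index(int(np.argmax(img)), img.shape)
    y, x, v = float(iy), float(ix), float(img[iy, ix])

    def refine(fm: float, f0: float, fp: float) -> tuple[float, float]:
        denom = fm - 2.0 * f0 + fp
        if denom >= 0:  # not a local max in this axis
            return 0.0, f0
        d = 0.5 * (fm - fp) / denom
        return d, f0 - 0.25 * (fm - fp) * d

    vy = vx = v
    if 0 < iy < img.shape[0] - 1:
        dy, vy = refine(img[iy - 1, ix], img[iy, ix], img[iy + 1, ix])
        y += dy
    if 0 < ix < img.shape[1] - 1:
        dx, vx = refine(img[iy, ix - 1], img[iy, ix], img[iy, ix + 1])
        x += dx
    return y, x, max(vy, vx)


def compute_psf(residual_phase: NDArray, grid: Grid, na: float) -> PSFProfile:
    """PSF of a unit-amplitude pupil of aperture ``na`` carrying
    ``residual_phase``: intensity of the inverse transform of the pupil,
    with the Strehl ratio taken against the zero-phase pupil of identical
    support (peak values are sub-pixel interpolated, so a pure tilt —
    a translated but undistorted focus — scores Strehl 1)."""
    mask = support_mask(grid, na)
    if not mask.any():
        raise ValueError("empty pupil support")
    phase = np.asarray(residual_phase, dtype=float)
    if phase.shape != mask.shape:
        raise ValueError(f"phase shape {phase.shape} != grid {mask.shape}")
    field = ifft2c(np.where(mask, np.exp(1j * phase), 0.0))
    intensity = np.abs(field) ** 2
    y, x, peak = _subpixel_peak(intensity)
    ideal = np.abs(ifft2c(mask.astype(np.complex128))) ** 2
    _, _, ideal_peak = _subpixel_peak(ideal)
    return PSFProfile(
        grid=grid,
        intensity=intensity,
        peak_value=peak,
        peak_pos=(y, x),
        strehl=float(peak / ideal_peak),
    )


def fwhm(profile: PSFProfile, axis: str = "x") -> float:
    """Full width at half maximum (µm) of the PSF along a line through the
    (sub-pixel) peak, with linear interpolation between samples; raises if
    the half-maximum level is never crossed on either side."""
    img = profile.intensity
    y0, x0 = profile.peak_pos
    n = img.shape[0]
    t = np.arange(n, dtype=float)
    if axis == "x":
        coords = np.vstack([np.full(n, y0), t])
        center = x0
    elif axis == "y":
        coords = np.vstack([t, np.full(n, x0)])
        center = y0
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    line = map_coordinates(img, coords, order=1, mode="nearest")
    half = 0.5 * profile.peak_value
    ic = int(round(center))

    def cross(direction: int) -> float:
        i = ic
        while 0 <= i + direction < n:
            a, b = line[i], line[i + direction]
            if a >= half > b:
                frac = (a - half) / (a - b)
                return i + direction * frac
            i += direction
        raise ValueError("half maximum never crossed within the grid")

    left = cross(-1)
    right = cross(+1)
    width = (right - left) * profile.grid.dx
    profile.fwhm = float(width)
    return profile.fwhm


def _airy_intensity(x: NDArray) -> NDArray:
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    amp = np.where(small, 1.0 - x**2 / 8.0, 2.0 * j1(xs) / xs)
    return amp**2


def airy_fit(profile: PSFProfile) -> dict:
    """Least-squares fit of scale·[2·J1(rate·r)/(rate·r)]² to the PSF,
    using every pixel from the peak out to the first dark ring (ring radius
    refined once from the fitted rate).  Returns a record with the fitted
    ``scale``, ``rate`` (rad/µm), ``residual_sq_norm`` = Σresid²/Σdata²
    over the fit domain, and a ``success`` flag; a non-convergent fit is
    reported in the record, not raised."""
    img = profile.intensity
    y0, x0 = profile.peak_pos
    n = img.shape[0]
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - y0, xx - x0) * profile.grid.dx
    # initial rate from the peak width: Airy half max at x = 1.61633
    try:
        w = profile.fwhm if profile.fwhm is not None else fwhm(profile)
        rate0 = 2.0 * 1.61633 / w
    except ValueError:
        rate0 = 3.8317 / (r[r > 0].min() * 4.0)
    record: dict = {"scale": float(profile.peak_value), "rate": float(rate0),
                    "residual_sq_norm": float("inf"), "success": False}
    rate = rate0
    for _ in range(2):
        r_max = 3.8317 / rate  # first dark ring of the current fit
        sel = r <= r_max
        rr, data = r[sel], img[sel]
        try:
            popt, _ = curve_fit(
                lambda rr_, s, k: s * _airy_intensity(k * rr_),
                rr, data, p0=[profile.peak_value, rate], maxfev=2000,
            )
        except (RuntimeError, ValueError):
            profile.airy_fit = record
            return record
        rate = abs(float(popt[1]))
    model = popt[0] * _airy_intensity(rate * rr)
    resid = data - model
    record = {
        "scale": float(popt[0]),
        "rate": rate,
        "residual_sq_norm": float(np.sum(resid**2) / np.sum(data**2)),
        "success": True,
    }
    profile.airy_fit = record
    return record


# --------------------------------------------------------------------------
# resolution read-outs
# --------------------------------------------------------------------------

def siemens_resolution(
    image: NDArray,
    grid: Grid,
    n_spokes: int,
    r_outer: float,
    contrast_threshold: float = 0.1,
    n_angles: int = 720,
    center: tuple | None = None,
) -> float:
    """Finest resolved azimuthal period (µm) of a Siemens-star image.

    Sweeps circles of decreasing radius about the star center (pixel
    coordinates ``center``, defaulting to the grid center; pass the
    registered center when the reconstruction is translated by the tilt
    gauge), extracts the
    azimuthal intensity profile by bilinear interpolation, and measures the
    Michelson contrast of its component at the spoke frequency
    (n_spokes/2 cycles per revolution): 2·|c_m| / c_0 from the profile's
    Fourier coefficients.  Returns the period 2πr*/(n_spokes/2) at the
    smallest radius r* whose contrast still reaches the threshold, or the
    :data:`UNRESOLVED` sentinel when no circle passes.
    """
    if not (0 < contrast_threshold < 1):
        raise ValueError("contrast_threshold must lie in (0, 1)")
    img = np.asarray(image, dtype=float)
    cy, cx = (float(grid.center), float(grid.center)) if center is None else (float(center[0]), float(center[1]))
    m = n_spokes // 2
    ang = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    radii_px = np.arange(2.0, (r_outer / grid.dx) - 1.0, 0.5)
    best: float = UNRESOLVED
    for r_px in radii_px[::-1]:
        coords = np.vstack([cy + r_px * sin_a, cx + r_px * cos_a])
        prof = map_coordinates(img, coords, order=1, mode="nearest")
        coeffs = np.fft.rfft(prof)
        c0 = abs(coeffs[0])
        if c0 == 0 or m >= len(coeffs):
            continue
        contrast = 2.0 * abs(coeffs[m]) / c0
        if contrast >= contrast_threshold:
            best = 2.0 * np.pi * (r_px * grid.dx) / m
        else:
            # contrast lost: stop at the finest contiguous resolved radius
            if best is not UNRESOLVED:
                break
    return best


def register_center(image: NDArray, reference: NDArray, grid: Grid) -> tuple:
    """Sub-pixel center (cy, cx) of a reference pattern inside ``image``.

    The tilt gauge of the correction translates reconstructions rigidly;
    this registers the image against the known pattern (phase cross
    correlation, 1/20-pixel upsampling) so circle sweeps stay concentric.
    """
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(
        np.asarray(reference, float), np.asarray(image, float),
        upsample_factor=20, normalization=None,
    )
    c = grid.center
    return (c - float(shift[0]), c - float(shift[1]))


def diffraction_limit(wavelength: float, na_ill: float, na_col: float) -> float:
    """Coherent synthetic-aperture diffraction limit
    Δ = λ / (NA_ill + NA_col), in the units of ``wavelength``."""
    if wavelength <= 0 or na_ill <= 0 or na_col <= 0:
        raise ValueError("wavelength and both numerical apertures must be positive")
    return wavelength / (na_ill + na_col)


# --------------------------------------------------------------------------
# phase-recovery metric
# --------------------------------------------------------------------------

def _remove_plane(d: NDArray, coords: NDArray, remove_tilt: bool) -> NDArray:
    """Subtract the gauge plane from wrapped phase residuals: first a
    wrapped-gradient tilt estimate (robust when the tilt itself wraps),
    then iterative circular-mean piston and least-squares refinement."""
    if remove_tilt and coords.shape[0] >= 3:
        tilt = fit_wrapped_tilt(d, coords.astype(int))
        d = wrap_phase(d - coords @ tilt)
    for _ in range(3):
        d = wrap_phase(d - np.angle(np.mean(np.exp(1j * d))))
        if remove_tilt and coords.shape[0] >= 3:
            A = np.column_stack([coords[:, 0], coords[:, 1], np.ones(len(d))])
            sol, *_ = np.linalg.lstsq(A, d, rcond=None)
            d = wrap_phase(d - A @ sol)
    return d


def circular_rms_phase_error(
    estimate: NDArray,
    truth: NDArray,
    mask: NDArray | None = None,
    kvecs: NDArray | None = None,
    remove_tilt: bool = True,
) -> float:
    """Circular RMS distance between two phase maps after gauge alignment.

    Accepts either 2-D maps with an optional boolean ``mask`` (support) or
    1-D per-illumination vectors with their lattice ``kvecs``.  The wrapped
    difference is reduced by its circular-mean piston and (optionally) its
    least-squares tilt — the gauge freedoms of the CLASS objective — and
    the RMS of the remaining wrapped residual is returned (radians).
    """
    e = np.asarray(estimate, dtype=float)
    t = np.asarray(truth, dtype=float)
    if e.shape != t.shape:
        raise ValueError(f"support mismatch: {e.shape} vs {t.shape}")
    if e.ndim == 2:
        if mask is None:
            mask = np.ones(e.shape, dtype=bool)
        if mask.shape != e.shape:
            raise ValueError("mask shape does not match the phase maps")
        iy, ix = np.nonzero(mask)
        coords = np.stack([ix - e.shape[1] // 2, iy - e.shape[0] // 2], axis=1).astype(float)
        d = wrap_phase(e[iy, ix] - t[iy, ix])
    elif e.ndim == 1:
        if kvecs is None:
            raise ValueError("1-D phase vectors require their lattice kvecs")
        coords = np.asarray(kvecs, dtype=float)
        if coords.shape != (e.size, 2):
            raise ValueError("kvecs shape must be (N, 2)")
        d = wrap_phase(e - t)
    else:
        raise ValueError("estimate must be 1-D or 2-D")
    if d.size == 0:
        raise ValueError("empty support")
    d = _remove_plane(d, coords, remove_tilt)
    return float(np.sqrt(np.mean(d**2)))
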