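"""Synthetic objects, condenser-like aberrations, phase drift, and the
forward model that generates angle-scanned transmission datasets.

The forward model is the single-scattering angular-spectrum relation for a
thin object between two aberrated lenses: for illumination wavevector k_i
and output wavevector k_o inside the collection aperture,

    E_o(k_o; k_i) = P_o^a(k_o) · O(k_o - k_i) · P_i^a(k_i) · exp(i g(k_i)),

where O is the object spectrum, P^a = exp(iφ) are the unit-amplitude pupils
and g(k_i) is an uncontrolled global phase per acquisition (interferometer
path-length drift).  The object spectrum value carried at k_o is the object
frequency Δk = k_o - k_i, which is what makes coherent aperture synthesis
(summing equal-Δk entries over k_i) reproduce O(Δk).

A second measurement geometry places a test target at the conjugate image
plane before the input lens; the wave then traverses both pupils *after*
the object, so the dataset carries the product pupil on the output side and
no input-side aberration:

    E'(k_o; k_i) = [P_o^a · P_i^a](k_o) · O'(k_o - k_i) · exp(i g'(k_i)).

Aberrations are parameterized as even-power radial polynomials of the
normalized pupil radius ρ = |k|/(na·k0) (matching the spherically
symmetric phase maps condenser lenses exhibit) plus optional low-order
azimuthal contamination terms.  A small Zernike evaluator is provided as a
convenience converter only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

from .core import (
    CONJUGATE_PLANE,
    SAMPLE_PLANE,
    Grid,
    IlluminationSet,
    ObjectField,
    Pupil,
    SizingError,
    TransmissionDataset,
    fft2c,
    support_mask,
)

__all__ = [
    "AberrationPhase",
    "DriftPhase",
    "Interferogram",
    "make_siemens_star",
    "make_phase_blobs",
    "make_condenser_aberration",
    "from_zernike",
    "make_pupil",
    "sample_drift",
    "simulate_dataset",
    "simulate_conjugate_dataset",
    "synthesize_hologram",
]


@dataclass(frozen=True)
class AberrationPhase:
    """Pupil aberration phase map with its generating parameters.

    ``phase(k) = Σ_j radial_coeffs[j] · ρ^(2j+2)`` on the support
    (ρ = |k|/(na·k0)), plus optional azimuthal terms; phase(0) = 0 by
    construction (piston-free).
    """

    grid: Grid
    na: float
    phase: NDArray  # (n, n) float, zero off support
    radial_coeffs: tuple = ()
    asym_coeffs: tuple = ()
    seed: int = 0

    @property
    def mask(self) -> NDArray[np.bool_]:
        return support_mask(self.grid, self.na)


@dataclass(frozen=True)
class DriftPhase:
    """Per-illumination uncontrolled phase g(k_i), radians in (-π, π],
    fully determined by ``seed``."""

    illuminations: IlluminationSet
    g: NDArray  # (N,) float
    magnitude: float
    seed: int

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if g.shape != (len(self.illuminations),):
            raise ValueError("drift vector length != number of illuminations")
        g.setflags(write=False)
        object.__setattr__(self, "g", g)


@dataclass(frozen=True)
class Interferogram:
    """Camera-like off-axis intensity frame I = |E_S + ref·e^{i k_R·r}|²."""

    grid: Grid
    intensity: NDArray  # (n, n) float, >= 0
    carrier: tuple  # lattice vector (p, q)
    ref_amplitude: float


# --------------------------------------------------------------------------
# objects
# --------------------------------------------------------------------------

def make_siemens_star(grid: Grid, n_spokes: int, r_outer: float) -> ObjectField:
    """Binary-amplitude Siemens star: ``n_spokes`` alternating opaque and
    transparent angular sectors of equal width inside radius ``r_outer``
    (µm), fully transparent outside.

    A pixel at polar angle θ and radius r < r_outer is opaque iff
    ``floor(θ·n_spokes / 2π)`` is even.  The local azimuthal period at
    radius r is ``2πr / (n_spokes/2)``.
    """
    if n_spokes < 4 or n_spokes % 2 != 0:
        raise ValueError(f"n_spokes must be an even integer >= 4, got {n_spokes}")
    if not (0 < r_outer <= grid.fov / 2):
        raise ValueError(f"r_outer must lie in (0, fov/2], got {r_outer}")
    X, Y = grid.x_maps()
    r = np.hypot(X, Y)
    theta = np.mod(np.arctan2(Y, X), 2.0 * np.pi)
    sector = np.floor(theta * n_spokes / (2.0 * np.pi)).astype(np.int64)
    opaque = (sector % 2 == 0) & (r < r_outer)
    return ObjectField(grid=grid, transmittance=np.where(opaque, 0.0, 1.0))


def make_phase_blobs(
    grid: Grid, n_blobs: int, max_phase: float, seed: int
) -> ObjectField:
    """Unit-amplitude smooth phase object: a sum of random Gaussian bumps
    rescaled so that max |arg t| = ``max_phase`` (radians, ≤ π); a coarse
    stand-in for the granular refractive-index structure of a cell."""
    if max_phase > np.pi:
        raise ValueError(f"max_phase must be <= π, got {max_phase}")
    n = grid.n
    phase = np.zeros((n, n), dtype=float)
    if n_blobs > 0 and max_phase > 0:
        rng = np.random.default_rng(seed)
        X, Y = grid.x_maps()
        cx = rng.uniform(-0.4, 0.4, size=n_blobs) * grid.fov
        cy = rng.uniform(-0.4, 0.4, size=n_blobs) * grid.fov
        sig = rng.uniform(0.02, 0.08, size=n_blobs) * grid.fov
        amp = rng.uniform(-1.0, 1.0, size=n_blobs)
        for j in range(n_blobs):
            phase += amp[j] * np.exp(
                -((X - cx[j]) ** 2 + (Y - cy[j]) ** 2) / (2.0 * sig[j] ** 2)
            )
        peak = np.abs(phase).max()
        if peak > 0:
            phase *= max_phase / peak
    return ObjectField(grid=grid, transmittance=np.exp(1j * phase))


# --------------------------------------------------------------------------
# aberrations and drift
# --------------------------------------------------------------------------

def make_condenser_aberration(
    grid: Grid,
    na: float,
    radial_coeffs: Sequence[float],
    asym_coeffs: Sequence[float] = (),
    seed: int = 0,
) -> AberrationPhase:
    """Radial-polynomial pupil aberration.

    ``phase(k) = Σ_j radial_coeffs[j]·ρ^(2j+2)`` with ρ = |k|/(na·k0);
    higher-order terms concentrate the phase excursion near the pupil edge,
    emulating condenser aberrations that steepen beyond ~0.8 of the cutoff.
    ``asym_coeffs[m]`` adds ``a·ρ^(m+1)·cos((m+1)·azimuth + ψ_m)`` with a
    random orientation ψ_m drawn from ``seed``; all terms vanish at k = 0.
    """
    radial = tuple(float(c) for c in radial_coeffs)
    asym = tuple(float(c) for c in asym_coeffs)
    if not all(math.isfinite(c) for c in radial + asym):
        raise ValueError("aberration coefficients must be finite")
    mask = support_mask(grid, na)
    kr = grid.k_radius()
    rho = np.where(mask, kr / (na * grid.k0), 0.0)
    phase = np.zeros_like(rho)
    for j, c in enumerate(radial):
        if c != 0.0:
            phase += c * rho ** (2 * j + 2)
    if asym:
        rng = np.random.default_rng(seed)
        psis = rng.uniform(0.0, 2.0 * np.pi, size=len(asym))
        kx, ky = grid.k_maps()
        az = np.arctan2(ky, kx)
        for m, a in enumerate(asym):
            if a != 0.0:
                phase += a * rho ** (m + 1) * np.cos((m + 1) * az + psis[m])
    phase = np.where(mask, phase, 0.0)
    return AberrationPhase(
        grid=grid, na=na, phase=phase, radial_coeffs=radial, asym_coeffs=asym, seed=seed
    )


def _zernike_radial(nz: int, mz: int, rho: NDArray) -> NDArray:
    out = np.zeros_like(rho)
    for s in range((nz - mz) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(nz - s)
            / (
                math.factorial(s)
                * math.factorial((nz + mz) // 2 - s)
                * math.factorial((nz - mz) // 2 - s)
            )
        )
        out += c * rho ** (nz - 2 * s)
    return out


def from_zernike(
    grid: Grid, na: float, terms: Sequence[tuple[int, int, float]]
) -> AberrationPhase:
    """Convenience converter: build an aberration phase from Zernike terms
    ``(n, m, coefficient)`` (unnormalized, coefficient in radians at ρ = 1;
    m >= 0 uses cos(mθ), m < 0 uses sin(|m|θ)).  The canonical aberration
    parameterization of this package remains the radial polynomial of
    :func:`make_condenser_aberration`; piston (n = m = 0) is dropped."""
    mask = support_mask(grid, na)
    rho = np.where(mask, grid.k_radius() / (na * grid.k0), 0.0)
    kx, ky = grid.k_maps()
    az = np.arctan2(ky, kx)
    phase = np.zeros_like(rho)
    for nz, mz, coeff in terms:
        if nz == 0 and mz == 0:
            continue
        if (nz - abs(mz)) < 0 or (nz - abs(mz)) % 2 != 0:
            raise ValueError(f"invalid Zernike indices (n={nz}, m={mz})")
        rad = _zernike_radial(nz, abs(mz), rho)
        ang = np.cos(mz * az) if mz >= 0 else np.sin(abs(mz) * az)
        phase += coeff * rad * ang
    phase = np.where(mask, phase, 0.0)
    return AberrationPhase(grid=grid, na=na, phase=phase)


def make_pupil(grid: Grid, na: float, aberration: AberrationPhase | None = None) -> Pupil:
    """Pupil with the given aberration phase (ideal when ``aberration`` is
    None).  The aberration must share the grid and NA cutoff."""
    if aberration is None:
        return Pupil(grid=grid, na=na)
    if not aberration.grid.compatible(grid) or not np.isclose(aberration.na, na):
        raise ValueError("aberration grid/NA does not match the requested pupil")
    return Pupil(grid=grid, na=na, phase=aberration.phase)


def sample_drift(illums: IlluminationSet, magnitude: float, seed: int) -> DriftPhase:
    """Independent uniform phase draws in [-magnitude, magnitude] per
    illumination (magnitude ≤ π), deterministic under ``seed``."""
    if not (0 <= magnitude <= np.pi):
        raise ValueError(f"drift magnitude must lie in [0, π], got {magnitude}")
    rng = np.random.default_rng(seed)
    g = rng.uniform(-magnitude, magnitude, size=len(illums))
    return DriftPhase(illuminations=illums, g=g, magnitude=magnitude, seed=seed)


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

def _check_simulation_inputs(
    obj: ObjectField,
    pupil_in: Pupil,
    pupil_out: Pupil,
    drift: DriftPhase | None,
    illums: IlluminationSet,
) -> NDArray:
    grid = obj.grid
    for other, name in ((pupil_in.grid, "input pupil"), (pupil_out.grid, "output pupil"),
                        (illums.grid, "illumination set")):
        if not grid.compatible(other):
            raise ValueError(f"{name} grid does not match the object grid")
    in_mask = pupil_in.mask
    iy, ix = illums.array_indices
    if not in_mask[iy, ix].all():
        raise ValueError("some illuminations lie outside the input-pupil support")
    if drift is None:
        return np.zeros(len(illums))
    if len(drift.illuminations) != len(illums):
        raise ValueError("drift vector does not match the illumination set")
    return np.asarray(drift.g, dtype=float)


def _build_dataset(
    obj: ObjectField,
    output_transfer: NDArray,
    input_phases: NDArray,
    illums: IlluminationSet,
    configuration: str,
    na_ill: float,
    na_col: float,
) -> TransmissionDataset:
    """Shared assembly: spectra[j] = output_transfer · shift_j(O) · input_phases[j]."""
    O = obj.spectrum
    n = obj.grid.n
    N = len(illums)
    spectra = np.empty((N, n, n), dtype=np.complex128)
    kv = illums.kvecs
    for j in range(N):
        p, q = int(kv[j, 0]), int(kv[j, 1])
        shifted = np.roll(O, shift=(q, p), axis=(0, 1))
        spectra[j] = output_transfer * shifted * input_phases[j]
    return TransmissionDataset(
        grid=obj.grid,
        illuminations=illums,
        spectra=spectra,
        configuration=configuration,
        na_ill=na_ill,
        na_col=na_col,
    )


def simulate_dataset(
    obj: ObjectField,
    pupil_in: Pupil,
    pupil_out: Pupil,
    drift: DriftPhase | None,
    illums: IlluminationSet,
) -> TransmissionDataset:
    """Angle-scanned dataset in the ordinary geometry (target at the sample
    plane): E_o(k_o; k_i) = P_o^a(k_o)·O(k_o-k_i)·P_i^a(k_i)·exp(i g(k_i)),
    zero outside the collection support."""
    g = _check_simulation_inputs(obj, pupil_in, pupil_out, drift, illums)
    iy, ix = illums.array_indices
    in_factor = pupil_in.transfer[iy, ix] * np.exp(1j * g)
    return _build_dataset(
        obj, pupil_out.transfer, in_factor, illums,
        SAMPLE_PLANE, illums.na_ill, pupil_out.na,
    )


def simulate_conjugate_dataset(
    test_obj: ObjectField,
    pupil_in: Pupil,
    pupil_out: Pupil,
    drift2: DriftPhase | None,
    illums: IlluminationSet,
) -> TransmissionDataset:
    """Dataset for the second geometry (test target at the conjugate image
    plane before the input lens): both pupils act after the object, so
    E'(k_o; k_i) = [P_o^a·P_i^a](k_o)·O'(k_o-k_i)·exp(i g'(k_i)) — no
    input-side aberration, a product pupil on the output side."""
    g = _check_simulation_inputs(test_obj, pupil_in, pupil_out, drift2, illums)
    combined = pupil_out.transfer * pupil_in.transfer
    in_factor = np.exp(1j * g)
    na_col = min(pupil_in.na, pupil_out.na)
    return _build_dataset(
        test_obj, combined, in_factor, illums,
        CONJUGATE_PLANE, illums.na_ill, na_col,
    )


# --------------------------------------------------------------------------
# off-axis interferograms
# --------------------------------------------------------------------------

def synthesize_hologram(
    field: NDArray,
    grid: Grid,
    carrier: tuple[int, int],
    ref_amplitude: float,
    well_depth: float | None = None,
    seed: int | None = None,
) -> Interferogram:
    """Off-axis interferogram I(r) = |E_S(r) + ref·exp(i k_R·r)|² with a
    tilted plane-wave reference at lattice carrier ``k_R = carrier·dk``.

    Requires |k_R| plus the field's band radius to stay within Nyquist;
    warns when the off-axis separation condition |k_R| > 3·band_radius is
    violated (the demodulation terms would alias).  Optional shot noise:
    ``well_depth`` scales the frame so its peak collects that many photons,
    then draws Poisson counts (deterministic under ``seed``).
    """
    field = np.asarray(field, dtype=np.complex128)
    n = grid.n
    if field.shape != (n, n):
        raise ValueError(f"field shape {field.shape} != grid {(n, n)}")
    p, q = int(carrier[0]), int(carrier[1])
    c_lat = math.hypot(p, q)
    spec = fft2c(field)
    mag = np.abs(spec)
    nz = mag > 1e-12 * (mag.max() if mag.max() > 0 else 1.0)
    if nz.any():
        P, Q = grid.lattice_axes()
        band_lat = float(np.hypot(P[nz], Q[nz]).max())
    else:
        band_lat = 0.0
    if c_lat + band_lat > grid.n // 2:
        raise SizingError(
            f"carrier |k_R| = {c_lat:.1f} lattice units plus band radius "
            f"{band_lat:.1f} exceeds Nyquist {grid.n // 2}"
        )
    if c_lat <= 3.0 * band_lat:
        warnings.warn(
            f"off-axis separation violated: |k_R| = {c_lat:.1f} lattice units "
            f"<= 3 × band radius {band_lat:.1f}; demodulation terms will alias",
            stacklevel=2,
        )
    X, Y = grid.x_maps()
    ref = ref_amplitude * np.exp(1j * (p * grid.dk * X + q * grid.dk * Y))
    intensity = np.abs(field + ref) ** 2
    if well_depth is not None:
        rng = np.random.default_rng(seed)
        peak = intensity.max()
        if peak > 0:
            photons = rng.poisson(intensity / peak * well_depth)
            intensity = photons.astype(float) * (peak / well_depth)
    return Interferogram(
        grid=grid, intensity=intensity, carrier=(p, q), ref_amplitude=float(ref_amplitude)
    )
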