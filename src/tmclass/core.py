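"""Sampling grids, pupils and angle-scanned transmission datasets.

Every module in the package shares one discrete sampling contract, fixed
here once:

* real-space pixels sit at ``x = (i - n/2)·dx`` with ``dx = fov/n``,
  ``i = 0 .. n-1`` (and likewise in y);
* the spatial-frequency lattice is ``k = (p, q)·dk`` with integer
  ``p, q ∈ [-n/2, n/2)`` and ``dk = 2π/fov`` exactly;
* forward/inverse transforms are the unitary centered pair
  :func:`fft2c` / :func:`ifft2c`, so Parseval-based intensity
  comparisons are exact.

Arrays are indexed ``[iy, ix]`` with ``iy = q + n/2`` and
``ix = p + n/2``; a lattice point ``(p, q)`` therefore addresses
``array[q + n//2, p + n//2]``.

A pupil is a thin phase screen: unit amplitude on the closed disk
``|k| ≤ na·k0`` (``k0 = 2π/λ``), zero outside, with a phase map (the
aberration) stored only on the support.  Constructors reject apertures
whose cutoff exceeds the grid Nyquist rather than silently truncating,
because the synthetic-aperture sums need the full support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "SizingError",
    "Grid",
    "Pupil",
    "ObjectField",
    "IlluminationSet",
    "TransmissionDataset",
    "TransmissionMatrix",
    "make_grid",
    "make_ideal_pupil",
    "enumerate_illuminations",
    "dataset_as_matrix",
    "matrix_as_dataset",
    "fft2c",
    "ifft2c",
    "wrap_phase",
    "support_mask",
    "fit_wrapped_tilt",
]

SAMPLE_PLANE = "sample_plane"
CONJUGATE_PLANE = "conjugate_plane"
_CONFIGURATIONS = (SAMPLE_PLANE, CONJUGATE_PLANE)


class SizingError(ValueError):
    """A grid/aperture combination violates the sampling contract."""


def wrap_phase(x: NDArray | float) -> NDArray | float:
    """Wrap phase(s) into (-π, π]."""
    return np.angle(np.exp(1j * np.asarray(x, dtype=float)))


def fit_wrapped_tilt(values: NDArray, kvecs: NDArray) -> NDArray:
    """Tilt (radians per lattice step, shape (2,) for (p, q)) of a phase map
    sampled on scattered lattice points, estimated as the mean *wrapped*
    nearest-neighbour difference per axis.  Robust to 2π ambiguities in
    steep maps, where a least-squares plane fit on wrapped values fails."""
    tilt = np.zeros(2)
    keys = {(int(p), int(q)): v for (p, q), v in zip(np.asarray(kvecs), np.asarray(values))}
    for axis, step in ((0, (1, 0)), (1, (0, 1))):
        diffs = [
            wrap_phase(keys[(p + step[0], q + step[1])] - keys[(p, q)])
            for (p, q) in keys
            if (p + step[0], q + step[1]) in keys
        ]
        if diffs:
            tilt[axis] = float(np.mean(diffs))
    return tilt


def fft2c(field: NDArray) -> NDArray:
    """Centered unitary forward transform (real space -> frequency lattice)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field), norm="ortho"))


def ifft2c(spectrum: NDArray) -> NDArray:
    """Centered unitary inverse transform (frequency lattice -> real space)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spectrum), norm="ortho"))


@dataclass(frozen=True)
class Grid:
    """Square sampling grid: field of view ``fov`` (µm), ``n`` pixels per
    side, vacuum wavelength ``wavelength`` (µm)."""

    fov: float
    n: int
    wavelength: float

    def __post_init__(self) -> None:
        if not (self.fov > 0):
            raise SizingError(f"field of view must be positive, got {self.fov}")
        if not (self.wavelength > 0):
            raise SizingError(f"wavelength must be positive, got {self.wavelength}")
        n = self.n
        if not (isinstance(n, (int, np.integer)) and n >= 16 and n % 2 == 0):
            raise SizingError(f"n must be an even integer >= 16, got {n!r}")
        object.__setattr__(self, "n", int(n))

    # -- sampling quantities -------------------------------------------------
    @property
    def dk(self) -> float:
        """Frequency spacing 2π/fov (rad/µm)."""
        return 2.0 * np.pi / self.fov

    @property
    def dx(self) -> float:
        """Pixel pitch fov/n (µm)."""
        return self.fov / self.n

    @property
    def k0(self) -> float:
        """Free-space wavenumber 2π/λ (rad/µm)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def nyquist(self) -> float:
        """Largest representable |k| along an axis, (n/2)·dk (rad/µm)."""
        return (self.n // 2) * self.dk

    @property
    def center(self) -> int:
        return self.n // 2

    # -- coordinate maps -----------------------------------------------------
    def lattice_axes(self) -> tuple[NDArray, NDArray]:
        """Integer lattice coordinates ``(P, Q)`` as 2-D maps, array order
        ``[iy, ix]`` so that ``P`` varies along the last axis."""
        idx = np.arange(self.n) - self.center
        P, Q = np.meshgrid(idx, idx, indexing="xy")
        return P, Q

    def k_maps(self) -> tuple[NDArray, NDArray]:
        P, Q = self.lattice_axes()
        return P * self.dk, Q * self.dk

    def k_radius(self) -> NDArray:
        kx, ky = self.k_maps()
        return np.hypot(kx, ky)

    def x_maps(self) -> tuple[NDArray, NDArray]:
        P, Q = self.lattice_axes()
        return P * self.dx, Q * self.dx

    def compatible(self, other: "Grid") -> bool:
        return (
            self.n == other.n
            and np.isclose(self.fov, other.fov)
            and np.isclose(self.wavelength, other.wavelength)
        )


def make_grid(fov: float, n: int, wavelength: float) -> Grid:
    """Construct a :class:`Grid`; rejects odd/undersized ``n`` and
    non-positive lengths with a :class:`SizingError`."""
    return Grid(fov=fov, n=n, wavelength=wavelength)


def support_mask(grid: Grid, na: float) -> NDArray[np.bool_]:
    """Boolean map of the closed aperture disk ``|k| ≤ na·k0``.

    The comparison is done on squared integer lattice radii against the
    squared cutoff in lattice units, so membership is deterministic and
    reproducible by an exhaustive scan.
    """
    P, Q = grid.lattice_axes()
    cut_sq = (na * grid.k0 / grid.dk) ** 2
    return (P.astype(np.int64) ** 2 + Q.astype(np.int64) ** 2) <= cut_sq


def _check_aperture(grid: Grid, na: float, what: str = "aperture") -> None:
    if not (na > 0):
        raise SizingError(f"{what} NA must be positive, got {na}")
    if na * grid.k0 > grid.nyquist * (1 + 1e-12):
        raise SizingError(
            f"{what} cutoff na·k0 = {na * grid.k0:.4g} rad/µm exceeds the grid "
            f"Nyquist {grid.nyquist:.4g} rad/µm; enlarge n or shrink fov"
        )


@dataclass(frozen=True)
class Pupil:
    """Unit-amplitude pupil with NA cutoff ``na`` and a phase map (radians)
    defined on the support; the stored phase is forced to zero off-support
    and is never read there."""

    grid: Grid
    na: float
    phase: NDArray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_aperture(self.grid, self.na, "pupil")
        n = self.grid.n
        mask = support_mask(self.grid, self.na)
        if self.phase is None:
            phase = np.zeros((n, n), dtype=float)
        else:
            phase = np.asarray(self.phase, dtype=float)
            if phase.shape != (n, n):
                raise ValueError(f"phase shape {phase.shape} != grid {(n, n)}")
            phase = np.where(mask, phase, 0.0)
        phase.setflags(write=False)
        object.__setattr__(self, "phase", phase)

    @property
    def mask(self) -> NDArray[np.bool_]:
        return support_mask(self.grid, self.na)

    @property
    def transfer(self) -> NDArray[np.complex128]:
        """Complex transfer function: exp(iφ) on support, 0 outside."""
        m = self.mask
        return np.where(m, np.exp(1j * self.phase), 0.0 + 0.0j)

    @property
    def support_count(self) -> int:
        return int(self.mask.sum())


def make_ideal_pupil(grid: Grid, na: float) -> Pupil:
    """Aberration-free pupil: phase ≡ 0 on the closed disk |k| ≤ na·k0."""
    return Pupil(grid=grid, na=na)


@dataclass
class ObjectField:
    """Complex transmittance of a thin object on the real-space pixel grid.

    ``spectrum`` is the exact unitary transform pair of ``transmittance``
    under the package convention.
    """

    grid: Grid
    transmittance: NDArray

    def __post_init__(self) -> None:
        t = np.asarray(self.transmittance, dtype=np.complex128)
        n = self.grid.n
        if t.shape != (n, n):
            raise ValueError(f"transmittance shape {t.shape} != grid {(n, n)}")
        self.transmittance = t

    @property
    def spectrum(self) -> NDArray[np.complex128]:
        return fft2c(self.transmittance)

    @classmethod
    def from_spectrum(cls, grid: Grid, spectrum: NDArray) -> "ObjectField":
        return cls(grid=grid, transmittance=ifft2c(np.asarray(spectrum, dtype=np.complex128)))


@dataclass(frozen=True)
class IlluminationSet:
    """Ordered set of illumination wavevectors on the frequency lattice.

    ``kvecs`` holds integer lattice pairs ``(p, q)``; the order is
    deterministic row-major by ``(q, p)``.  Physical wavevectors are
    ``kvecs·dk``.
    """

    grid: Grid
    na_ill: float
    kvecs: NDArray  # (N, 2) int64, columns (p, q)

    def __post_init__(self) -> None:
        kv = np.asarray(self.kvecs, dtype=np.int64)
        if kv.ndim != 2 or kv.shape[1] != 2:
            raise ValueError("kvecs must have shape (N, 2)")
        kv.setflags(write=False)
        object.__setattr__(self, "kvecs", kv)

    def __len__(self) -> int:
        return int(self.kvecs.shape[0])

    @property
    def array_indices(self) -> tuple[NDArray, NDArray]:
        """(iy, ix) index arrays addressing each k in an (n, n) map."""
        c = self.grid.center
        return self.kvecs[:, 1] + c, self.kvecs[:, 0] + c

    @property
    def origin_index(self) -> int:
        """Position of k = (0, 0) in the enumeration (raises if absent)."""
        hits = np.flatnonzero((self.kvecs == 0).all(axis=1))
        if hits.size != 1:
            raise ValueError("illumination set does not contain the origin")
        return int(hits[0])

    def k_phys(self) -> NDArray:
        return self.kvecs.astype(float) * self.grid.dk


def enumerate_illuminations(grid: Grid, na_ill: float) -> IlluminationSet:
    """Every lattice point inside the closed disk |k| ≤ na_ill·k0, ordered
    row-major by (q, p).  This is the full set of orthogonal free modes of
    the field of view within the illumination aperture."""
    _check_aperture(grid, na_ill, "illumination")
    mask = support_mask(grid, na_ill)
    iy, ix = np.nonzero(mask)  # row-major: sorted by iy (=q) then ix (=p)
    c = grid.center
    kvecs = np.stack([ix - c, iy - c], axis=1)
    return IlluminationSet(grid=grid, na_ill=na_ill, kvecs=kvecs)


@dataclass
class TransmissionDataset:
    """Angle-scanned complex spectra E_o(k_o; k_i), one (n, n) spectrum per
    illumination, each zero outside the collection-pupil support.

    ``configuration`` records which measurement geometry produced the data:
    ``"sample_plane"`` (target between the two lenses) or
    ``"conjugate_plane"`` (test target at the conjugate image plane before
    the input lens, used to isolate the input aberration).
    """

    grid: Grid
    illuminations: IlluminationSet
    spectra: NDArray  # (N, n, n) complex128
    configuration: str
    na_ill: float
    na_col: float
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        s = np.asarray(self.spectra, dtype=np.complex128)
        n = self.grid.n
        if s.shape != (len(self.illuminations), n, n):
            raise ValueError(
                f"spectra shape {s.shape} != ({len(self.illuminations)}, {n}, {n})"
            )
        if self.configuration not in _CONFIGURATIONS:
            raise ValueError(
                f"configuration must be one of {_CONFIGURATIONS}, got {self.configuration!r}"
            )
        self.spectra = s

    @property
    def out_mask(self) -> NDArray[np.bool_]:
        return support_mask(self.grid, self.na_col)

    def validate_support(self, atol: float = 0.0) -> None:
        """Assert every spectrum vanishes outside the output-pupil support."""
        off = ~self.out_mask
        worst = float(np.abs(self.spectra[:, off]).max()) if off.any() else 0.0
        if worst > atol:
            raise ValueError(
                f"spectra leak outside the collection support (max |E| = {worst:g})"
            )


@dataclass
class TransmissionMatrix:
    """Matrix view T[k_o, k_i] of a :class:`TransmissionDataset`: rows are the
    output-lattice points within the collection cutoff (row-major by (q, p)),
    columns the illumination points."""

    grid: Grid
    rows: NDArray  # (M, 2) int lattice points (p, q)
    cols: NDArray  # (N, 2) int lattice points (p, q)
    values: NDArray  # (M, N) complex128
    configuration: str
    na_ill: float
    na_col: float
    provenance: str = "matrix"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != (self.rows.shape[0], self.cols.shape[0]):
            raise ValueError("values shape inconsistent with rows/cols")


def dataset_as_matrix(dataset: TransmissionDataset) -> TransmissionMatrix:
    """Lossless matrix view of a dataset (used by the phase-conjugation step)."""
    if len(dataset.illuminations) == 0:
        raise ValueError("dataset has no illuminations")
    out_pts = enumerate_illuminations(dataset.grid, dataset.na_col)
    iy, ix = out_pts.array_indices
    values = dataset.spectra[:, iy, ix].T  # (M, N)
    return TransmissionMatrix(
        grid=dataset.grid,
        rows=out_pts.kvecs,
        cols=dataset.illuminations.kvecs,
        values=values,
        configuration=dataset.configuration,
        na_ill=dataset.na_ill,
        na_col=dataset.na_col,
        provenance=dataset.provenance,
    )


def matrix_as_dataset(tm: TransmissionMatrix) -> TransmissionDataset:
    """Inverse of :func:`dataset_as_matrix` (entries off the stored rows are
    zero, exactly as the dataset invariant requires)."""
    grid = tm.grid
    n = grid.n
    c = grid.center
    illums = IlluminationSet(grid=grid, na_ill=tm.na_ill, kvecs=tm.cols)
    spectra = np.zeros((tm.cols.shape[0], n, n), dtype=np.complex128)
    iy = tm.rows[:, 1] + c
    ix = tm.rows[:, 0] + c
    spectra[:, iy, ix] = tm.values.T
    return TransmissionDataset(
        grid=grid,
        illuminations=illums,
        spectra=spectra,
        configuration=tm.configuration,
        na_ill=tm.na_ill,
        na_col=tm.na_col,
        provenance=tm.provenance,
    )
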