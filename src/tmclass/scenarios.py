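"""Reference simulation scenarios used throughout testing and validation.

``standard_scenario`` is the package's canonical stress case: a 1.2 NA
pair of aberrated large-aperture lenses at λ = 785 nm imaging a 36-spoke
binary Siemens star, with radial pupil aberrations reaching 6 rad at each
pupil edge (steepest terms concentrated in the outer pupil, as condenser
lenses exhibit) and uniform per-illumination phase drift in ±π.  The grid
is 128² over a 10 µm field of view, which keeps the 1.2 NA cutoff well
inside Nyquist and enumerates ≈ 7×10² illumination angles — every
orthogonal free mode of the field of view within the illumination
aperture — so a full solver run stays in the tens of seconds.

``conjugate_scenario`` produces the companion measurement with a test
target at the conjugate image plane before the input lens (no input-side
aberration, product pupil on the output side, its own drift realization),
which the two-configuration procedure needs to separate φ_i from the
drift.  ``small_scenario`` is a reduced variant for cheap paired runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Grid, IlluminationSet, ObjectField, Pupil, TransmissionDataset, make_grid, enumerate_illuminations
from .synth import (
    AberrationPhase,
    DriftPhase,
    make_condenser_aberration,
    make_phase_blobs,
    make_pupil,
    make_siemens_star,
    sample_drift,
    simulate_conjugate_dataset,
    simulate_dataset,
)

__all__ = ["Scenario", "standard_scenario", "conjugate_scenario", "small_scenario"]

# radial polynomial coefficients (rad at the pupil edge per term); each set
# sums to 6 rad at ρ = 1 with the steepest contribution beyond ~0.8 ρ
INPUT_RADIAL = (1.0, 2.0, 3.0)
OUTPUT_RADIAL = (0.5, 1.5, 4.0)


@dataclass
class Scenario:
    """Bundle of one simulated measurement with its ground truth."""

    grid: Grid
    illuminations: IlluminationSet
    obj: ObjectField
    pupil_in: Pupil
    pupil_out: Pupil
    aberration_in: AberrationPhase
    aberration_out: AberrationPhase
    drift: DriftPhase
    dataset: TransmissionDataset
    n_spokes: int | None = None
    r_outer: float | None = None

    @property
    def phi_i(self) -> np.ndarray:
        return self.aberration_in.phase

    @property
    def phi_o(self) -> np.ndarray:
        return self.aberration_out.phase

    def phi_i_at_illums(self) -> np.ndarray:
        iy, ix = self.illuminations.array_indices
        return self.phi_i[iy, ix]


def standard_scenario(
    seed: int = 0,
    n: int = 128,
    fov: float = 10.0,
    wavelength: float = 0.785,
    na_ill: float = 1.2,
    na_col: float = 1.2,
    n_spokes: int = 36,
    r_outer: float = 4.5,
    input_radial: tuple = INPUT_RADIAL,
    output_radial: tuple = OUTPUT_RADIAL,
    drift_magnitude: float = np.pi,
) -> Scenario:
    """Siemens star between two aberrated 1.2 NA lenses with full drift."""
    grid = make_grid(fov, n, wavelength)
    illums = enumerate_illuminations(grid, na_ill)
    obj = make_siemens_star(grid, n_spokes, r_outer)
    ab_in = make_condenser_aberration(grid, na_ill, input_radial)
    ab_out = make_condenser_aberration(grid, na_col, output_radial)
    pupil_in = make_pupil(grid, na_ill, ab_in)
    pupil_out = make_pupil(grid, na_col, ab_out)
    drift = sample_drift(illums, drift_magnitude, seed=seed)
    dataset = simulate_dataset(obj, pupil_in, pupil_out, drift, illums)
    return Scenario(
        grid=grid, illuminations=illums, obj=obj,
        pupil_in=pupil_in, pupil_out=pupil_out,
        aberration_in=ab_in, aberration_out=ab_out,
        drift=drift, dataset=dataset, n_spokes=n_spokes, r_outer=r_outer,
    )


def conjugate_scenario(base: Scenario, seed: int = 1, n_spokes: int = 24) -> Scenario:
    """Companion measurement for input-aberration separation: a second test
    star imaged through the same two lenses with the target at the
    conjugate image plane and an independent drift realization."""
    grid = base.grid
    illums = base.illuminations
    r_outer = base.r_outer if base.r_outer is not None else 0.45 * grid.fov
    obj = make_siemens_star(grid, n_spokes, r_outer)
    drift2 = sample_drift(illums, base.drift.magnitude, seed=seed)
    dataset = simulate_conjugate_dataset(obj, base.pupil_in, base.pupil_out, drift2, illums)
    return Scenario(
        grid=grid, illuminations=illums, obj=obj,
        pupil_in=base.pupil_in, pupil_out=base.pupil_out,
        aberration_in=base.aberration_in, aberration_out=base.aberration_out,
        drift=drift2, dataset=dataset, n_spokes=n_spokes, r_outer=r_outer,
    )


def small_scenario(
    seed: int = 0,
    n: int = 64,
    fov: float = 6.0,
    object_kind: str = "star",
    drift_magnitude: float = np.pi,
    **kwargs,
) -> Scenario:
    """Reduced-size variant (64² grid, 6 µm field, ≈ 2.6×10² illuminations)
    for paired runs and property sweeps; ``object_kind`` may be ``"star"``,
    ``"blobs"`` or ``"point"`` (uniform spectrum)."""
    if object_kind == "star":
        return standard_scenario(
            seed=seed, n=n, fov=fov, n_spokes=16, r_outer=0.45 * fov,
            drift_magnitude=drift_magnitude, **kwargs,
        )
    sc = standard_scenario(
        seed=seed, n=n, fov=fov, n_spokes=16, r_outer=0.45 * fov,
        drift_magnitude=drift_magnitude, **kwargs,
    )
    if object_kind == "blobs":
        obj = make_phase_blobs(sc.grid, n_blobs=12, max_phase=1.5, seed=seed + 7)
    elif object_kind == "point":
        t = np.zeros((sc.grid.n, sc.grid.n), dtype=complex)
        t[sc.grid.center, sc.grid.center] = 1.0
        obj = ObjectField(grid=sc.grid, transmittance=t)
    else:
        raise ValueError(f"unknown object_kind {object_kind!r}")
    dataset = simulate_dataset(obj, sc.pupil_in, sc.pupil_out, sc.drift, sc.illuminations)
    return Scenario(
        grid=sc.grid, illuminations=sc.illuminations, obj=obj,
        pupil_in=sc.pupil_in, pupil_out=sc.pupil_out,
        aberration_in=sc.aberration_in, aberration_out=sc.aberration_out,
        drift=sc.drift, dataset=dataset,
    )
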