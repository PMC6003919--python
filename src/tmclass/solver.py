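"""Synthetic-aperture assembly and the iterative CLASS solver.

The synthetic-aperture spectrum coherently sums all transmitted-field
entries sharing the same momentum difference Δk = k_o - k_i,

    E_SA(Δk) = Σ_{k_i} E_o(k_i + Δk; k_i) · e^{-iθ_i(k_i)} · e^{-iθ_o(k_i+Δk)},

and the solver searches the per-angle correction phases θ_i (input pupil,
entangled with the acquisition drift) and θ_o (output pupil) that maximize
the intensity of the synthetic-aperture spectrum.  The maximization, and
the monitored ``intensity_trace``, run over the scattered components
(Δk ≠ 0): the bright-field bin Δk = 0 constrains only the *sum*
θ_i(k) + θ_o(k) and is blind to how the aberration splits between the two
pupils, and for transmissive specimens its weight would dominate the
correlations and stall the separation.  Each half-iteration aligns one
side:

* input step — for every k_i, the increment is the argument of the scalar
  product between that illumination's corrected, demodulated spectrum and
  the current E_SA; accumulating it rotates all contributions toward a
  common phase, which can only raise the total intensity;
* output step — the same rule applied to the numerically phase-conjugated
  dataset (entries conjugated, illumination/detection roles swapped), which
  turns the output pupil into an input.  Conjugation flips the sign of the
  per-angle phases, so the increments enter θ_o negated; it also moves the
  drift factor onto the (new) output index, which is why the recovered θ_o
  decouples from the drift.

Corrections are applied as e^{-iθ}; the accumulated maps therefore converge
toward +(φ_i + g) and +φ_o.  Two gauge freedoms leave the objective
unchanged — a piston per map and the paired tilt (+a·k on θ_i, -a·k on θ_o,
a rigid image translation) — and :func:`remove_gauge` quotients them out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import NDArray
from scipy.signal import fftconvolve

from .core import (
    Grid,
    IlluminationSet,
    TransmissionDataset,
    enumerate_illuminations,
    fit_wrapped_tilt,
    ifft2c,
    support_mask,
)

__all__ = [
    "CorrectionState",
    "SASpectrum",
    "synth_aperture",
    "total_intensity",
    "scattered_intensity",
    "reconstruct_image",
    "input_step",
    "phase_conjugate",
    "output_step",
    "run_class",
    "remove_gauge",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrectionState:
    """Accumulated correction phases and the intensity trace of the run.

    ``theta_i`` is one value per illumination (order of the dataset's
    illumination set); ``theta_o`` is an (n, n) map, zero off the
    collection support.  ``intensity_trace`` records the solver objective
    — the scattered-field (Δk ≠ 0) SA intensity — starting with the
    uncorrected value and gaining one entry per completed half-iteration;
    it is non-decreasing to solver tolerance.
    """

    grid: Grid
    illuminations: IlluminationSet
    na_col: float
    theta_i: NDArray
    theta_o: NDArray
    intensity_trace: list
    n_iter: int = 0
    converged: bool = False
    gauge: dict | None = None

    @classmethod
    def zeros(cls, dataset: TransmissionDataset) -> "CorrectionState":
        n = dataset.grid.n
        return cls(
            grid=dataset.grid,
            illuminations=dataset.illuminations,
            na_col=dataset.na_col,
            theta_i=np.zeros(len(dataset.illuminations)),
            theta_o=np.zeros((n, n)),
            intensity_trace=[],
        )

    @property
    def out_mask(self) -> NDArray[np.bool_]:
        return support_mask(self.grid, self.na_col)


@dataclass
class SASpectrum:
    """Synthetic-aperture spectrum over the Δk lattice plus the integer
    count of contributing (k_i, k_o) pairs per Δk (zero values where the
    weight is zero)."""

    grid: Grid
    values: NDArray
    weights: NDArray


def _pair_weights(dataset: TransmissionDataset) -> NDArray[np.int64]:
    """weights(Δk) = #{k_i : k_i in illumination set, k_i + Δk in collection
    support}, computed as the cross-correlation of the two support masks."""
    grid = dataset.grid
    n = grid.n
    in_map = np.zeros((n, n))
    iy, ix = dataset.illuminations.array_indices
    in_map[iy, ix] = 1.0
    out_map = dataset.out_mask.astype(float)
    corr = fftconvolve(out_map, in_map[::-1, ::-1], mode="same")
    return np.rint(np.clip(corr, 0, None)).astype(np.int64)


def _corrected_stack(
    dataset: TransmissionDataset, theta_i: NDArray, theta_o: NDArray
) -> NDArray[np.complex128]:
    """Demodulated, corrected spectra: stack[j](Δk) = E_o(k_j + Δk; k_j)
    · e^{-iθ_o(k_j+Δk)} · e^{-iθ_i(k_j)}  (each spectrum translated so its
    own illumination sits at the origin)."""
    n = dataset.grid.n
    kv = dataset.illuminations.kvecs
    N = kv.shape[0]
    to_factor = np.exp(-1j * theta_o)
    stack = np.empty((N, n, n), dtype=np.complex128)
    for j in range(N):
        p, q = int(kv[j, 0]), int(kv[j, 1])
        stack[j] = np.roll(dataset.spectra[j] * to_factor, shift=(-q, -p), axis=(0, 1))
    stack *= np.exp(-1j * theta_i)[:, None, None]
    return stack


def synth_aperture(dataset: TransmissionDataset, state: CorrectionState | None = None) -> SASpectrum:
    """Coherent equal-Δk summation of the (corrected) dataset."""
    if state is None:
        state = CorrectionState.zeros(dataset)
    if len(state.theta_i) != len(dataset.illuminations):
        raise ValueError("correction state does not match the dataset's illuminations")
    stack = _corrected_stack(dataset, state.theta_i, state.theta_o)
    values = stack.sum(axis=0)
    return SASpectrum(grid=dataset.grid, values=values, weights=_pair_weights(dataset))


def total_intensity(sa: SASpectrum) -> float:
    """Total synthetic-aperture intensity Σ_Δk |E_SA(Δk)|² over every bin
    (by Parseval also the image-domain total intensity)."""
    return float(np.sum(np.abs(sa.values) ** 2))


def scattered_intensity(sa: SASpectrum) -> float:
    """Solver objective: SA intensity restricted to the scattered
    components, Σ_{Δk ≠ 0} |E_SA(Δk)|²."""
    c = sa.values.shape[0] // 2
    return float(np.sum(np.abs(sa.values) ** 2) - np.abs(sa.values[c, c]) ** 2)


def _stack_objective(stack: NDArray, inc: NDArray) -> float:
    esa = np.tensordot(np.exp(-1j * inc), stack, axes=(0, 0))
    c = esa.shape[0] // 2
    return float(np.sum(np.abs(esa) ** 2) - np.abs(esa[c, c]) ** 2)


def reconstruct_image(sa: SASpectrum, equalize: bool = False) -> NDArray:
    """Intensity image of a synthetic-aperture spectrum.

    With ``equalize=True`` the spectrum is first divided by the pair-count
    weights, removing the triangular taper of the (k_i, k_o) coverage so
    the passband transfer is flat up to the hard cutoff at
    (NA_ill + NA_col)·k0 — the unbiased object-spectrum estimate used for
    resolution analysis.  The raw sum (default) keeps the natural taper,
    which apodizes ringing."""
    v = sa.values
    if equalize:
        v = np.where(sa.weights > 0, v / np.maximum(sa.weights, 1), 0.0)
    return np.abs(ifft2c(v)) ** 2


def _correlation_increments(
    stack: NDArray, leave_one_out: bool
) -> tuple[NDArray, NDArray]:
    """Per-illumination correlation against the aggregate SA spectrum and
    its phase; exactly-zero correlations get a zero increment.

    The Δk = 0 bin is excluded from the correlation: that bin is the
    bright-field term, which constrains only the *sum* of the input and
    output phases at the same wavevector and so carries no information on
    how to split them.  For transmissive specimens its weight dominates the
    spectrum and would lock the two half-steps into trading the combined
    aberration back and forth instead of separating it; dropping it
    restores convergence in a handful of iterations.  The monitored
    objective (:func:`scattered_intensity`) excludes the same bin, and each
    half-step is non-decreasing in it.
    """
    esa = stack.sum(axis=0)
    corr = np.einsum("jyx,yx->j", stack, np.conj(esa))
    c = stack.shape[1] // 2
    corr = corr - stack[:, c, c] * np.conj(esa[c, c])
    if leave_one_out:
        corr = corr - np.sum(np.abs(stack) ** 2, axis=(1, 2))
        corr = corr + np.abs(stack[:, c, c]) ** 2
    inc = np.angle(corr)
    dead = corr == 0
    if dead.any():
        logger.warning(
            "%d illumination(s) have zero correlation with the synthetic "
            "aperture; their increments are forced to 0",
            int(dead.sum()),
        )
        inc = np.where(dead, 0.0, inc)
    return inc, esa


def input_step(
    dataset: TransmissionDataset,
    state: CorrectionState,
    leave_one_out: bool = False,
) -> CorrectionState:
    """One input half-iteration: accumulate per-illumination phase increments
    arg⟨Ẽ_j, E_SA⟩ into θ_i and append the post-update total intensity."""
    if len(dataset.illuminations) == 0:
        raise ValueError("dataset has no illuminations")
    stack = _corrected_stack(dataset, state.theta_i, state.theta_o)
    inc, _ = _correlation_increments(stack, leave_one_out)
    intensity = _stack_objective(stack, inc)
    return replace(
        state,
        theta_i=state.theta_i + inc,
        theta_o=state.theta_o.copy(),
        intensity_trace=state.intensity_trace + [intensity],
    )


def phase_conjugate(dataset: TransmissionDataset, state: CorrectionState) -> TransmissionDataset:
    """Numerically phase-conjugated view of the dataset: the accumulated
    input correction is applied, every entry is conjugated, and the
    illumination/detection roles are transposed (the former collection
    support becomes the illumination set).  Equivalent to propagating the
    corrected light backwards through the system."""
    grid = dataset.grid
    n = grid.n
    out_pts = enumerate_illuminations(grid, dataset.na_col)
    oy, ox = out_pts.array_indices
    col_phase = np.exp(-1j * state.theta_i)
    vals = dataset.spectra[:, oy, ox] * col_phase[:, None]  # (N_ill, M)
    new_spectra = np.zeros((len(out_pts), n, n), dtype=np.complex128)
    iy, ix = dataset.illuminations.array_indices
    new_spectra[:, iy, ix] = np.conj(vals).T
    return TransmissionDataset(
        grid=grid,
        illuminations=out_pts,
        spectra=new_spectra,
        configuration=dataset.configuration,
        na_ill=dataset.na_col,
        na_col=dataset.na_ill,
        provenance="phase_conjugate",
    )


def output_step(
    dataset: TransmissionDataset,
    state: CorrectionState,
    leave_one_out: bool = False,
) -> CorrectionState:
    """One output half-iteration: the input-step correlation rule on the
    phase-conjugated view.  Conjugation negates every phase, so the
    increments are subtracted from θ_o at the conjugated-view illumination
    points (the collection-support lattice); the drift factor sits on the
    conjugated view's output index and drops out of the per-angle
    correlations, decoupling θ_o from the drift."""
    pc = phase_conjugate(dataset, state)
    oy, ox = pc.illuminations.array_indices
    # current output correction in the conjugated view: conj() flipped
    # e^{-iθ_o} into e^{+iθ_o}, realized here as a per-illumination phase.
    theta_pc = -state.theta_o[oy, ox]
    stack = _corrected_stack(pc, theta_pc, np.zeros_like(state.theta_o))
    inc_pc, _ = _correlation_increments(stack, leave_one_out)
    theta_o_new = state.theta_o.copy()
    theta_o_new[oy, ox] = theta_o_new[oy, ox] - inc_pc
    intensity = _stack_objective(stack, inc_pc)
    return replace(
        state,
        theta_i=state.theta_i.copy(),
        theta_o=theta_o_new,
        intensity_trace=state.intensity_trace + [intensity],
    )


def remove_gauge(state: CorrectionState) -> CorrectionState:
    """Quotient the gauge freedoms out of a correction state.

    Subtracts the piston of each map (value at the origin) and the shared
    tilt pair (the image-translation gauge: a·k on θ_i paired with -a·k on
    θ_o).  The tilt is estimated from θ_o over the inner half of the
    collection pupil: θ_o is free of the white per-angle drift that
    dominates θ_i, and in the inner region its wrapped nearest-neighbour
    differences stay well inside (-π, π), making the estimator exactly
    linear in an injected tilt — hence idempotent and exactly inverting
    the injected pair.  Records the removed (piston_i, piston_o, tilt).
    """
    grid = state.grid
    illums = state.illuminations
    kv = illums.kvecs
    P, Q = grid.lattice_axes()
    out_mask = state.out_mask
    c = grid.center
    inner = support_mask(grid, 0.5 * state.na_col)
    iy, ix = np.nonzero(inner)
    tilt_o = fit_wrapped_tilt(state.theta_o[iy, ix],
                              np.stack([ix - c, iy - c], axis=1))
    tilt = -tilt_o  # θ_o carries -a·k when θ_i carries +a·k
    theta_i = state.theta_i - kv[:, 0] * tilt[0] - kv[:, 1] * tilt[1]
    tilt_map = np.where(out_mask, P * tilt[0] + Q * tilt[1], 0.0)
    theta_o = state.theta_o + tilt_map
    piston_i = float(theta_i[illums.origin_index])
    theta_i = theta_i - piston_i
    c = grid.center
    piston_o = float(theta_o[c, c])
    theta_o = np.where(out_mask, theta_o - piston_o, 0.0)
    return replace(
        state,
        theta_i=theta_i,
        theta_o=theta_o,
        intensity_trace=list(state.intensity_trace),
        gauge={"piston_i": piston_i, "piston_o": piston_o, "tilt": tilt.copy()},
    )


def run_class(
    dataset: TransmissionDataset,
    max_iter: int = 15,
    rel_tol: float = 1e-6,
    order: str = "input_first",
    leave_one_out: bool = False,
) -> tuple[CorrectionState, SASpectrum]:
    """Run the full alternating maximization.

    Alternates input and output half-iterations (input first by default,
    following the measurement's narrative order) until the relative change
    of the total SA intensity over a full iteration falls below ``rel_tol``
    or ``max_iter`` is reached; non-convergence is reported in the state,
    not raised.  Returns the gauge-normalized state and the final SA
    spectrum computed from it.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if order not in ("input_first", "output_first"):
        raise ValueError(f"unknown order {order!r}")
    state = CorrectionState.zeros(dataset)
    sa0 = synth_aperture(dataset, state)
    state.intensity_trace = [scattered_intensity(sa0)]
    steps = (input_step, output_step) if order == "input_first" else (output_step, input_step)
    for it in range(1, max_iter + 1):
        prev = state.intensity_trace[-1]
        for step in steps:
            state = step(dataset, state, leave_one_out=leave_one_out)
        state.n_iter = it
        now = state.intensity_trace[-1]
        logger.info("iteration %d: total SA intensity %.6e", it, now)
        if prev > 0 and abs(now - prev) < rel_tol * prev:
            state.converged = True
            break
    state = remove_gauge(state)
    return state, synth_aperture(dataset, state)
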