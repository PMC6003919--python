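# tmclass

Computational aberration correction for **transmission-mode
synthetic-aperture holographic microscopy** with large-aperture lenses.

## The problem

High-NA objectives have working distances of a few hundred micrometers, so
thick mounted specimens are simply out of reach.  Microscope condenser
lenses offer both a large NA (up to 1.4) and millimeter-scale working
distances — but they were never corrected for imaging and carry severe,
steeply varying pupil aberrations, especially beyond ~0.8 NA.  A coherent
transmission microscope built from two condensers (one illuminating, one
collecting) can nevertheless reach the diffraction limit if those
aberrations are measured and removed numerically.  This package implements
the closed-loop accumulation of single scattering (CLASS) approach to that
problem for angle-scanned transmission data, together with a complete
forward simulator, so every stage is testable without instrument data.

## Model and algorithm

With a thin object of spectrum 𝒪(Δk) illuminated by a plane wave of
transverse wavevector **k**ⁱ, the transmitted angular spectrum through input
and output pupils `P_i = exp(iφ_i)`, `P_o = exp(iφ_o)` (unit amplitude on
|k| ≤ NA·k₀) is

    E_o(kᵒ; kⁱ) = P_o(kᵒ) · 𝒪(kᵒ − kⁱ) · P_i(kⁱ) · exp(i g(kⁱ)),

where `g(kⁱ)` is an uncontrolled global phase per acquisition
(interferometer path-length drift).  Summing all entries with the same
momentum difference Δk = kᵒ − kⁱ builds the synthetic-aperture spectrum

    E_SA(Δk) = Σ_{kⁱ} E_o(kⁱ+Δk; kⁱ) · e^{−iθ_i(kⁱ)} · e^{−iθ_o(kⁱ+Δk)},

whose support extends to (NA_ill + NA_col)·k₀, i.e. a resolution of
Δ = λ/(NA_ill + NA_col).  Aberrations and drift de-phase the sum; the CLASS
solver finds the correction phases θ_i, θ_o that maximize the
synthetic-aperture intensity by alternating

* an **input step** — each illumination's demodulated spectrum is
  correlated against the aggregate E_SA and its phase argument accumulates
  into θ_i, and
* an **output step** — the same rule on the numerically *phase-conjugated*
  dataset (entries conjugated, illumination/detection roles transposed),
  which turns the output pupil into an input and decouples θ_o from the
  drift.

The accumulated corrections converge to θ_i → φ_i + g and θ_o → φ_o in
about ten iterations.  Because the drift is entangled with θ_i, the pure
input aberration is isolated with a second measurement: a test target at
the conjugate image plane before the input lens sees *both* pupils after
the object, so that run's output correction is θ′_o → φ_i + φ_o and the
wrapped difference θ′_o − θ_o is φ_i.

The package also provides off-axis hologram synthesis and demodulation
(2D Hilbert transform: FFT, circular low-pass about the carrier, exact
lattice recentering), and PSF/Strehl/FWHM/Airy-fit and Siemens-star
resolution metrics.

## Worked example

```python
import numpy as np
from tmclass import (run_class, circular_rms_phase_error, support_mask,
                     diffraction_limit)
from tmclass.scenarios import standard_scenario

sc = standard_scenario(seed=0)          # 128² grid, 10 µm FOV, 741 angles
state, sa = run_class(sc.dataset, max_iter=15, rel_tol=1e-6)

mask = support_mask(sc.grid, 1.2)
err_i = circular_rms_phase_error(state.theta_i,
                                 sc.phi_i_at_illums() + sc.drift.g,
                                 kvecs=sc.illuminations.kvecs)
err_o = circular_rms_phase_error(state.theta_o, sc.phi_o, mask=mask)
trace = state.intensity_trace

print(f"illumination angles      : {len(sc.illuminations)}")
print(f"iterations (converged)   : {state.n_iter} ({state.converged})")
print(f"SA intensity gain        : {trace[-1] / trace[0]:.0f}x")
print(f"theta_i vs phi_i + g RMS : {err_i:.2e} rad")
print(f"theta_o vs phi_o RMS     : {err_o:.2e} rad")
print(f"diffraction limit        : {diffraction_limit(785, 1.2, 1.2):.0f} nm")
```

prints

```
illumination angles      : 741
iterations (converged)   : 8 (True)
SA intensity gain        : 447x
theta_i vs phi_i + g RMS : 4.25e-04 rad
theta_o vs phi_o RMS     : 2.46e-04 rad
diffraction limit        : 327 nm
```

The scenario injects 6 rad of radial aberration at the edge of each 1.2 NA
pupil and a uniform ±π drift per illumination; after eight iterations the
solver has recovered both pupil phase maps (and the drift-entangled input
map) to a few 10⁻⁴ rad, raising the synthetic-aperture intensity 447-fold.

### Command line

```sh
tmclass simulate --seed 5 --out run.h5           # dataset + ground truth
tmclass correct run.h5 --out state.h5 --report metrics.json
tmclass separate sample_state.h5 conjugate_state.h5 --out phi_i.h5
tmclass report state.h5
```

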