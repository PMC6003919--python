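# Methods

## Forward model

The simulator implements single-scattering coherent transmission through
two thin pupils.  All quantities live on one discrete contract: an n×n
real-space grid over a square field of view L (pixels at (i − n/2)·L/n)
and the conjugate frequency lattice k = (p, q)·dk with dk = 2π/L and
integer p, q ∈ [−n/2, n/2); transforms are the unitary centered FFT pair,
so Parseval-based intensity comparisons are exact.  A pupil is a hard
closed disk |k| ≤ NA·k₀ of unit amplitude carrying a phase map; apertures
whose cutoff exceeds the grid Nyquist are rejected at construction rather
than truncated, because the synthetic-aperture sums need the full support.

For each illumination wavevector kⁱ (every lattice point inside the
illumination aperture — the complete set of orthogonal free modes of the
field of view), the transmitted spectrum is

    E_o(kᵒ; kⁱ) = P_o(kᵒ) · 𝒪(kᵒ − kⁱ) · P_i(kⁱ) · e^{i g(kⁱ)}.

The object spectrum is evaluated at the momentum difference kᵒ − kⁱ, which
is what makes the equal-Δk synthetic-aperture sum factor as
𝒪(Δk) · Σ P_o P_i e^{ig}: the ideal system reproduces the object spectrum
times the real, positive pair-count weights, and any unit-amplitude pupil
phase or drift can only reduce the magnitude of that cross-correlation
(the intensity inequality that the solver exploits; verified as an exact
property in the tests).  The conjugate-plane geometry places the test
target before both lenses, giving the product pupil on the output side and
no input-side aberration.

## Synthetic-data generator: what it emulates

* **Objects.**  A binary-amplitude Siemens star (alternating equal
  sectors, transparent outside its outer radius) whose local azimuthal
  period 2πr/(n_spokes/2) shrinks linearly with radius — the standard
  resolution read-out target; and a unit-amplitude sum-of-Gaussian-bumps
  phase object as a coarse stand-in for cellular granularity.
* **Aberrations.**  Even-power radial polynomials of the normalized pupil
  radius, φ(ρ) = Σ_j c_j ρ^{2j+2}, matching the spherically symmetric
  phase maps condenser lenses exhibit, with optional low-order azimuthal
  contamination terms; all terms vanish at the pupil center (piston-free).
  A radial-Zernike converter is provided as a convenience only.  A Zernike
  basis was deliberately not made canonical: the radial polynomial keeps
  the ground truth trivially serializable and matches the dominant
  symmetry.
* **Drift.**  Independent uniform phases in ±magnitude per illumination,
  seeded.  Uniform is the least-informative bounded choice; the solver
  must not (and does not) depend on the drift distribution.  The default
  magnitude π represents completely scrambled interferometric phase.
* **Interferograms.**  Off-axis holograms I = |E_S + ref·e^{ik_R·r}|² on
  integer lattice carriers, with optional Poisson shot noise scaled by a
  configurable full-well depth (off by default; the spectral datasets
  themselves are noise-free).

Features of real data deliberately *not* emulated: multiple scattering,
partial coherence, defocus between planes, camera nonlinearity, and
sample-induced (as opposed to system) aberrations.  Passing tests
therefore demonstrate the correctness of the algorithmic chain under the
stated physical model, not robustness to instrument non-idealities.

### Standard scenario

The canonical stress case fixes λ = 785 nm, NA_ill = NA_col = 1.2, a 128²
grid and a 10 µm field of view (741 illumination angles; chosen so the
1.2 NA cutoff sits well inside Nyquist and a full run takes tens of
seconds), a 36-spoke star of 4.5 µm outer radius, radial coefficients
(1.0, 2.0, 3.0) rad on the input pupil and (0.5, 1.5, 4.0) rad on the
output pupil — each summing to 6 rad at the pupil edge with the steepest
contribution beyond ~0.8 of the cutoff — and full ±π drift.

## Solver

The correction phases are applied as e^{−iθ}, so the accumulated maps
converge toward +(φ_i + g) and +φ_o.  Each input half-iteration computes,
per illumination, arg ⟨Ẽ_j, E_SA⟩ (the corrected, demodulated spectrum
against the aggregate synthetic aperture, self-term included — the
self-term is a real positive bias that cannot rotate the argument; a
leave-one-out variant exists behind a flag for very small illumination
counts).  The output half-iteration applies the same rule to the
phase-conjugated dataset: entries conjugated with the accumulated input
correction applied, illumination/detection roles transposed.  Conjugation
negates every per-angle phase, so those increments enter θ_o with a minus
sign, and the drift factor lands on the conjugated view's *output* index,
which is why θ_o decouples from the drift (paired runs differing only in
drift agree on θ_o to ~10⁻⁷ rad RMS when run to tight tolerance).

**Bright-field exclusion.**  The Δk = 0 bin of the synthetic aperture is
excluded from both the correlations and the monitored objective
(`scattered_intensity`, Σ_{Δk≠0}|E_SA|²; `total_intensity` keeps the full
sum).  That bin constrains only the *sum* θ_i(k) + θ_o(k) — it carries no
information about how the aberration splits between the pupils — and for
a transmissive specimen it holds the majority of the object power.  With
it included, the alternating updates trade the combined aberration back
and forth and creep (still ~1 rad RMS from truth after 40 iterations);
with it excluded the solver converges in eight to ten iterations and the
scattered-intensity trace is non-decreasing to machine precision.  This
is the package's realization of the intensity-maximization principle for
bright-field transmission data.

**Iteration and stopping.**  Input step first (matching the measurement
narrative; configurable), default 15 iterations maximum with a 10⁻⁶
relative intensity-change stopping rule over a full iteration —
convergence is observed at 7–10 iterations on the standard scenario.
Non-convergence is reported in the state, never raised.  Zero
correlations (an illumination with no spectral overlap) produce a zero
increment and a logged warning rather than an undefined argument.

**Gauge.**  Two freedoms leave the objective invariant: a piston per map
and the paired tilt (+a·k on θ_i, −a·k on θ_o — a rigid image
translation).  `remove_gauge` zeroes each piston at the origin and
removes the tilt pair, estimating the tilt from θ_o over the *inner half*
of the collection pupil: θ_o is free of the white per-angle drift that
dominates θ_i, and in the inner region its wrapped nearest-neighbour
differences stay well inside (−π, π), which makes the estimator exactly
linear in an injected tilt — hence idempotent and exactly inverting an
injected gauge pair.  Recovery metrics (`circular_rms_phase_error`)
additionally quotient piston and tilt out of the wrapped residual, using
the same wrapped-gradient estimator first so that a multiply-wrapped tilt
gauge (the relative translation of two independent reconstructions)
cannot masquerade as error.  Note the per-map tilt quotient is a slight
superset of the strictly paired gauge; for the sub-milliradian residuals
observed this is immaterial.

## Holographic demodulation

The 2D Hilbert transform is exact on this sampling contract: the carrier
is an integer lattice vector, so the spectral shift is an index
translation, and the low-pass is a hard closed disk (boundary included,
consistent with the pupil convention).  Under the package's FFT sign
convention the lobe at +k_R carries the *conjugate* sample spectrum; the
implementation crops there, recenters, inverse-transforms and conjugates
once, returning E_S exactly (≲10⁻¹⁴ relative) for band-limited fields
when the separation condition |k_R| > 3·band holds.  Violations raise an
error naming the margin.  Raised-cosine apodization is opt-in and breaks
exactness.  16-bit TIFF export quantizes to the stack peak over 65535
(scale recorded in the JSON sidecar); demodulation from quantized frames
recovers fields to ~10⁻³ relative.

## Metrics

* **PSF/Strehl.**  The PSF of a unit-amplitude pupil carrying a residual
  phase; Strehl is the sub-pixel-interpolated peak over the ideal peak of
  the same support, so a pure tilt (translated, undistorted focus) scores
  1.  In the small-residual regime Strehl ≈ e^{−σ²}.
* **FWHM.**  Linear-interpolated half-maximum crossings along a line
  through the quadratically refined peak; errors if the half level is
  never crossed.
* **Airy fit.**  Least squares of scale·[2J₁(x)/x]², x = rate·r, over the
  pixels from the peak to the first dark ring (ring radius refined once
  from the fitted rate; the restriction avoids ring-weighting ambiguity);
  non-convergence is reported in the record.
* **Siemens resolution.**  Circles of decreasing radius are swept about
  the (registered) star center; the azimuthal intensity profile is sampled
  by bilinear interpolation and the Michelson contrast of its component at
  the spoke frequency (2|c_m|/c₀) is thresholded.  The default threshold
  0.1 is a deterministic stand-in for the visual "finest resolved"
  judgment.  Because the tilt gauge translates reconstructions by a few
  pixels, images are registered to the known target by phase cross
  correlation before the sweep.

### Resolution closure

Two distinct questions are answered by the same sweep.  *What is the
finest detectable period?* — threshold 0.1 on the reconstruction as-is.
*Where does the transfer cut off?* — the contrast transition of a star
has an intrinsic width of several Δk bins (the circle samples a
PSF-limited annulus, smearing the local spoke frequency), so any
fixed low threshold reads the *foot* of the transition and is biased by
that width: on the coverage-tapered sum it reads coarse, on the
equalized spectrum it reads past the cutoff (ringing and the intensity
nonlinearity leak contrast slightly beyond the passband).  The cutoff
location is instead estimated at the mid-transition (0.5) crossing of the
coverage-equalized reconstruction (synthetic-aperture spectrum divided by
the pair-count weights, flattening the passband transfer), which is
insensitive to the transition width; on the standard scenario it lands
within 0.02 Δk bins of λ/(NA_ill + NA_col).

## Numerical choices and degenerate inputs

Aperture membership is decided on squared integer lattice radii against
the squared cutoff, so disk enumeration is deterministic and exactly
reproducible by brute force.  Simulated spectra are assembled by integer
`roll` of the object spectrum — exact, with no interpolation anywhere in
the pipeline.  Complex data serialize as paired float64 real/imag HDF5
arrays without timestamp tracking, making repeated writes byte-identical.
Empty pupils, odd grids, apertures beyond Nyquist, drift magnitudes above
π, overlapping demodulation bands, flat FWHM profiles and swapped
separation arguments all raise typed errors with the violated quantity
named.

## Known limitations

* The solver assumes unit pupil amplitudes; apodization/vignetting is not
  estimated.
* Identifiability requires a broad object spectrum: for an object with a
  single spectral component only θ_i + θ_o is determined.
* The drift-decoupling figure (~10⁻⁷ rad RMS) requires running well past
  the intensity plateau (tight tolerance, ~20+ iterations); at the default
  stopping rule the two runs agree to ~10⁻⁴ rad.
* Problem sizes in the shipped scenarios (128² standard, 64²/32² reduced)
  were chosen so the full validation chain runs in about a minute; the
  algorithms are O(N_ill · n²) per half-iteration and scale to larger
  grids unchanged.
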