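# Methods

## Model and conventions

The object is thin: a single complex transmittance
`u(x) = exp(−B(x) + iφ(x))` at the exit plane, with `B ≥ 0` and
`φ = −(2π/λ)∫δ dz ≤ 0` for a positive refractive-index decrement.  The
contact-plane intensity is `I₀ = exp(−2B)`.

Spatial frequencies are in **cycles per metre**; with that convention the
Fresnel chirp phase is `χ_D(f) = πλD|f|²` and the propagation transfer
function `H_D(f) = exp(−iχ_D(f))`.  Propagation is the single-FFT product
`u_D = IDFT[H_D · DFT[u]]`.  The wavelength is derived from the photon
energy as `λ[m] = 1.23984193×10⁻⁹ / E[keV]` (rounded CODATA `hc`, fixed for
reproducibility).

The sign pattern of the weak-object (CTF) model,
`DFT[I_D − 1] = 2 sin χ_D · DFT[φ] − 2 cos χ_D · DFT[B]`,
is the one consistent with `u = exp(−B + iφ)` and `H_D = exp(−iχ_D)`; the
test suite validates it against the full Fresnel propagator rather than
against any published convention (an overall complex conjugation of the
Fourier convention would flip signs coherently without changing any
intensity).

Cone-beam acquisitions are mapped to this parallel-beam picture by the
Fresnel scaling theorem: effective distance `D = z1(zD − z1)/zD`,
magnification `M = zD/z1`, effective pixel `p/M`.  The geometry module
computes the effective pixel rather than calibrating it: for the published
nano-imaging setup it yields 5.86 nm where 6 nm was *measured*; the
discrepancy is a property of the measurement, not of the formula.

## Propagator boundary handling

The transfer-function propagator assumes a periodic field.  It is exactly
unitary, additive in distance, and invertible — identities the tests assert
at 1e-12/1e-10 — and those identities are the reason edge-padding is **off
by default**: symmetric padding to twice the size (`pad=True`), cropped
after propagation, suppresses wrap-around from non-periodic fields but
breaks exactness at the ~1e-3 level.  Simulations of compact phantoms with
long propagation distances use `pad=True` explicitly.

Spectral (FFT) derivatives are used in the TIE forward model, with the same
periodic-boundary assumption.

## Direct methods: regularization and the f = 0 convention

All filter methods damp ill-conditioned frequencies with a Tikhonov term
`α` (default 1e-8, on the scale of the O(1) DC gain of the filters); a
floor `α_min = 1e-12` is always added so the chirp zeros never divide by
zero.  `α` is uniform across frequency; no low/high-frequency split is
implemented.  The mean phase is unobservable in every model here, so
`φ̂(0) = 0` by convention and all phase comparisons in the tests are
mean-matched.  The absorption mean follows from the data (mean
attenuation).  Logarithms (`tiehom`, the mixed priors) clip their argument
at 1e-8 and log a warning count.

The CTF 2×2 normal-equation solve is intrinsically near-singular at low
frequency (`sin χ → 0`, the classic CTF low-frequency problem) and on rings
where the distances' chirps coincide.  The self-consistency oracles
therefore use few-mode phantoms whose spectral support avoids those rings;
the recovery studies use band-limited random phantoms and distance sets
whose chirp zeros interleave.

Multi-distance stacks must be pre-aligned and resampled to the common
(smallest) effective pixel before stacking; `fourier_resample` implements
mean-preserving Fourier cropping/zero-padding for that purpose.  Images are
assumed normalized to unit background (flat correction); `wtie`
additionally divides by the image mean as part of its contrast definition.

## Iterative methods

The iterate is the full complex wave `u`, not a phase map, so both outputs
(phase and amplitude) are refined; phase maps are read off as `arg(u)`.

*Gradient descent* minimizes `C(u) = Σ_D ‖|P_D u|² − I_D‖²` with the
Wirtinger gradient `Σ_D 4 P_{−D}[(|P_D u|² − I_D) P_D u]` (validated against
finite differences at 1e-5 relative — the mandatory oracle before any
optimization test).  The initial step is `1/(8 Σ_D max I_D)`; Armijo
backtracking (factor ½, slope parameter 1e-4) guarantees a non-increasing
cost history.  Initialization from a direct method is recommended: from a
flat or random start the nonconvex misfit has poor local optima.

*HIO/ER* alternates between the detector-modulus projection (replace
`|P_D u|` by `√I_D`, keep the phase, back-propagate) and per-pixel
object-domain constraints: outside the support the object equals the unit
background `u = 1`; non-negativity means `|u| ≤ 1`.  Both constraint sets
are convex and per-pixel, so the ER object step is an exact projection and,
for a **single distance**, ER is an alternating projection whose detector
residual `Σ_D ‖|P_D u| − √I_D‖²` is provably non-increasing — the
monotonicity contract is asserted in that setting.  With several distances
visited cyclically the residual may oscillate and no monotonicity is
claimed.  The HIO update at constraint-violating pixels is the
background-referenced Fienup feedback `u ← u − β_fb (u′ − 1)` (default
`β_fb = 0.9`); referencing the unit background is required for the update
to relax violating pixels toward the background rather than drift away from
it.  The multi-image recipe "run the schedule separately per image and
average" is provided as `averaged_hio_er`, a convenience driver that runs
the schedule independently on each single-distance sub-stack, averages
phases and amplitudes, and repeats for a set number of cycles; this is one
reading of an ambiguous prescription and is documented as such.

## Synthetic data: what it does and does not emulate

`simulate_stack` emulates moving the sample to several focus distances of a
cone-beam setup, converting each position to its effective parallel-beam
distance, and recording Fresnel holograms of a known phantom on the
phantom's own (sample-plane) grid — i.e. as if the frames were already
magnification-corrected, which is the state the retrieval methods expect.
The only noise source is per-pixel Poisson counting noise at fluence `N0`
photons/pixel (`N0 = inf` → noiseless); the generator is an explicit seeded
`numpy` Generator and the same seed reproduces a dataset bit for bit.

Not modelled: detector PSF / scintillator blur, source size and partial
coherence, flat-field structure (an optional per-distance multiplicative
flat exists only to exercise the correction code), vibration or drift, and
polychromaticity.  Passing the recovery tests therefore demonstrates
correctness of the algorithms under their stated models, not robustness to
every experimental imperfection.

## Study conditions used by the tests

Chosen once, as conditions a practitioner would call representative:

- **Direct filter methods**: 256² grids, λ = 1 Å (12.4 keV), 1 µm effective
  pixel; weak random-blob phantoms (feature σ 4–12 px, |φ| ≤ 0.01,
  B ≤ 0.005) and distance sets 0.02–0.09 m whose chirp zeros interleave.
- **TIE-HOM disc**: homogeneous disc (δ/β = 500) of radius 30 µm, peak
  thickness 2 µm, at `F(radius) = 20`.  The thickness-error metric excludes
  a rim band one Fresnel-fringe width `√(λD)` wide: the projected
  spherical-cap thickness has an infinite gradient exactly at the rim,
  where no finite-bandwidth filter is pointwise accurate.
- **Iterative methods**: 64² grids at 50 nm pixel (nano-holography
  sampling), distances 0.02–0.05 m, so `χ ≈ 1` at the feature scale and the
  holograms genuinely constrain the phase; |φ| up to 0.3 rad for gradient
  descent (enough that the CTF init carries visible bias to remove) and a
  −0.5 rad supported bump for HIO/ER.
- **Poisson statistics**: fluence 1e4–1e5 photons/pixel, typical of
  single-frame synchrotron projections.

## Degenerate inputs and numerical guards

Zero propagation distance is an error for `wtie` (the filter is identically
zero) and a no-op for the propagator.  Non-positive `flat − dark` aborts
flat correction with the offending pixel count; negative corrected
intensities are clipped at zero with a logged count.  All-zero images make
phase correlation undefined and raise.  Non-finite iterative costs raise a
divergence error naming the iteration.  The alignment is rigid translation
only — adequate for simulated or magnification-matched data; strongly
magnification-mismatched multi-distance stacks would need deformable
registration, which is out of scope.

## Known limitations

- Uniform `α`; no automatic `δ/β` selection or two-band regularization.
- Rigid alignment only (see above).
- The HDF5 and TIFF dataset dialects are this package's own documented
  layouts, not any beamline's native format.
- `parallel_map` offers serial and local-process backends only; cluster
  schedulers are not interfaced.
- No tomographic reconstruction: the package stops at per-projection phase
  maps.
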