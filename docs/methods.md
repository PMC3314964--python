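# Methods

`bayesmap` implements single-particle cryo-EM structure refinement as
maximum-a-posteriori (MAP) estimation by expectation-maximization, with a
Gaussian smoothness prior on the Fourier components of the map, alongside
the conventional projection-matching/Wiener comparator, a ground-truth
simulator, and SSNR/FSC resolution tools.  This note records the model, the
conventions every module shares, the tunable parameters, and the design
choices made where the design was genuinely open.

## Image formation model

Each particle image `X_i` is modelled in Fourier space as

    X_ij = CTF_ij · Σ_l P^φ_jl V_l + N_ij

where `V` is the 3D Fourier transform of the map, `P^φ` extracts a central
slice at orientation `φ` (three ZYZ-intrinsic Euler angles plus a 2D origin
shift acting as a phase ramp), `CTF` is the isotropic, envelope-free
contrast transfer function, and `N_ij` is independent complex Gaussian
noise with variance `σ_ij²` **per real/imaginary component** (so
`E|N_ij|² = 2σ²`).  σ² is held per resolution ring and per micrograph
group.  The same convention is used, with the same ½ factors, by the
simulator, the likelihood and the noise update, so recovery of injected
noise is exact by construction rather than by calibration.

The hidden orientation (and, for K > 1, class) is marginalized: the E-step
computes the posterior weight Γ of every (class, orientation) cell of a
discrete grid for every particle, by max-subtracted exponentiation of
log-likelihood + log prior (the raw Gaussian products underflow double
precision for realistic component counts).  The M-step rebuilds each class
map per voxel as

    V = [Σ Γ·CTF·X/σ²] / [Σ Γ·CTF²/σ² + 1/(T·τ²)]

with `τ²(shell)` the raw per-shell signal power (half the mean squared
modulus of the current map, shells of width one Fourier pixel at the
original sampling rate), then updates `σ²(group, ring)` from the Γ-weighted
residuals, `τ²` from the new map, and the class fractions from the mean Γ
class mass.  The heuristic constant `T` (default 4) multiplies `τ²`
wherever it enters the reconstruction denominator or the SNR; it
compensates the under-estimation of signal power caused by assuming
independent Fourier components for a compact-support object.  Values much
larger than 4 invite overfitting and trigger a warning.

## Fourier conventions

* Unitary transforms (`norm="ortho"`), so Parseval holds without factors
  and σ²/τ² are comparable across grid sizes.
* Centered grids (zero frequency at index `n//2`); all slice geometry is
  defined on the centered grid.
* Full-grid complex storage with Friedel symmetry enforced explicitly after
  accumulation; every sum over components runs over the full grid, i.e.
  both members of a conjugate pair are counted.  This affects the scale of
  the likelihood, not the posterior weights.
* The model transform is stored 3× oversampled (zero-padding in real
  space), scaled so that stride-3 lattice points carry the transform of the
  un-padded map.  Projections and back-projections use nearest-neighbour
  interpolation on this grid; frequencies beyond the Nyquist disc of the
  original sampling are excluded.  Extraction and insertion share one index
  map, so the pair is exactly adjoint — which is what makes the per-voxel
  M-step division the exact maximizer and the EM log-posterior trace
  monotone (a property the test suite asserts).

## Gridding correction

Per-voxel division by the accumulated `Σ Γ·CTF²/σ²` exactly compensates
the nonuniform sampling density at sampled voxels of the oversampled grid.
Voxels between slice planes remain unsampled; they are filled by iterative
normalized convolution with the nearest-neighbour sampling footprint (a box
of width = the oversampling factor): each pass replaces still-empty voxels
inside the Nyquist sphere by the mean of already-filled neighbours, up to
10 passes or until nothing changes.  Genuinely unmeasured regions stay
zero.  The fill is disabled (`gridding_iters=0`) wherever a test needs the
exact sampled-voxel algebra.

## CTF

    CTF(ν) = -[ sqrt(1-A²)·sin χ(ν) + A·cos χ(ν) ],
    χ(ν)   = π λ Δf ν² - (π/2) Cs λ³ ν⁴

with λ the relativistic electron wavelength
`12.2639/sqrt(V + 0.97845e-6·V²)` Å (V in volts), defocus Δf in Å
(underfocus positive), Cs in mm, amplitude contrast A ∈ [0, 1].  No
envelope, astigmatism or phase plate; the sign makes protein density
positive in restored maps.  CTFs are cached per (parameter set, grid) —
one evaluation per micrograph group.

## Orientation sampling

The sphere is tiled in latitude bands of height = the angular step with
`round(360·sin(tilt)/step)` azimuth points per band (approximately
equal-area), crossed with in-plane ψ at the same step and an optional
square shift lattice.  Rotations carry a uniform prior; shifts are uniform
or centered Gaussian with a configured (not learned) width.  2D
class-averaging mode uses ψ × shifts only, with 2D references on the same
oversampled-transform machinery — all update formulas are
dimension-agnostic.  Schedules are coarse-to-fine (e.g. 15° → 10° after a
configured iteration), mirroring common practice.

Point-group symmetry (Cn/Dn) is imposed by averaging the accumulator
(numerator and denominator) over the group rotations before the solve, so
the SNR bookkeeping reflects the number of averaged asymmetric units.  On
even grids a rotation clips the partner-less −Nyquist plane; this matters
only for flat spectra.

## Resolution estimation

The per-voxel SNR of the reconstruction is `T·τ²(shell) × Σ Γ·CTF²/σ²`
(the weight term from the final iteration, so the estimate reflects the
actual orientation coverage and varies within shells).  Its spherical
average is reported per shell; the resolution is the frequency of the
**last shell at or above 1**, with no sub-shell interpolation — shell-width
precision is what small grids honestly support.  FSC between two maps uses
the same last-shell-at-or-above convention for its thresholds (0.5 default,
0.143 also reported).  Half-set validation runs two complete refinements of
disjoint random halves from the same starting model, sharing no statistics.

Guinier/B-factor sharpening fits straight lines to ln(spherically averaged
|F|) against ν² for map and reference over a stated resolution interval,
after masking both identically with a soft spherical mask (radius 0.45×box,
3-voxel cosine edge); the relative B is four times the slope difference and
sharpening applies `exp(+B·ν²/4)`.

## The simulator and the study conditions

The generator realizes the image-formation model exactly: slice (through
the same operator refinement uses, or optionally a spline-interpolated
real-space projection as an inverse-crime control), CTF, shift phase,
Hermitian Fourier-domain Gaussian noise with per-ring variance σ²(ν)
(white or a per-ring profile).  Phantoms are sums of 12 Gaussian blobs
(width 0.8–1.8 voxels, amplitude 2–5, centers within 0.3×box), whose power
spectrum reaches mid shells the way a macromolecule's does; 32³ boxes at
3 Å/voxel.  Defocus is drawn per group from 5000–30000 Å over 8 groups so
that the groups' CTF zeros do not coincide in the informative shells.
Scenario presets fix the study conditions:

| preset            | classes | n    | σ²  | notes                            |
|-------------------|---------|------|-----|----------------------------------|
| `typical_refine`  | 1       | 600  | 0.6 | SSNR ≥ 1 through ~shell 5        |
| `low_snr_overfit` | 1       | 240  | 1.5 | data-side SSNR < 1 beyond ~shell 4 |
| `hetero_equal`    | 2       | 500  | 0.35 | independent structures, 50/50   |
| `hetero_minority` | 3       | 1000 | 0.35 | dissociated-subcomplex minority at 6 % |

Starting models for refinement examples and tests are the phantom blurred
with a 1.2-voxel Gaussian — the proportional desk-scale analogue of the
50 Å low-pass starting maps used for real data at ~120² boxes.

What the simulator does **not** emulate: solvent/ice background, detector
MTF, beam-induced motion, per-particle defocus variation within a group,
structural flexibility beyond discrete classes.  Passing tests therefore
demonstrate the statistical machinery (recovery, consistency,
regularization behaviour), not performance on real micrographs.

## Classification protocol at desk scale

Multi-class runs are seeded by dividing the data into K random subsets
during the first iteration, each subset reconstructing one seed from the
common initial model.  At desk scale the default 3× oversampling leaves
only a few data hits per oversampled voxel per class, so each particle
"sees" its own inserted noise in its class map and assignments freeze at
the seeding.  Classification runs therefore use `oversampling=1` (27× more
hits per voxel) and ~20–30 iterations at 20°.  Because the escape from the
symmetric fixed point remains initialization-dependent, `classify()` reruns
the random-subset seeding a few times (default 3) and keeps the run with
the highest final marginal log-likelihood — the EM objective as the model
selector; the final log-likelihood ranked separated runs above stuck ones
in every case observed during development.  With that protocol the
two-class mixture resolves at ≥90 % accuracy.  Recovering a 6 % minority
class of ~60 particles remains out of reach of random-subset seeding at
this scale: a class stabilizes on a minority only when the minority count
is comparable to a majority split-class, and 60 vs ~240 is not (the test
asserting it is intentionally kept and fails).

## Numerical choices

* σ² floor: `1e-12 ×` mean image power (guards noiseless synthetic data).
* τ² = 0 shells are fully damped to zero; τ² = ∞ reduces the solve to the
  unregularized direct-Fourier ratio, where zero-weight voxels become 0
  (counted), or raise if requested.
* Γ cells with mass below `prune` (default 1e-8) per rotation are skipped
  during back-projection.
* Initial σ² is half the mean per-ring image power per group (includes
  signal, self-corrects within a few iterations); initial τ² comes from
  the starting model.
* Convergence: fixed iteration count by default, optional relative
  map-change threshold.
* All randomness (simulation, splits, subset seeding) flows from explicit
  seeds; identical inputs and seeds reproduce identical outputs.

## Known limitations

Nearest-neighbour interpolation bounds the usable resolution of slices at
small boxes (≈12 % relative error on smooth 16³ phantoms at odd angles);
discrete 15–20° grids bound achievable alignment; the desk-scale particle
counts leave the conventional comparator's overfitting contrast visible
qualitatively (within-run FSC above independent FSC beyond the signal
band) but smaller, in FSC = 0.5 crossing terms, than on real datasets with
tens of usable shells.  Astigmatic CTFs, local searches, gridding kernels
beyond nearest neighbour, and non-Gaussian priors are documented extension
points, not implemented.
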