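# Methods

## Scope and coordinate conventions

`fibercell` assesses myosin thick-filament models against sampled
low-angle fiber-diffraction intensities. Only the myosin filament is
placed in the unit cell: actin layer lines are unsampled in these
lattices and are assumed stripped from observed tables along with the
continuous background, so actin, tropomyosin and troponin are handled by
layer-line exclusion (e.g. dropping l = 3 in the insect geometry, where
actin and troponin also contribute) rather than by modelling.

The filament axis is z and coincides with the crystallographic c axis.
Azimuthal rotation is counterclockwise looking down +z; rotation 0 aligns
the model's x axis with the cell a edge. The observed pattern fixes only
relative azimuths (the R-factor trace), not this zero, so no absolute
angle is ever interpreted. Fractional coordinates are wrapped into
[0, 1) half-open, so a scatterer landing exactly on a cell corner is
counted once.

Only the hexagonal a = b, α = β = 90°, γ = 120° setting is supported;
other settings are rejected at construction rather than silently
mis-handled. Superlattice A-bands (statistically mixed filament
rotations) are out of scope.

## Scatterer reduction

All model sources are reduced to weighted point scatterers:

* **atoms** — weight = atomic number, hydrogens omitted. At the ≥ 60 Å
  resolution of these patterns atomic form factors are flat, so
  element-resolved scattering curves would only rescale weights.
* **density-map voxels** — one point per voxel above a threshold
  (default 0), at the voxel centre, weight = raw voxel value, negatives
  included. Map scale is irrelevant because fitting rescales total
  intensity. No interpolation is done, so the discrete structure-factor
  sum is reproduced literally from the map samples.
* **synthetic blobs** — unit weights (below).

Total weight is conserved by placement and equals F(0,0,0), which is the
pipeline-level conservation check.

## Diffraction

Reflections are enumerated for l ≥ 0 with h, k of both signs, to a
resolution cutoff on total d-spacing (default d_min = 60 Å, the
practical limit of the layer-line data these lattices provide), with an
optional independent equatorial r_max to mimic detector extent. Friedel
mates of the l > 0 half are added, with conjugate structure factors,
only inside the Fourier synthesis; everywhere else the upper-half
pattern suffices because observed fiber quadrants are mirror-folded.

Structure factors are computed by direct vectorized summation in double
precision — the reference path; there is no FFT approximation anywhere in
the scoring chain. The suite checks the implementation against an
independent scalar brute-force sum to 1e-9 relative.

Multiplets are keyed by the exact integer s = h² + hk + k², valid
because a = b; floating-point radius grouping exists only as a test
oracle. Member intensities are summed **incoherently** (intensities, not
amplitudes): multiplet members are symmetry-unrelated reflections from
cells at independent azimuths, so their waves carry no stable relative
phase.

The lateral-disorder factor applied to sampled intensities is the
standard 2D Gaussian lattice-disorder attenuation
exp(−2π²σ²R⊥²), with σ the rms lateral displacement of the filament from
its lattice point; meridional rows (R⊥ = 0) are untouched. This is a
design choice of this package: the factor is conventionally named but
its algebraic form is rarely printed, and the 2D Gaussian is the
standard result for uncorrelated lateral displacements.

Fourier synthesis evaluates Δ(x,y,z) = (1/V)·ΣF·exp(−2πi(hx+ky+lz)) on
the fractional grid by direct summation after Friedel completion and
raises if the imaginary residual exceeds 1e-6 of the real peak —
a broken completion is a bug, not a warning. The round-trip check
(model → F → density) is validated against a numpy-FFT inversion of
independently computed structure factors, with correlation ≥ 0.99.

## Scaling and scoring

Calculated intensities are put on the observed scale by total intensity,
k = ΣI_obs/ΣI_calc, which is how simulated and observed fiber patterns
are conventionally compared; a least-squares scale is available as an
option. The same unweighted total-intensity scale is used for the
Φ-weighted R-factor — weighting enters the residual, not the scale —
and this is switchable. Both R-factors are invariant under joint
positive rescaling of I_obs, I_calc (and Φ); with constant Φ the
weighted form reduces exactly to the unweighted one.

The rotation search is an exhaustive grid (fish default 0–60° in 1°
steps; insect default 0–2° in 0.25° steps, since 32-fold projected
filament symmetry in a 6-fold lattice leaves ≈ 360/192° of unique
rotation). Ties in R go to the smallest angle, and the disorder search
ties go to the smallest σ, so results are deterministic. A single
matched peak is permitted with a warning: after scaling its R is
identically 0 and carries no information.

The R-versus-rotation trace is periodic: rotating the filament by 60°
maps the hexagonal reciprocal lattice onto itself within each multiplet
class, so 60° divides the period for any motif, and motif C_n symmetry
reduces it further — 60° for C3, 30° for C4 (gcd of 60° with 120° and
90° respectively). The default vertebrate toy's crown perturbations
break its approximate 9-fold projection, which is why the period is 60°
and not 20°; a perfectly helical toy would show the shorter
pseudo-period.

## Synthetic data

The toy generator emulates the two filament symmetries, not their
molecular detail:

* **vertebrate-like** — head pairs on a 3-start helix, 9 pairs per turn
  (40°/crown), rise 143.2 Å, C3, repeat 429.6 Å. The three crowns in a
  repeat carry a periodic perturbation, default
  (Δz, Δφ) = (0, 0), (+8 Å, −5°), (−8 Å, +5°); real vertebrate crown
  perturbations are of this order but their exact values are a property
  of each species' filament, and the defaults here are chosen simply to
  populate the otherwise-forbidden l = 1, 2 layer lines visibly.
* **insect-like** — C4, 8 crowns per 1160 Å repeat at 145 Å, twist
  33.75°/crown. Any twist giving the known 32 projected azimuths is
  admissible; 33.75° (= 360/10.667 per crown) is fixed for
  reproducibility and yields 32 equally spaced azimuths 11.25° apart.

Each myosin molecule carries two heads as isotropic Gaussian blobs of 40
points, σ = 20 Å — the size of a myosin head pair seen at 60 Å
resolution. `compact_pair` packs both blobs tangentially at the anchor
radius (backbone radius + 25 Å), an interacting-head-motif-like
arrangement; `radial_extended` puts one blob at the anchor and one at
head_radius (160 Å fish / 170 Å insect) along the outward radial
direction. Head point counts and weights are identical between modes, so
discrimination is purely shape-driven. The backbone is a uniform
cylinder of point scatterers (radius 65 Å fish / 80 Å insect) giving a
strong equator. One C_n wedge is sampled and replicated exactly by the
C_n rotations, so the declared symmetry holds to machine precision. All
randomness comes from the single spec seed.

Synthetic observed tables are pipeline-computed multiplet intensities
with multiplicative Gaussian noise: I_obs = max(I(1+ε), 0) + floor,
ε ~ N(0, rel_sigma), and Φ = rel_sigma·I + floor. Under total-intensity
scaling the expected noise-floor R-factor is
σ²·ΣI²(1 − 2w + Σw²)/(ΣI²(1+σ²)) with w = I/ΣI; the suite verifies the
Monte-Carlo mean over 200 replicate seeds against this closed form.

What the toys do **not** emulate: realistic head shapes and
orientations, S2, axially varying backbone structure, actin/troponin
layer lines, and real measurement error structure (which is neither
purely multiplicative nor independent across multiplets). Passing tests
therefore demonstrate that the pipeline machinery is correct and
discriminating under its stated model, not that any particular published
filament structure fits any particular observed pattern — scoring real
models requires real stripped-intensity tables, which are inputs, not
package data.

## Numerical choices and problem sizes

* Structure-factor phase matrices are chunked to ≈ 4 M elements to bound
  memory; results are identical to the unchunked sum.
* Multiplet grouping is exact-integer, immune to radius rounding.
* Radius-keyed observed peaks match the nearest calculated multiplet on
  the same layer line within 1e-4 Å⁻¹; two candidates inside the
  tolerance raise an ambiguity error rather than guessing.
* Axial-repeat mismatch between model and cell warns at > 1% rather
  than failing: EM-derived repeats routinely differ slightly from X-ray
  cells.
* Test and acceptance runs use the default toys (≈ 1300 scatterers,
  ≈ 430 reflections, 88 fish multiplets on l = 1–6) except where a
  cut-down toy (fewer blob points) exercises the same symmetry logic;
  trace periodicity is a property of the lattice and motif symmetry, not
  of scatterer count.

## Known limitations

* Ideal lattice sampling only: no inter-filament substitution disorder,
  paracrystallinity, or finite-lattice peak broadening beyond the
  Gaussian spot spread used for rendering.
* No Lorentz/polarization/absorption corrections; observed tables are
  assumed already corrected.
* Rendering is a reporting convenience calibrated in reciprocal space;
  fitting never consumes pixels.
* The rotation search is exhaustive by design; no gradient or annealing
  search over head conformations is provided.
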