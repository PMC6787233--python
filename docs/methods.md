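# Methods

This note documents the models implemented in `excitube`, the numerical
and design choices behind them, and what the synthetic-data tests do and
do not demonstrate.

## Lattice geometry

Each nanotube wall is a rectangular grid of molecules wrapped on a
cylinder: `n_circ` sites around the circumference, `n_axial` along the
axis, both directions periodic, lattice constant a = 0.74 nm. The
reference system is the C8S3 double-walled nanotube: inner wall
30 × 1000, outer wall 55 × 1000, giving tube diameters n_circ·a/π ≈ 7.1
and ≈ 13.0 nm. All kinetic distances are measured on the unrolled grid
in lattice units (1 unit = a), because the annihilation radius is
specified in molecules; physical quantities are recovered by multiplying
by a.

Radial adjacency between walls of unequal circumference is not uniquely
defined by the physical picture. We map a site `(i, j)` to
`(round(i·n_to/n_from), j)` with round-half-up. This preserves the axial
registration exactly and local circumferential adjacency to within one
site (the round trip inner→outer→inner moves a site by at most one
circumferential position), and it preserves site density on average.
Curvature-corrected chord distances and the true two-molecule helical
unit cell are deliberately out of scope here; the microscopic structure
enters only the HSR module.

## Kinetic Monte Carlo engine

State: a population of excitons with integer grid positions, wall
labels, origin labels and annihilation histories. Time advances in
dt = 1 fs steps. Within a step, excitons are visited in a freshly
shuffled order; for each alive exciton one uniform draw u decides decay
(`u < dt/τ`, first-order kinetics; dt ≪ τ makes the linear and
exponential forms indistinguishable at double precision), and if it
survives, a second draw v selects the move:

* `v < H` — hop. H is the **total** per-step probability to move,
  split equally over the four nearest neighbours. This interpretation
  is fixed by the consistency of H = 0.04/fs with D ≈ 5.5 nm²/ps:
  the isotropic nearest-neighbour walk has ⟨x²⟩ = H·(t/dt) lattice
  units², hence D = H a²/(4 dt) = 5.476 nm²/ps ≈ 10 molecules/ps.
* `H ≤ v < H + k·dt` — attempt inter-wall transfer to the radially
  adjacent molecule (k = k_io on the inner wall, k_oi on the outer),
  performed only if that molecule is unoccupied; otherwise the exciton
  stays. Occupancy exclusion applies **only** to transfer; intra-wall
  hops ignore occupancy, and same-site encounters are resolved by the
  annihilation sweep.
* otherwise — stay.

After all excitons have moved, the annihilation sweep runs: while any
same-wall pair has minimum-image distance strictly below R0, a violating
pair is picked (excitons scanned in the step's shuffled order; among a
given exciton's violating partners one is chosen uniformly by reservoir
sampling), one member chosen uniformly at random is deleted, the
survivor's history is updated, and the scan repeats. Iterating until no
violating pair remains resolves clusters of three or more excitons
within a single step, which is what allows one exciton to participate in
several sequential annihilation events. Strict inequality implements
"closer than the annihilation radius": two excitons at distance exactly
3.0 do not interact. Cross-wall pairs never annihilate — the inter-wall
separation (~3.5 nm) makes the dipole–dipole interactions responsible
for annihilation negligible compared to intra-wall ones.

Planting places `round(sites/density)` excitons per wall uniformly at
random without double occupancy, with the same density (molecules per
exciton) on both walls; an annihilation sweep is applied at t = 0
immediately after planting, and observables are sampled after each
step's sweep (including the t = 0 sweep). This ordering reproduces the
instantaneous annihilation signal at essentially zero waiting time for
dense plantings.

Bookkeeping per exciton: origin wall, zero-time position, unwrapped
displacement, terminal event (decayed / annihilation-deleted / censored
at the horizon, with wall and time), number of annihilation events
survived, participated in, and participated in with a same-origin
partner. Hops and transfers are tallied per exciton; a per-event hop log
at 1 fs resolution would dominate memory without adding physics, so the
event log records annihilation events only (decays are recoverable from
the terminal records).

Randomness: each realization gets an independent child seed derived from
the master seed through `numpy.random.SeedSequence`, making ensembles
bit-reproducible for a given (seed, n_real, parameters). The inner loop
is a numba-compiled kernel with a cell-linked-list neighbourhood search
for the sweep, so a full fluence series remains a desk-scale
computation.

### Reference parameters

| quantity | symbol | isolated inner | complete nanotube |
|---|---|---|---|
| time step | dt | 1 fs | 1 fs |
| one-exciton lifetime | τ | 58 ps | 33 ps |
| hopping probability | H | 0.04 /fs | 0.04 /fs (both walls) |
| annihilation radius | R0 | 3 sites | 3 sites (both walls) |
| transfer inner→outer | k_io | – | 0.0013 /fs |
| transfer outer→inner | k_oi | – | 0.0031 /fs |
| lattice constant | a | 0.74 nm | 0.74 nm |

The uphill/downhill rate ratio k_io/k_oi = 0.419 is consistent with
detailed balance, exp(−ΔE/k_BT)·(55/30) = 0.409, for the ΔE = 300 cm⁻¹
gap between the wall exciton bands at k_BT ≈ 200 cm⁻¹.

## Observables

Six predicates map the labelled population onto the measurable signals.
Absorptive signals count all alive excitons matching the origin/current
wall constraints; EEI signals additionally require at least one
annihilation event with a same-origin partner. The outer→inner EEI cross
peak is the explicitly specified case: excitons (1) planted on the outer
wall, (2) with ≥1 same-wall annihilation event, (3) residing on the
inner wall at waiting time T. The diagonal predicates mirror this
construction by symmetry and carry a `reconstructed` flag in their
metadata, since only the totals and the cross peak are fixed by the
experimental prerequisite list.

* **MSD / diffusion constant.** Computed only for annihilation-free
  runs, from unwrapped displacements (periodic folding would cap the MSD
  at (grid/2)² and bias D down). D is the least-squares slope of
  ⟨x²⟩ vs τ divided by 4, excluding τ = 0; a residual check warns when
  R² < 0.999.
* **Transfer efficiency.** Among outer-origin excitons, the fraction
  whose terminal event (decay or annihilation-deletion) occurred on the
  inner wall; excitons alive at the horizon are censored and counted by
  their current wall. Runs extend to 10τ so censoring is ~e⁻¹⁰.
* **Peak time.** Discrete argmax refined by a parabola through the three
  neighbouring (t, y) samples — robust on log-spaced waiting-time grids;
  returns 0 when the maximum is the first sample, and falls back to the
  grid point when the local parabola is degenerate.
* **Multi-annihilation fraction.** Share of excitons with ≥2
  annihilation events. The natural denominator is the annihilation
  participants (≥1 event) — deleted partners are excluded from the
  numerator by construction, only participants can reach two events —
  but the all-planted normalisation is reported alongside.

## Haken–Strobl–Reineker diffusion tensor

Couplings use the extended-dipole approximation: charges ±q a distance l
apart along each molecule's transition-dipole axis, Coulomb-summed over
the four charge pairs; in the far field this reduces to the point-dipole
interaction with μ = q·l (verified to 1% at 25 nm separation in the
tests). Site energies and couplings are kept in cm⁻¹, converted to
angular frequency (×2πc) before the tensor is assembled, so Γ and ω_μν
share rad/fs units and the Lorentzian weight Γ/(Γ²+ω²) has units of
time; D emerges in nm²/fs and is reported in nm²/ps.

The flux operator along direction u is built from the antisymmetric
matrix (u·r_mn)J_nm rotated into the eigenbasis; its Hermiticity and the
closed dimer form |ĵ₊₋(z)| = a|J| are asserted in the tests. Axial (z)
displacements are plain coordinate differences; circumferential (φ)
displacements are arc lengths on the unrolled cylinder with
minimum-image wrapping of the angle, measured about the molecular
centroid so the tensor is invariant under rigid translations. Boltzmann
weights are referenced to the band bottom; this cancels in the Z
normalisation and only prevents overflow.

The microscopic structure parameters (extended-dipole l and q, dephasing
Γ, helical lattice and dipole tilt of each wall) are sample-specific
inputs with no defaults: the published axial values for C8S3
(23.9/16.3 nm²/ps, i.e. 43/29 molecules/ps at 1.8 molecules/nm² with two
molecules per unit cell) depend on a specific structural model that is
not part of this package, so the module is validated property-wise
instead — a literal quadruple-sum oracle at N ≤ 20, dimer/ring closed
forms, invariance under site-energy shifts and rigid translations,
non-negative diagonal elements, and the 1/Γ tail of the motional
narrowing limit.

## Global fitting

The experimental constraint is that one parameter pair θ = (H, R0) must
reproduce a whole fluence series with a single amplitude scale per
signal class. The objective is the detection-noise-weighted sum of
squared residuals over all series, with the two scales profiled out in
closed form (s = Σw·m·d / Σw·m², pooled over the class). Because the
forward model is Monte Carlo, the objective is noisy and has no usable
gradients; the fit is an exhaustive evaluation on a coarse grid
(default H ∈ {0.005…0.1}/fs, R0 ∈ {1…6}), returning the full objective
surface. Forward runs are seeded deterministically per (θ, density), so
fits are reproducible, and a forward cache lets re-noised replicates of
the same design reuse ensembles. Model curves are interpolated to the
data grid linearly in log-time (log(t + t_ref) with t_ref the smallest
positive model time), matching the log-sampled waiting-time axis.
Per-density adjustments within the stated experimental uncertainty are
supported in principle by refitting with shifted densities; the default
fit holds the nominal densities fixed.

## Synthetic data

The generator emulates the structure of the measured datasets: bundles
of absorptive and EEI transients on a 0–50 ps log-spaced grid (40
points by default), one file per (density, observable), at the
experimental density series — 19/64/625 molecules per exciton for
complete nanotubes, 18/83/165/404 for flash-diluted inner tubes. Noise
is additive white Gaussian with SD equal to a fixed fraction (default
5%) of each series' maximum, reflecting a detection-noise floor rather
than shot noise; the SD is written to the `sem` column, and the truth
sidecar round-trips the generating parameters.

What passing tests on synthetic data show: that the pipeline recovers
known ground truth under the stated study conditions — the estimators,
labelling rules and fit machinery are internally consistent. What they
do not show: robustness to features of real measurements that the
generator does not emulate — correlated or heteroscedastic noise,
transient-heating distortions at high fluence, baseline drifts, and
uncertainty in the absolute exciton density beyond the nominal values.

## Problem sizes and numerical tolerances

Scaled-down conditions used in the test suite were chosen to keep each
check a desk-scale computation while leaving the tested effect far above
its Monte Carlo error:

* diffusion constant: 100 realizations × 60 independent walkers, 10 ps
  (≈ 2% statistical error on D vs the 3.7% acceptance band);
* transfer plateau: 300 realizations at 1 exciton per 10⁴ molecules to
  10τ (binomial SEM ≈ 0.011 vs the ±0.03 band);
* cross-peak timing: the maximum is broad (the transient varies by only
  ~3% between 3 and 7 ps), so its argmax needs large ensembles —
  150–400 realizations depending on the context;
* parameter recovery: truth bundles on a 30 × 250 wall to 20 ps with
  the four-density flash-diluted series, forward ensembles of 8
  realizations, grid H ∈ {0.02…0.08} × R0 ∈ {2,3,4}.

Degenerate inputs are handled explicitly: 1×1 and 2-wide lattices fold
neighbours onto themselves (allowed); R0 = 0 disables annihilation and
marks the run MSD-eligible; density = 1 plants every site; all-zero
transients have no peak (error); the probability budget
dt/τ + H + max(k)·dt ≤ 1 is validated at construction.

## Known limitations

* Transport is purely diffusive and isotropic; coherent/wavelike
  contributions and exciton coherences are outside the model, so the
  fitted H is an effective incoherent hopping rate.
* The annihilation rule is a hard distance cutoff with unit probability;
  no distance-dependent rate law.
* The inter-wall site map is an idealisation of unknown real
  registration between incommensurate lattices.
* The HSR module yields tensors for user-supplied structures only; it
  does not ship a C8S3 structural model.
* MSD extraction assumes a single wall (no transfer); displacements
  across walls of different circumference have no common metric.
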