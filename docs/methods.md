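# Methods

## The disorder measure

`mixentropy` quantifies the disorder of a multicomponent system — a lattice
of discrete states or a fluid of labelled particles — through a
conditional-entropy estimate of the Shannon entropy per particle,

    S  ≈  H(σ_i | b_i)  =  H(σ_i, b_i) − H(b_i),

where σ_i is the state of particle (or site) i and b_i is a discrete
variable describing the state of its neighbourhood.  All entropies are
plug-in Shannon entropies in nats computed from raw observed frequencies
pooled over particles and frames; the Boltzmann constant is omitted, so a
balanced binary mixture is bounded by ln 2.  The convention 0·ln 0 = 0
applies throughout.

The key construction is the **half-space rule**: only neighbours whose
minimum-image displacement from i points into the upper half-space (last
coordinate positive; exact zeros resolved lexicographically on the earlier
axes, and on the lattice: dy > 0, or dy = 0 with dx > 0) enter b_i.
Counting each pair from one side only prevents the same pair correlation
from being conditioned on twice; on the lattice, this is what lets the
conditional entropy converge onto the exact entropy rather than
undershooting it.  In 1D, conditioning on the preceding symbols makes the
estimate exact for nearest-neighbour interactions and non-increasing in the
neighbourhood size, with the true entropy per symbol as its limit; the 2D
half-plane construction inherits that behaviour empirically (verified
against the exact Onsager solution in the acceptance suite).

Because the estimator is a conditional entropy of empirical frequencies it
is automatically bounded by the mean-field (composition) entropy above and
by 0 below, and is invariant under rigid translations, global label
permutations and (on the lattice) spin flips.  These invariants are
enforced by property tests.

## Comparison estimators

* **Mean field**: entropy of the pooled single-site/type marginal.  For any
  zero-magnetisation (equimolar) ensemble it returns ln 2 regardless of the
  actual order in the system — the failure mode that motivates the
  conditional measure.
* **Bethe (1D)**: S = S₂ − S₁ from adjacent-pair and site entropies; exact
  for nearest-neighbour chains, and identical to the conditional estimate
  with a single-predecessor neighbourhood.
* **Kikuchi / cluster variation (2D square lattice)**:
  S = S_square − S2_h − S2_v + S1 with the 2×2 square, both
  nearest-neighbour pair orientations, and the single site (per lattice
  site: one square, minus two pairs, plus one site).  The standard CVM
  combination; validated against the Onsager entropy.
* **Subregion (binned) Shannon entropy**: the box is divided into m^dim
  equal regions; the composition entropy of each non-empty region is
  averaged.  Correct in the fully mixed/demixed limits but strongly
  dependent on m, which is precisely what the clustered-configuration test
  demonstrates.

## Neighbourhood discretisations for particles

Three ways to turn the half-space environment of a particle into a
discrete state (`NeighbourhoodSpec`):

* **NB-cutoff** (`variant="cutoff"`, default k = 6): ordered types of the
  k nearest half-space neighbours; q^k states.  k = 6 keeps the joint
  state space at 2·2⁶ = 128 cells, adequately sampled by a single
  n ≈ 10⁴ snapshot.
* **NB-shell** (`variant="shell"`, default shells (4, 8)): per-shell type
  counts, ignoring order within a shell; far fewer states than NB-cutoff
  at the same depth.
* **NB-weight** (`variant="weight"`, default 32 bins): exponentially
  distance-weighted type frequencies
  f_i(c) = Σ_j 1[type_j = c] e^(−r_ij/λ) / Σ_j e^(−r_ij/λ),
  binned uniformly on [0, 1] for the first q − 1 components (the last is
  redundant on the simplex); f = 1 is clamped into the top bin, so a
  binary system has exactly `n_bins` states.  λ defaults to half the mean
  inter-particle spacing, (V/n)^(1/dim)/2.  The sum is truncated at 8λ,
  beyond which a neighbour contributes < 4·10⁻⁴ of the normalisation.

Particles with too few half-space neighbours (possible near open
boundaries or at tiny n) are skipped and tallied, not errors; the tally is
reported on every estimate.  Undersampling (mean count per occupied joint
cell < 10) sets a warning flag; no bias correction is applied, because the
measure is used comparatively and the raw plug-in estimate is what the
bounds and invariants above refer to.

## Exact references

* **Onsager** (2D square-lattice Ising, J = k_B = 1): free energy from the
  single-integral reduction of the double integral (the inner angular
  integral has the closed form 2π ln[(a + √(a²−b²))/2]); internal energy
  from the complete-elliptic-integral form, with the vanishing prefactor
  taken analytically at T_c where K(m) diverges.  Quadrature tolerance
  1e−10 with the integration split at the logarithmic singularity.
  S(T) = (u − f)/T; cross-validated in the tests against thermodynamic
  integration of C(T)/T from the high-temperature limit (agreement 1e−5)
  and u(T_c) = −√2.
* **Transfer matrix** (1D): S = ln(2 cosh(J/T)) − (J/T) tanh(J/T).
* **Exhaustive enumeration** (periodic L ≤ 4): exact S = (U − F)/(T N)
  from the full partition function, plus the exact conditional entropy for
  any neighbourhood, obtained by pushing the Boltzmann-weighted ensemble
  of all 2^(L²) configurations through the same estimator code path used
  for Monte-Carlo samples (estimators accept per-frame weights for this
  purpose).  Note that on L = 3–4 periodic lattices the exact conditional
  entropy sits slightly *below* the exact entropy (by 0.01–0.04 nats at
  T = 3) because wrap-around correlations are visible to the
  neighbourhood; in the thermodynamic limit the conditional estimate is an
  upper bound instead.

## Simulators (the study conditions)

**Ising Monte-Carlo.** Metropolis acceptance min(1, e^(−ΔE/T)); one sweep
is L² attempted moves.  Glauber attempts single-spin flips; Kawasaki
proposes exchanging a uniformly random site with a uniformly random one of
its four neighbours (equal-spin exchanges count as attempts), conserving
the magnetisation exactly; we work at exactly zero magnetisation via a
balanced random initial condition.  Defaults: 1000 burn-in sweeps,
thinning 10, 2000 sampled sweeps — enough that autocorrelation away from
T_c is negligible; the quantitative comparisons avoid |T − T_c| < 0.15,
where critical slowing down would require far longer runs.  Lattice sizes
used in the validation suite: L = 64 (Glauber), L = 48 (Kawasaki) — large
enough that finite-size effects are below the stated tolerances while an
ensemble takes seconds.

**Brownian dynamics.** 2D overdamped Euler–Maruyama integration,
x ← x + (F/γ)dt + √(2k_BT dt/γ)η, of n Lennard-Jones particles
(σ = ε_AB = k_B = 1, 50/50 binary composition, periodic square box,
density 0.85 σ⁻² — closely packed but fluid).  In **mix** mode every pair
interaction is truncated at the potential minimum 2^(1/6)σ, the unique
cut-off that leaves a purely repulsive force, so the two species are
mechanically identical and mix by diffusion.  In **demix** mode the A-B
interaction is unchanged while A-A and B-B get ε = 2 with the cut-off
extended to 2.5σ; at T = 1 this same-type attraction drives spinodal
decomposition.  Defaults γ = 1, dt = 2·10⁻⁴ (the largest step that stays
stable under the ε = 2 attraction at this density; any per-step
displacement > 0.5σ aborts with advice to reduce dt).  Forces use a
linked-cell list with Newton's-third-law pair iteration; an O(n²)
brute-force reference path is tested to give identical forces.  Potentials
are truncated, not shifted: BD needs only forces.  The validation runs use
n = 4096 with 3·10⁵ demixing steps (t = 60), by which point the
conditional entropy has fallen ≈ 0.34 nats from ln 2 — domain growth
continues beyond, but slowly (diffusive coarsening).

**Synthetic configurations.** Deterministic label patterns on a jittered
square lattice (jitter ±0.25 spacing; the BD initial condition uses ±0.1
to avoid overlapping LJ cores): `mixed` (i.i.d. labels), `demixed` (labels
split at the composition quantile of x, giving two flat interfaces under
periodicity), `clustered` (type-A discs of a given radius on a type-B
background, centres placed by random sequential addition with minimum
separation 2r).  The clustered study condition uses 180 domains of radius
3σ in the n = 10⁴ box (≈ 43% area fraction): domains small enough that a
10×10 subregion grid (~100 particles per region) still sees near-balanced
compositions, which is what makes the binned Shannon entropy blind to the
obvious local order while the conditional entropy drops to ≈ 0.37 nats.

What the generators deliberately do not emulate: thermal interface
roughness in `demixed`, polydisperse or anisotropic domains in
`clustered`, and any coupling between labels and positions in `mixed`.
Passing tests on them therefore validate the estimators' limits and
contrasts, not the realism of any particular membrane.

## Numerical choices and edge cases

* Exact distance ties in neighbour ranking are broken by particle index;
  lattice offsets are ordered by (distance², dy, dx).  Duplicate positions
  (zero displacement) are excluded from every half-space set.
* KD-trees (periodic `boxsize` variant where all axes are periodic) back
  the bulk state extraction; a brute-force per-particle path is the
  reference implementation and remains the fallback for mixed
  periodicity.  Both paths are asserted equal in the tests.
* The per-frame windowing of `entropy_time_series` defaults to single
  frames (window = 1), matching single-snapshot usage; pooling windows
  are available for variance reduction and are checked to be consistent
  on stationary data.
* MSD uses time-origin averaging on unwrapped coordinates; diffusion
  checks fit the first quarter of the lag range, where the estimator
  variance is smallest.
* RNG: every simulator consumes one `numpy` `default_rng(seed)`; the
  compiled kernels receive a single derived integer seed, making runs
  bit-reproducible on one platform.

## Known limitations

* Plug-in entropies are negatively biased when undersampled; the package
  flags but does not correct this (comparative use is the design point).
* The Kikuchi implementation covers the 2D square lattice only; the BD
  simulator is 2D only; Wolff/cluster Monte-Carlo moves are out of scope,
  so temperatures very close to T_c equilibrate slowly.
* The GRO reader extracts one bead per residue from a single frame; it is
  an adapter for analysing coarse-grained membrane snapshots, not a
  trajectory engine.
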