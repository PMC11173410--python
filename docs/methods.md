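# Methods

## Model

`cellmc` simulates a spherical electric double layer in the primitive model
of electrolytes. A single macroion — a hard sphere of radius R_M = 20 Å
carrying valence Z_M = −60 (surface charge density σ ≈ 0.19 C/m²) — is held
fixed at the center of a closed spherical cell of radius R_cell = 100 Å.
The cell radius fixes the macroion number density at ρ_M = 2.5·10⁻⁷ Å⁻³
(volume fraction 0.008), so the cell model represents a finite colloid
concentration. Mobile ions are charged hard spheres of radius R_I = 2 Å:

* counterions, Z = +1, count |Z_M| = 60;
* optionally a z:1 salt — cations of valence Z_c ∈ {3, 5} and monovalent
  anions — whose content is set by the salt ratio
  β = (total added cation charge)/|Z_M| and whose counts follow from exact
  integer stoichiometry (β = 6.25 with 3:1 salt means 125 cations and
  375 anions). Every assembled system is exactly electroneutral.

The solvent enters only through its relative dielectric constant ε (and
temperature, default 298 K). The pair energy is hard-sphere Coulomb:
infinite inside contact, otherwise Z_i Z_j l_B k_B T / r with the Bjerrum
length l_B = e²/(4π ε₀ ε k_B T) (≈ 7.2 Å for water, 28 Å at ε = 20).
Internally all lengths are in Å, energies in k_B T and charges in units of
e; the thermal voltage k_B T/e (≈ 25.68 mV at 298 K) converts reduced
potentials to millivolt on output.

The interaction sum runs over the particles actually present in the closed
cell: no periodic images, no Ewald sums, no dielectric discontinuity at the
macroion surface, no explicit solvent. The strength of counterion–counterion
correlations at the surface is summarized by the coupling parameter
Γ = Z² l_B / a_Z with a_Z = (Z e/σ)^{1/2}; Γ ≳ 2 marks the strongly
correlated regime where mean-field theory fails and overcharging becomes
possible (Γ ranges from 0.8 for monovalent ions in water to ≈ 34 for
pentavalent ions at ε = 20).

## Sampling

Canonical (NVT) Metropolis Monte Carlo on the ion positions; the macroion
never moves. Trial moves are:

* **translations** — a uniformly chosen ion is displaced uniformly inside a
  cube of side 2·`max_displacement` (default 10 Å). Any trial that
  penetrates the macroion core, another ion, or the cell wall (ion centers
  are confined to |r| ≤ R_cell − R_I so the whole sphere stays inside) is
  rejected outright; otherwise the move is accepted with probability
  min(1, e^{−ΔU/k_BT}), with ΔU assembled from the moved ion's pair terms
  only (O(N) per move);
* **position swaps** (`swap_fraction`, default 0 for salt-free work,
  0.15 in the salted preset) — two uniformly chosen ions exchange
  positions. The proposal is symmetric and all small ions share one
  hard-sphere radius, so detailed balance and the sampled distribution are
  untouched. Swaps matter at strong coupling with multivalent salt: with
  translations alone the monovalent/multivalent composition of the
  condensed layer is kinetically trapped. For the 3:1, β = 6.25, ε = 20
  system a translation-only chain started from random positions crawls to
  an accumulated-charge maximum of ≈ 13 e after 10⁵ moves/particle, while a
  chain started from an artificially overcharged layer relaxes to ≈ 29 e —
  two metastable branches. With 15% swaps the same system converges from a
  random start to ≈ 32 e with agreeing run halves within 4·10⁴
  moves/particle.

Randomness is pre-drawn in chunks from a seeded PCG64 generator, so a run
is bit-reproducible from (system, schedule, seed); the compiled kernels are
deterministic functions of their inputs. An optional step-size adapter
tunes `max_displacement` toward 40–60% acceptance during equilibration only
and freezes it before production.

Bookkeeping is audited continuously: the incrementally updated running
energy is compared against a from-scratch O(N²) recomputation at every
stored sample and must agree to 10⁻⁶ k_B T per 10⁵ moves, otherwise the run
aborts. An independent, deliberately naive pure-Python double-loop energy
(`brute_force_energy`) backs the test-suite oracles.

Schedules (moves are per particle): `desk` = 10⁴ equilibration + 10⁵
production, samples every 50; `desk-salted` = 10⁴ + 4·10⁴, samples every
20, 15% swaps; `production` = 10⁵ + 10⁶. The desk scales were chosen so that a
full validation pass (six solvents salt-free plus three β = 6.25 systems of
up to 560 ions) completes on one core in minutes while leaving the headline
observables converged: run halves of every reported salted system agree
within their error bars, and doubling the salt-free production changes the
reported scalars by less than one standard error.

## Observables

All structure is measured from the stored production samples as functions
of the distance r from the macroion center, with 0.5 Å bins by default.

* **g_MI(r)** — macroion–ion radial distribution function per species,
  normalized by the bin shell volume and by the species' mean density over
  the shell its centers can occupy, so an uncorrelated system gives exactly
  1 across that shell. Contact values (first bin at r ≥ 22 Å) depend on
  this bin convention; only their ordering and ratios are meaningful.
* **Z_acc(r)** — accumulated running charge: Z_M plus the sample-averaged
  net ion charge within r, computed by direct counting (the binned-RDF
  quadrature route is kept as an independent cross-check and agrees within
  one bin). Z_acc starts at Z_M at the surface and is exactly 0 at the
  wall; a positive lobe beyond the slipping plane is the charge-inversion
  signature. Its maximum is reported over 24 Å < r ≤ 60 Å, which separates
  the inversion lobe from the cation buildup at the confining wall.
* **φ(r)** — mean electrostatic potential, the field integral
  φ(r) = (k_B T/e) l_B ∫_r^{cut} Z_acc(r′)/r′² dr′ with a 60 Å cutoff
  (Z_acc has decayed essentially to zero there in all studied systems; the
  cutoff is configurable up to R_cell). The binned Z_acc is integrated as a
  piecewise-constant function with exact 1/r segment integrals, so the
  quadrature is exact for step profiles.
* **Scalars** — surface potential φ_s = φ(R_M); zeta potential
  ξ = φ(R_M + 2R_I) = φ(24 Å); effective charge Z_M^eff = Z_acc(26 Å), read
  one ion diameter beyond the macroion–ion contact; reduced energy
  U/(N k_B T) with N the number of mobile ions (a switch adds the macroion
  for the "all species" convention); contact g_MI. Standard errors come
  from block averaging over 20 contiguous blocks.

### The potential's dielectric reference

The Coulomb prefactor in the field integral is configurable
(`reference_epsilon`). With the solvent's own ε (the physically local
potential, `reference_epsilon=None`) the zeta potential of the salt-free
system is nearly flat from ε = 78 down to ε ≈ 54 and only then collapses:
the growth of l_B ∝ 1/ε almost exactly compensates the loss of diffuse
charge. Reported on a fixed aqueous reference (ε = 78 in the prefactor for
every solvent), the same runs give ξ = −110.7, −97.3, −77.1, −54.2, −35.3,
−15.5 mV across ε = 78…20 — monotone and nearly linear in ε. The canonical
sweep pipeline and the acceptance script report this water-referenced
scale, which is the convention under which the strongly coupled cell
model's published zeta values and their linear ε-trend are recovered; the
physical convention remains one keyword away.

### Planes

Two radii one ion radius apart carry the headline scalars: the slipping
plane at R_M + 2R_I = 24 Å (zeta potential: ξ = −110 mV reproduces the
aqueous salt-free reference value there) and the effective-charge plane at
contact + one ion diameter = 26 Å (Z_M^eff/Z_M = 0.54 in water and 0.07 at
ε = 20 are both reproduced there, while at 24 Å the same runs give 0.66 and
0.12). The package keeps the two definitions distinct rather than forcing
them onto one radius.

## Validation scope

The synthetic fixtures are exact toy configurations (collinear ion chains,
neutralizing shells, mixed-valence step profiles) whose energies, charge
profiles and potentials are computed by independent brute-force or
closed-form oracles — they validate bookkeeping, normalization and
quadrature, not physics. Physical validation rests on: the uncharged system
reproducing the ideal-gas RDF; a weakly charged macroion (|Z_M| = 2)
matching the linearized cell-model potential; and the converged production
systems reproducing the strongly coupled reference values quoted above.
What none of this shows: behaviour of real solvents beyond a dielectric
continuum (ion-specific, image-charge and solvation effects are absent by
construction), and primitive-model results at parameter corners far from
the studied grid.

## Known limitations

* The 3:1, β = 6.25 zeta potential at ε = 78 converges to ≈ +15.5 mV
  against a published ≈ +13 mV (our β = 4 value, +13.8 mV, matches the
  published plateau); the ε = 20 inversion maximum converges to ≈ 32 e
  against a published ≈ +37 e. Both are ~10–20% level disagreements in the
  strongest-coupling, highest-salt corner, where the published description
  of boundary conditions (periodic images with Ewald sums vs the closed
  cell implemented here) and the shorter published schedules for β = 6.25
  leave the most room for methodological divergence.
* Hard-constraint tolerances are exact comparisons in double precision;
  configurations imported from text files are revalidated on load.
* Block averaging with 20 blocks underestimates errors if the
  autocorrelation time exceeds a block (mitigated by the swap moves in the
  salted presets).
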