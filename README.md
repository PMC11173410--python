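# cellmc

Primitive-model Monte Carlo of spherical electric double layers: the ion
atmosphere around a highly charged colloidal sphere in solvents of varying
polarity, with or without multivalent salt.

`cellmc` is for people studying charged colloids — globular proteins,
micelles, latex or silica particles, nano-drug carriers — who need the ion
structure, effective charge and electrokinetic (zeta) potential of a
macroion beyond mean-field theory, where ion–ion correlations drive
phenomena like charge inversion that Poisson–Boltzmann/DLVO treatments miss
entirely.

## Model and method

A hard sphere of radius R_M = 20 Å and valence Z_M = −60 is fixed at the
center of a closed spherical cell of radius 100 Å (macroion volume fraction
0.008) together with its 60 monovalent counterions and, optionally, a z:1
salt (trivalent or pentavalent cations plus monovalent anions) at salt
ratio β = Z_c ρ_c / |Z_M ρ_M|. All ions are charged hard spheres of radius
2 Å; the solvent is a dielectric continuum of constant ε. The pair energy
is

    U_ij(r) = ∞                                r <  R_i + R_j
    U_ij(r) = Z_i Z_j e² / (4π ε₀ ε r)         r ≥  R_i + R_j

i.e. Z_i Z_j l_B / r in units of k_B T, with l_B = e²/(4π ε₀ ε k_B T) the
Bjerrum length. Ion positions are sampled by canonical (NVT) Metropolis
Monte Carlo (single-particle translations, plus optional position-swap
moves that equilibrate strongly coupled salted systems), and the stored
samples yield

* g_MI(r) — macroion–ion radial distribution functions,
* Z_acc(r) = Z_M + ⟨net ion charge within r⟩ — the accumulated running
  charge,
* φ(r) = (k_B T/e) l_B ∫_r^60Å Z_acc(r′)/r′² dr′ — the mean electrostatic
  potential,
* scalars: surface potential φ_s = φ(R_M), zeta potential
  ξ = φ(R_M + 2R_I), effective charge Z_M^eff = Z_acc(contact + 2R_I),
  reduced energy U/(N k_B T), with block-averaged standard errors.

Potentials are reported by default on a water-referenced scale (a fixed
aqueous ε in the Coulomb prefactor of the field integral) so that solvents
of different polarity are directly comparable; pass
`reference_epsilon=None` for the physically local potential. See
`docs/methods.md` for the full conventions and their rationale.

## Worked example

Simulate the salt-free 60:1 system in water and print its summary:

```
$ cellmc run --epsilon 78 --preset desk --seed 7 --outdir out/
{
 "epsilon_r": 78.0,
 "beta": 0.0,
 "surface_potential_mV": -194.31111335010854,
 "zeta_potential_mV": -110.24493930295873,
 "effective_charge_e": -32.36,
 "reduced_energy": -8.661454289964182,
 "contact_gMI": 155.98346262694298,
 "zacc_extremum_e": -38.4665,
 "acceptance_rate": 0.49209216666666666,
 ...
 "stderr_zeta_potential_mV": 0.282151348179025,
 "stderr_effective_charge_e": 0.0520728235010204,
 ...
}
```

Reading the numbers: the 60 counterions screen the bare charge of −60 e
down to an effective charge of −32.4 e one ion diameter from contact
(Z_M^eff/Z_M ≈ 0.54) — about half the bare charge is neutralized by the
condensed layer. The slipping-plane (zeta) potential is −110 mV, the
surface potential −194 mV, and the mean electrostatic energy is −8.7 k_B T
per ion. Repeating with `--epsilon 20` (an ethanol-like solvent, where the
counterion coupling parameter Γ reaches 3) collapses the effective charge
to ≈ −4.2 e (0.07 Z_M) and the water-referenced zeta potential to ≈ −15 mV.

Charge inversion appears with multivalent salt:

```
$ cellmc run --epsilon 78 --beta 6.25 --valence 5 --preset desk-salted --seed 7 --outdir out51/
```

gives ξ ≈ +41 mV — the pentavalent cations overcharge the macroion, so its
apparent charge flips sign. The run directory contains the profiles
(`gmi.csv`, `zacc.csv`, `phi.csv`), the summary JSON, the sampled
configurations in XYZ format and the system config (`system.yaml`).
`cellmc sweep` drives ε × β × valence grids with independent per-cell
seeds, and `cellmc summarize` recomputes observables from stored XYZ
trajectories.

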