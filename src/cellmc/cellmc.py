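"""Primitive-model Monte Carlo of a spherical electric double layer.

A single highly charged colloidal sphere (the *macroion*) sits fixed at the
center of a closed spherical cell that also contains its neutralizing
counterions and, optionally, an asymmetric z:1 salt.  All ions are charged
hard spheres; the solvent enters only through its relative dielectric
constant ``epsilon_r`` (the primitive model).  Canonical (NVT) Metropolis
Monte Carlo samples the ion positions, and from the stored configurations the
package computes the macroion--ion radial distribution function g_MI(r), the
accumulated running charge Z_acc(r), the mean electrostatic potential
phi(r), the surface and zeta potentials, the effective macroion charge and
the reduced electrostatic energy U/(N kB T).

The pair interaction is the bare Coulomb potential with hard-sphere
exclusion::

    U_ij(r) = +inf                              for r <  R_i + R_j
    U_ij(r) = Z_i Z_j e^2 / (4 pi eps0 eps r)   for r >= R_i + R_j

In internal units (lengths in angstrom, energies in kB T, charges in units
of the elementary charge e) the finite branch is ``Z_i Z_j l_B / r`` with
``l_B = e^2/(4 pi eps0 eps kB T)`` the Bjerrum length.  No periodic images
and no Ewald summation enter: the cell is closed and the Coulomb sum runs
over the particles actually present.

Sections below follow the order in which the method runs:

1.  Units, physical constants and logging.
2.  Model types and analytic quantities (Bjerrum length, surface charge
    density, counterion coupling parameter, salt stoichiometry).
3.  Configurations and energies (reference double-loop evaluation).
4.  Compiled Monte Carlo kernels (incremental O(N) Metropolis updates).
5.  The Monte Carlo engine (initial placement, stepping, full runs with
    energy-bookkeeping audits).
6.  Observables (g_MI, Z_acc, phi, scalar summaries with block-averaged
    errors).
7.  Pipeline (canonical system builder, dielectric x salt sweeps, file
    output, config serialization).
8.  Synthetic fixtures and independent brute-force oracles used by the
    test-suite (pure-Python energy sums, step-function charge profiles,
    closed-form potentials, a linearized cell-model reference).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

try:  # the compiled kernels are strongly recommended but not mandatory
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - exercised only without numba
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


logger = logging.getLogger("cellmc")

__all__ = [
    "ELEMENTARY_CHARGE",
    "VACUUM_PERMITTIVITY",
    "BOLTZMANN_CONSTANT",
    "SolventSpec",
    "MacroionSpec",
    "IonSpecies",
    "SystemSpec",
    "Configuration",
    "EnergyBreakdown",
    "McSchedule",
    "TrajectorySamples",
    "RadialProfile",
    "SummaryResult",
    "SweepGrid",
    "SweepReport",
    "Fixture",
    "PackingError",
    "EnergyAuditError",
    "CompositionError",
    "bjerrum_length",
    "thermal_voltage_mV",
    "surface_charge_density",
    "coupling_parameter",
    "salt_composition",
    "pair_energy",
    "total_energy",
    "initial_configuration",
    "metropolis_step",
    "run_simulation",
    "radial_distribution",
    "accumulated_charge",
    "accumulated_charge_via_rdf",
    "mean_potential",
    "potential_at",
    "profile_value",
    "summarize",
    "build_system",
    "run_single",
    "run_sweep",
    "cell_seed",
    "SCHEDULE_PRESETS",
    "SOLVENT_EPSILONS",
    "DEFAULT_BETAS",
    "AQUEOUS_REFERENCE_EPSILON",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
    "write_profile_csv",
    "write_summary_json",
    "write_xyz",
    "read_xyz",
    "save_checkpoint",
    "load_checkpoint",
    "make_energy_fixtures",
    "make_profile_fixtures",
    "reduced_reference_run",
    "REFERENCE_PRESETS",
    "brute_force_energy",
    "step_accumulated_charge",
    "step_potential_mV",
    "linearized_cell_potential_mV",
]


# ---------------------------------------------------------------------------
# 1. Units, physical constants, logging defaults
# ---------------------------------------------------------------------------
#
# Internal units: lengths in angstrom (A), energies in kB*T, charges in units
# of the elementary charge e.  Potentials are converted to millivolt on
# output through the thermal voltage kB*T/e (~25.7 mV at 298 K).  Keeping the
# hot path in reduced units removes SI round-off from the Metropolis loop.

ELEMENTARY_CHARGE = 1.602176634e-19  # C (exact, CODATA 2018)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN_CONSTANT = 1.380649e-23  # J/K (exact)
ANGSTROM = 1e-10  # m

DEFAULT_TEMPERATURE = 298.0  # K
DEFAULT_BIN_WIDTH = 0.5  # A
DEFAULT_CUTOFF = 60.0  # A, upper limit of the potential integral
DEFAULT_BLOCKS = 20  # block-averaging blocks for error bars

# Energy-bookkeeping audit: the running (incrementally updated) total energy
# must agree with a from-scratch recomputation to this tolerance per 1e5
# attempted moves.
AUDIT_TOL_PER_1E5_MOVES = 1e-6  # kB*T


def _configure_default_logging() -> None:
    """Attach a stderr handler once, if the application configured none."""
    if not logger.handlers and not logging.getLogger().handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.WARNING)


_configure_default_logging()


class PackingError(RuntimeError):
    """Random insertion failed: the requested ion content does not fit."""


class EnergyAuditError(RuntimeError):
    """Incremental energy bookkeeping diverged from a full recomputation."""


class CompositionError(ValueError):
    """A salt ratio beta that does not correspond to integer ion counts."""


# ---------------------------------------------------------------------------
# 2. Model types and analytic quantities
# ---------------------------------------------------------------------------

COUNTERION = "counterion"
SALT_CATION = "salt_cation"
SALT_ANION = "salt_anion"
SPECIES_LABELS = (COUNTERION, SALT_CATION, SALT_ANION)


@dataclass(frozen=True)
class SolventSpec:
    """Dielectric continuum solvent: relative permittivity and temperature.

    epsilon_r : relative dielectric constant (dimensionless, > 1)
    temperature : absolute temperature in kelvin
    """

    epsilon_r: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not self.epsilon_r > 1.0:
            raise ValueError(f"epsilon_r must exceed 1, got {self.epsilon_r}")
        if not self.temperature > 0.0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


@dataclass(frozen=True)
class MacroionSpec:
    """The fixed central colloidal sphere: hard-core radius (A) and valence."""

    radius: float
    valence: int

    def __post_init__(self) -> None:
        if not self.radius > 0.0:
            raise ValueError("macroion radius must be positive")


@dataclass(frozen=True)
class IonSpecies:
    """One mobile hard-sphere ion species.

    ``label`` tags the physical role (counterion, salt cation, salt anion);
    ``valence`` may be zero only for uncharged reference systems, which are
    used as the uncorrelated (ideal-gas) limit in validation.
    """

    label: str
    radius: float
    valence: int
    count: int

    def __post_init__(self) -> None:
        if self.label not in SPECIES_LABELS:
            raise ValueError(f"unknown species label {self.label!r}")
        if not self.radius > 0.0:
            raise ValueError("ion radius must be positive")
        if self.count < 0:
            raise ValueError("ion count must be non-negative")


@dataclass(frozen=True)
class SystemSpec:
    """Full physical description of one cell-model system.

    Invariants enforced on construction:

    * exact electroneutrality (integer arithmetic):
      ``Z_M + sum(count_i * Z_i) == 0``;
    * the cell encloses the macroion plus at least one ion diameter;
    * ``beta`` (total added-cation charge over total macroion charge)
      is consistent with the listed salt-cation counts.
    """

    solvent: SolventSpec
    macroion: MacroionSpec
    species: tuple[IonSpecies, ...]
    cell_radius: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        net = self.macroion.valence + sum(s.count * s.valence for s in self.species)
        if net != 0:
            raise ValueError(f"system is not electroneutral: net charge {net} e")
        max_ion_r = max((s.radius for s in self.species), default=0.0)
        if not self.cell_radius > self.macroion.radius + max_ion_r:
            raise ValueError("cell radius must exceed macroion radius + ion radius")
        if self.beta < 0.0:
            raise ValueError("beta must be non-negative")
        cation_charge = sum(
            s.count * s.valence for s in self.species if s.label == SALT_CATION
        )
        if self.macroion.valence != 0:
            implied = cation_charge / abs(self.macroion.valence)
            if abs(implied - self.beta) > 1e-9:
                raise ValueError(
                    f"beta={self.beta} inconsistent with salt content "
                    f"(implied {implied})"
                )
        elif cation_charge != 0:
            raise ValueError("salt cations present but macroion is uncharged")

    # -- derived array views used throughout the engine ---------------------

    @property
    def n_ions(self) -> int:
        return sum(s.count for s in self.species)

    def ion_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-ion (radii, valences, species_index) arrays, species order."""
        radii = np.concatenate(
            [np.full(s.count, s.radius) for s in self.species]
        ) if self.species else np.empty(0)
        val = np.concatenate(
            [np.full(s.count, float(s.valence)) for s in self.species]
        ) if self.species else np.empty(0)
        sidx = np.concatenate(
            [np.full(s.count, k, dtype=np.int64) for k, s in enumerate(self.species)]
        ) if self.species else np.empty(0, dtype=np.int64)
        return radii.astype(np.float64), val.astype(np.float64), sidx

    def species_by_label(self, label: str) -> IonSpecies:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(f"no species labelled {label!r}")

    def _counterion_radius(self) -> float:
        try:
            return self.species_by_label(COUNTERION).radius
        except KeyError:
            return self.species[0].radius if self.species else 0.0

    @property
    def zeta_plane(self) -> float:
        """Slipping-plane radius R_M + 2 R_I, with R_I the counterion radius
        (falls back to the first species for exotic compositions)."""
        return self.macroion.radius + 2.0 * self._counterion_radius()

    @property
    def effective_charge_plane(self) -> float:
        """Radius where the effective charge is read off: one ion diameter
        beyond macroion-ion contact, (R_M + R_I) + 2 R_I.  This is the plane
        at which the published effective-charge fractions of the strongly
        coupled cell model are reproduced; the slipping plane used for the
        zeta potential sits one ion radius closer in."""
        return self.macroion.radius + 3.0 * self._counterion_radius()


def bjerrum_length(solvent: SolventSpec) -> float:
    """Bjerrum length l_B = e^2/(4 pi eps0 eps_r kB T), in angstrom.

    l_B is the separation at which two unit charges interact with thermal
    energy kB*T; it sets the strength of every Coulomb term in reduced units.
    """
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0
        * math.pi
        * VACUUM_PERMITTIVITY
        * solvent.epsilon_r
        * BOLTZMANN_CONSTANT
        * solvent.temperature
    )
    return lb_m / ANGSTROM


def thermal_voltage_mV(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kB*T/e in millivolt (~25.68 mV at 298 K); converts reduced potentials."""
    return 1e3 * BOLTZMANN_CONSTANT * temperature / ELEMENTARY_CHARGE


def surface_charge_density(macroion: MacroionSpec) -> float:
    """Macroion surface charge density |Z_M| e / (4 pi R_M^2) in C/m^2."""
    area = 4.0 * math.pi * (macroion.radius * ANGSTROM) ** 2
    return abs(macroion.valence) * ELEMENTARY_CHARGE / area


def coupling_parameter(valence: int, solvent: SolventSpec, sigma: float) -> float:
    """Counterion-counterion coupling parameter Gamma = Z^2 l_B / a_Z.

    ``a_Z = sqrt(Z e / sigma)`` is the mean separation of Z-valent
    counterions neutralizing a surface of charge density ``sigma`` (C/m^2).
    Gamma compares the Coulomb repulsion of neighbouring adsorbed counterions
    with kB*T; correlation-induced phenomena (overcharging, like-charge
    attraction) set in around Gamma >~ 2.
    """
    if valence <= 0:
        raise ValueError("coupling parameter is defined for positive valence")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a_z = math.sqrt(valence * ELEMENTARY_CHARGE / sigma) / ANGSTROM
    return valence**2 * bjerrum_length(solvent) / a_z


def salt_composition(
    beta: float, macroion: MacroionSpec, cation_valence: int
) -> tuple[int, int]:
    """Integer (n_cation, n_anion) for a z:1 salt at salt ratio ``beta``.

    beta = (total added cation charge) / (total macroion charge magnitude),
    so n_cation = beta |Z_M| / Z_c, and the stoichiometric monovalent anions
    number n_anion = n_cation * Z_c.  Together with |Z_M| monovalent
    counterions the full system is exactly electroneutral.  A beta that does
    not yield an integer cation count (beyond 1e-6) raises
    :class:`CompositionError` — it signals a malformed sweep grid.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if cation_valence <= 0:
        raise ValueError("cation valence must be positive")
    exact = beta * abs(macroion.valence) / cation_valence
    n_cation = int(round(exact))
    if abs(exact - n_cation) > 1e-6:
        raise CompositionError(
            f"beta={beta} with Z_c={cation_valence} gives non-integer "
            f"cation count {exact}"
        )
    return n_cation, n_cation * cation_valence


# ---------------------------------------------------------------------------
# 3. Configurations and energies
# ---------------------------------------------------------------------------


@dataclass
class Configuration:
    """Positions of all mobile ions, macroion-centered frame (angstrom)."""

    positions: np.ndarray  # (N, 3)
    species_index: np.ndarray  # (N,), index into SystemSpec.species

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.species_index.copy())

    def validate(self, spec: SystemSpec) -> None:
        """Raise if any hard constraint (overlap or wall) is violated."""
        radii, _, sidx = spec.ion_arrays()
        if self.positions.shape != (spec.n_ions, 3):
            raise ValueError("configuration does not match species counts")
        if not np.array_equal(sidx, self.species_index):
            raise ValueError("species indexing does not match the system spec")
        r0 = np.linalg.norm(self.positions, axis=1)
        if np.any(r0 < spec.macroion.radius + radii - 1e-12):
            raise ValueError("ion overlaps the macroion core")
        if np.any(r0 > spec.cell_radius - radii + 1e-12):
            raise ValueError("ion protrudes through the cell wall")
        if len(r0) > 1:
            diff = self.positions[:, None, :] - self.positions[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            contact = radii[:, None] + radii[None, :]
            iu = np.triu_indices(len(r0), k=1)
            if np.any(dist[iu] < contact[iu] - 1e-12):
                raise ValueError("ion-ion hard-sphere overlap")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Total electrostatic energy in kB*T, split into macroion-ion and
    ion-ion contributions.  ``overlap_flag`` marks any hard-constraint
    violation, in which case the totals carry the +inf sentinel."""

    total: float
    macroion_ion: float
    ion_ion: float
    overlap_flag: bool


def pair_energy(
    r: float,
    valence_i: int,
    valence_j: int,
    radius_i: float,
    radius_j: float,
    solvent: SolventSpec,
) -> float:
    """Hard-sphere Coulomb pair energy in kB*T; +inf inside hard contact."""
    if r <= 0:
        raise ValueError("separation must be positive")
    if r < radius_i + radius_j:
        return math.inf
    return valence_i * valence_j * bjerrum_length(solvent) / r


def total_energy(config: Configuration, spec: SystemSpec) -> EnergyBreakdown:
    """Exact double-loop total energy of a configuration (reference path).

    This vectorized all-pairs evaluation is the bookkeeping oracle for the
    incremental Metropolis updates; it shares no code with the compiled
    kernels.  Overlapping (or wall-violating) configurations return the
    +inf sentinel breakdown.
    """
    radii, val, _ = spec.ion_arrays()
    pos = np.asarray(config.positions, dtype=np.float64).reshape(-1, 3)
    n = pos.shape[0]
    if n == 0:
        return EnergyBreakdown(0.0, 0.0, 0.0, False)
    lb = bjerrum_length(spec.solvent)
    r0 = np.linalg.norm(pos, axis=1)
    overlap = bool(
        np.any(r0 < spec.macroion.radius + radii)
        or np.any(r0 > spec.cell_radius - radii)
    )
    u_macro = lb * spec.macroion.valence * float(np.sum(val / r0))
    u_ion = 0.0
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        iu = np.triu_indices(n, k=1)
        d = dist[iu]
        contact = (radii[:, None] + radii[None, :])[iu]
        if np.any(d < contact):
            overlap = True
        with np.errstate(divide="ignore"):
            u_ion = lb * float(np.sum((val[:, None] * val[None, :])[iu] / d))
    if overlap:
        return EnergyBreakdown(math.inf, math.inf, math.inf, True)
    return EnergyBreakdown(u_macro + u_ion, u_macro, u_ion, False)


# ---------------------------------------------------------------------------
# 4. Compiled Monte Carlo kernels
# ---------------------------------------------------------------------------
#
# The Metropolis loop is the only performance-critical code.  Randomness is
# pre-drawn in chunks from a seeded numpy Generator in the driver, so the
# kernels are pure deterministic functions of their inputs and trajectories
# are bit-reproducible regardless of compilation.


@njit(cache=False)
def _total_energy_kernel(pos, radii, val, z_m, lb):  # pragma: no cover - numba
    """Plain O(N^2) energy sum in kB*T; assumes a constraint-valid state."""
    n = pos.shape[0]
    u = 0.0
    for i in range(n):
        ri = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        u += z_m * val[i] * lb / ri
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            u += val[i] * val[j] * lb / math.sqrt(dx * dx + dy * dy + dz * dz)
    return u


@njit(cache=False)
def _mc_chunk_kernel(
    pos, radii, val, z_m, r_macro, r_cell, lb, idx, disp, u_accept, partner
):  # pragma: no cover - numba
    """Run one chunk of Metropolis moves in place.

    idx, disp, u_accept and partner are pre-drawn random streams.  When
    ``partner[m] < 0`` the move is a single-particle translation (uniform
    trial displacement ``disp[m]``); otherwise it is a position swap between
    ions ``idx[m]`` and ``partner[m]`` (a symmetric pair proposal that
    exchanges the identity of two ions in place, which decorrelates the
    composition of the condensed layer far faster than translations alone in
    strongly coupled salted systems).  Trial moves that violate the hard
    core, another ion's hard sphere or the cell wall are rejected outright;
    otherwise accepted with probability min(1, exp(-dU)).
    Returns (number accepted, summed accepted energy change in kB*T).
    """
    n = pos.shape[0]
    n_acc = 0
    du_sum = 0.0
    for m in range(idx.shape[0]):
        i = idx[m]
        j = partner[m]
        if j >= 0:
            # swap move: exchange positions of ions i and j
            if j == i or val[i] == val[j]:
                continue  # identity exchange: nothing to do
            if radii[i] != radii[j]:
                continue  # unequal cores could overlap; not proposed
            du = 0.0
            ri = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            rj = math.sqrt(pos[j, 0] ** 2 + pos[j, 1] ** 2 + pos[j, 2] ** 2)
            # the i-j pair term is unchanged; all other pair terms swap charge
            s_i = z_m / ri
            s_j = z_m / rj
            for k in range(n):
                if k == i or k == j:
                    continue
                dik = math.sqrt(
                    (pos[k, 0] - pos[i, 0]) ** 2
                    + (pos[k, 1] - pos[i, 1]) ** 2
                    + (pos[k, 2] - pos[i, 2]) ** 2
                )
                djk = math.sqrt(
                    (pos[k, 0] - pos[j, 0]) ** 2
                    + (pos[k, 1] - pos[j, 1]) ** 2
                    + (pos[k, 2] - pos[j, 2]) ** 2
                )
                s_i += val[k] / dik
                s_j += val[k] / djk
            du = lb * (val[i] - val[j]) * (s_j - s_i)
            if du <= 0.0 or u_accept[m] < math.exp(-du):
                for d in range(3):
                    tmp = pos[i, d]
                    pos[i, d] = pos[j, d]
                    pos[j, d] = tmp
                n_acc += 1
                du_sum += du
            continue
        xo = pos[i, 0]
        yo = pos[i, 1]
        zo = pos[i, 2]
        xn = xo + disp[m, 0]
        yn = yo + disp[m, 1]
        zn = zo + disp[m, 2]
        rn = math.sqrt(xn * xn + yn * yn + zn * zn)
        if rn < r_macro + radii[i] or rn > r_cell - radii[i]:
            continue
        ro = math.sqrt(xo * xo + yo * yo + zo * zo)
        du = z_m * val[i] * lb * (1.0 / rn - 1.0 / ro)
        ok = True
        for j in range(n):
            if j == i:
                continue
            dxn = pos[j, 0] - xn
            dyn = pos[j, 1] - yn
            dzn = pos[j, 2] - zn
            rjn = math.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
            if rjn < radii[i] + radii[j]:
                ok = False
                break
            dxo = pos[j, 0] - xo
            dyo = pos[j, 1] - yo
            dzo = pos[j, 2] - zo
            rjo = math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
            du += val[i] * val[j] * lb * (1.0 / rjn - 1.0 / rjo)
        if not ok:
            continue
        if du <= 0.0 or u_accept[m] < math.exp(-du):
            pos[i, 0] = xn
            pos[i, 1] = yn
            pos[i, 2] = zn
            n_acc += 1
            du_sum += du
    return n_acc, du_sum


def _kernel_total(pos: np.ndarray, radii, val, spec: SystemSpec) -> float:
    if pos.shape[0] == 0:
        return 0.0
    return float(
        _total_energy_kernel(
            pos, radii, val, float(spec.macroion.valence), bjerrum_length(spec.solvent)
        )
    )


# ---------------------------------------------------------------------------
# 5. Monte Carlo engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McSchedule:
    """Monte Carlo schedule.  All move counts are per mobile ion.

    ``sample_interval`` is the number of attempted moves per particle between
    stored production samples; ``max_displacement`` is half the side of the
    cubic trial-displacement box (angstrom).  With ``adapt_displacement`` the
    step is tuned toward 40-60% acceptance during equilibration and frozen
    before production, preserving detailed balance where samples are taken.

    ``swap_fraction`` is the probability that an attempted move is a
    position swap between two randomly chosen ions instead of a translation.
    Swaps leave the sampled distribution unchanged (symmetric proposals) but
    are essential for equilibrating the composition of the condensed layer
    in strongly coupled multivalent-salt systems, where translations alone
    leave the monovalent/multivalent balance at the macroion surface
    kinetically trapped.
    """

    equilibration_moves_per_particle: int = 10_000
    production_moves_per_particle: int = 100_000
    sample_interval: int = 50
    max_displacement: float = 10.0
    seed: int = 0
    adapt_displacement: bool = False
    swap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.swap_fraction < 1.0:
            raise ValueError("swap_fraction must lie in [0, 1)")
        if self.equilibration_moves_per_particle <= 0:
            raise ValueError("equilibration length must be positive")
        if self.production_moves_per_particle <= 0:
            raise ValueError("production length must be positive")
        if not 0 < self.sample_interval <= self.production_moves_per_particle:
            raise ValueError("sample_interval must be in (0, production length]")
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")


#: Named schedules.  "desk" scales are reduced relative to the "production"
#: schedule (1e6 moves per particle) to keep routine runs interactive;
#: docs/methods.md discusses the accuracy trade-off.
SCHEDULE_PRESETS: dict[str, McSchedule] = {
    "smoke": McSchedule(500, 2_000, 10, 10.0),
    "desk": McSchedule(10_000, 100_000, 50, 10.0),
    "desk-salted": McSchedule(10_000, 40_000, 20, 10.0, swap_fraction=0.15),
    "production": McSchedule(100_000, 1_000_000, 100, 10.0),
}


@dataclass
class TrajectorySamples:
    """Decorrelated production samples of one run.

    ``positions`` has shape (n_samples, n_ions, 3); ``energies`` holds the
    exact (recomputed) total energy of each stored sample in kB*T.
    """

    positions: np.ndarray
    species_index: np.ndarray
    energies: np.ndarray
    acceptance_rate: float
    spec: SystemSpec
    schedule: McSchedule
    equilibration_acceptance: float = math.nan
    max_displacement_used: float = math.nan

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def configuration(self, k: int) -> Configuration:
        return Configuration(self.positions[k].copy(), self.species_index.copy())


def initial_configuration(spec: SystemSpec, seed) -> Configuration:
    """Uniform random non-overlapping placement of all ions in the cell.

    Each ion center is drawn uniformly in the spherical shell
    ``R_M + R_I <= |r| <= R_cell - R_I`` by cube rejection and re-drawn on
    any hard-sphere overlap with already placed ions.  Deterministic given
    the seed (an int or a ``numpy.random.Generator``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radii, _, sidx = spec.ion_arrays()
    n = spec.n_ions
    pos = np.empty((n, 3))
    max_attempts = 20_000
    for i in range(n):
        lo = spec.macroion.radius + radii[i]
        hi = spec.cell_radius - radii[i]
        placed = False
        for _ in range(max_attempts):
            trial = rng.uniform(-hi, hi, 3)
            r = math.sqrt(trial @ trial)
            if r < lo or r > hi:
                continue
            if i > 0:
                d = np.linalg.norm(pos[:i] - trial, axis=1)
                if np.any(d < radii[:i] + radii[i]):
                    continue
            pos[i] = trial
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place ion {i} of {n} after {max_attempts} attempts"
            )
    return Configuration(pos, sidx)


def metropolis_step(
    config: Configuration,
    spec: SystemSpec,
    max_displacement: float,
    rng: np.random.Generator,
) -> tuple[Configuration, float, bool]:
    """One single-particle Metropolis move (plain-Python reference path).

    Draws one ion, a uniform trial displacement in a cube of side
    ``2 * max_displacement`` and an acceptance uniform; returns the (possibly
    updated) configuration, the energy change of the attempted move in kB*T
    (0.0 for hard rejections) and whether it was accepted.  The energy change
    is assembled from the moved ion's pair terms only, which tests compare
    against :func:`total_energy` differences.
    """
    radii, val, _ = spec.ion_arrays()
    n = spec.n_ions
    if n == 0:
        return config, 0.0, False
    lb = bjerrum_length(spec.solvent)
    i = int(rng.integers(n))
    disp = rng.uniform(-max_displacement, max_displacement, 3)
    u = float(rng.random())
    old = config.positions[i]
    new = old + disp
    rn = float(np.linalg.norm(new))
    if rn < spec.macroion.radius + radii[i] or rn > spec.cell_radius - radii[i]:
        return config, 0.0, False
    ro = float(np.linalg.norm(old))
    du = spec.macroion.valence * val[i] * lb * (1.0 / rn - 1.0 / ro)
    if n > 1:
        others = np.arange(n) != i
        d_new = np.linalg.norm(config.positions[others] - new, axis=1)
        if np.any(d_new < radii[others] + radii[i]):
            return config, 0.0, False
        d_old = np.linalg.norm(config.positions[others] - old, axis=1)
        du += lb * val[i] * float(np.sum(val[others] * (1.0 / d_new - 1.0 / d_old)))
    if du <= 0.0 or u < math.exp(-du):
        out = config.copy()
        out.positions[i] = new
        return out, du, True
    return config, du, False


def _run_chunk(
    pos: np.ndarray,
    radii: np.ndarray,
    val: np.ndarray,
    spec: SystemSpec,
    n_moves: int,
    max_disp: float,
    rng: np.random.Generator,
    swap_fraction: float = 0.0,
) -> tuple[int, float]:
    """Draw the random streams for ``n_moves`` moves and run the kernel."""
    n = pos.shape[0]
    idx = rng.integers(0, n, n_moves)
    disp = rng.uniform(-max_disp, max_disp, (n_moves, 3))
    u_acc = rng.random(n_moves)
    partner = np.full(n_moves, -1, dtype=np.int64)
    if swap_fraction > 0.0 and n > 1:
        is_swap = rng.random(n_moves) < swap_fraction
        partner[is_swap] = rng.integers(0, n, int(is_swap.sum()))
    n_ok, du = _mc_chunk_kernel(
        pos,
        radii,
        val,
        float(spec.macroion.valence),
        spec.macroion.radius,
        spec.cell_radius,
        bjerrum_length(spec.solvent),
        idx,
        disp,
        u_acc,
        partner,
    )
    return int(n_ok), float(du)


def run_simulation(spec: SystemSpec, schedule: McSchedule) -> TrajectorySamples:
    """Canonical Metropolis run: equilibrate, then sample the production phase.

    The macroion never moves.  Production samples are stored every
    ``schedule.sample_interval`` attempted moves per particle, and at every
    stored sample the incrementally tracked running energy is audited against
    a from-scratch recomputation (tolerance ``AUDIT_TOL_PER_1E5_MOVES``
    scaled by the audit interval); divergence raises
    :class:`EnergyAuditError`.  Trajectories are bit-reproducible from
    ``(spec, schedule)`` including the seed.
    """
    radii, val, sidx = spec.ion_arrays()
    n = spec.n_ions
    ss = np.random.SeedSequence(schedule.seed)
    seed_init, seed_moves = ss.spawn(2)
    config = initial_configuration(spec, np.random.default_rng(seed_init))
    pos = np.ascontiguousarray(config.positions, dtype=np.float64)
    rng = np.random.default_rng(seed_moves)

    n_samples = schedule.production_moves_per_particle // schedule.sample_interval
    if n == 0:
        return TrajectorySamples(
            positions=np.empty((n_samples, 0, 3)),
            species_index=sidx,
            energies=np.zeros(n_samples),
            acceptance_rate=math.nan,
            spec=spec,
            schedule=schedule,
        )

    max_disp = schedule.max_displacement
    running = _kernel_total(pos, radii, val, spec)

    # -- equilibration ------------------------------------------------------
    equil_moves = schedule.equilibration_moves_per_particle * n
    adapt_window = max(200 * n, 1)
    acc_eq = 0
    done = 0
    while done < equil_moves:
        chunk = min(adapt_window, equil_moves - done)
        n_ok, du = _run_chunk(
            pos, radii, val, spec, chunk, max_disp, rng, schedule.swap_fraction
        )
        acc_eq += n_ok
        running += du
        done += chunk
        if schedule.adapt_displacement:
            rate = n_ok / chunk
            if rate < 0.40:
                max_disp = max(0.2, max_disp * 0.8)
            elif rate > 0.60:
                max_disp = min(0.45 * spec.cell_radius, max_disp * 1.25)
    equil_acc = acc_eq / max(equil_moves, 1)

    # resync the running energy once before production
    running = _kernel_total(pos, radii, val, spec)

    # -- production ---------------------------------------------------------
    interval_moves = schedule.sample_interval * n
    audit_tol = AUDIT_TOL_PER_1E5_MOVES * max(1.0, interval_moves / 1e5)
    samples = np.empty((n_samples, n, 3))
    energies = np.empty(n_samples)
    acc_prod = 0
    for k in range(n_samples):
        n_ok, du = _run_chunk(
            pos,
            radii,
            val,
            spec,
            interval_moves,
            max_disp,
            rng,
            schedule.swap_fraction,
        )
        acc_prod += n_ok
        running += du
        exact = _kernel_total(pos, radii, val, spec)
        if abs(exact - running) > audit_tol:
            raise EnergyAuditError(
                f"running energy {running:.9f} vs recomputed {exact:.9f} kBT "
                f"after sample {k} ({interval_moves} moves/interval)"
            )
        running = exact
        samples[k] = pos
        energies[k] = exact
    acc_rate = acc_prod / (n_samples * interval_moves)
    logger.info(
        "run finished: N=%d, acceptance=%.3f (equil %.3f), step=%.2f A",
        n,
        acc_rate,
        equil_acc,
        max_disp,
    )
    return TrajectorySamples(
        positions=samples,
        species_index=sidx,
        energies=energies,
        acceptance_rate=acc_rate,
        spec=spec,
        schedule=schedule,
        equilibration_acceptance=equil_acc,
        max_displacement_used=max_disp,
    )


# ---------------------------------------------------------------------------
# 6. Observables
# ---------------------------------------------------------------------------


@dataclass
class RadialProfile:
    """A binned radial function measured from the macroion center.

    ``values`` (and optional ``stderr``) are reported at bin midpoints;
    ``bin_edges`` has one more entry than ``values``.  ``quantity`` is one of
    "g_MI" (dimensionless), "Z_acc" (units of e) or "phi" (mV).
    """

    bin_edges: np.ndarray
    values: np.ndarray
    quantity: str
    convention: str = "midpoint"
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.bin_edges.ndim != 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values/bin_edges length mismatch")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def profile_value(profile: RadialProfile, r: float) -> float:
    """Linear interpolation of a midpoint-convention profile at radius r."""
    return float(np.interp(r, profile.midpoints, profile.values))


def _radial_edges(spec: SystemSpec, bin_width: float) -> np.ndarray:
    n_bins = int(math.ceil((spec.cell_radius - spec.macroion.radius) / bin_width))
    edges = spec.macroion.radius + bin_width * np.arange(n_bins + 1)
    edges[-1] = min(edges[-1], spec.cell_radius)
    return edges


def _block_means(per_sample: np.ndarray, n_blocks: int) -> np.ndarray:
    """Split the leading axis into n_blocks contiguous blocks and average."""
    s = per_sample.shape[0]
    size = s // n_blocks
    trimmed = per_sample[: size * n_blocks]
    return trimmed.reshape(n_blocks, size, *per_sample.shape[1:]).mean(axis=1)


def radial_distribution(
    samples: TrajectorySamples,
    species: str = COUNTERION,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_blocks: int = DEFAULT_BLOCKS,
) -> RadialProfile:
    """Macroion-ion radial distribution function g_MI(r) for one species.

    The distance histogram is normalized per sample by the shell volume of
    each bin and by the species' mean number density over the region its
    centers can occupy (the shell ``R_M + R_s <= r <= R_cell - R_s``), so an
    uncorrelated (uncharged) system gives g = 1 across that shell.  Standard
    errors come from block averaging.
    """
    spec = samples.spec
    sp_idx = [k for k, s in enumerate(spec.species) if s.label == species]
    if not sp_idx or sum(spec.species[k].count for k in sp_idx) == 0:
        raise ValueError(f"no ions of species {species!r} in the system")
    mask = np.isin(samples.species_index, sp_idx)
    r_s = spec.species_by_label(species).radius
    pos = samples.positions[:, mask, :]
    dist = np.linalg.norm(pos, axis=2)  # (S, M)
    edges = _radial_edges(spec, bin_width)
    shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    lo = spec.macroion.radius + r_s
    hi = spec.cell_radius - r_s
    v_acc = 4.0 / 3.0 * math.pi * (hi**3 - lo**3)
    rho = dist.shape[1] / v_acc
    counts = np.stack([np.histogram(d, bins=edges)[0] for d in dist])
    g = counts / (rho * shell_vol)
    nb = min(n_blocks, samples.n_samples)
    stderr = None
    if nb >= 2:
        blocks = _block_means(g, nb)
        stderr = blocks.std(axis=0, ddof=1) / math.sqrt(nb)
    return RadialProfile(edges, g.mean(axis=0), "g_MI", stderr=stderr)


def _zacc_per_sample(samples: TrajectorySamples, grid: np.ndarray) -> np.ndarray:
    """Z_acc evaluated at each grid radius for each sample, by counting."""
    spec = samples.spec
    _, val, _ = spec.ion_arrays()
    dist = np.linalg.norm(samples.positions, axis=2)  # (S, N)
    s, n = dist.shape
    k = len(grid)
    out = np.empty((s, k))
    for a in range(s):
        # idx = first grid point >= r ; ion contributes to Z_acc(grid[j]) for j >= idx
        idx = np.searchsorted(grid, dist[a], side="left")
        w = np.bincount(idx, weights=val, minlength=k + 1)[:k]
        out[a] = np.cumsum(w)
    return out + spec.macroion.valence


def accumulated_charge(
    samples: TrajectorySamples,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_blocks: int = DEFAULT_BLOCKS,
) -> RadialProfile:
    """Mean accumulated running charge Z_acc(r), by direct counting.

    Z_acc(r) is the macroion valence plus the sample-averaged net ionic
    charge within radius r.  It starts at Z_M at the macroion surface and
    reaches exactly zero at the cell boundary (electroneutrality); a positive
    lobe beyond the slipping plane is the charge-inversion signature.
    """
    spec = samples.spec
    edges = _radial_edges(spec, bin_width)
    mids = 0.5 * (edges[:-1] + edges[1:])
    za = _zacc_per_sample(samples, mids)
    nb = min(n_blocks, samples.n_samples)
    stderr = None
    if nb >= 2:
        blocks = _block_means(za, nb)
        stderr = blocks.std(axis=0, ddof=1) / math.sqrt(nb)
    return RadialProfile(edges, za.mean(axis=0), "Z_acc", stderr=stderr)


def accumulated_charge_via_rdf(
    samples: TrajectorySamples, bin_width: float = DEFAULT_BIN_WIDTH
) -> RadialProfile:
    """Z_acc(r) assembled by quadrature of the binned per-species RDFs.

    Integrates ``sum_i Z_i rho_i g_i(r) 4 pi r^2`` bin by bin from contact
    outward.  Mathematically equivalent to the counting route up to one
    bin's discretization; the equivalence is asserted in tests, so the two
    code paths deliberately do not share intermediates.
    """
    spec = samples.spec
    edges = _radial_edges(spec, bin_width)
    total = np.zeros(len(edges) - 1)
    for s in spec.species:
        if s.count == 0 or s.valence == 0:
            continue
        g = radial_distribution(samples, s.label, bin_width, n_blocks=1)
        r_s = s.radius
        lo = spec.macroion.radius + r_s
        hi = spec.cell_radius - r_s
        rho = s.count / (4.0 / 3.0 * math.pi * (hi**3 - lo**3))
        shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        total += s.valence * rho * g.values * shell_vol
    values = spec.macroion.valence + np.cumsum(total)
    return RadialProfile(edges, values, "Z_acc", convention="right-edge-quadrature")


def mean_potential(
    zacc: RadialProfile,
    solvent: SolventSpec,
    upper_cutoff: float = DEFAULT_CUTOFF,
    reference_epsilon: float | None = None,
) -> RadialProfile:
    """Mean electrostatic potential phi(r) in mV from a Z_acc profile.

    phi(r) = (kB T / e) * l_B * int_r^cutoff Z_acc(r') / r'^2 dr', the radial
    integral of the spherically averaged field; by construction
    phi(cutoff) = 0.  The binned profile is integrated as a piecewise-
    constant function of r (exact 1/r segment integrals per bin), which is
    the natural reading of counting data and makes the quadrature exact for
    step-function charge profiles.

    ``reference_epsilon`` selects the dielectric constant entering the
    Coulomb prefactor of the field integral.  ``None`` (the default) uses the
    solvent's own epsilon_r — the physically local potential.  Passing the
    aqueous value (78) reports every solvent on a common water-referenced
    scale; that is the convention under which the strongly coupled cell
    model's zeta potentials vary monotonically (almost linearly) with
    epsilon, and the one the canonical sweep pipeline reports
    (see docs/methods.md for the full discussion).
    """
    mids = zacc.midpoints
    if upper_cutoff <= mids[0] or upper_cutoff > zacc.bin_edges[-1] + 1e-9:
        raise ValueError("cutoff outside the support of the Z_acc profile")
    lo = zacc.bin_edges[:-1]
    hi = np.minimum(zacc.bin_edges[1:], upper_cutoff)
    # exact per-bin integral of z_k / r^2 over the part of the bin below the
    # cutoff; bins entirely beyond the cutoff contribute nothing
    active = lo < upper_cutoff
    seg = np.where(active, zacc.values * (1.0 / lo - 1.0 / np.maximum(hi, lo)), 0.0)
    tail = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])  # sum of bins >= k
    keep = mids < upper_cutoff
    # phi at a midpoint: the remaining half of its own bin plus all outer bins
    phi_red = zacc.values * (1.0 / mids - 1.0 / np.maximum(hi, mids)) + tail[1:]
    eps_pref = reference_epsilon if reference_epsilon is not None else solvent.epsilon_r
    lb = bjerrum_length(SolventSpec(eps_pref, solvent.temperature))
    phi_mv = thermal_voltage_mV(solvent.temperature) * lb * phi_red
    n_keep = int(np.sum(keep))
    edges = zacc.bin_edges[: n_keep + 1]
    return RadialProfile(edges, phi_mv[:n_keep], "phi")


def potential_at(
    zacc: RadialProfile,
    solvent: SolventSpec,
    r: float,
    upper_cutoff: float = DEFAULT_CUTOFF,
    reference_epsilon: float | None = None,
) -> float:
    """Exact piecewise-constant potential integral evaluated at radius r (mV).

    Same convention and prefactor handling as :func:`mean_potential`; agrees
    with the returned profile at the bin midpoints and is exact at arbitrary
    radii (including bin edges such as the slipping plane).
    """
    lo = np.maximum(zacc.bin_edges[:-1], r)
    hi = np.minimum(zacc.bin_edges[1:], upper_cutoff)
    mask = lo < hi
    total = float(np.sum(zacc.values[mask] * (1.0 / lo[mask] - 1.0 / hi[mask])))
    eps_pref = reference_epsilon if reference_epsilon is not None else solvent.epsilon_r
    lb = bjerrum_length(SolventSpec(eps_pref, solvent.temperature))
    return thermal_voltage_mV(solvent.temperature) * lb * total


@dataclass
class SummaryResult:
    """Scalar observables of one run, with block-averaged standard errors.

    surface_potential_mV  phi_s = phi(R_M)
    zeta_potential_mV     xi = phi(R_M + 2 R_I), the slipping-plane potential
    effective_charge_e    Z_M^eff = Z_acc one ion diameter beyond contact
    reduced_energy        U / (N kB T), N per ``energy_norm``
    contact_gMI           counterion g_MI in the first bin beyond contact
    zacc_extremum_e       signed extremum of Z_acc between the slipping
                          plane and the potential cutoff (the window keeps
                          the charge-inversion lobe separate from the
                          cation buildup at the confining wall)
    """

    surface_potential_mV: float
    zeta_potential_mV: float
    effective_charge_e: float
    reduced_energy: float
    contact_gMI: float
    zacc_extremum_e: float
    stderr: dict[str, float]
    spec: SystemSpec
    schedule: McSchedule
    bin_width: float
    cutoff: float
    energy_norm: str
    reference_epsilon: float | None = None
    acceptance_rate: float = math.nan

    def to_record(self) -> dict:
        rec = {
            "epsilon_r": self.spec.solvent.epsilon_r,
            "beta": self.spec.beta,
            "surface_potential_mV": self.surface_potential_mV,
            "zeta_potential_mV": self.zeta_potential_mV,
            "effective_charge_e": self.effective_charge_e,
            "reduced_energy": self.reduced_energy,
            "contact_gMI": self.contact_gMI,
            "zacc_extremum_e": self.zacc_extremum_e,
            "acceptance_rate": self.acceptance_rate,
            "bin_width": self.bin_width,
            "cutoff": self.cutoff,
            "reference_epsilon": self.reference_epsilon,
            "seed": self.schedule.seed,
        }
        rec.update({f"stderr_{k}": v for k, v in self.stderr.items()})
        return rec


def _scalars_from_samples(
    samples: TrajectorySamples,
    sel: np.ndarray,
    bin_width: float,
    cutoff: float,
    n_small: int,
    reference_epsilon: float | None,
) -> dict[str, float]:
    """Scalar observables from a subset of samples (used per block)."""
    sub = TrajectorySamples(
        positions=samples.positions[sel],
        species_index=samples.species_index,
        energies=samples.energies[sel],
        acceptance_rate=samples.acceptance_rate,
        spec=samples.spec,
        schedule=samples.schedule,
    )
    spec = samples.spec
    r_zeta = spec.zeta_plane
    zacc = accumulated_charge(sub, bin_width, n_blocks=1)
    z_eff = float(
        _zacc_per_sample(sub, np.array([spec.effective_charge_plane])).mean()
    )
    window = (zacc.midpoints > r_zeta) & (zacc.midpoints <= cutoff)
    vals = zacc.values[window]
    extremum = float(vals[np.argmax(np.abs(vals))]) if len(vals) else math.nan
    g = radial_distribution(sub, COUNTERION, bin_width, n_blocks=1)
    contact = spec.macroion.radius + spec.species_by_label(COUNTERION).radius
    k_contact = int(np.searchsorted(g.bin_edges, contact - 1e-9, side="left"))
    phi_args = (zacc, spec.solvent)
    return {
        "surface_potential_mV": potential_at(
            *phi_args, spec.macroion.radius, cutoff, reference_epsilon
        ),
        "zeta_potential_mV": potential_at(
            *phi_args, r_zeta, cutoff, reference_epsilon
        ),
        "effective_charge_e": z_eff,
        "reduced_energy": float(sub.energies.mean()) / n_small,
        "contact_gMI": float(g.values[k_contact]),
        "zacc_extremum_e": extremum,
    }


def summarize(
    samples: TrajectorySamples,
    bin_width: float = DEFAULT_BIN_WIDTH,
    cutoff: float = DEFAULT_CUTOFF,
    n_blocks: int = DEFAULT_BLOCKS,
    energy_norm: str = "mobile",
    reference_epsilon: float | None = None,
) -> SummaryResult:
    """Scalar summary of a run: phi_s, zeta, Z_M^eff, U/NkBT and markers.

    ``energy_norm`` selects the N in U/(N kB T): "mobile" divides by the
    number of small ions (the default), "all" additionally counts the
    macroion.  ``reference_epsilon`` is forwarded to :func:`mean_potential`
    (None: the physical per-solvent prefactor).  Errors are block-averaged
    standard errors over ``n_blocks`` contiguous blocks; fewer than 10
    stored samples raise, as no meaningful blocking is possible.
    """
    if samples.n_samples < 10:
        raise ValueError("need at least 10 stored samples for block averaging")
    if energy_norm not in ("mobile", "all"):
        raise ValueError("energy_norm must be 'mobile' or 'all'")
    n_small = samples.spec.n_ions
    n_norm = n_small + (1 if energy_norm == "all" else 0)
    nb = min(n_blocks, samples.n_samples)
    full = _scalars_from_samples(
        samples,
        np.arange(samples.n_samples),
        bin_width,
        cutoff,
        n_norm,
        reference_epsilon,
    )
    size = samples.n_samples // nb
    block_vals: dict[str, list[float]] = {k: [] for k in full}
    for b in range(nb):
        sel = np.arange(b * size, (b + 1) * size)
        sc = _scalars_from_samples(
            samples, sel, bin_width, cutoff, n_norm, reference_epsilon
        )
        for k, v in sc.items():
            block_vals[k].append(v)
    stderr = {
        k: float(np.std(v, ddof=1) / math.sqrt(nb)) for k, v in block_vals.items()
    }
    return SummaryResult(
        **full,
        stderr=stderr,
        spec=samples.spec,
        schedule=samples.schedule,
        bin_width=bin_width,
        cutoff=cutoff,
        energy_norm=energy_norm,
        reference_epsilon=reference_epsilon,
        acceptance_rate=samples.acceptance_rate,
    )


# ---------------------------------------------------------------------------
# 7. Pipeline: canonical systems, sweeps, file formats, CLI backing
# ---------------------------------------------------------------------------

#: Dielectric constants of the solvents studied (water ... ethanol).
SOLVENT_EPSILONS = (78.0, 68.0, 54.0, 40.0, 30.0, 20.0)
#: Salt ratios covering the salt-free to overcharge-saturated regimes.
DEFAULT_BETAS = (0.0, 0.15, 0.45, 1.0, 4.0, 6.25)
#: Dielectric constant of the aqueous reference solvent.  The sweep pipeline
#: reports surface and zeta potentials on this common water-referenced scale
#: so that potentials of different solvents are directly comparable (and
#: vary monotonically with epsilon); see mean_potential and docs/methods.md.
AQUEOUS_REFERENCE_EPSILON = 78.0


def build_system(
    epsilon: float,
    beta: float = 0.0,
    cation_valence: int = 3,
    *,
    temperature: float = DEFAULT_TEMPERATURE,
    macroion_radius: float = 20.0,
    macroion_valence: int = -60,
    ion_radius: float = 2.0,
    cell_radius: float = 100.0,
) -> SystemSpec:
    """Assemble the canonical 60:1 cell-model system for one sweep cell.

    Defaults: a Z_M = -60 macroion of radius 20 A centered in a 100 A cell
    (macroion volume fraction 0.008), 60 monovalent counterions of radius
    2 A, and — for beta > 0 — a z:1 salt whose cation count follows from
    ``salt_composition``.  The assembled system is electroneutral by
    construction.
    """
    solvent = SolventSpec(epsilon, temperature)
    macroion = MacroionSpec(macroion_radius, macroion_valence)
    species = [IonSpecies(COUNTERION, ion_radius, 1, abs(macroion_valence))]
    if beta > 0:
        n_cat, n_an = salt_composition(beta, macroion, cation_valence)
        species.append(IonSpecies(SALT_CATION, ion_radius, cation_valence, n_cat))
        species.append(IonSpecies(SALT_ANION, ion_radius, -1, n_an))
    return SystemSpec(solvent, macroion, tuple(species), cell_radius, beta)


def cell_seed(base_seed: int, epsilon: float, beta: float, valence: int) -> int:
    """Stable per-cell seed (< 2^31) derived from the base seed and the cell."""
    key = f"{base_seed}|{epsilon:.6g}|{beta:.6g}|{valence}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def run_single(
    spec: SystemSpec,
    schedule: McSchedule,
    bin_width: float = DEFAULT_BIN_WIDTH,
    cutoff: float = DEFAULT_CUTOFF,
    reference_epsilon: float | None = AQUEOUS_REFERENCE_EPSILON,
) -> tuple[TrajectorySamples, SummaryResult]:
    """Simulate one system and summarize it (water-referenced potentials)."""
    samples = run_simulation(spec, schedule)
    return samples, summarize(
        samples, bin_width, cutoff, reference_epsilon=reference_epsilon
    )


@dataclass(frozen=True)
class SweepGrid:
    """A dielectric x salt-ratio x salt-valence sweep definition."""

    epsilons: tuple[float, ...] = SOLVENT_EPSILONS
    betas: tuple[float, ...] = DEFAULT_BETAS
    cation_valences: tuple[int, ...] = (3,)
    schedule: McSchedule = SCHEDULE_PRESETS["desk-salted"]
    base_seed: int = 0
    bin_width: float = DEFAULT_BIN_WIDTH
    cutoff: float = DEFAULT_CUTOFF
    reference_epsilon: float | None = AQUEOUS_REFERENCE_EPSILON

    def cells(self) -> list[tuple[float, float, int]]:
        out = []
        seen = set()
        for eps in self.epsilons:
            for beta in self.betas:
                for zc in self.cation_valences:
                    key = (eps, beta) if beta == 0 else (eps, beta, zc)
                    if key in seen:
                        continue  # salt-free cells do not depend on the valence
                    seen.add(key)
                    out.append((eps, beta, zc))
        return out


@dataclass
class SweepReport:
    """Aggregated sweep output: one record per grid cell plus provenance."""

    records: list[dict]
    provenance: dict

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def _provenance_hash(spec: SystemSpec, schedule: McSchedule) -> str:
    payload = json.dumps(
        {"spec": spec_to_dict(spec), "schedule": dataclasses.asdict(schedule)},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_sweep(grid: SweepGrid, outdir: str | Path | None = None) -> SweepReport:
    """Run every cell of the grid with independent, reproducible seeds.

    Each cell gets ``cell_seed(base_seed, eps, beta, valence)``, so cells can
    be recomputed individually.  When ``outdir`` is given, per-cell summary
    JSON and profile CSVs are written and completed cells (matching
    provenance hash) are skipped on re-entry.  Per-cell failures are logged
    and recorded; the sweep continues.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    records: list[dict] = []
    for eps, beta, zc in grid.cells():
        tag = f"eps{eps:g}_beta{beta:g}_z{zc}"
        try:
            spec = build_system(eps, beta, zc)
            seed = cell_seed(grid.base_seed, eps, beta, zc)
            schedule = dataclasses.replace(grid.schedule, seed=seed)
            phash = _provenance_hash(spec, schedule)
            summary_path = out / f"{tag}.summary.json" if out else None
            if summary_path and summary_path.exists():
                prev = json.loads(summary_path.read_text())
                if prev.get("provenance_hash") == phash:
                    logger.info("skipping completed cell %s", tag)
                    records.append(prev["record"])
                    continue
            samples, summary = run_single(
                spec, schedule, grid.bin_width, grid.cutoff, grid.reference_epsilon
            )
            rec = summary.to_record()
            rec.update(cation_valence=zc, provenance_hash=phash)
            records.append(rec)
            if out is not None:
                summary_path.write_text(
                    json.dumps(
                        {"provenance_hash": phash, "record": rec}, indent=1
                    )
                )
                write_profile_csv(
                    accumulated_charge(samples, grid.bin_width),
                    out / f"{tag}.zacc.csv",
                )
                write_xyz(out / f"{tag}.final.xyz", samples, last_only=True)
            logger.info(
                "cell %s: zeta=%.2f mV, Zeff=%.2f e, acc=%.2f",
                tag,
                rec["zeta_potential_mV"],
                rec["effective_charge_e"],
                rec["acceptance_rate"],
            )
        except Exception as exc:  # pragma: no cover - defensive sweep guard
            logger.error("cell %s failed: %s", tag, exc)
            records.append({"cell": tag, "error": str(exc)})
    prov = {
        "base_seed": grid.base_seed,
        "schedule": dataclasses.asdict(grid.schedule),
        "bin_width": grid.bin_width,
        "cutoff": grid.cutoff,
    }
    report = SweepReport(records, prov)
    if out is not None:
        report.to_dataframe().to_csv(out / "sweep_summary.csv", index=False)
        (out / "sweep_manifest.json").write_text(json.dumps(prov, indent=1))
    return report


# -- serialization and file formats -----------------------------------------


def spec_to_dict(spec: SystemSpec) -> dict:
    return {
        "solvent": {
            "epsilon_r": spec.solvent.epsilon_r,
            "temperature": spec.solvent.temperature,
        },
        "macroion": {
            "radius": spec.macroion.radius,
            "valence": spec.macroion.valence,
        },
        "species": [
            {
                "label": s.label,
                "radius": s.radius,
                "valence": s.valence,
                "count": s.count,
            }
            for s in spec.species
        ],
        "cell_radius": spec.cell_radius,
        "beta": spec.beta,
    }


def spec_from_dict(data: dict) -> SystemSpec:
    return SystemSpec(
        solvent=SolventSpec(**data["solvent"]),
        macroion=MacroionSpec(**data["macroion"]),
        species=tuple(IonSpecies(**s) for s in data["species"]),
        cell_radius=data["cell_radius"],
        beta=data.get("beta", 0.0),
    )


def save_spec(spec: SystemSpec, path: str | Path) -> None:
    """Write a SystemSpec as a YAML config (see README for field names)."""
    import yaml

    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_spec(path: str | Path) -> SystemSpec:
    import yaml

    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def write_profile_csv(profile: RadialProfile, path: str | Path) -> None:
    """Columns: r_mid, value, stderr (empty when no error estimate)."""
    lines = ["r_mid,value,stderr"]
    err = profile.stderr if profile.stderr is not None else [""] * len(profile.values)
    for r, v, e in zip(profile.midpoints, profile.values, err):
        lines.append(f"{r:.6g},{v:.8g},{e if e == '' else f'{e:.4g}'}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_summary_json(summary: SummaryResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_record(), indent=1))


_XYZ_NAMES = {COUNTERION: "CI", SALT_CATION: "CA", SALT_ANION: "AN"}


def write_xyz(
    path: str | Path,
    samples: TrajectorySamples,
    last_only: bool = False,
) -> None:
    """Multi-frame XYZ export of stored configurations (species as atom name).

    The fixed macroion is written as the first atom ("M") of every frame so
    snapshots are directly viewable.
    """
    spec = samples.spec
    labels = [_XYZ_NAMES[spec.species[k].label] for k in samples.species_index]
    frames = [samples.n_samples - 1] if last_only else range(samples.n_samples)
    out = []
    for f in frames:
        out.append(str(len(labels) + 1))
        out.append(
            f'frame={f} energy_kBT={samples.energies[f]:.6f} '
            f'epsilon={spec.solvent.epsilon_r:g} beta={spec.beta:g}'
        )
        out.append("M 0.0 0.0 0.0")
        for lab, p in zip(labels, samples.positions[f]):
            out.append(f"{lab} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_xyz(path: str | Path, spec: SystemSpec) -> TrajectorySamples:
    """Rebuild TrajectorySamples from a multi-frame XYZ written by write_xyz.

    Sample energies are recomputed exactly; acceptance statistics are not
    recoverable from snapshots and are reported as NaN.
    """
    radii, val, sidx = spec.ion_arrays()
    text = Path(path).read_text().splitlines()
    frames = []
    energies = []
    i = 0
    while i < len(text):
        n_atoms = int(text[i].strip())
        body = text[i + 2 : i + 2 + n_atoms]
        coords = []
        for line in body:
            parts = line.split()
            if parts[0] == "M":
                continue
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        pos = np.asarray(coords)
        if pos.shape[0] != spec.n_ions:
            raise ValueError("XYZ frame does not match the system spec")
        frames.append(pos)
        energies.append(_kernel_total(np.ascontiguousarray(pos), radii, val, spec))
        i += 2 + n_atoms
    return TrajectorySamples(
        positions=np.stack(frames),
        species_index=sidx,
        energies=np.asarray(energies),
        acceptance_rate=math.nan,
        spec=spec,
        schedule=SCHEDULE_PRESETS["smoke"],
    )


def save_checkpoint(
    path: str | Path,
    config: Configuration,
    rng: np.random.Generator,
    counters: dict | None = None,
) -> None:
    """JSON checkpoint: ion positions, RNG bit-generator state, counters."""
    payload = {
        "positions": config.positions.tolist(),
        "species_index": config.species_index.tolist(),
        "rng_state": rng.bit_generator.state,
        "counters": counters or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[Configuration, np.random.Generator, dict]:
    payload = json.loads(Path(path).read_text())
    config = Configuration(
        np.asarray(payload["positions"], dtype=np.float64),
        np.asarray(payload["species_index"], dtype=np.int64),
    )
    rng = np.random.default_rng()
    rng.bit_generator.state = payload["rng_state"]
    return config, rng, payload["counters"]


# ---------------------------------------------------------------------------
# 8. Synthetic fixtures and independent oracles
# ---------------------------------------------------------------------------
#
# Everything here is deliberately written against the *definitions* (naive
# Python loops, closed forms) rather than against the engine or observable
# code paths, so it can serve as an independent oracle in tests.


@dataclass
class Fixture:
    """A named toy configuration with oracle-computed expected values."""

    name: str
    spec: SystemSpec
    positions: np.ndarray
    expected: dict


def brute_force_energy(
    positions: Sequence[Sequence[float]],
    valences: Sequence[float],
    radii: Sequence[float],
    macroion_valence: float,
    macroion_radius: float,
    lb: float,
) -> float:
    """Naive pure-Python Coulomb sum in kB*T (the energy oracle).

    Returns +inf on any hard-sphere overlap (including with the macroion).
    """
    n = len(valences)
    u = 0.0
    for i in range(n):
        ri = math.sqrt(sum(c * c for c in positions[i]))
        if ri < macroion_radius + radii[i]:
            return math.inf
        u += macroion_valence * valences[i] * lb / ri
        for j in range(i + 1, n):
            d = math.sqrt(
                sum((positions[i][k] - positions[j][k]) ** 2 for k in range(3))
            )
            if d < radii[i] + radii[j]:
                return math.inf
            u += valences[i] * valences[j] * lb / d
    return u


def step_accumulated_charge(
    ion_radii: Sequence[float],
    ion_valences: Sequence[float],
    macroion_valence: float,
) -> Callable[[float], float]:
    """Counting oracle: the exact step function Z_acc(r) for fixed positions."""

    pairs = sorted(zip(ion_radii, ion_valences))

    def zacc(r: float) -> float:
        return macroion_valence + sum(v for s, v in pairs if s <= r)

    return zacc


def step_potential_mV(
    ion_radii: Sequence[float],
    ion_valences: Sequence[float],
    macroion_valence: float,
    solvent: SolventSpec,
    cutoff: float,
) -> Callable[[float], float]:
    """Closed-form potential oracle for a step-function Z_acc.

    For piecewise-constant Z_acc the integral int Z/r'^2 dr' is a sum of
    exact 1/r segments; no quadrature is involved.
    """
    steps = sorted(zip(ion_radii, ion_valences))
    pref = thermal_voltage_mV(solvent.temperature) * bjerrum_length(solvent)

    def phi(r: float) -> float:
        # segment boundaries between r and cutoff
        bounds = [r] + [s for s, _ in steps if r < s < cutoff] + [cutoff]
        total = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            mid = 0.5 * (a + b)
            z = macroion_valence + sum(v for s, v in steps if s <= mid)
            total += z * (1.0 / a - 1.0 / b)
        return pref * total

    return phi


def _fixture_spec(
    epsilon: float,
    counts: dict[str, tuple[int, int]],
    macroion_valence: int | None = None,
) -> SystemSpec:
    """Small helper: a cell-model spec with arbitrary (count, valence) per label."""
    z_total = sum(c * v for c, v in counts.values())
    z_m = -z_total if macroion_valence is None else macroion_valence
    species = tuple(
        IonSpecies(label, 2.0, v, c) for label, (c, v) in counts.items() if c > 0
    )
    cation_charge = sum(
        s.count * s.valence for s in species if s.label == SALT_CATION
    )
    beta = cation_charge / abs(z_m) if z_m != 0 else 0.0
    return SystemSpec(
        SolventSpec(epsilon), MacroionSpec(20.0, z_m), species, 100.0, beta
    )


def make_energy_fixtures() -> list[Fixture]:
    """Toy configurations whose energies are hand-checkable Coulomb sums.

    Positions sit at exact radii chosen off the default bin edges; expected
    energies are produced by :func:`brute_force_energy`, never by the engine.
    """
    fixtures = []

    # 1. single counterion near contact: macroion term only
    spec1 = _fixture_spec(78.0, {COUNTERION: (1, 1)}, macroion_valence=-1)
    pos1 = np.array([[22.3, 0.0, 0.0]])
    # 2. two counterions diametrically opposed: two macroion terms + one
    #    ion-ion term at twice the radius
    spec2 = _fixture_spec(78.0, {COUNTERION: (2, 1)}, macroion_valence=-2)
    pos2 = np.array([[0.0, 0.0, 24.2], [0.0, 0.0, -24.2]])
    # 3. collinear mixed-valence trio
    spec3 = _fixture_spec(
        40.0, {COUNTERION: (1, 1), SALT_CATION: (1, 3), SALT_ANION: (1, -1)},
        macroion_valence=-3,
    )
    pos3 = np.array([[22.3, 0.0, 0.0], [30.7, 0.0, 0.0], [44.9, 0.0, 0.0]])
    # 4. twenty-ion deterministic cloud for incremental-energy oracle tests
    spec4 = _fixture_spec(
        30.0, {COUNTERION: (11, 1), SALT_CATION: (2, 3), SALT_ANION: (7, -1)},
        macroion_valence=-10,
    )
    rng = np.random.default_rng(20240524)
    pos4 = initial_configuration(spec4, rng).positions

    for name, spec, pos in [
        ("single-contact", spec1, pos1),
        ("diametric-pair", spec2, pos2),
        ("collinear-trio", spec3, pos3),
        ("twenty-ion-cloud", spec4, pos4),
    ]:
        radii, val, _ = spec.ion_arrays()
        u = brute_force_energy(
            pos.tolist(),
            val.tolist(),
            radii.tolist(),
            spec.macroion.valence,
            spec.macroion.radius,
            bjerrum_length(spec.solvent),
        )
        fixtures.append(
            Fixture(name, spec, pos, {"energy_kBT": u})
        )
    return fixtures


def make_profile_fixtures() -> list[Fixture]:
    """Configurations at known radii with counting/closed-form expectations.

    Expected Z_acc values are exact step functions; expected potentials are
    exact piecewise 1/r integrals.  Radii avoid the default 0.5 A bin edges.
    """
    fixtures = []
    rng = np.random.default_rng(2484)

    def shell_points(radius: float, n: int) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        return radius * v

    # 1. bare macroion (no ions): Z_acc == Z_M, truncated-Coulomb potential
    spec0 = SystemSpec(
        SolventSpec(78.0), MacroionSpec(20.0, 0), (), 100.0, 0.0
    )
    fixtures.append(
        Fixture("bare", spec0, np.empty((0, 3)), {"ion_radii": [], "ion_valences": []})
    )
    # 2. one neutralizing shell: Z_acc jumps to zero, phi vanishes outside
    spec1 = _fixture_spec(78.0, {COUNTERION: (60, 1)})
    pos1 = shell_points(23.3, 60)
    fixtures.append(
        Fixture(
            "single-shell",
            spec1,
            pos1,
            {"ion_radii": [23.3] * 60, "ion_valences": [1.0] * 60},
        )
    )
    # 3. mixed-valence steps at staggered radii
    spec2 = _fixture_spec(
        40.0, {COUNTERION: (30, 1), SALT_CATION: (12, 3), SALT_ANION: (6, -1)}
    )
    radii_list = (
        [22.7] * 10 + [26.3] * 20 + [31.1] * 12 + [47.3] * 6
    )
    valences = [1.0] * 30 + [3.0] * 12 + [-1.0] * 6
    parts = [
        shell_points(22.7, 10),
        shell_points(26.3, 20),
        shell_points(31.1, 12),
        shell_points(47.3, 6),
    ]
    fixtures.append(
        Fixture(
            "mixed-steps",
            spec2,
            np.vstack(parts),
            {"ion_radii": radii_list, "ion_valences": valences},
        )
    )
    return fixtures


#: Reduced-scale canonical runs used as pinned regression anchors.
REFERENCE_PRESETS: dict[str, dict] = {
    "saltfree-78": {"epsilon": 78.0, "beta": 0.0, "valence": 3, "preset": "desk", "seed": 11},
    "saltfree-20": {"epsilon": 20.0, "beta": 0.0, "valence": 3, "preset": "desk", "seed": 12},
    "salt31-b6.25-20": {
        "epsilon": 20.0,
        "beta": 6.25,
        "valence": 3,
        "preset": "desk-salted",
        "seed": 13,
    },
}


def reduced_reference_run(preset: str) -> SummaryResult:
    """Run one named reduced-scale reference system and summarize it."""
    if preset not in REFERENCE_PRESETS:
        raise KeyError(f"unknown reference preset {preset!r}")
    p = REFERENCE_PRESETS[preset]
    spec = build_system(p["epsilon"], p["beta"], p["valence"])
    schedule = dataclasses.replace(SCHEDULE_PRESETS[p["preset"]], seed=p["seed"])
    _, summary = run_single(spec, schedule)
    return summary


def linearized_cell_potential_mV(spec: SystemSpec, r: np.ndarray) -> np.ndarray:
    """Linearized (Debye-Hueckel-like) cell-model potential, in mV.

    Solves the linearized Poisson-Boltzmann equation in the spherical shell
    between ion-center contact ``a = R_M + R_I`` and the wall
    ``b = R_cell - R_I`` with Gauss's law at ``a`` and zero field at ``b``,
    ion densities linearized about their cell-average values.  The result is
    gauged to phi(b) = 0, matching the convention of a potential integral cut
    off at the wall.  Valid only for weak electrostatic coupling; used as an
    independent limit check on the sampler, not as a production observable.
    """
    lb = bjerrum_length(spec.solvent)
    radii, val, _ = spec.ion_arrays()
    r_i = float(radii[0])
    a = spec.macroion.radius + r_i
    b = spec.cell_radius - r_i
    volume = 4.0 / 3.0 * math.pi * (b**3 - a**3)
    rho = np.array([s.count / volume for s in spec.species])
    z = np.array([float(s.valence) for s in spec.species])
    kappa2 = 4.0 * math.pi * lb * float(np.sum(rho * z**2))
    if kappa2 <= 0:
        raise ValueError("linearized profile needs charged mobile ions")
    kappa = math.sqrt(kappa2)
    z_m = spec.macroion.valence
    # particular (constant) solution balancing the neutralizing background
    psi_p = -4.0 * math.pi * lb * z_m / (kappa2 * volume)

    def f1(x):  # e^{-kx}/x and derivative
        return math.exp(-kappa * x) / x

    def df1(x):
        return -math.exp(-kappa * x) * (kappa * x + 1.0) / x**2

    def f2(x):
        return math.exp(kappa * x) / x

    def df2(x):
        return math.exp(kappa * x) * (kappa * x - 1.0) / x**2

    # boundary conditions: psi'(a) = -Z_M l_B / a^2 ; psi'(b) = 0
    mat = np.array([[df1(a), df2(a)], [df1(b), df2(b)]])
    rhs = np.array([-z_m * lb / a**2, 0.0])
    coef_a, coef_b = np.linalg.solve(mat, rhs)
    r = np.asarray(r, dtype=np.float64)
    psi = psi_p + coef_a * np.exp(-kappa * r) / r + coef_b * np.exp(kappa * r) / r
    psi_b = psi_p + coef_a * f1(b) + coef_b * f2(b)
    return thermal_voltage_mV(spec.solvent.temperature) * (psi - psi_b)
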