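"""Observables: RDF normalization, accumulated charge vs counting/quadrature
oracles, exact step-profile potentials, and summary error estimation."""

import dataclasses
import math

import numpy as np
import pytest

import cellmc as cm


def _samples_from_positions(spec, positions):
    """Wrap a single fixed configuration as a one-sample trajectory."""
    return cm.TrajectorySamples(
        positions=np.asarray(positions)[None, ...],
        species_index=spec.ion_arrays()[2],
        energies=np.zeros(1),
        acceptance_rate=math.nan,
        spec=spec,
        schedule=cm.SCHEDULE_PRESETS["smoke"],
    )


class TestRadialDistribution:
    def test_normalization_recovers_species_count(self, mc_run):
        samples = mc_run(78.0, preset="smoke")
        spec = samples.spec
        g = cm.radial_distribution(samples, "counterion", 0.5)
        edges = g.bin_edges
        shell = 4 / 3 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        rho = 60 / (4 / 3 * math.pi * (98.0**3 - 22.0**3))
        assert np.sum(g.values * rho * shell) == pytest.approx(60, rel=1e-9)

    def test_missing_species_raises(self, mc_run):
        with pytest.raises(ValueError):
            cm.radial_distribution(mc_run(78.0, preset="smoke"), "salt_cation")

    def test_contact_peak_grows_as_epsilon_drops(self, mc_run):
        g78 = cm.radial_distribution(mc_run(78.0, preset="smoke"))
        g20 = cm.radial_distribution(mc_run(20.0, preset="smoke"))
        k = int(np.searchsorted(g78.bin_edges, 22.0 - 1e-9))
        assert g20.values[k] > g78.values[k]
        # the maximum sits at hard-sphere contact
        assert np.argmax(g20.values) == k


class TestAccumulatedCharge:
    def test_boundary_values_exact(self, mc_run):
        za = cm.accumulated_charge(mc_run(78.0, preset="smoke"))
        assert za.values[0] == pytest.approx(-60.0)
        assert za.values[-1] == pytest.approx(0.0)

    def test_counting_matches_step_oracle_on_fixtures(self, profile_fixtures):
        for fx in profile_fixtures.values():
            if len(fx.expected["ion_radii"]) == 0:
                continue
            samples = _samples_from_positions(fx.spec, fx.positions)
            za = cm.accumulated_charge(samples)
            oracle = cm.step_accumulated_charge(
                fx.expected["ion_radii"],
                fx.expected["ion_valences"],
                fx.spec.macroion.valence,
            )
            for r in za.midpoints[:: 7]:
                assert cm.profile_value(za, r) == pytest.approx(oracle(r))

    def test_counting_matches_rdf_quadrature_within_one_bin(self, mc_run):
        samples = mc_run(78.0, preset="smoke")
        bw = 0.5
        za_count = cm.accumulated_charge(samples, bw)
        za_quad = cm.accumulated_charge_via_rdf(samples, bw)
        # quadrature accumulates to right bin edges, counting reads at
        # midpoints: agreement required within one bin's jump
        jump = np.max(np.abs(np.diff(za_count.values, prepend=-60.0)))
        interp = np.interp(
            za_count.midpoints, za_quad.bin_edges[1:], za_quad.values
        )
        assert np.max(np.abs(interp - za_count.values)) <= jump + 1e-9

    def test_salted_system_charge_inversion_sign(self, mc_run):
        samples = mc_run(20.0, 6.25, 3, preset="smoke")
        za = cm.accumulated_charge(samples)
        window = (za.midpoints > 24.0) & (za.midpoints <= 60.0)
        assert za.values[window].max() > 0  # inverted lobe present


class TestMeanPotential:
    def test_zero_charge_gives_zero_potential(self):
        edges = np.arange(20.0, 100.5, 0.5)
        za = cm.RadialProfile(edges, np.zeros(len(edges) - 1), "Z_acc")
        phi = cm.mean_potential(za, cm.SolventSpec(78.0), 60.0)
        assert np.all(phi.values == 0.0)

    def test_constant_charge_closed_form(self):
        edges = np.arange(20.0, 100.5, 0.5)
        q = -60.0
        za = cm.RadialProfile(edges, np.full(len(edges) - 1, q), "Z_acc")
        solvent = cm.SolventSpec(78.0)
        phi = cm.mean_potential(za, solvent, 60.0)
        pref = cm.thermal_voltage_mV() * cm.bjerrum_length(solvent)
        expected = pref * q * (1.0 / phi.midpoints - 1.0 / 60.0)
        assert np.allclose(phi.values, expected, rtol=1e-12)

    def test_step_profile_matches_closed_form_oracle(self):
        """Piecewise-constant Z_acc integrates exactly (1e-6 relative)."""
        solvent = cm.SolventSpec(40.0)
        edges = np.arange(20.0, 100.5, 0.5)
        mids = 0.5 * (edges[:-1] + edges[1:])
        # steps at bin edges 23.5 and 31.0: representable exactly by bins
        step_r = [23.5, 31.0]
        step_q = [40.0, 15.0]
        vals = np.full(len(mids), -60.0)
        vals[mids > 23.5] += 40.0
        vals[mids > 31.0] += 15.0
        za = cm.RadialProfile(edges, vals, "Z_acc")
        phi = cm.mean_potential(za, solvent, 60.0)
        oracle = cm.step_potential_mV(step_r, step_q, -60.0, solvent, 60.0)
        for r, v in zip(phi.midpoints, phi.values):
            assert v == pytest.approx(oracle(r), rel=1e-6, abs=1e-9)
        # point evaluation agrees too, including at a bin edge
        assert cm.potential_at(za, solvent, 24.0, 60.0) == pytest.approx(
            oracle(24.0), rel=1e-6
        )

    def test_neutralized_shell_has_zero_outer_potential(self, profile_fixtures):
        fx = profile_fixtures["single-shell"]
        samples = _samples_from_positions(fx.spec, fx.positions)
        za = cm.accumulated_charge(samples)
        phi = cm.mean_potential(za, fx.spec.solvent, 60.0)
        outside = phi.midpoints > 23.75
        assert np.allclose(phi.values[outside], 0.0, atol=1e-9)

    def test_potential_monotone_toward_cutoff_saltfree(self, mc_run):
        phi = cm.mean_potential(
            cm.accumulated_charge(mc_run(78.0, preset="smoke")),
            cm.SolventSpec(78.0),
            60.0,
        )
        assert np.all(np.diff(phi.values) > 0)  # negative, rising to 0
        assert abs(phi.values[-1]) < abs(phi.values[0])

    def test_cutoff_outside_support_raises(self, mc_run):
        za = cm.accumulated_charge(mc_run(78.0, preset="smoke"))
        with pytest.raises(ValueError):
            cm.mean_potential(za, cm.SolventSpec(78.0), 150.0)


class TestSummarize:
    def test_too_few_samples_raises(self, mc_run):
        samples = mc_run(78.0, preset="smoke")
        short = dataclasses.replace(
            samples, positions=samples.positions[:5], energies=samples.energies[:5]
        )
        with pytest.raises(ValueError, match="block"):
            cm.summarize(short)

    def test_standard_errors_nonnegative_and_finite(self, summaries):
        s = summaries(78.0, preset="smoke")
        for k, v in s.stderr.items():
            assert v >= 0 and math.isfinite(v)

    def test_surface_potential_sign_matches_charge(self, summaries):
        s = summaries(78.0, preset="smoke")
        assert s.surface_potential_mV < 0
        assert s.zeta_potential_mV < 0
        assert -60.0 < s.effective_charge_e < 0.0

    def test_reference_epsilon_rescales_potentials_only(self, mc_run):
        samples = mc_run(20.0, preset="smoke")
        phys = cm.summarize(samples, reference_epsilon=None)
        aq = cm.summarize(samples, reference_epsilon=78.0)
        assert aq.zeta_potential_mV == pytest.approx(
            phys.zeta_potential_mV * 20.0 / 78.0, rel=1e-9
        )
        assert aq.effective_charge_e == phys.effective_charge_e
        assert aq.reduced_energy == phys.reduced_energy

    def test_energy_norm_switch(self, mc_run):
        samples = mc_run(78.0, preset="smoke")
        mobile = cm.summarize(samples, energy_norm="mobile")
        all_n = cm.summarize(samples, energy_norm="all")
        assert mobile.reduced_energy == pytest.approx(
            all_n.reduced_energy * 61 / 60, rel=1e-9
        )
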