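"""Shared fixtures: a session-level cache of Monte Carlo runs.

Simulations dominate the suite's runtime, so tests that need the same
physical system share one cached run.  All seeds are fixed; every result in
the suite is deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import cellmc as cm


@pytest.fixture(scope="session")
def mc_run():
    """Factory returning cached TrajectorySamples for a grid cell.

    ``mc_run(epsilon, beta, valence, preset)`` runs (once) the canonical
    system for that cell with a seed derived from the cell coordinates.
    """
    cache: dict = {}

    def get(
        epsilon: float,
        beta: float = 0.0,
        valence: int = 3,
        preset: str = "desk",
        **overrides,
    ) -> cm.TrajectorySamples:
        key = (epsilon, beta, valence, preset, tuple(sorted(overrides.items())))
        if key not in cache:
            spec = cm.build_system(epsilon, beta, valence)
            schedule = dataclasses.replace(
                cm.SCHEDULE_PRESETS[preset],
                seed=cm.cell_seed(0, epsilon, beta, valence),
                **overrides,
            )
            cache[key] = cm.run_simulation(spec, schedule)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def summaries(mc_run):
    """Factory for cached water-referenced summaries of cached runs."""
    cache: dict = {}

    def get(epsilon, beta=0.0, valence=3, preset="desk", **overrides):
        key = (epsilon, beta, valence, preset, tuple(sorted(overrides.items())))
        if key not in cache:
            cache[key] = cm.summarize(
                mc_run(epsilon, beta, valence, preset, **overrides),
                reference_epsilon=cm.AQUEOUS_REFERENCE_EPSILON,
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def uncharged_run():
    """An uncharged 60-ion hard-sphere gas in the cell (ideal-gas limit)."""
    spec = cm.SystemSpec(
        solvent=cm.SolventSpec(78.0),
        macroion=cm.MacroionSpec(20.0, 0),
        species=(cm.IonSpecies("counterion", 2.0, 0, 60),),
        cell_radius=100.0,
    )
    schedule = dataclasses.replace(cm.SCHEDULE_PRESETS["desk"], seed=97)
    return cm.run_simulation(spec, schedule)


@pytest.fixture(scope="session")
def energy_fixtures():
    return {f.name: f for f in cm.make_energy_fixtures()}


@pytest.fixture(scope="session")
def profile_fixtures():
    return {f.name: f for f in cm.make_profile_fixtures()}
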