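"""Shared fixtures.

The 2D pair-potential table and the annealing ensembles are expensive, so
they are built once per session and shared between the module tests and the
acceptance tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from wedgelat.assembly_mc import AnnealSchedule, anneal, random_configuration
from wedgelat.elastic1d import BilayerParameters, WedgeParameters
from wedgelat.thickness2d import pair_potential_table

N_SEEDS = 10  # annealing ensemble size
ANNEAL_STEPS = (100_000, 50_000)  # scaled-down hot/cool protocol


@pytest.fixture(scope="session")
def bilayer() -> BilayerParameters:
    return BilayerParameters()


@pytest.fixture(scope="session")
def deep_wedge() -> WedgeParameters:
    return WedgeParameters(U=-0.9)


@pytest.fixture(scope="session")
def shallow_wedge() -> WedgeParameters:
    return WedgeParameters(U=0.0)


@pytest.fixture(scope="session")
def h0_table(bilayer):
    """Deep-state H0-H0 pair potential table at desk-scale resolution."""
    return pair_potential_table(
        bilayer, U=-0.9, extent=6.0, step=0.5, n_theta=6,
        resolution=0.15, margin=5.0,
    )


def _ensemble(h0_table, bar_on: bool):
    finals = []
    for seed in range(N_SEEDS):
        cfg = random_configuration(16, 60.0, seed=seed)
        sched = AnnealSchedule(
            n_hot=ANNEAL_STEPS[0], n_cool=ANNEAL_STEPS[1], seed=seed
        )
        final, trace = anneal(cfg, h0_table, bar_on, sched)
        finals.append((final, trace))
    return finals


@pytest.fixture(scope="session")
def annealed_h0_only(h0_table):
    """Final states of the scaled-down annealing ensemble, H0 potential only."""
    return _ensemble(h0_table, bar_on=False)


@pytest.fixture(scope="session")
def annealed_with_bar(h0_table):
    """Final states with the BAR-BAR pair potential added."""
    return _ensemble(h0_table, bar_on=True)
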