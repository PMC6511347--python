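"""Shared fixtures: small synthetic cases and a session-wide template.

The expensive objects (a reference cohort at 10,000 events/tube and the
template trained on it) are built once per session and shared by the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from radargate import EventMatrix, build_template, default_panel
from radargate.synth import default_phenotypes, simulate_case, simulate_cohort

ACCEPTANCE_EVENTS = 10_000
REFERENCE_SEED = 42


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def phenotypes():
    return default_phenotypes()


def small_event_matrix(values, markers=("CD45", "SSC")):
    """Tiny EventMatrix over named marker columns for unit tests."""
    values = np.asarray(values, dtype=float)
    channels = tuple(f"ch{i}" for i in range(values.shape[1]))
    return EventMatrix(
        values=values,
        channels=channels,
        markers=dict(zip(channels, markers)),
    )


@pytest.fixture(scope="session")
def reference_cohort(phenotypes):
    """6 hypergranular + 2 microgranular reference cases, seed 42."""
    cases, manifest = simulate_cohort(
        6, 2, 0, n_events=ACCEPTANCE_EVENTS, master_seed=REFERENCE_SEED
    )
    return cases, manifest


@pytest.fixture(scope="session")
def trained_template(reference_cohort):
    cases, _ = reference_cohort
    return build_template(
        [c.tubes for c in cases if c.group == "hypergranular"],
        [c.tubes for c in cases if c.group == "microgranular"],
    )


@pytest.fixture(scope="session")
def heldout_hyper(phenotypes):
    """10 held-out hypergranular cases, seeds 101-110."""
    return [
        simulate_case(phenotypes["hypergranular"], n_events=ACCEPTANCE_EVENTS, seed=s)
        for s in range(101, 111)
    ]


@pytest.fixture(scope="session")
def heldout_micro(phenotypes):
    """5 held-out microgranular cases, seeds 201-205."""
    return [
        simulate_case(phenotypes["microgranular"], n_events=ACCEPTANCE_EVENTS, seed=s)
        for s in range(201, 206)
    ]
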