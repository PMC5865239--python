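"""Shared study-condition runs (session-scoped: each is integrated once).

The desk-scale study column is 1000 m at 10 m resolution, integrated to the
statistical steady state (max relative tendency below 1e-4 d^-1 sustained
over five checks) and reported as a 2000-day time average to remove the
weak predator-prey wobble. docs/methods.md describes the problem sizes.
"""

import numpy as np
import pytest

from nitrifycol.column import ColumnGrid, ColumnState, default_initial_state
from nitrifycol.config import IntegrationConfig, make_fixture, run_column
from nitrifycol.ecosystem import VAR_NAMES

STUDY_INTEGRATION = dict(
    tolerance=1e-4, max_time=40000.0, window=5, average_window=2000.0
)


def study_config(experiment: str, dz: float = 10.0, h: float = 1000.0):
    cfg = make_fixture("subtropical_stratified")
    cfg.grid = ColumnGrid(h=h, dz=dz)
    cfg.experiment = experiment
    cfg.integration = IntegrationConfig(**STUDY_INTEGRATION)
    return cfg


@pytest.fixture(scope="session")
def subtropical_solutions():
    """Equilibria of the four nitrifier-difference experiments."""
    return {
        exp: run_column(study_config(exp))
        for exp in (
            "both_differences",
            "yield_only",
            "affinity_only",
            "no_difference",
        )
    }


def _h700_config(dz: float = 10.0):
    """A 700 m domain: shallow enough that the bottom boundary layer
    ventilates the interior and full diffusive equilibration is affordable,
    deep enough to keep the PNM structure; used for the twin-run and
    grid-refinement checks."""
    cfg = study_config("both_differences", dz=dz, h=700.0)
    cfg.integration.average_window = 4000.0
    return cfg


@pytest.fixture(scope="session")
def h700_solution():
    return run_column(_h700_config())


@pytest.fixture(scope="session")
def twin_solution():
    """The same column started from a distinct seeding (50-fold larger
    biomass everywhere, identical nutrient ramps)."""
    cfg = _h700_config()
    return run_column(
        cfg, initial=default_initial_state(cfg.grid, biomass_um=5e-2)
    )


@pytest.fixture(scope="session")
def fine_grid_solution():
    """The 700 m column at halved grid spacing (dz = 5 m)."""
    return run_column(_h700_config(dz=5.0))
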