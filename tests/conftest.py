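"""Shared fixtures: the default synthetic study scene run through the full
calibration chain, and the emulator training fixture.

Both are session-scoped because they are the expensive end-to-end objects
that several test modules interrogate.
"""

from __future__ import annotations

import datetime as dt
import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")

from lcspp.grids import GridSpec
from lcspp.pipeline import run_calibration
from lcspp.synthetic import (
    SceneConfig,
    SifTruthModel,
    SurfaceTruthModel,
    simulate_scene,
    simulate_soundings,
)

SCENE_SEED = 20
EMULATOR_SEED = 11


@pytest.fixture(scope="session")
def scene():
    """The default 40x40-pixel, 16-year, 3-epoch study scene."""
    return simulate_scene(SceneConfig(), seed=SCENE_SEED)


@pytest.fixture(scope="session")
def calibration(scene):
    """Full harmonize + cross-calibration chain on the default scene."""
    return run_calibration(scene, seed=SCENE_SEED)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec.from_bounds(42.0, 0.0, 8, 8, 0.05)


@pytest.fixture(scope="session")
def emulator_data():
    """Gridded sounding samples from a 4-year record (2 train, 1+1 test)."""
    from lcspp.emulator import grid_soundings, split_samples

    grid = GridSpec.from_bounds(42.0, 0.0, 40, 40, 0.05)
    truth = SurfaceTruthModel.random(grid, seed=EMULATOR_SEED, base_year=1993)
    sif = SifTruthModel()
    table = simulate_soundings(
        truth, sif, dt.date(1993, 1, 1), dt.date(1996, 12, 31),
        seed=EMULATOR_SEED + 1, cell_probability=0.25, swath_width=6,
    )
    cells = grid_soundings(table, grid)
    train, val, test = split_samples(
        cells, {1994, 1995}, {1993, 1996}, seed=EMULATOR_SEED + 2)
    return {"grid": grid, "truth": truth, "sif": sif, "table": table,
            "cells": cells, "train": train, "val": val, "test": test}
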