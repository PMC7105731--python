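"""Shared fixtures: small, programmatically generated inputs."""

import numpy as np
import pytest

from arrhythmech.cell_models import CellParams
from arrhythmech.synthetic_data import SpiralSpec, gen_spiral_movie
from arrhythmech.stats_engine import (REFERENCE_CORRELATION,
                                      REFERENCE_MEANS, REFERENCE_SDS)


@pytest.fixture(scope="session")
def reduced_params():
    return CellParams(model_kind="reduced")


@pytest.fixture(scope="session")
def detailed_params():
    return CellParams()


@pytest.fixture(scope="session")
def spiral_movie():
    """One counterclockwise rotor, period 200 ms, 3 s of frames."""
    movie, tracks = gen_spiral_movie(SpiralSpec(period=200.0), 3000.0)
    return movie, tracks


@pytest.fixture(scope="session")
def reference_table_spec():
    """TableSpec targeting the packaged 48-case summary (all six variables)."""
    from arrhythmech.synthetic_data import TableSpec
    cols = list(REFERENCE_CORRELATION.columns)
    return TableSpec(means=REFERENCE_MEANS[cols].values,
                     sds=REFERENCE_SDS[cols].values,
                     correlation=REFERENCE_CORRELATION.values,
                     n=10_000, seed=20260920, columns=cols,
                     integer_columns=())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
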