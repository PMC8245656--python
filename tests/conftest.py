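from __future__ import annotations

import numpy as np
import pytest

from algalmeta.matrix_io import IncidenceMatrix, SiteTaxonTable


def make_incidence(a) -> IncidenceMatrix:
    a = np.asarray(a, dtype=np.int8)
    return IncidenceMatrix([f"S{i}" for i in range(a.shape[0])],
                           [f"T{j}" for j in range(a.shape[1])], a)


def make_table(a) -> SiteTaxonTable:
    a = np.asarray(a, dtype=float)
    return SiteTaxonTable([f"S{i}" for i in range(a.shape[0])],
                          [f"T{j}" for j in range(a.shape[1])], a)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def study_data():
    """One study-shape scenario shared by the slower integration tests."""
    from algalmeta.synthetic import study_shape_scenario

    return study_shape_scenario(seed=11)
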