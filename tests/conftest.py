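"""Shared fixtures: the packaged study-shaped dataset and small toys."""

import numpy as np
import pytest

from rdsinfer import (
    RespondentRecord,
    Variable,
    VariableCatalogue,
    build_forest,
    study_shaped_fixture,
)


@pytest.fixture(scope="session")
def study_bundle():
    """The deterministic packaged fixture (N=15,000, n=539, 20 seeds)."""
    return study_shaped_fixture()


@pytest.fixture(scope="session")
def xy_catalogue():
    return VariableCatalogue([Variable("x"), Variable("y")], outcome="y")


def make_records(x, y, parents, degree=5):
    """Records over binary vectors x, y with a recruitment structure given
    as a list of parent indices (None = seed)."""
    recs = []
    for i in range(len(x)):
        par = parents[i]
        recs.append(RespondentRecord(
            f"r{i}", None if par is None else f"r{par}", degree,
            {"x": int(x[i]), "y": int(y[i])}, int(y[i])))
    return recs


@pytest.fixture()
def toy_chain_records():
    """Three-seed, 12-respondent toy with short chains."""
    x = np.array([1, 1, 1, 1, 0, 1, 0, 0, 0, 1, 0, 0])
    y = np.array([1, 1, 0, 1, 0, 1, 0, 0, 1, 0, 0, 0])
    parents = [None, 0, 1, None, 3, 4, None, 6, 6, 2, 4, 8]
    recs = make_records(x, y, parents)
    return recs, build_forest(recs), x, y
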