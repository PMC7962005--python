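import numpy as np
import pytest

from trpscope import mdf
from trpscope import synthetic as syn


@pytest.fixture(scope="session")
def trp_bank():
    return syn.default_trp_bank()


def build_eem_cube(bank, scores, exc_grid=None, em_grid=None, mask=None):
    """Fully observed EEM cube built directly from outer products."""
    exc_grid = np.arange(260.0, 321, 2.0) if exc_grid is None else exc_grid
    em_grid = np.arange(300.0, 441, 2.0) if em_grid is None else em_grid
    scores = np.atleast_2d(np.asarray(scores, float))
    B = np.stack([c.excitation(exc_grid) for c in bank], axis=1)
    C = np.stack([c.emission(em_grid) for c in bank], axis=1)
    values = np.einsum("sk,ek,mk->sem", scores, B, C)
    if mask is None:
        mask = np.zeros(values.shape, bool)
    ids = [f"s{i}" for i in range(scores.shape[0])]
    return mdf.EEMCube(ids, exc_grid, em_grid, values, mask)


@pytest.fixture(scope="session")
def rank2_cube(trp_bank):
    scores = np.random.default_rng(11).uniform(0.5, 2.0, (8, 2))
    return build_eem_cube(trp_bank, scores)


@pytest.fixture(scope="session")
def two_component_truth():
    """Two-lifetime decay: 1.32/5.5 ns with intensity fractions 86/14.5%."""
    taus = np.array([1.32, 5.5])
    fractions = np.array([86.0, 14.5])
    amps = fractions / taus
    return syn.DecayGroundTruth(
        lifetimes=tuple(taus), amplitudes=tuple(amps / amps.sum())
    )
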