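"""Shared fixtures: a default synthetic study and its pipeline outputs."""

import warnings

import numpy as np
import pytest

import epicre


@pytest.fixture(scope="session")
def default_study():
    """The default-configuration synthetic study (seed 0)."""
    return epicre.simulate_study(epicre.SimulationConfig())


@pytest.fixture(scope="session")
def default_estimates(default_study):
    """Epistasis estimates from the default study."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = epicre.normalize(default_study.fluorescence)
        est = epicre.estimate_epistasis(norm, default_study.pairs)
    return norm, est


@pytest.fixture(scope="session")
def noiseless_study():
    """A noise-free study: the pipeline must reproduce the model exactly."""
    return epicre.simulate_study(epicre.SimulationConfig(noise_sd=0.0))


@pytest.fixture()
def tiny_matrices():
    """Small handcrafted matrix pair on an 8-bp CRE for exact-value tests.

    RNAP covers [0, 6), repressor [2, 8); entries are small integers so
    expected energies can be written down by hand.
    """
    wt = "ACGTACGT"
    rnap_entries = np.array(
        [
            [0.0, 1.0, 2.0, 3.0],
            [0.5, 0.0, 1.5, 2.5],
            [1.0, 2.0, 0.0, 0.5],
            [2.0, 1.0, 3.0, 0.0],
            [0.0, 0.5, 1.0, 1.5],
            [1.5, 0.0, 0.5, 1.0],
        ]
    )
    rep_entries = np.array(
        [
            [1.0, 2.0, 0.0, 3.0],
            [2.0, 1.0, 0.5, 0.0],
            [0.0, 3.0, 1.0, 2.0],
            [1.0, 0.0, 2.0, 0.5],
            [2.0, 1.5, 0.0, 1.0],
            [0.5, 2.0, 1.0, 0.0],
        ]
    )
    rnap = epicre.EnergyMatrix("rnap", rnap_entries, wt[0:6], offset=0)
    rep = epicre.EnergyMatrix("rep", rep_entries, wt[2:8], offset=2)
    return wt, rnap, rep
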