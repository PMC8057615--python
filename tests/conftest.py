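import numpy as np
import pytest

from csf1r_grn import (
    basal_state, build_model, default_network, default_params,
)
from csf1r_grn.network import Component, NetworkDefinition, Regulation
from csf1r_grn.params import ParameterSet


@pytest.fixture(scope="session")
def net():
    return default_network()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def model(net, params):
    return build_model(net, params)


@pytest.fixture(scope="session")
def y0(model):
    return basal_state(model)


@pytest.fixture(scope="session")
def toy_one_gene():
    """Single gene driven linearly by LPS, no feedback: closed-form dynamics.

    Steady state M* = (b + w*lps)/kd; relaxation rate kd.
    """
    toy_net = NetworkDefinition(
        [Component("GENE", "transcription_factor", False)],
        [Regulation(1, "LPS", "GENE", "activation", "transcriptional", "toy")],
    )
    toy_params = ParameterSet({"kd_GENE": 0.2, "b_GENE": 0.4, "w1": 0.6,
                               "protein_mrna_ratio": 3000.0})
    return toy_net, toy_params


@pytest.fixture(scope="session")
def toy_two_gene():
    """A regulates B; B has no outgoing edges."""
    toy_net = NetworkDefinition(
        [Component("A", "transcription_factor", False),
         Component("B", "transcription_factor", False)],
        [Regulation(1, "A", "B", "activation", "transcriptional", "toy")],
    )
    toy_params = ParameterSet({
        "kd_A": 0.2, "b_A": 0.2, "kd_B": 0.2, "b_B": 0.1,
        "w1": 0.3, "K1": 6000.0, "n1": 2.0, "protein_mrna_ratio": 3000.0,
    })
    return toy_net, toy_params
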