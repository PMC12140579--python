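"""Shared fixtures: short paradigms, encodings, and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ecpredict.cohort import CohortSpec, pseudo_posteriors, sample_cohort_truth
from ecpredict.dcm.forward import HemodynamicParams
from ecpredict.paradigm import encode_inputs, generate_paradigm

TR = 2.03
MICRO_DT = TR / 16.0


@pytest.fixture(scope="session")
def hemo():
    return HemodynamicParams()


@pytest.fixture(scope="session")
def paradigm_default():
    return generate_paradigm(1)


@pytest.fixture(scope="session")
def paradigm_short():
    return generate_paradigm(3, overrides={"n_blocks": 4})


@pytest.fixture(scope="session")
def enc_event_short(paradigm_short):
    return encode_inputs(paradigm_short, "event", dt=MICRO_DT)


@pytest.fixture(scope="session")
def enc_block_short(paradigm_short):
    return encode_inputs(paradigm_short, "block", dt=MICRO_DT)


@pytest.fixture(scope="session")
def truth_small():
    """Tiny 9-node cohort for forward-model tests."""
    return sample_cohort_truth(4, seed=11)


@pytest.fixture(scope="session")
def truth60():
    """Default-scale pseudo-posterior cohort for PEB/prediction tests."""
    return sample_cohort_truth(60, seed=21)


@pytest.fixture(scope="session")
def posts60(truth60):
    return pseudo_posteriors(truth60, post_sd=0.02, seed=22)


def small_spec(n_nodes: int = 6) -> CohortSpec:
    """A reduced network spec (driving input into the first two nodes)."""
    return CohortSpec(
        node_labels=tuple(f"n{i}" for i in range(n_nodes)),
        driving_nodes=(0, 1),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
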