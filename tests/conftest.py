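import dataclasses

import numpy as np
import pytest

from pina import synth


@pytest.fixture(scope="session")
def tiny_bundle():
    """Noise-free two-cluster bundle with perfectly recoverable structure."""
    bundle, ledger = synth.generate_bundle(synth.PRESETS["tiny"](7))
    return bundle, ledger


@pytest.fixture(scope="session")
def crosstalk_bundle():
    """Noise-free bundle that exercises crosstalk/interacting pathway routes."""
    cfg = dataclasses.replace(
        synth.PRESETS["tiny"](3),
        n_pathways=14,
        crosstalk_rate=0.3,
        interacting_rate=0.3,
    )
    bundle, ledger = synth.generate_bundle(cfg)
    return bundle, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
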