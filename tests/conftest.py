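"""Shared fixtures.

The heavy study fixtures are session-scoped: network training runs once and
its results are shared by every test that scores it.
"""

import pytest

from lsfmrestore import experiments


@pytest.fixture(scope="session")
def denoising_result():
    """CI-profile DAE trained on the standard 300-pair corpus (seed 11)."""
    return experiments.denoising_study(seed=11)


@pytest.fixture(scope="session")
def bead_synthesis_result():
    """Standard 40-bead, elongation-4 phantom (seed 3) with detections and
    rendered target."""
    return experiments.bead_synthesis_study(seed=3)


@pytest.fixture(scope="session")
def conv_distortion_result():
    """CI conv-AE distortion study: train on seed-3 stack, evaluate on the
    held-out seed-4 stack."""
    return experiments.distortion_conv_study(seed=3, eval_seed=4)


@pytest.fixture(scope="session")
def lstm_distortion_result():
    """ConvLSTM distortion study at smoke-level training budget."""
    return experiments.distortion_lstm_study(seed=3, eval_seed=4)
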