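import pytest

from sczra.simulator import (GalvanicModelParams, default_treatments,
                             simulate_sczra)


def _by_label(label: str):
    return next(c for c in default_treatments() if c.label == label)


@pytest.fixture(scope="session")
def unbuffered_inoculated_noisefree():
    """Default bicarbonate-free, WE1-inoculated run with noise off."""
    cfg = _by_label("without_bicarbonate__WE1_inoculated")
    return simulate_sczra(cfg, galv=GalvanicModelParams(noise_sd=0.0))


@pytest.fixture(scope="session")
def buffered_inoculated_noisefree():
    cfg = _by_label("with_bicarbonate__WE1_inoculated")
    return simulate_sczra(cfg, galv=GalvanicModelParams(noise_sd=0.0))


@pytest.fixture(scope="session")
def uninoculated_noisefree():
    cfg = _by_label("with_bicarbonate__uninoculated")
    return simulate_sczra(cfg, galv=GalvanicModelParams(noise_sd=0.0))
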