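"""Shared fixtures: default config and reduced builds for fast tests."""

import numpy as np
import pytest

from purksim import ModelConfig
from purksim.engine import ProtocolSpec, Simulation


@pytest.fixture()
def config():
    return ModelConfig()


@pytest.fixture()
def small_config():
    """Reduced 5-compartment build (1 soma + 2 smooth + 2 spiny)."""
    cfg = ModelConfig()
    cfg.geometry.n_smooth = 2
    cfg.geometry.n_spiny = 2
    cfg.synapse.n_cf_contacts = 2
    return cfg


@pytest.fixture()
def passive_config():
    """Full-size build with every active conductance removed."""
    cfg = ModelConfig()
    for name in cfg.densities_soma:
        if name != "leak":
            cfg.densities_soma[name] = 0.0
            cfg.densities_dend[name] = 0.0
    cfg.pump.density = 0.0
    return cfg


def run_sim(cfg, proto=None, duration=1000.0, settle=0.0, **kw):
    """Small helper: build, optionally settle, advance, return Simulation."""
    proto = proto or ProtocolSpec("test", duration, **kw)
    cfg.integration.settle_ms = settle
    sim = Simulation(cfg, proto)
    return sim
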