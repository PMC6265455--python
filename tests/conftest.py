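"""Shared fixtures: simulated instrument data reused across the suite.

Heavy simulations (fit ensembles, trace ensembles) are session-scoped so
that unit tests and the acceptance tests draw on the same objects.
"""

import numpy as np
import pytest

from sifi import (
    ABASIC_HAIRPIN,
    InstrumentConfig,
    TraceSimConfig,
    fit_reconvolution,
    simulate_decay,
    simulate_irf,
    simulate_trace,
)
from sifi import smkinetics as smk


@pytest.fixture(scope="session")
def instrument_cfg():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def irf(instrument_cfg):
    return simulate_irf(instrument_cfg, seed=1)


@pytest.fixture(scope="session")
def abasic_decay(instrument_cfg, irf):
    return simulate_decay(ABASIC_HAIRPIN, instrument_cfg, irf, seed=2)


@pytest.fixture(scope="session")
def abasic_fit(abasic_decay, irf):
    return fit_reconvolution(abasic_decay, irf, n_components=3)


@pytest.fixture(scope="session")
def abasic_fit_ensemble(instrument_cfg, irf):
    """Twenty independent simulate+fit repeats of the abasic preset."""
    fits = []
    for s in range(20):
        decay = simulate_decay(ABASIC_HAIRPIN, instrument_cfg, irf, seed=1000 + s)
        fits.append(fit_reconvolution(decay, irf, n_components=3))
    return fits


@pytest.fixture(scope="session")
def trace_ensemble():
    """One hundred simulated molecules at the maximum enhancement (2.5x),
    segmented, with dwells and per-trace enhancement ratios extracted."""
    cfg = TraceSimConfig(k_open=1.0, k_close=1.0, enhancement=2.5, duration=100.0)
    traces, segs, dwells = [], [], []
    for s in range(100):
        tr = simulate_trace(cfg, seed=2000 + s)
        seg = smk.segment_trace(tr)
        if seg.no_transitions:
            continue
        traces.append(tr)
        segs.append(seg)
        dwells.append(smk.extract_dwells(seg, tr.frame_time))
    return {"config": cfg, "traces": traces, "segs": segs, "dwells": dwells}
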