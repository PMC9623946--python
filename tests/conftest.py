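"""Shared fixtures: small idealized domain and the scenario runs.

The transient scenario runs are expensive (a sparse factorization each), so
they are session-scoped and shared between the unit suite and the
acceptance tests.
"""

import numpy as np
import pytest

from icpulse.geometry import IdealizedSpec, build_idealized
from icpulse.params import MaterialParams
from icpulse.qoi import compute_qoi
from icpulse.timeloop import RunConfig, run_transient
from icpulse.waveform import default_waveform

# test-tier resolution: coarse icosphere, 2 cycles, 100 steps per cycle
TEST_SUBDIV = 1
TEST_CYCLES = 2
TEST_SPC = 100


@pytest.fixture(scope="session")
def ideal_domain():
    return build_idealized(IdealizedSpec(subdivisions=TEST_SUBDIV))


@pytest.fixture(scope="session")
def waveform():
    return default_waveform()


def _run(domain, params, waveform, store_fields=False, cycles=TEST_CYCLES):
    cfg = RunConfig(domain=domain, params=params, waveform=waveform,
                    n_cycles=cycles, steps_per_cycle=TEST_SPC,
                    store_fields=store_fields)
    return run_transient(cfg)


@pytest.fixture(scope="session")
def standard_run(ideal_domain, waveform):
    return _run(ideal_domain, MaterialParams(), waveform, store_fields=True,
                cycles=3)


@pytest.fixture(scope="session")
def model_runs(ideal_domain, waveform, standard_run):
    """Histories for the standard scenario and the A/B/D variations."""
    base = MaterialParams()
    runs = {"standard": standard_run}
    for name, pp in (("A", base.with_(PVI=10e-6)),
                     ("B", base.with_(E=3000.0)),
                     ("D", base.with_(c=1e-5))):
        runs[name] = _run(ideal_domain, pp, waveform)
    return runs


@pytest.fixture(scope="session")
def model_qoi(model_runs):
    return {k: compute_qoi(h) for k, h in model_runs.items()}
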