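"""Shared fixtures: the heavyweight coupled studies are run once per session
and reused by the physiology and acceptance tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardiowave import benchmarks

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_run():
    """Three coupled beats on the 126 mm baseline aortic segment."""
    traces, beats, net = benchmarks.coupled_run(
        benchmarks.make_single_vessel(length=0.126), beats=3, init_cycles=10)
    return {"traces": traces, "beats": beats, "network": net}


@pytest.fixture(scope="session")
def dt_study():
    """Coupled 200 mm runs over the (dt3D, dt1D) grid."""
    return benchmarks.dt_robustness_study(beats=3, init_cycles=10)


@pytest.fixture(scope="session")
def stiffening():
    """PV-loop indices for E in {0.25, 0.50, 0.75} MPa, plain vessel."""
    return benchmarks.stiffening_study(beats=3, init_cycles=10)


@pytest.fixture(scope="session")
def stiffening_stenotic():
    """Same stiffness sweep with the 30% mid-vessel stenosis."""
    return benchmarks.stiffening_study(beats=3, init_cycles=10,
                                       stenosis=True, dt1D=5e-5)


@pytest.fixture(scope="session")
def tree_runs():
    """Young vs aged 3-generation bifurcating-tree runs."""
    return benchmarks.tree_study(generations=3, beats=2, init_cycles=8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
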