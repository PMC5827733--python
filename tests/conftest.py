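"""Shared fixtures: the toy bundle, a reference state and canonical runs.

Everything here is deterministic; the hypothesis profile is derandomized
so the suite gives the same verdict on every machine.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dynamoma.coupling import run_dmoma
from dynamoma.fixtures import generate_toy_fixture
from dynamoma.metrics import PathwayClustering, perturbation_report
from dynamoma.pbpk import acetylator_preset, resample
from dynamoma.reference import ExpressionProfile, build_reference_state
from dynamoma.xenobiotic import extend_network, isoniazid_preset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 1
DURATION_MIN = 4320.0  # 72 h


@pytest.fixture(scope="session")
def toy():
    return generate_toy_fixture(seed=SEED, size="small")


@pytest.fixture(scope="session")
def extended_net(toy):
    return extend_network(toy.network, isoniazid_preset(toy.network))


@pytest.fixture(scope="session")
def reference(toy, extended_net):
    return build_reference_state(
        extended_net, ExpressionProfile(toy.expression), toy.utilization
    )


@pytest.fixture(scope="session")
def pk_fast():
    return acetylator_preset("fast").simulate(duration=DURATION_MIN, dt=1.0)


@pytest.fixture(scope="session")
def pk_slow():
    return acetylator_preset("slow").simulate(duration=DURATION_MIN, dt=1.0)


@pytest.fixture(scope="session")
def series_dt10(pk_fast):
    return resample(pk_fast.series, 10.0)


@pytest.fixture(scope="session")
def fm_dt10(reference, series_dt10):
    return run_dmoma(reference, series_dt10, progress_every=0)


@pytest.fixture(scope="session")
def report_dt10(reference, fm_dt10):
    clustering = PathwayClustering.from_network(reference.network)
    return perturbation_report(fm_dt10, reference, clustering)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
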