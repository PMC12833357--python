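"""Shared fixtures: a memoized scenario runner so network-level tests reuse
simulations instead of re-integrating the same 475-cell network."""

from __future__ import annotations

import pytest

from tcnet.engine import Protocol
from tcnet.experiments import Scenario, run_scenario

#: Reduced-length protocol for network-level tests: 1.5 s settle + 4 s
#: recording still covers two full Welch segments at 10 kHz but keeps the
#: suite fast.  The acceptance script uses the full standard protocol.
TEST_PROTOCOL = Protocol(settle_duration=1500.0, record_duration=4000.0)


@pytest.fixture(scope="session")
def scenario_cache():
    """Callable: scenario_cache(Scenario, dt=0.025) -> SpectralSummary,
    memoized across the whole test session."""
    cache: dict = {}

    def get(scenario: Scenario, dt: float = 0.025):
        key = (scenario, dt)
        if key not in cache:
            proto = Protocol(
                settle_duration=TEST_PROTOCOL.settle_duration,
                record_duration=TEST_PROTOCOL.record_duration,
                dt=dt,
            )
            cache[key] = run_scenario(scenario, protocol=proto)
        return cache[key]

    return get
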