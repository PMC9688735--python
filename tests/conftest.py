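"""Shared fixtures.

The six-scenario default run and the native 50/100 shear pair are expensive
(minutes), so they are computed once per session and shared by the acceptance
tests and the module-level checks that need them.
"""

from __future__ import annotations

import pytest

from mivmsim import (
    FlowParams,
    build_scenario,
    max_shear_on_cocs,
    solve_flow,
)
from mivmsim.runner import DEFAULT_SEEDS, default_configs, run_scenario


@pytest.fixture(scope="session")
def sixpack():
    """ScenarioResult per scenario for the six default configurations."""
    return {cfg.scenario: run_scenario(cfg) for cfg in default_configs()}


@pytest.fixture(scope="session")
def native_shear_pair():
    """Max COC shear in the native chamber at 50 and 100 uL/min (shared mesh)."""
    dom = build_scenario("native", {"placement_seed": DEFAULT_SEEDS["native"]})
    cache: dict = {}
    out = {}
    for q in (50.0, 100.0):
        field = solve_flow(dom, FlowParams.from_ul_min(q), cache=cache)
        out[q] = max_shear_on_cocs(field, dom)
    return out


SMALL_STATIC = {"media_volume": 50e-9, "n_cocs": 5}


@pytest.fixture()
def small_static():
    """A 50 uL static well with 5 COCs: cheap enough for per-test solves."""
    return build_scenario("static", overrides=dict(SMALL_STATIC, placement_seed=3))
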