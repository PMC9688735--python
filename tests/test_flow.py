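import numpy as np
import pytest

from mivmsim import (
    ConfigurationError,
    FlowParams,
    GeometryError,
    max_shear_on_cocs,
    reynolds_number,
    solve_flow,
    wall_shear,
    zero_flow,
)
from mivmsim.geometry import Material
from mivmsim.synth import make_fixture

UL_MIN = 1e-9 / 60.0


@pytest.fixture(scope="module")
def duct():
    fx = make_fixture("plane_poiseuille")
    return fx, fx.build_domain()


def test_duct_wall_shear_matches_poiseuille(duct):
    """Stokes solve on the channel fixture vs tau = 6 mu Q / (w h^2)."""
    fx, dom = duct
    q = 50 * UL_MIN
    field = solve_flow(dom, FlowParams(flow_rate=q, inertial=False))
    taus = wall_shear(field, dom, dom.materials == Material.INSERT)
    assert taus.max() == pytest.approx(fx.closed_form(q), rel=0.02)


def test_stokes_fields_scale_linearly_with_flow_rate(duct):
    _, dom = duct
    f1 = solve_flow(dom, FlowParams(flow_rate=1e-9, inertial=False))
    f2 = solve_flow(dom, FlowParams(flow_rate=3e-9, inertial=False))
    scale = np.abs(f1.u).max()
    assert np.abs(f2.u - 3 * f1.u).max() <= 1e-9 * scale
    assert np.abs(f2.w - 3 * f1.w).max() <= 1e-9 * scale


def test_zero_flow_gives_zero_velocity_and_shear(small_static):
    field = solve_flow(small_static, FlowParams(flow_rate=0.0))
    assert field.is_zero
    assert np.all(field.u == 0) and np.all(field.w == 0)
    assert max_shear_on_cocs(field, small_static) == 0.0


def test_flow_on_portless_scenario_raises(small_static):
    with pytest.raises(ConfigurationError):
        solve_flow(small_static, FlowParams(flow_rate=1e-9))


def test_mass_conservation_diagnostics(duct):
    _, dom = duct
    field = solve_flow(dom, FlowParams(flow_rate=1e-9, inertial=False))
    r = field.residuals
    assert r["inflow"] == pytest.approx(r["outflow"], rel=1e-12)
    assert r["div_linf_over_Q"] < 1e-4


def test_reynolds_number_examples():
    p0 = FlowParams(flow_rate=0.0)
    assert reynolds_number(p0, 1e-3) == 0.0
    p = FlowParams.from_ul_min(50)
    re = reynolds_number(p, 1e-3)  # 0.5 mm-radius port
    assert re == pytest.approx(1.52, rel=0.02)
    assert reynolds_number(FlowParams.from_ul_min(100), 1e-3) == pytest.approx(2 * re)


def test_shear_layout_mismatch_raises(small_static):
    from mivmsim.geometry import place_cocs

    field = zero_flow(small_static)
    other = place_cocs("static", 5, seed=99, params=small_static.params)
    with pytest.raises(GeometryError):
        max_shear_on_cocs(field, small_static, layout=other)
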