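import numpy as np
import pytest

from mivmsim import (
    MivmError,
    OxygenParams,
    StepSizeError,
    build_scenario,
    coc_sink,
    mass_balance_residual,
    solve_oxygen_steady,
    solve_oxygen_transient,
    volume_average,
)
from mivmsim.geometry import Material
from mivmsim.grid import RectilinearGrid
from mivmsim.oxygen import OxygenField, PMOL_MIN
from mivmsim.synth import make_fixture

V_COC = 4.0 / 3.0 * np.pi * (3e-4) ** 3


def test_coc_sink_cutoff_shape():
    p = OxygenParams()
    assert coc_sink(0.0, p) == 0.0
    q0 = p.ocr_per_coc / V_COC
    assert coc_sink(p.c_crit, p) == pytest.approx(q0)
    assert coc_sink(0.21, p) == pytest.approx(q0)  # ~5.9e-4 mol m^-3 s^-1
    assert q0 == pytest.approx(5.9e-4, rel=0.01)
    assert coc_sink(p.c_crit / 2, p) == pytest.approx(q0 / 2)
    with pytest.raises(MivmError):
        coc_sink(-1e-3, p)


def test_sink_integrates_to_4_pmol_per_min_per_coc(small_static):
    """At saturation the solver's total consumption is exactly n x OCR."""
    par = OxygenParams()
    field = solve_oxygen_steady(small_static, None, par)
    n = small_static.coc_layout.n_cocs
    assert field.fluxes["consumption"] == pytest.approx(n * 4.0 * PMOL_MIN, rel=1e-9)


def test_total_ocr_interpretation_switch(small_static):
    par = OxygenParams(per_coc=False)  # 4 pmol/min split across all COCs
    field = solve_oxygen_steady(small_static, None, par)
    assert field.fluxes["consumption"] == pytest.approx(4.0 * PMOL_MIN, rel=1e-9)


def test_two_layer_slab_matches_series_resistance_closed_form():
    fx = make_fixture("two_layer_slab")
    dom = fx.build_domain()
    par = OxygenParams()
    field = solve_oxygen_steady(dom, None, par)
    num = field.concentration[0, 0, :]
    ana = fx.closed_form(dom.grid.zc)
    assert np.nanmax(np.abs(num - ana)) < 1e-2 * par.c_sat * 1e-3  # machine-level
    assert mass_balance_residual(field, dom, par) < 1e-3


def test_saturated_no_consumption_is_uniform():
    fx = make_fixture("uniform_box")
    dom = fx.build_domain()
    field = solve_oxygen_steady(dom, None, OxygenParams())
    c = field.concentration[np.isfinite(field.concentration)]
    assert np.allclose(c, 0.21, atol=1e-12)


def test_volume_average_weights_by_cell_volume():
    # two-cell mesh with volumes 2V and V holding 0.1 and 0.4 -> 0.2
    g = RectilinearGrid([0, 2e-3, 3e-3], [0, 1e-3], [0, 1e-3])
    from mivmsim.geometry import BoundarySpec, COCLayout, ScenarioDomain, ScenarioParams

    dom = ScenarioDomain(
        scenario_name="toy", grid=g,
        materials=np.full(g.shape, Material.MEDIA, dtype=np.uint8),
        coc_id=np.full(g.shape, -1, np.int32),
        coc_layout=COCLayout(0, 3e-4, np.zeros((0, 3)), 0),
        bc=BoundarySpec(), params=ScenarioParams(), resolution=1e-4,
    )
    c = np.array([0.1, 0.4]).reshape(2, 1, 1)
    field = OxygenField(concentration=c, time=np.inf)
    assert volume_average(field, dom, "media") == pytest.approx(0.2)
    with pytest.raises(MivmError):
        volume_average(field, dom, "gel")  # empty region


def test_transient_constant_when_saturated_and_unconsuming():
    fx = make_fixture("uniform_box")
    dom = fx.build_domain()
    par = OxygenParams(ocr_per_coc=0.0)
    fields = solve_oxygen_transient(dom, None, par, t_end=600.0, dt=60.0)
    c = fields[-1].concentration
    assert np.allclose(c[np.isfinite(c)], 0.21, atol=1e-12)


def test_transient_approaches_steady_state(small_static):
    par = OxygenParams()
    steady = solve_oxygen_steady(small_static, None, par)
    trans = solve_oxygen_transient(small_static, None, par, t_end=6 * 3600.0, dt=120.0)
    a_s = volume_average(steady, small_static, "media")
    a_t = volume_average(trans[-1], small_static, "media")
    assert a_t == pytest.approx(a_s, rel=0.01)


def test_transient_rejects_bad_steps(small_static):
    with pytest.raises(StepSizeError):
        solve_oxygen_transient(small_static, None, OxygenParams(), t_end=0.0, dt=1.0)


def test_average_oxygen_decreases_with_ocr(small_static):
    avgs = []
    for pmol in (2.0, 4.0, 8.0):
        par = OxygenParams(ocr_per_coc=pmol * PMOL_MIN)
        f = solve_oxygen_steady(small_static, None, par)
        avgs.append(volume_average(f, small_static, "media"))
    assert avgs[0] > avgs[1] > avgs[2]


def test_missing_flow_on_perfused_scenario_raises():
    dom = build_scenario("native", overrides={"n_cocs": 3})
    with pytest.raises(Exception):
        solve_oxygen_steady(dom, None, OxygenParams())
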