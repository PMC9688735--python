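import numpy as np
import pytest

from mivmsim import (
    GeometryError,
    Material,
    PlacementError,
    ResolutionError,
    build_scenario,
    coc_surface_areas,
    liquid_volume,
    place_cocs,
)
from mivmsim.geometry import SCENARIOS, ScenarioParams, region_volume

COC_VOL = 21 * 4.0 / 3.0 * np.pi * (3e-4) ** 3


@pytest.mark.parametrize("name", SCENARIOS)
def test_all_scenarios_build_with_labelled_liquid(name):
    dom = build_scenario(name)
    assert dom.scenario_name == name
    assert dom.liquid.any()
    # every COC is carved and the culture region is non-empty liquid
    assert dom.coc_id.max() == dom.coc_layout.n_cocs - 1
    assert dom.region_mask("culture").any()
    # oil only in the static well, gel only in the alginate scenario
    assert ((dom.materials == Material.OIL).any()) == (name == "static")
    assert ((dom.materials == Material.ALGINATE).any()) == (name == "alginate")


def test_static_volume_matches_400ul_well():
    dom = build_scenario("static")
    analytic = 400e-9 - COC_VOL
    assert liquid_volume(dom) == pytest.approx(analytic, rel=0.05)
    # two stacked layers of 2.1 mm each
    assert dom.grid.zf[-1] == pytest.approx(4.2e-3)
    zc = dom.grid.zc
    oil = dom.materials == Material.OIL
    assert zc[np.nonzero(oil.any(axis=(0, 1)))[0]].min() > 2.1e-3


def test_native_volume_is_two_ml_minus_cocs():
    dom = build_scenario("native")
    analytic = 2e-6 - COC_VOL
    assert liquid_volume(dom) == pytest.approx(analytic, rel=0.05)


def test_alginate_gel_volume_is_150ul():
    dom = build_scenario("alginate")
    assert region_volume(dom, "gel") == pytest.approx(150e-9, rel=0.05)


def test_volume_error_shrinks_with_refinement():
    """Voxel liquid volume converges to the analytic well volume."""
    analytic = 400e-9 - COC_VOL
    errs = [
        abs(liquid_volume(build_scenario("static", resolution=r)) - analytic)
        for r in (1.5e-4, 1.0e-4, 0.75e-4)
    ]
    assert errs[-1] <= errs[0]
    assert max(errs) / analytic < 0.01


def test_placement_is_deterministic_and_non_overlapping():
    a = place_cocs("native", 21, seed=1)
    b = place_cocs("native", 21, seed=1)
    assert np.array_equal(a.centers, b.centers)
    # exhaustive pairwise check
    d = a.centers[:, None, :] - a.centers[None, :, :]
    dist = np.sqrt((d**2).sum(-1))
    iu = np.triu_indices(21, 1)
    assert dist[iu].min() >= 2 * a.coc_radius


def test_ring_placement_confined_to_ring_interior():
    lay = place_cocs("ring", 21, seed=7)
    r = np.hypot(lay.centers[:, 0], lay.centers[:, 1])
    assert np.all(r < 5.5e-3 - lay.coc_radius)


def test_packing_failure_raises():
    with pytest.raises(PlacementError):
        place_cocs("ring", 500, seed=0)


def test_resolution_too_coarse_raises():
    with pytest.raises(ResolutionError):
        build_scenario("native", resolution=2e-4)


def test_insert_must_fit_chamber():
    with pytest.raises(GeometryError):
        build_scenario("ring", overrides={"ring_outer_radius": 8e-3})


def test_coc_surface_area_close_to_sphere():
    dom = build_scenario("native")
    areas = coc_surface_areas(dom)
    assert areas.shape == (21,)
    assert np.all(np.abs(areas - 4 * np.pi * (3e-4) ** 2) / (4 * np.pi * 9e-8) < 0.10)


def test_concave_bowl_profile_and_volume():
    p = ScenarioParams()
    ins = p.insert
    assert ins.bowl_floor_z(0.0) == pytest.approx(ins.concave_rim_thickness - 1.5e-3)
    assert ins.bowl_floor_z(ins.concave_bowl_radius + 1e-4) == pytest.approx(
        ins.concave_rim_thickness
    )
    full = ins.bowl_volume_below(ins.concave_rim_thickness)
    cap = np.pi * 1.5e-3**2 * (3 * ins._cap_sphere_radius - 1.5e-3) / 3
    assert full == pytest.approx(cap)


def test_liquid_volume_of_empty_domain_is_zero():
    import numpy as np

    from mivmsim.geometry import (
        BoundarySpec, COCLayout, Material, ScenarioDomain, ScenarioParams,
    )
    from mivmsim.grid import RectilinearGrid

    g = RectilinearGrid([0, 1e-3], [0, 1e-3], [0, 1e-3])
    dom = ScenarioDomain(
        scenario_name="empty", grid=g,
        materials=np.full(g.shape, Material.OUTSIDE, dtype=np.uint8),
        coc_id=np.full(g.shape, -1, np.int32),
        coc_layout=COCLayout(0, 3e-4, np.zeros((0, 3)), 0),
        bc=BoundarySpec(), params=ScenarioParams(), resolution=1e-4,
    )
    assert liquid_volume(dom) == 0.0
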