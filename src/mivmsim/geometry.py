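"""Parametric geometry for the six oocyte-culture configurations.

The package models the culture systems compared in the study:

* ``static``       -- a well of a multiwell plate: 400 uL of medium (2.1 mm deep)
                      under a 2.1 mm mineral-oil overlay, open to the incubator
                      atmosphere at the oil surface.
* ``native``       -- a 2 mL cylindrical PDMS perfusion chamber with two
                      diametrically opposed lateral ports; COCs rest free on the
                      chamber floor.
* ``ring``         -- native chamber plus an impermeable resin ring
                      (inner/outer radius 5.5/7 mm) confining the COCs.
* ``concave_ring`` -- a concave resin dish (outer radius 7 mm, bowl depth
                      1.5 mm) on the chamber floor with the ring on top; COCs
                      rest in the bowl.
* ``box``          -- concave dish + ring + plain lid, fully enclosing the COCs
                      except for a thin assembly clearance between ring and lid.
* ``alginate``     -- concave dish + ring holding 150 uL of alginate gel in
                      which the COCs are embedded; medium is perfused above.

Every scenario is voxelised onto a graded rectilinear grid with per-cell
material labels; cumulus-oocyte complexes (COCs) are 0.3 mm-radius spheres
placed reproducibly from a seed.  All quantities are SI (metres, m^3).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable

import numpy as np

from .errors import GeometryError, PlacementError, ResolutionError
from .grid import RectilinearGrid, graded_axis

SCENARIOS = ("static", "native", "ring", "concave_ring", "box", "alginate")


class Material(IntEnum):
    """Per-cell material labels."""

    OUTSIDE = 0   # not part of the computational domain (PDMS bulk / beyond walls)
    MEDIA = 1     # culture medium (the only flowing material)
    OIL = 2       # mineral-oil overlay (static wells only)
    ALGINATE = 3  # calcium-alginate hydrogel (diffusion only)
    INSERT = 4    # impermeable 3D-printed resin support
    COC = 5       # interior of a cumulus-oocyte complex sphere


LIQUIDS = (Material.MEDIA, Material.OIL, Material.ALGINATE, Material.COC)


# ---------------------------------------------------------------------------
# component specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChamberSpec:
    """The cylindrical PDMS perfusion chamber (2 mL working volume)."""

    chamber_radius: float = 7.8e-3
    chamber_height: float = 10.5e-3
    wall_thickness: float = 3.0e-3
    port_radius: float = 0.75e-3
    port_center_height: float = 9.0e-3

    @property
    def chamber_volume(self) -> float:
        return np.pi * self.chamber_radius**2 * self.chamber_height

    def validate(self) -> None:
        if min(self.chamber_radius, self.chamber_height, self.wall_thickness,
               self.port_radius) <= 0:
            raise GeometryError("all chamber lengths must be positive")
        if self.chamber_radius < 7.0e-3:
            raise GeometryError("chamber radius must be >= 7 mm to contain the inserts")
        if not (self.port_radius < self.port_center_height < self.chamber_height):
            raise GeometryError("port must lie on the lateral wall between floor and lid")


@dataclass(frozen=True)
class StaticWellSpec:
    """Static-control well: 2.1 mm of medium under 2.1 mm of oil (400 uL medium)."""

    media_depth: float = 2.1e-3
    oil_depth: float = 2.1e-3
    media_volume: float = 400e-9

    @property
    def well_radius(self) -> float:
        return float(np.sqrt(self.media_volume / (np.pi * self.media_depth)))

    def validate(self) -> None:
        if min(self.media_depth, self.oil_depth, self.media_volume) <= 0:
            raise GeometryError("well dimensions must be positive")


@dataclass(frozen=True)
class InsertSpec:
    """The 3D-printed resin supports: ring, concave dish and plain lid.

    The concave dish sits on the chamber floor with the ring on top of it and,
    for the box, the plain disk as a lid; the only diffusive path into the
    closed box is the annular assembly clearance ``box_gap`` between the ring
    top and the lid (the resin itself is treated as gas-impermeable).
    """

    ring_inner_radius: float = 5.5e-3
    ring_outer_radius: float = 7.0e-3
    ring_height: float = 2.0e-3
    concave_outer_radius: float = 7.0e-3
    concave_max_depth: float = 1.5e-3
    concave_rim_thickness: float = 2.0e-3
    concave_bowl_radius: float = 6.0e-3
    plain_thickness: float = 1.0e-3
    box_gap: float = 0.55e-3

    def validate(self, chamber_radius: float) -> None:
        if self.ring_inner_radius >= self.ring_outer_radius:
            raise GeometryError("ring inner radius must be smaller than outer radius")
        if self.ring_outer_radius > chamber_radius or self.concave_outer_radius > chamber_radius:
            raise GeometryError("insert does not fit inside the chamber")
        if self.concave_max_depth > self.concave_rim_thickness:
            raise GeometryError("bowl depth exceeds the dish thickness")
        if self.concave_bowl_radius > self.concave_outer_radius:
            raise GeometryError("bowl radius exceeds the dish radius")
        if min(self.ring_height, self.plain_thickness, self.box_gap) <= 0:
            raise GeometryError("insert thicknesses must be positive")

    # -- concave bowl profile (spherical cap) ---------------------------
    @property
    def _cap_sphere_radius(self) -> float:
        r, d = self.concave_bowl_radius, self.concave_max_depth
        return (r * r + d * d) / (2.0 * d)

    def bowl_floor_z(self, r: np.ndarray | float) -> np.ndarray | float:
        """Height of the bowl surface above the chamber floor at radius r."""
        r = np.asarray(r, dtype=float)
        rs = self._cap_sphere_radius
        inside = r < self.concave_bowl_radius
        depth = np.where(
            inside,
            np.sqrt(np.maximum(rs * rs - np.minimum(r, self.concave_bowl_radius) ** 2, 0.0))
            - (rs - self.concave_max_depth),
            0.0,
        )
        return self.concave_rim_thickness - depth

    def bowl_volume_below(self, z: float) -> float:
        """Liquid volume held by the bowl below height z (z above chamber floor)."""
        rim = self.concave_rim_thickness
        fill = np.clip(z - (rim - self.concave_max_depth), 0.0, self.concave_max_depth)
        rs = self._cap_sphere_radius
        return float(np.pi * fill**2 * (3.0 * rs - fill) / 3.0)


@dataclass(frozen=True)
class COCLayout:
    """Positions of the COC spheres (deterministic given the seed)."""

    n_cocs: int
    coc_radius: float
    centers: np.ndarray  # (n, 3)
    placement_seed: int

    def min_separation(self) -> float:
        if self.n_cocs < 2:
            return np.inf
        d = self.centers[:, None, :] - self.centers[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        return float(dist[np.triu_indices(self.n_cocs, 1)].min())


@dataclass(frozen=True)
class PortBC:
    """An inlet or outlet on a grid-boundary plane (normal along x)."""

    side: str                 # "x-" or "x+"
    mask: np.ndarray          # (ny, nz) boolean: boundary faces belonging to the port
    u_unit: np.ndarray        # (ny, nz) normal velocity for unit flow rate (1 m^3/s)


@dataclass
class BoundarySpec:
    """How the domain boundary behaves for flow and oxygen."""

    inlet: PortBC | None = None
    outlet: PortBC | None = None
    lateral_robin: bool = False      # PDMS side walls permeable to oxygen
    top_dirichlet: bool = False      # atmosphere-saturated top surface
    bottom_flux: float = 0.0         # prescribed oxygen flux into the domain at z- (fixtures)
    slip_sides: frozenset[str] = frozenset()  # free-slip walls (verification ducts)


@dataclass
class ScenarioParams:
    """Full parameter set for a scenario build; overridable field by field."""

    chamber: ChamberSpec = field(default_factory=ChamberSpec)
    well: StaticWellSpec = field(default_factory=StaticWellSpec)
    insert: InsertSpec = field(default_factory=InsertSpec)
    n_cocs: int = 21
    coc_radius: float = 3.0e-4
    gel_volume: float = 150e-9
    placement_seed: int = 1
    resolution: float = 1.5e-4      # fine cell size near the COCs (vertical)
    lateral_factor: float = 2.0     # lateral spacing = lateral_factor * resolution

    def replace(self, **kw) -> "ScenarioParams":
        spec_fields = {}
        for name in ("chamber", "well", "insert"):
            sub = getattr(self, name)
            sub_kw = {k: kw.pop(k) for k in list(kw) if k in {f.name for f in dataclasses.fields(sub)}}
            spec_fields[name] = dataclasses.replace(sub, **sub_kw) if sub_kw else sub
        unknown = set(kw) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise GeometryError(f"unknown scenario parameters: {sorted(unknown)}")
        return dataclasses.replace(self, **spec_fields, **kw)


@dataclass
class ScenarioDomain:
    """A meshed, material-labelled culture configuration."""

    scenario_name: str
    grid: RectilinearGrid
    materials: np.ndarray          # (nx, ny, nz) Material codes
    coc_id: np.ndarray             # (nx, ny, nz) int: COC index per cell, -1 elsewhere
    coc_layout: COCLayout
    bc: BoundarySpec
    params: ScenarioParams
    resolution: float
    in_chamber: np.ndarray | None = None   # cells radially inside the chamber wall
    culture_mask: np.ndarray | None = None  # liquid cells of the COC culture region

    @property
    def liquid(self) -> np.ndarray:
        return np.isin(self.materials, LIQUIDS)

    @property
    def fluid(self) -> np.ndarray:
        """Cells in which medium can flow."""
        return self.materials == Material.MEDIA

    def region_mask(self, region: str) -> np.ndarray:
        m = self.materials
        if region == "media":
            return m == Material.MEDIA
        if region == "media+alginate":
            return (m == Material.MEDIA) | (m == Material.ALGINATE)
        if region == "gel":
            return m == Material.ALGINATE
        if region == "all_liquid":
            return self.liquid
        if region == "culture":
            if self.culture_mask is None:
                raise GeometryError("domain has no culture region defined")
            return self.culture_mask
        raise GeometryError(f"unknown region {region!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _radius_grid(grid: RectilinearGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xc, yc, zc = grid.centers()
    return np.sqrt(xc**2 + yc**2), yc, zc


def _port_profile(grid: RectilinearGrid, chamber: ChamberSpec, side: str) -> PortBC:
    """Parabolic (Poiseuille-like) normal-velocity profile over the port disk."""
    yc, zc = np.meshgrid(grid.yc, grid.zc, indexing="ij")
    rho2 = (yc**2 + (zc - chamber.port_center_height) ** 2) / chamber.port_radius**2
    mask = rho2 < 1.0
    w = np.where(mask, 1.0 - rho2, 0.0)
    areas = grid.dy[:, None] * grid.dz[None, :]
    total = float((w * areas).sum())
    if total <= 0:
        raise ResolutionError("mesh does not resolve the inlet/outlet port")
    return PortBC(side=side, mask=mask, u_unit=w / total)


def _carve_cocs(
    domain_materials: np.ndarray,
    grid: RectilinearGrid,
    layout: COCLayout,
) -> np.ndarray:
    """Label cells whose centre lies inside a COC sphere; returns coc_id array."""
    coc_id = np.full(domain_materials.shape, -1, dtype=np.int32)
    xc, yc, zc = grid.centers()
    for idx, (cx, cy, cz) in enumerate(layout.centers):
        d2 = (xc - cx) ** 2 + (yc - cy) ** 2 + (zc - cz) ** 2
        inside = (d2 <= layout.coc_radius**2) & (
            (domain_materials == Material.MEDIA) | (domain_materials == Material.ALGINATE)
        )
        if not inside.any():
            raise ResolutionError("mesh too coarse: a COC sphere contains no cell centre")
        domain_materials[inside] = Material.COC
        coc_id[inside] = idx
    return coc_id


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    radial_max: float,
    floor_z: Callable[[float], float],
    coc_radius: float,
    z_range: tuple[float, float] | None = None,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample non-overlapping sphere centres on a floor (or in a slab)."""
    centers: list[np.ndarray] = []
    min_d2 = (2.0 * coc_radius * (1.0 + 1e-9)) ** 2
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n} non-overlapping COCs after {max_attempts} attempts"
            )
        r = radial_max * np.sqrt(rng.random())
        th = 2.0 * np.pi * rng.random()
        x, y = r * np.cos(th), r * np.sin(th)
        if z_range is None:
            z = floor_z(r) + coc_radius
        else:
            lo = floor_z(r) + 1.2 * coc_radius
            hi = max(z_range[1] - 1.2 * coc_radius, lo)
            z = lo + (hi - lo) * rng.random()
        cand = np.array([x, y, z])
        if all(((cand - c) ** 2).sum() >= min_d2 for c in centers):
            centers.append(cand)
    return np.array(centers)


def place_cocs(domain_or_name, n: int, seed: int, params: ScenarioParams | None = None) -> COCLayout:
    """Sample a reproducible COC layout for a scenario.

    Accepts either a built :class:`ScenarioDomain` or a scenario name plus
    parameters.  Placement is uniform over the admissible floor area of the
    configuration (the bowl for concave scenarios, a slab inside the gel for
    the alginate scenario), with an exhaustive non-overlap guarantee.
    """
    if isinstance(domain_or_name, ScenarioDomain):
        name = domain_or_name.scenario_name
        params = domain_or_name.params
    else:
        name = str(domain_or_name)
        params = params or ScenarioParams()
    if n < 1:
        raise PlacementError("need at least one COC")
    a = params.coc_radius
    ins = params.insert
    rng = np.random.default_rng(seed)
    flat = lambda r: 0.0  # noqa: E731

    if name == "static":
        centers = _sample_positions(rng, n, params.well.well_radius - 1.5 * a, flat, a)
    elif name == "native":
        centers = _sample_positions(rng, n, params.chamber.chamber_radius - 1.5 * a, flat, a)
    elif name == "ring":
        centers = _sample_positions(rng, n, ins.ring_inner_radius - 1.5 * a, flat, a)
    elif name in ("concave_ring", "box"):
        centers = _sample_positions(
            rng, n, ins.concave_bowl_radius - 2.5 * a, lambda r: float(ins.bowl_floor_z(r)), a
        )
    elif name == "alginate":
        # keep the spheres a couple of cells below the gel surface so the
        # carved COC cells never abut flowing medium (embedded => zero shear)
        gel_top = _gel_top(params) - 2.5 * params.resolution
        centers = _sample_positions(
            rng, n, min(ins.ring_inner_radius, ins.concave_bowl_radius) - 2.5 * a,
            lambda r: float(ins.bowl_floor_z(r)), a, z_range=(0.0, gel_top),
        )
    else:
        raise GeometryError(f"unknown scenario {name!r}")
    return COCLayout(n_cocs=n, coc_radius=a, centers=centers, placement_seed=seed)


def _gel_top(params: ScenarioParams) -> float:
    """Height of the alginate surface giving the requested gel volume."""
    ins = params.insert
    rim = ins.concave_rim_thickness
    v_bowl = ins.bowl_volume_below(rim)
    if params.gel_volume >= v_bowl:
        extra = params.gel_volume - v_bowl
        return rim + extra / (np.pi * ins.ring_inner_radius**2)
    # partially filled bowl: invert the cap-volume formula by bisection
    lo, hi = rim - ins.concave_max_depth, rim
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ins.bowl_volume_below(mid) < params.gel_volume:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

def build_scenario(
    name: str,
    overrides: dict | None = None,
    resolution: float | None = None,
) -> ScenarioDomain:
    """Build a meshed, labelled domain for one of the six culture configurations.

    ``resolution`` is the fine (near-COC) cell size; the voxelised COC spheres
    require at least two cells across a radius, so values above half the COC
    radius raise :class:`ResolutionError`.
    """
    if name not in SCENARIOS:
        raise GeometryError(f"unknown scenario {name!r}; valid: {SCENARIOS}")
    params = ScenarioParams()
    if overrides:
        params = params.replace(**overrides)
    if resolution is not None:
        params = dataclasses.replace(params, resolution=float(resolution))
    if params.resolution > params.coc_radius / 2 + 1e-12:
        raise ResolutionError(
            f"resolution {params.resolution:g} m too coarse to resolve "
            f"COCs of radius {params.coc_radius:g} m (need <= radius/2)"
        )
    params.chamber.validate()
    params.well.validate()
    params.insert.validate(params.chamber.chamber_radius)

    layout = place_cocs(name, params.n_cocs, params.placement_seed, params)
    if name == "static":
        dom = _build_static(params, layout)
    else:
        dom = _build_bioreactor(name, params, layout)
    return dom


def _build_static(params: ScenarioParams, layout: COCLayout) -> ScenarioDomain:
    res = params.resolution
    lat = params.lateral_factor * res
    well = params.well
    rw = well.well_radius
    fine_top = min(6 * res, well.media_depth)
    zf = graded_axis([
        (0.0, fine_top, res),
        (fine_top, well.media_depth, 2 * res),
        (well.media_depth, well.media_depth + well.oil_depth, 3 * res),
    ])
    xf = graded_axis([(-rw, rw, lat)])
    grid = RectilinearGrid(xf, xf.copy(), zf)

    rc, _, zc = _radius_grid(grid)
    m = np.full(grid.shape, Material.OUTSIDE, dtype=np.uint8)
    inside = rc <= rw
    m[inside & (zc < well.media_depth)] = Material.MEDIA
    m[inside & (zc >= well.media_depth)] = Material.OIL
    coc_id = _carve_cocs(m, grid, layout)

    bc = BoundarySpec(top_dirichlet=True)
    culture = m == Material.MEDIA
    return ScenarioDomain(
        scenario_name="static", grid=grid, materials=m, coc_id=coc_id,
        coc_layout=layout, bc=bc, params=params, resolution=res,
        in_chamber=inside, culture_mask=culture,
    )


def _build_bioreactor(name: str, params: ScenarioParams, layout: COCLayout) -> ScenarioDomain:
    res = params.resolution
    lat = params.lateral_factor * res
    ch = params.chamber
    ins = params.insert
    R, H = ch.chamber_radius, ch.chamber_height
    port_top = ch.port_center_height + ch.port_radius

    # vertical grading: fine across the COC layer, medium around the ports and
    # insert tops, coarse in the upper chamber; insert-feature heights are
    # forced onto mesh faces.
    if name in ("concave_ring", "box", "alginate"):
        fine_top = ins.concave_rim_thickness + 2 * params.coc_radius + res
    else:
        fine_top = 6 * res
    port_lo = max(ch.port_center_height - ch.port_radius - 2 * res, fine_top)
    port_hi = min(port_top + 2 * res, H)
    assembly_top = ins.concave_rim_thickness + ins.ring_height
    bps = {fine_top, port_lo, port_hi, H}
    if name == "ring":
        bps.add(ins.ring_height)
    if name in ("concave_ring", "box", "alginate"):
        bps.update({ins.concave_rim_thickness, assembly_top})
        if name == "box":
            bps.update({assembly_top + ins.box_gap,
                        assembly_top + ins.box_gap + ins.plain_thickness})
        if name == "alginate":
            bps.add(_gel_top(params))
    zs: list[float] = []
    for b in sorted(bp for bp in bps if 0.0 < bp <= H):
        if not zs or b - zs[-1] > 1e-9:
            zs.append(b)
    if abs(zs[-1] - H) > 1e-9:
        zs.append(H)

    def _spacing(z0: float, z1: float) -> float:
        if name == "box" and abs(z0 - assembly_top) < 1e-12 and z1 <= assembly_top + ins.box_gap + 1e-12:
            return ins.box_gap  # one dedicated cell layer across the assembly clearance
        zm = 0.5 * (z0 + z1)
        if zm <= fine_top:
            return res
        if port_lo <= zm <= port_hi:
            return 2 * res  # resolve the port band
        if zm <= fine_top + 2 * res:
            return 2 * res
        return 5 * res

    segments, z0 = [], 0.0
    for z1 in zs:
        segments.append((z0, z1, _spacing(z0, z1)))
        z0 = z1
    zf = graded_axis(segments)

    chan = ch.wall_thickness / max(2, int(round(ch.wall_thickness / (5 * res))))
    xf = graded_axis([(-R - ch.wall_thickness, -R, chan), (-R, R, lat), (R, R + ch.wall_thickness, chan)])
    yf = graded_axis([(-R, R, lat)])
    grid = RectilinearGrid(xf, yf, zf)

    rc, ycg, zc = _radius_grid(grid)
    xc = grid.centers()[0]
    m = np.full(grid.shape, Material.OUTSIDE, dtype=np.uint8)
    in_chamber = rc <= R
    m[in_chamber] = Material.MEDIA

    # port channels through the wall thickness, along +-x at y = 0
    port = (np.abs(xc) > R) & (
        ycg**2 + (zc - ch.port_center_height) ** 2 <= ch.port_radius**2
    )
    m[port] = Material.MEDIA

    # inserts
    if name == "ring":
        ring = (rc >= ins.ring_inner_radius) & (rc <= ins.ring_outer_radius) & (zc <= ins.ring_height)
        m[ring & in_chamber] = Material.INSERT
    elif name in ("concave_ring", "box", "alginate"):
        floor = ins.bowl_floor_z(rc)
        dish = (rc <= ins.concave_outer_radius) & (zc <= floor)
        m[dish & in_chamber] = Material.INSERT
        rim = ins.concave_rim_thickness
        ring = (
            (rc >= ins.ring_inner_radius) & (rc <= ins.ring_outer_radius)
            & (zc > rim) & (zc <= rim + ins.ring_height)
        )
        m[ring & in_chamber] = Material.INSERT
        if name == "box":
            lid_lo = rim + ins.ring_height + ins.box_gap
            lid = (rc <= ins.concave_outer_radius) & (zc > lid_lo) & (zc <= lid_lo + ins.plain_thickness)
            m[lid & in_chamber] = Material.INSERT
        if name == "alginate":
            gel_top = _gel_top(params)
            gel = (m == Material.MEDIA) & (zc <= gel_top) & (
                ((zc <= rim) & (rc <= ins.concave_bowl_radius))
                | ((zc > rim) & (rc <= ins.ring_inner_radius))
            )
            m[gel] = Material.ALGINATE

    coc_id = _carve_cocs(m, grid, layout)

    bc = BoundarySpec(
        inlet=_port_profile(grid, ch, "x-"),
        outlet=_port_profile(grid, ch, "x+"),
        lateral_robin=True,
    )

    # culture region: the liquid the COCs actually sit in
    if name == "native":
        culture = m == Material.MEDIA
    elif name == "ring":
        culture = (m == Material.MEDIA) & (rc < ins.ring_inner_radius) & (zc < ins.ring_height)
    elif name in ("concave_ring", "box"):
        top = ins.concave_rim_thickness + ins.ring_height
        culture = (m == Material.MEDIA) & (zc < top) & (
            (rc < ins.ring_inner_radius)
            | ((zc < ins.concave_rim_thickness) & (rc < ins.concave_bowl_radius))
        )
    else:  # alginate
        top = ins.concave_rim_thickness + ins.ring_height
        culture = ((m == Material.ALGINATE)
                   | ((m == Material.MEDIA) & (rc < ins.ring_inner_radius) & (zc < top)))

    return ScenarioDomain(
        scenario_name=name, grid=grid, materials=m, coc_id=coc_id,
        coc_layout=layout, bc=bc, params=params, resolution=res,
        in_chamber=in_chamber, culture_mask=culture,
    )


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def liquid_volume(domain: ScenarioDomain) -> float:
    """Total medium + gel volume (m^3), excluding oil, solids and COC interiors."""
    vols = domain.grid.cell_volumes()
    mask = (domain.materials == Material.MEDIA) | (domain.materials == Material.ALGINATE)
    return float(vols[mask].sum())


def region_volume(domain: ScenarioDomain, region: str) -> float:
    vols = domain.grid.cell_volumes()
    return float(vols[domain.region_mask(region)].sum())


def coc_surface_areas(domain: ScenarioDomain) -> np.ndarray:
    """Surface area of each COC as represented at the mesh's fine resolution.

    The area is measured by triangulating the zero level set of each sphere's
    signed distance function sampled at the fine cell size (marching cubes),
    which is accurate to a few percent even for spheres a handful of cells
    wide, unlike raw voxel-face counting which overestimates curved areas by
    up to 50%.
    """
    from skimage.measure import marching_cubes, mesh_surface_area

    a = domain.coc_layout.coc_radius
    h = domain.resolution
    n = int(np.ceil((a + 2 * h) / h))
    coords = np.arange(-n, n + 1) * h
    xg, yg, zg = np.meshgrid(coords, coords, coords, indexing="ij")
    sdf = np.sqrt(xg**2 + yg**2 + zg**2) - a
    verts, faces_tri, _, _ = marching_cubes(sdf, level=0.0, spacing=(h, h, h))
    area = mesh_surface_area(verts, faces_tri)
    return np.full(domain.coc_layout.n_cocs, area)
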