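"""Synthetic data generators and analytic verification fixtures.

The outcome-table generator draws multinomial category counts with the same
structure as the published nuclear-chromatin/mitochondria tables (default
probabilities: the observed control and native-flow proportions).  The
fluorescence generator draws truncated-normal per-oocyte intensities on the
0-255 ADU scale; the study's own per-oocyte values are unpublished, so the
default group means are a synthetic calibration chosen to reproduce the
reported significance pattern (both native-flow groups far below control),
not data from the study.

Analytic fixtures provide closed-form oracles for the PDE solvers: plane
Poiseuille flow in a duct (wall shear 6 mu Q / (w h^2)), the two-layer
series-resistance oxygen slab, and a uniform saturated box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from .errors import MivmError
from .geometry import (
    BoundarySpec,
    COCLayout,
    Material,
    PortBC,
    ScenarioDomain,
    ScenarioParams,
)
from .grid import RectilinearGrid
from .stats import FluorescenceSample, OutcomeTable


# ---------------------------------------------------------------------------
# outcome tables
# ---------------------------------------------------------------------------

@dataclass
class OutcomeGeneratorSpec:
    """Multinomial generator for group x category outcome counts."""

    categories: list[str]
    group_probs: dict[str, np.ndarray]   # per-group probabilities on the simplex
    n_per_group: dict[str, int]
    seed: int = 0

    def validate(self) -> None:
        for g, p in self.group_probs.items():
            p = np.asarray(p, float)
            if p.ndim != 1 or p.size != len(self.categories):
                raise MivmError(f"group {g!r}: probability vector has wrong length")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise MivmError(f"group {g!r}: probabilities must lie on the simplex")
            if self.n_per_group.get(g, 0) <= 0:
                raise MivmError(f"group {g!r}: n must be positive")


def default_outcome_spec(seed: int = 0) -> OutcomeGeneratorSpec:
    """Observed nuclear-maturation proportions of the native-flow experiment."""
    counts = {
        "CTRL": np.array([12, 8, 49, 6], float),
        "native_50": np.array([14, 24, 20, 17], float),
        "native_100": np.array([12, 27, 18, 15], float),
    }
    return OutcomeGeneratorSpec(
        categories=["GV", "MI-TI", "MII", "Abnormal"],
        group_probs={g: c / c.sum() for g, c in counts.items()},
        n_per_group={"CTRL": 75, "native_50": 75, "native_100": 72},
        seed=seed,
    )


def gen_outcome_table(spec: OutcomeGeneratorSpec) -> OutcomeTable:
    """Draw an outcome table; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.group_probs)
    counts = np.vstack([
        rng.multinomial(spec.n_per_group[g], np.asarray(spec.group_probs[g], float))
        for g in groups
    ])
    return OutcomeTable(groups=groups, categories=list(spec.categories), counts=counts)


# ---------------------------------------------------------------------------
# fluorescence intensities
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceGeneratorSpec:
    """Truncated-normal generator for per-oocyte ADU intensities."""

    group_means: dict[str, float]
    group_sds: dict[str, float]
    n_per_group: dict[str, int]
    measure: str = "mito_activity"
    bounds: tuple[float, float] = (0.0, 255.0)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise MivmError("invalid truncation bounds")
        for g, m in self.group_means.items():
            if not lo <= m <= hi:
                raise MivmError(f"group {g!r}: mean outside bounds")
            if self.group_sds.get(g, -1.0) < 0:
                raise MivmError(f"group {g!r}: SD must be non-negative")
            if self.n_per_group.get(g, 0) <= 0:
                raise MivmError(f"group {g!r}: n must be positive")


def default_fluorescence_spec(seed: int = 0, measure: str = "mito_activity") -> FluorescenceGeneratorSpec:
    """Synthetic calibration emulating the reported pattern (mIVM << control).

    Means/SDs are in ADU; the ~2-SD separation makes both native-flow groups
    come out *** against the control, as the study reports.
    """
    return FluorescenceGeneratorSpec(
        group_means={"CTRL": 150.0, "native_50": 90.0, "native_100": 85.0},
        group_sds={"CTRL": 30.0, "native_50": 30.0, "native_100": 30.0},
        n_per_group={"CTRL": 30, "native_50": 20, "native_100": 18},
        measure=measure,
        seed=seed,
    )


def gen_fluorescence(spec: FluorescenceGeneratorSpec) -> list[FluorescenceSample]:
    """Draw truncated-normal samples per group; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.bounds
    out = []
    for g, mean in spec.group_means.items():
        sd = spec.group_sds[g]
        n = spec.n_per_group[g]
        if sd == 0:
            vals = np.full(n, mean)
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            vals = sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        out.append(FluorescenceSample(group=g, values=vals, measure=spec.measure))
    return out


# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------

@dataclass
class AnalyticFixture:
    """A geometry + closed-form pair used as an independent solver oracle."""

    name: str
    params: dict
    closed_form: Callable
    build_domain: Callable[..., ScenarioDomain] | None = None


def _empty_layout() -> COCLayout:
    return COCLayout(n_cocs=0, coc_radius=3e-4, centers=np.zeros((0, 3)), placement_seed=0)


def build_duct(
    width: float = 4e-3, height: float = 1e-3, length: float = 8e-3,
    resolution: float = 5e-5,
) -> ScenarioDomain:
    """A rectangular channel with free-slip sides: plane Poiseuille flow in x.

    The inlet/outlet impose the parabolic profile and the channel floor is a
    layer of solid cells, so the wall-shear extraction runs through the same
    code path as the COC surfaces and can be checked against 6 mu Q/(w h^2).
    """
    nz = max(6, int(round(height / resolution)))
    dz = height / nz
    g = RectilinearGrid(
        np.linspace(0, length, max(4, int(round(length / (4 * resolution)))) + 1),
        np.linspace(0, width, max(2, int(round(width / (8 * resolution)))) + 1),
        np.linspace(-dz, height, nz + 2),  # one solid floor layer below z = 0
    )
    m = np.full(g.shape, Material.MEDIA, dtype=np.uint8)
    m[:, :, 0] = Material.INSERT
    yc, zc = np.meshgrid(g.yc, g.zc, indexing="ij")
    prof = np.where(zc > 0, zc * (height - zc), 0.0)
    areas = g.dy[:, None] * g.dz[None, :]
    u_unit = prof / float((prof * areas).sum())
    mask = prof > 0
    bc = BoundarySpec(
        inlet=PortBC(side="x-", mask=mask, u_unit=u_unit),
        outlet=PortBC(side="x+", mask=mask, u_unit=u_unit),
        slip_sides=frozenset({"y-", "y+"}),
    )
    return ScenarioDomain(
        scenario_name="duct_fixture", grid=g, materials=m,
        coc_id=np.full(g.shape, -1, dtype=np.int32), coc_layout=_empty_layout(),
        bc=bc, params=ScenarioParams(), resolution=resolution,
    )


def build_slab(
    media_depth: float = 2.1e-3, oil_depth: float = 2.1e-3,
    flux_out: float = 7.35e-9, side: float = 1e-3, resolution: float = 7e-5,
) -> ScenarioDomain:
    """A 1-D two-layer column: medium under oil, saturated top, bottom sink flux.

    ``flux_out`` (mol m^-2 s^-1) is drawn through the floor, standing in for
    the areal COC consumption; the steady profile is piecewise linear with the
    series resistance L_oil/D_oil + L_media/D_media.
    """
    nz1 = max(4, int(round(media_depth / resolution)))
    nz2 = max(4, int(round(oil_depth / resolution)))
    zf = np.concatenate([
        np.linspace(0, media_depth, nz1 + 1),
        np.linspace(media_depth, media_depth + oil_depth, nz2 + 1)[1:],
    ])
    g = RectilinearGrid(np.array([0.0, side]), np.array([0.0, side]), zf)
    m = np.full(g.shape, Material.MEDIA, dtype=np.uint8)
    m[:, :, g.zc > media_depth] = Material.OIL
    bc = BoundarySpec(top_dirichlet=True, bottom_flux=-flux_out)
    return ScenarioDomain(
        scenario_name="slab_fixture", grid=g, materials=m,
        coc_id=np.full(g.shape, -1, dtype=np.int32), coc_layout=_empty_layout(),
        bc=bc, params=ScenarioParams(), resolution=resolution,
    )


def build_uniform_box(side: float = 2e-3, resolution: float = 2e-4) -> ScenarioDomain:
    """A small saturated media box with no consumption (constant solution)."""
    n = max(3, int(round(side / resolution)))
    f = np.linspace(0, side, n + 1)
    g = RectilinearGrid(f, f.copy(), f.copy())
    m = np.full(g.shape, Material.MEDIA, dtype=np.uint8)
    bc = BoundarySpec(top_dirichlet=True)
    return ScenarioDomain(
        scenario_name="uniform_box_fixture", grid=g, materials=m,
        coc_id=np.full(g.shape, -1, dtype=np.int32), coc_layout=_empty_layout(),
        bc=bc, params=ScenarioParams(), resolution=resolution,
    )


def make_fixture(name: str, **kw) -> AnalyticFixture:
    """Build one of the named analytic fixtures with its closed form."""
    if name == "plane_poiseuille":
        p = {"width": 4e-3, "height": 1e-3, "length": 8e-3, "viscosity": 6.913e-4}
        p.update(kw)

        def tau_wall(flow_rate: float) -> float:
            return 6.0 * p["viscosity"] * flow_rate / (p["width"] * p["height"] ** 2)

        return AnalyticFixture(
            name=name, params=p, closed_form=tau_wall,
            build_domain=lambda resolution=5e-5: build_duct(
                p["width"], p["height"], p["length"], resolution
            ),
        )
    if name == "two_layer_slab":
        p = {
            "media_depth": 2.1e-3, "oil_depth": 2.1e-3, "d_media": 3e-9,
            "d_oil": 2e-9, "flux_out": 7.35e-9, "c_sat": 0.21,
        }
        p.update(kw)

        def profile(z):
            z = np.asarray(z, float)
            lm, lo = p["media_depth"], p["oil_depth"]
            j = p["flux_out"]
            in_media = z <= lm
            c_media = p["c_sat"] - j * lo / p["d_oil"] - j * (lm - z) / p["d_media"]
            c_oil = p["c_sat"] - j * (lm + lo - z) / p["d_oil"]
            return np.where(in_media, c_media, c_oil)

        return AnalyticFixture(
            name=name, params=p, closed_form=profile,
            build_domain=lambda resolution=7e-5: build_slab(
                p["media_depth"], p["oil_depth"], p["flux_out"], resolution=resolution
            ),
        )
    if name == "uniform_box":
        p = {"side": 2e-3, "c_sat": 0.21}
        p.update(kw)
        return AnalyticFixture(
            name=name, params=p, closed_form=lambda z: np.full_like(np.asarray(z, float), p["c_sat"]),
            build_domain=lambda resolution=2e-4: build_uniform_box(p["side"], resolution),
        )
    raise MivmError(f"unknown fixture {name!r}")
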