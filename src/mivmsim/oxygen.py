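"""Oxygen convection-reaction-diffusion over the labelled culture domain.

The oxygen balance is discretised by a conservative finite-volume scheme on
the same rectilinear grid as the flow: harmonic-mean diffusive conductances
across material interfaces (medium / oil / alginate / COC), first-order upwind
advection using the staggered flow field, and the following boundaries:

* inlet port       -- fixed inlet concentration (advective + diffusive),
* outlet port      -- advective outflow,
* PDMS side walls  -- Robin flux (permeability / wall thickness) x
                      (atmospheric partial pressure - local partial pressure),
* oil surface      -- fixed atmospheric saturation (static wells),
* everything else  -- impermeable.

Each COC consumes oxygen at a constant rate (OCR, default 4 pmol/min per COC)
distributed over its sphere; below a cutoff concentration the sink decays
linearly to zero so the steady state can never go negative.  Because upwind
fluxes and harmonic conductances yield an M-matrix, the discrete solution
obeys the maximum principle: concentrations stay between zero and saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, MivmError, StepSizeError
from .flow import FlowField, zero_flow
from .geometry import Material, ScenarioDomain

PMOL_MIN = 1e-12 / 60.0  # mol/s per pmol/min


@dataclass
class OxygenParams:
    """Transport, reaction and boundary parameters for the oxygen model."""

    d_media: float = 3.0e-9          # m^2/s
    d_alginate: float = 2.5e-9       # m^2/s
    d_oil: float = 2.0e-9            # m^2/s
    d_coc: float = 3.0e-9            # m^2/s inside the COC sphere (as medium)
    pdms_permeability: float = 3.78e-11   # mol m / (m^2 s mmHg)
    pdms_wall_thickness: float = 3.0e-3   # m
    ocr_per_coc: float = 4.0 * PMOL_MIN   # mol/s per COC
    per_coc: bool = True             # False: ocr_per_coc is the total for all COCs
    c_initial: float = 0.21          # mol/m^3
    p_atm: float = 159.0             # mmHg
    c_crit: float = 0.005            # mol/m^3, linear-sink cutoff
    inlet_concentration: float | None = None  # default: saturated inlet
    coc_radius: float = 3.0e-4       # m, sphere over which the OCR is distributed

    @property
    def solubility(self) -> float:
        """Henry solubility alpha fixed by the (0.21 mol/m^3, 159 mmHg) pair."""
        return self.c_initial / self.p_atm

    @property
    def c_sat(self) -> float:
        return self.solubility * self.p_atm  # == c_initial exactly

    @property
    def c_inlet(self) -> float:
        return self.c_initial if self.inlet_concentration is None else self.inlet_concentration

    @property
    def wall_transfer_coeff(self) -> float:
        """Robin coefficient in concentration form, m/s."""
        return self.pdms_permeability / (self.pdms_wall_thickness * self.solubility)

    def diffusivity_of(self, materials: np.ndarray) -> np.ndarray:
        d = np.zeros(materials.shape)
        d[materials == Material.MEDIA] = self.d_media
        d[materials == Material.OIL] = self.d_oil
        d[materials == Material.ALGINATE] = self.d_alginate
        d[materials == Material.COC] = self.d_coc
        return d


@dataclass
class OxygenField:
    """Concentration field (mol/m^3) with per-boundary flux diagnostics."""

    concentration: np.ndarray        # (nx, ny, nz), nan outside the liquid
    time: float                      # seconds; inf for a steady solution
    fluxes: dict = dfield(default_factory=dict)  # boundary influx / consumption, mol/s
    diagnostics: dict = dfield(default_factory=dict)


def coc_sink(c, params: OxygenParams):
    """Volumetric oxygen consumption (mol m^-3 s^-1) inside a COC at concentration c.

    Zeroth order at the full OCR above the cutoff, decaying linearly to zero
    below it; the rate density distributes the per-COC OCR over the sphere
    volume (4/3) pi a^3.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise MivmError("negative oxygen concentration passed to coc_sink")
    v_coc = 4.0 / 3.0 * np.pi * params.coc_radius**3
    q0 = params.ocr_per_coc / v_coc
    return q0 * np.minimum(1.0, c / params.c_crit)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class _Transport:
    """Steady transport operator  A c = b  (integrated, mol/s per cell row)."""

    def __init__(self, domain: ScenarioDomain, flow: FlowField | None, params: OxygenParams):
        self.domain = domain
        self.params = params
        self._Q = 0.0 if flow is None else flow.params.flow_rate
        g = domain.grid
        liquid = domain.liquid
        self.liquid = liquid
        self.ncell = int(liquid.sum())
        cidx = np.full(g.shape, -1, dtype=np.int64)
        cidx[liquid] = np.arange(self.ncell)
        self.cidx = cidx
        self.vol = g.cell_volumes()[liquid]
        if flow is None:
            flow = zero_flow(domain)
        dcell = params.diffusivity_of(domain.materials)
        spac = (g.dx, g.dy, g.dz)
        vel = (flow.u, flow.v, flow.w)

        rows, cols, vals = [], [], []
        b = np.zeros(self.ncell)
        diag = np.zeros(self.ncell)
        # boundary flux bookkeeping (assembled terms are evaluated after solve)
        self._robin_cells: list[np.ndarray] = []
        self._robin_g: list[np.ndarray] = []
        self._dir_cells: list[np.ndarray] = []
        self._dir_g: list[np.ndarray] = []
        self._dir_val: list[np.ndarray] = []
        self._adv_out_cells: list[np.ndarray] = []
        self._adv_out_F: list[np.ndarray] = []
        self._adv_in = 0.0
        self._fixed_influx = 0.0

        for axis in range(3):
            d_n = spac[axis]
            other = [a for a in range(3) if a != axis]
            area = np.multiply.outer(spac[other[0]], spac[other[1]])

            # ---- interior faces between liquid cells ----
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            L = liquid[tuple(lo)] & liquid[tuple(hi)]
            I, J, K = np.nonzero(L)
            idxs = [I, J, K]
            cell_lo = [I, J, K]
            cell_hi = [I.copy(), J.copy(), K.copy()]
            cell_hi[axis] = cell_hi[axis] + 1
            n_lo = cidx[tuple(cell_lo)]
            n_hi = cidx[tuple(cell_hi)]
            A_f = area[idxs[other[0]], idxs[other[1]]]
            d1 = d_n[cell_lo[axis]]
            d2 = d_n[cell_hi[axis]]
            D1 = dcell[tuple(cell_lo)]
            D2 = dcell[tuple(cell_hi)]
            # harmonic-mean conductance: A / (d1/(2 D1) + d2/(2 D2))
            g_f = A_f / (0.5 * d1 / D1 + 0.5 * d2 / D2)
            # diffusion
            np.add.at(diag, n_lo, g_f)
            np.add.at(diag, n_hi, g_f)
            rows.extend([n_lo, n_hi])
            cols.extend([n_hi, n_lo])
            vals.extend([-g_f, -g_f])
            # advection (upwind); face velocity is the staggered component at
            # the shared face, zero across any non-flowing interface
            uf = vel[axis]
            face_idx = [I, J, K]
            face_idx[axis] = face_idx[axis] + 1  # face between cell_lo and cell_hi
            F = uf[tuple(face_idx)] * A_f        # m^3/s, positive lo -> hi
            Fp = np.maximum(F, 0.0)
            Fm = np.maximum(-F, 0.0)
            np.add.at(diag, n_lo, Fp)
            np.add.at(diag, n_hi, Fm)
            rows.extend([n_lo, n_hi])
            cols.extend([n_hi, n_lo])
            vals.extend([-Fm, -Fp])

            # ---- boundary faces of the grid ----
            for side in (0, 1):
                sl = [slice(None)] * 3
                sl[axis] = -1 if side else 0
                cells = liquid[tuple(sl)]
                I2, J2 = np.nonzero(cells)
                if I2.size == 0:
                    continue
                full_idx = [None, None, None]
                full_idx[axis] = np.full(I2.size, (d_n.size - 1) if side else 0)
                full_idx[other[0]] = I2
                full_idx[other[1]] = J2
                rowc = cidx[tuple(full_idx)]
                A_b = area[I2, J2]
                g_half = A_b * dcell[tuple(full_idx)] / (0.5 * d_n[full_idx[axis]])
                self._boundary_terms(
                    axis, side, full_idx, rowc, A_b, g_half, diag, b
                )

            # ---- interior liquid/outside or liquid/insert faces: no flux ----
            # (nothing to assemble; PDMS Robin handled below)

        # PDMS lateral Robin on interior liquid|outside faces (x/y normals)
        if domain.bc.lateral_robin:
            self._assemble_robin(diag, b, spac)

        me = np.arange(self.ncell)
        rows.append(me)
        cols.append(me)
        vals.append(diag)
        self.A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ncell, self.ncell),
        )
        self.b = b

        # COC sinks: per-COC voxel sets, OCR normalised to the voxelised volume
        self._build_sinks()

    # -- boundary handling ----------------------------------------------
    def _boundary_terms(self, axis, side, full_idx, rowc, A_b, g_half, diag, b):
        dom, par = self.domain, self.params
        bc = dom.bc
        side_name = {0: ("x-", "x+"), 1: ("y-", "y+"), 2: ("z-", "z+")}[axis][side]

        # atmosphere-saturated top (static wells, fixtures)
        if bc.top_dirichlet and side_name == "z+":
            np.add.at(diag, rowc, g_half)
            b[rowc] += g_half * par.c_sat
            self._dir_cells.append(rowc)
            self._dir_g.append(g_half)
            self._dir_val.append(np.full(rowc.size, par.c_sat))
            return
        # prescribed bottom flux (analytic slab fixtures)
        if bc.bottom_flux and side_name == "z-":
            b[rowc] += bc.bottom_flux * A_b
            self._fixed_influx += float((bc.bottom_flux * A_b).sum())
            return
        # ports
        for port, is_inlet in ((bc.inlet, True), (bc.outlet, False)):
            if port is None or port.side != side_name:
                continue
            mask2d = port.mask[tuple(full_idx[1:])] if axis == 0 else None
            if mask2d is None:
                continue
            Q = self._flow_rate
            qface = Q * port.u_unit[tuple(full_idx[1:])] * A_b  # m^3/s per face
            if is_inlet:
                sel = mask2d
                r = rowc[sel]
                b[r] += qface[sel] * par.c_inlet            # advective influx
                np.add.at(diag, r, g_half[sel])             # diffusive to c_inlet
                b[r] += g_half[sel] * par.c_inlet
                self._dir_cells.append(r)
                self._dir_g.append(g_half[sel])
                self._dir_val.append(np.full(r.size, par.c_inlet))
                self._adv_in += float(qface[sel].sum()) * par.c_inlet
            else:
                sel = mask2d
                r = rowc[sel]
                np.add.at(diag, r, qface[sel])              # advective outflow
                self._adv_out_cells.append(r)
                self._adv_out_F.append(qface[sel])
            return
        # default: impermeable boundary — no terms

    def _assemble_robin(self, diag, b, spac):
        dom, par = self.domain, self.params
        k = par.wall_transfer_coeff
        liquid = self.liquid
        chamber = dom.in_chamber if dom.in_chamber is not None else np.ones_like(liquid)
        outside = dom.materials == Material.OUTSIDE
        for axis in (0, 1):
            d_n = spac[axis]
            other = [a for a in range(3) if a != axis]
            area = np.multiply.outer(spac[other[0]], spac[other[1]])
            for sgn in (+1, -1):
                nb = np.roll(outside, -sgn, axis=axis)
                edge = [slice(None)] * 3
                edge[axis] = -1 if sgn > 0 else 0
                nb[tuple(edge)] = True  # beyond the grid counts as outside
                wallc = liquid & chamber & nb
                if not wallc.any():
                    continue
                I, J, K = np.nonzero(wallc)
                idxs = [I, J, K]
                A_b = area[idxs[other[0]], idxs[other[1]]]
                rowc = self.cidx[I, J, K]
                # wall resistance dominates (medium half-cell neglected); the
                # pi/4 factor corrects the staircase perimeter of the voxelised
                # cylinder (8R) to the true lateral perimeter (2 pi R)
                g = A_b * k * (np.pi / 4.0)
                np.add.at(diag, rowc, g)
                b[rowc] += g * par.c_sat
                self._robin_cells.append(rowc)
                self._robin_g.append(g)

    @property
    def _flow_rate(self) -> float:
        return self._Q

    # -- sinks -----------------------------------------------------------
    def _build_sinks(self) -> None:
        dom, par = self.domain, self.params
        n = dom.coc_layout.n_cocs
        ocr = par.ocr_per_coc if par.per_coc else par.ocr_per_coc / n
        vols = dom.grid.cell_volumes()
        self.sink_rows: list[np.ndarray] = []
        self.sink_rate: list[np.ndarray] = []  # mol/s per cell at full consumption
        for i in range(n):
            cells = dom.coc_id == i
            v = vols[cells]
            rowc = self.cidx[cells]
            self.sink_rows.append(rowc)
            self.sink_rate.append(ocr * v / v.sum())
        self.sink_rows_all = np.concatenate(self.sink_rows) if n else np.zeros(0, int)
        self.sink_rate_all = np.concatenate(self.sink_rate) if n else np.zeros(0)

    # -- solve -----------------------------------------------------------
    def sink_system(self, hypoxic: np.ndarray) -> tuple[sp.spmatrix, np.ndarray]:
        """Operator and RHS with the cutoff sink linearised for a hypoxia pattern."""
        diag_add = np.zeros(self.ncell)
        rows_h = self.sink_rows_all[hypoxic]
        diag_add[rows_h] = self.sink_rate_all[hypoxic] / self.params.c_crit
        b = self.b.copy()
        full = ~hypoxic
        np.subtract.at(b, self.sink_rows_all[full], self.sink_rate_all[full])
        return sp.diags(diag_add), b

    def solve_steady(self, max_picard: int = 25) -> np.ndarray:
        """Solve with Picard iteration on the set of oxygen-starved COC cells."""
        par = self.params
        hypoxic = np.zeros(self.sink_rows_all.size, dtype=bool)
        c_vec = None
        for _ in range(max_picard):
            S, b = self.sink_system(hypoxic)
            c_vec = spla.spsolve((self.A + S).tocsc(), b)
            new_h = c_vec[self.sink_rows_all] < par.c_crit
            if np.array_equal(new_h, hypoxic):
                break
            hypoxic = new_h
        self._last_hypoxic = hypoxic
        return c_vec

    def consumption(self, c_vec: np.ndarray) -> float:
        frac = np.minimum(
            1.0, np.maximum(c_vec[self.sink_rows_all], 0.0) / self.params.c_crit
        )
        return float((self.sink_rate_all * frac).sum())

    def boundary_influx(self, c_vec: np.ndarray) -> dict:
        out = {"robin": 0.0, "dirichlet": 0.0, "advective_in": self._adv_in,
               "advective_out": 0.0, "fixed_flux": self._fixed_influx}
        for rowc, g in zip(self._robin_cells, self._robin_g):
            out["robin"] += float((g * (self.params.c_sat - c_vec[rowc])).sum())
        for rowc, g, v in zip(self._dir_cells, self._dir_g, self._dir_val):
            out["dirichlet"] += float((g * (v - c_vec[rowc])).sum())
        for rowc, F in zip(self._adv_out_cells, self._adv_out_F):
            out["advective_out"] -= float((F * c_vec[rowc]).sum())
        out["net_in"] = sum(out[k] for k in ("robin", "dirichlet", "advective_in",
                                             "advective_out", "fixed_flux"))
        return out

    def to_field(self, c_vec: np.ndarray, time: float) -> OxygenField:
        c = np.full(self.domain.grid.shape, np.nan)
        c[self.liquid] = c_vec
        fluxes = self.boundary_influx(c_vec)
        fluxes["consumption"] = self.consumption(c_vec)
        return OxygenField(concentration=c, time=time, fluxes=fluxes)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _make_transport(domain, flow, params) -> _Transport:
    if flow is not None and not flow.is_zero and domain.bc.inlet is None:
        raise ConfigurationError("flow field provided for a scenario without ports")
    if flow is None and domain.bc.inlet is not None:
        raise ConfigurationError(
            "perfused scenario requires a flow field (use zero_flow for Q=0)"
        )
    return _Transport(domain, flow, params)


def solve_oxygen_steady(
    domain: ScenarioDomain, flow: FlowField | None, params: OxygenParams
) -> OxygenField:
    """Steady advection-diffusion-reaction solution on the labelled domain."""
    tr = _make_transport(domain, flow, params)
    c_vec = tr.solve_steady()
    return tr.to_field(c_vec, time=np.inf)


def solve_oxygen_transient(
    domain: ScenarioDomain,
    flow: FlowField | None,
    params: OxygenParams,
    t_end: float,
    dt: float,
    save_every: int | None = None,
) -> list[OxygenField]:
    """Implicit-Euler transient solution from a uniform initial concentration.

    Returns the saved sequence of fields (always including the final state).
    The sink is linearised from the previous step; the operator is refactorised
    only when the set of oxygen-starved COC cells changes.
    """
    if dt <= 0 or t_end <= 0:
        raise StepSizeError("t_end and dt must be positive")
    tr = _make_transport(domain, flow, params)
    nsteps = int(np.ceil(t_end / dt))
    save_every = save_every or nsteps
    c = np.full(tr.ncell, params.c_initial)
    Mdt = sp.diags(tr.vol / dt)
    lu = None
    prev_h = None
    fields: list[OxygenField] = []
    tol = 1e-9
    for step in range(1, nsteps + 1):
        hyp = c[tr.sink_rows_all] < params.c_crit
        if lu is None or prev_h is None or not np.array_equal(hyp, prev_h):
            S, b_base = tr.sink_system(hyp)
            lu = spla.splu((tr.A + Mdt + S).tocsc())
            prev_h = hyp
        else:
            _, b_base = tr.sink_system(hyp)
        b = b_base + tr.vol / dt * c
        c = lu.solve(b)
        if c.min() < -1e-6 * params.c_sat or c.max() > params.c_sat * (1 + 1e-6) + tol:
            raise StepSizeError(
                f"transient step left the physical range at t={step * dt:g}s: "
                f"[{c.min():.3e}, {c.max():.3e}]"
            )
        if step % save_every == 0 or step == nsteps:
            fields.append(tr.to_field(c, time=step * dt))
    return fields


def volume_average(
    field: OxygenField, domain: ScenarioDomain, region: str | np.ndarray = "media+alginate"
) -> float:
    """Volume-weighted mean concentration over a material region.

    The default region is the medium (plus gel where present), excluding the
    oil overlay, solids and the COC interiors.
    """
    mask = domain.region_mask(region) if isinstance(region, str) else region
    if not mask.any():
        raise MivmError("empty averaging region")
    vols = domain.grid.cell_volumes()[mask]
    c = field.concentration[mask]
    if np.any(np.isnan(c)):
        raise MivmError("averaging region extends outside the solved liquid")
    return float((c * vols).sum() / vols.sum())


def mass_balance_residual(
    field: OxygenField, domain: ScenarioDomain, params: OxygenParams
) -> float:
    """|net boundary influx - consumption| / consumption for a steady field.

    With zero consumption the absolute net flux (mol/s) is returned instead and
    flagged in the field diagnostics.
    """
    cons = field.fluxes.get("consumption", 0.0)
    net = field.fluxes.get("net_in", 0.0)
    if cons == 0.0:
        field.diagnostics["mass_balance_flagged_absolute"] = True
        return abs(net)
    return abs(net - cons) / cons
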