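"""Radially symmetric 1D rhizosphere nutrient transport and uptake model.

The model solves, for each nutrient, the cylindrical advection–diffusion–
reaction equation around a single root with linear (instantaneous) sorption:

    (theta + b) dc/dt = (1/r) d/dr ( r De dc/dr + a Jw(t) c ) − sinks,

with ``c`` the pore-water concentration (mol cm⁻³ solution), ``De = D·theta·f``
the effective diffusion coefficient, and ``a·Jw(t)/r`` the radial pore-water
velocity of the (incompressible) water flow toward the root.  At the root
surface (r = a) nutrient influx follows Michaelis–Menten kinetics,

    De dc/dr + Jw c = Fm c / (Km + c),

and at the outer boundary (r = R_out, default 6 cm) the concentration is
pinned at its initial pore-water value (a closed, zero-total-flux variant is
available for conservation checks).  Two sink terms can act in the domain:

* irreversible CaSO₄ precipitation at rate k·M² (shared 1:1 between the Ca
  and S balances), with M the supersaturation driving concentration;
* a homogenized root-hair uptake sink, active only within one mean hair
  length of the root surface and only while the hairs are functional.

The discretization is a conservative finite-volume scheme on a geometrically
graded radial grid (first cell 5 μm at the root, growth ratio 1.05, cell
width capped away from the root), with central flux interpolation (the cell
Péclet number is ≪ 1 at the prescribed water fluxes) and method-of-lines
time integration by an implicit stiff solver (BDF) with an analytically
prescribed Jacobian sparsity pattern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .params import (NutrientSpec, ParameterError, PrecipitationSpec,
                     RootHairSpec, RootSegment, Substrate)

__all__ = [
    "effective_diffusion",
    "water_flux_at",
    "mm_uptake_flux",
    "hair_spacing",
    "hair_sink",
    "precip_driving",
    "RadialGrid",
    "Scenario",
    "StateField",
    "SimulationResult",
    "initial_state",
    "advance_state",
    "run_simulation",
    "pools_per_soil_volume",
]


# ---------------------------------------------------------------------------
# elementary operations


def effective_diffusion(D: float, theta: float, f: float) -> float:
    """Effective diffusion coefficient in soil, De = D·theta·f (cm² s⁻¹)."""
    if not (D > 0 and theta > 0 and f > 0):
        raise ParameterError("D, theta and f must all be strictly positive")
    return D * theta * f


def water_flux_at(t_hours, Jw_daily: float):
    """Diurnal water flux to the root at time-of-day ``t_hours`` (cm s⁻¹).

    Jw(t) = Jw_daily · (sin(2π t/24 − π/2) + 1): zero at midnight, twice the
    daily mean at noon, 24-h periodic with mean Jw_daily.
    """
    if Jw_daily < 0:
        raise ParameterError("Jw_daily must be non-negative")
    t = np.asarray(t_hours, dtype=float)
    out = Jw_daily * (np.sin(2.0 * np.pi * t / 24.0 - np.pi / 2.0) + 1.0)
    return out if out.ndim else float(out)


def mm_uptake_flux(c, Fm: float, Km: float):
    """Michaelis–Menten uptake flux Fm·c/(Km + c), mol cm⁻² s⁻¹."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = Fm * c / (Km + c)
    return out if out.ndim else float(out)


def hair_spacing(a_root: float, N: float, a_h: float | None = None,
                 convention: str = "root_radius") -> float:
    """Mean spacing between root hairs, cm.

    With the default convention the spacing is the square root of the root
    surface area associated with one hair, l = sqrt(2π·a_root/N).  The
    ``hair_radius`` convention substitutes the hair radius for the root
    radius.  A warning is issued when the hairs are not sparse
    (a_h / l ≥ 0.15), since the homogenized sink assumes a dilute hair
    population.
    """
    if not (a_root > 0 and N > 0):
        raise ParameterError("a_root and N must be strictly positive")
    if convention == "root_radius":
        l = math.sqrt(2.0 * math.pi * a_root / N)
    elif convention == "hair_radius":
        if a_h is None:
            raise ParameterError("hair_radius convention requires a_h")
        l = math.sqrt(2.0 * math.pi * a_h / N)
    else:
        raise ParameterError(f"unknown spacing convention {convention!r}")
    if a_h is not None and a_h / l >= 0.15:
        warnings.warn(
            f"root hairs are not sparse (a_h/l = {a_h / l:.3f} >= 0.15); "
            "the homogenized hair sink assumes a dilute hair population",
            stacklevel=2)
    return l


def hair_sink(c, r, t_seconds: float, segment: RootSegment,
              hairs: RootHairSpec, Fmh: float, Kmh: float):
    """Homogenized root-hair uptake sink Q_rh, mol cm⁻³ soil s⁻¹.

    Q_rh = (L/l)·(2π·a_h/l²)·Fmh·c/(Kmh + c) inside the hair zone
    (a ≤ r ≤ a + l_rh) while the hairs are functional (t < lifetime) and the
    segment carries hairs; zero elsewhere.
    """
    c = np.asarray(c, dtype=float)
    r = np.asarray(r, dtype=float)
    if (not segment.has_hairs) or t_seconds >= hairs.lifetime_seconds:
        out = np.zeros(np.broadcast(c, r).shape)
        return out if out.ndim else float(out)
    l = hairs.spacing(segment.a)
    pref = (hairs.L / l) * (2.0 * math.pi * hairs.a_h / l ** 2)
    zone = (r >= segment.a) & (r - segment.a < hairs.l_rh)
    cc = np.maximum(c, 0.0)
    out = np.where(zone, pref * Fmh * cc / (Kmh + cc), 0.0)
    return out if out.ndim else float(out)


def precip_driving(c_Ca, c_S, Ksp: float):
    """Supersaturation driving concentration M for gypsum, mol cm⁻³.

    M = max(min(c_Ca − √Ksp, c_S − √Ksp), 0): positive only where both the
    Ca and the S pore-water concentration exceed the saturation value √Ksp.
    """
    s = math.sqrt(Ksp)
    c_Ca = np.asarray(c_Ca, dtype=float)
    c_S = np.asarray(c_S, dtype=float)
    out = np.maximum(np.minimum(c_Ca - s, c_S - s), 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# grid


@dataclass(frozen=True)
class RadialGrid:
    """Geometrically graded radial finite-volume grid from r = a to R_out."""

    a: float
    R_out: float
    faces: np.ndarray        # cell faces, cm, faces[0] = a, faces[-1] = R_out
    centers: np.ndarray      # cell centers, cm

    @classmethod
    def make(cls, a: float, R_out: float = 6.0, first_cell: float = 5e-4,
             growth: float = 1.05, max_cell: float = 0.04) -> "RadialGrid":
        if not (0 < a < R_out):
            raise ParameterError("require 0 < a < R_out")
        faces = [a]
        w = first_cell
        while faces[-1] + w < R_out:
            faces.append(faces[-1] + w)
            w = min(w * growth, max_cell)
        # land the last face exactly on R_out; merge if the cell got too thin
        if R_out - faces[-1] < 0.3 * (faces[-1] - faces[-2]):
            faces.pop()
        faces.append(R_out)
        faces = np.asarray(faces)
        centers = 0.5 * (faces[:-1] + faces[1:])
        return cls(a=a, R_out=R_out, faces=faces, centers=centers)

    @property
    def n(self) -> int:
        return self.centers.size

    @property
    def volumes(self) -> np.ndarray:
        """Cell volumes per unit root length, per radian (∫ r dr), cm²."""
        return 0.5 * (self.faces[1:] ** 2 - self.faces[:-1] ** 2)


# ---------------------------------------------------------------------------
# scenario and state containers


@dataclass(frozen=True)
class Scenario:
    """One simulation case: substrate, root segment and uptake variant."""

    id: str
    substrate: Substrate
    segment: RootSegment
    nutrients: dict[str, NutrientSpec]
    hair: RootHairSpec | None = None          # None: no hair sink (e.g. rth3)
    precip: PrecipitationSpec | None = None   # None: no gypsum reaction
    Jw_daily: float = 0.0
    R_out: float = 6.0
    outer_bc: str = "dirichlet"               # "dirichlet" | "closed"
    variant: str = ""                         # e.g. WT-full / WT-half / rth3
    core: bool = True

    def __post_init__(self) -> None:
        if self.outer_bc not in ("dirichlet", "closed"):
            raise ParameterError(f"unknown outer BC {self.outer_bc!r}")
        if self.precip is not None and not {"Ca", "S"} <= set(self.nutrients):
            raise ParameterError("gypsum precipitation requires both Ca and S")
        if self.segment.has_hairs and self.hair is None:
            raise ParameterError("segment has hairs but no RootHairSpec given")

    def c_pw_ini(self, nutrient: str) -> float:
        return self.substrate.c_pw_ini(nutrient)


@dataclass
class StateField:
    """Instantaneous model state: per-node concentrations and pools."""

    t: float                                  # s
    c: dict[str, np.ndarray]                  # pore-water conc, mol cm-3
    precip: np.ndarray | None                 # CaSO4 pool, mol cm-3 soil
    cum_root: dict[str, float]                # mol per cm root length
    cum_hair: dict[str, float]
    cum_outer: dict[str, float]               # net influx through r = R_out


# ---------------------------------------------------------------------------
# the assembled ODE system (method of lines)


class _System:
    """Finite-volume semi-discretization of one scenario on one grid.

    State layout: the pore-water concentration blocks for each nutrient (n
    nodes each), then the precipitated pool block (if the gypsum reaction is
    on), then three cumulative bookkeeping scalars per nutrient (root uptake,
    hair uptake, outer-boundary influx; all mol per cm of root, so the mass
    balance closes exactly in the continuous limit).
    """

    def __init__(self, scenario: Scenario, grid: RadialGrid):
        self.scn = scenario
        self.grid = grid
        self.names = list(scenario.nutrients)
        self.n = grid.n
        self.has_precip = scenario.precip is not None
        sub = scenario.substrate
        self.De = {m: effective_diffusion(scenario.nutrients[m].D, sub.theta, sub.f)
                   for m in self.names}
        self.beta = {m: sub.theta + scenario.nutrients[m].b for m in self.names}
        self.c_out = {m: scenario.c_pw_ini(m) for m in self.names}
        self.a = scenario.segment.a

        fc = grid.faces
        cc = grid.centers
        self.V = grid.volumes
        self.dr_int = cc[1:] - cc[:-1]                   # center spacing
        self.rf_int = fc[1:-1]                           # interior faces
        self.dr_out = fc[-1] - cc[-1]
        # hair-zone geometry (fixed per scenario)
        self.hair_mask = None
        self.hair_pref = 0.0
        if scenario.hair is not None and scenario.segment.has_hairs:
            h = scenario.hair
            l = h.spacing(self.a)
            self.hair_pref = (h.L / l) * (2.0 * math.pi * h.a_h / l ** 2)
            self.hair_mask = (cc - self.a) < h.l_rh
        # state indexing
        self.n_blocks = len(self.names) + (1 if self.has_precip else 0)
        self.n_state = self.n_blocks * self.n + 3 * len(self.names)

    # -- state packing ------------------------------------------------------

    def pack(self, state: StateField) -> np.ndarray:
        y = np.empty(self.n_state)
        for j, m in enumerate(self.names):
            y[j * self.n:(j + 1) * self.n] = state.c[m]
        if self.has_precip:
            y[len(self.names) * self.n:self.n_blocks * self.n] = state.precip
        aux = []
        for m in self.names:
            aux += [state.cum_root[m], state.cum_hair[m], state.cum_outer[m]]
        y[self.n_blocks * self.n:] = aux
        return y

    def unpack(self, t: float, y: np.ndarray) -> StateField:
        c = {m: y[j * self.n:(j + 1) * self.n].copy()
             for j, m in enumerate(self.names)}
        precip = (y[len(self.names) * self.n:self.n_blocks * self.n].copy()
                  if self.has_precip else None)
        aux = y[self.n_blocks * self.n:]
        cum_root, cum_hair, cum_outer = {}, {}, {}
        for j, m in enumerate(self.names):
            cum_root[m], cum_hair[m], cum_outer[m] = aux[3 * j:3 * j + 3]
        return StateField(t=t, c=c, precip=precip, cum_root=cum_root,
                          cum_hair=cum_hair, cum_outer=cum_outer)

    # -- right-hand side ----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, hairs_on: bool) -> np.ndarray:
        scn = self.scn
        n = self.n
        dydt = np.zeros_like(y)
        Jw = water_flux_at(t / 3600.0, scn.Jw_daily)
        aJw = self.a * Jw

        cs = {}
        for j, m in enumerate(self.names):
            c = y[j * n:(j + 1) * n]
            cs[m] = c
            spec = scn.nutrients[m]
            De = self.De[m]
            c0 = max(c[0], 0.0)
            # r·F at every face; F = De dc/dr + (a·Jw/r)·c
            G = np.empty(n + 1)
            G[0] = self.a * spec.Fm * c0 / (spec.Km + c0)
            G[1:-1] = (self.rf_int * De * (c[1:] - c[:-1]) / self.dr_int
                       + aJw * 0.5 * (c[1:] + c[:-1]))
            if scn.outer_bc == "dirichlet":
                G[-1] = (self.grid.faces[-1] * De * (self.c_out[m] - c[-1])
                         / self.dr_out + aJw * self.c_out[m])
            else:
                G[-1] = 0.0
            dcdt = (G[1:] - G[:-1]) / (self.beta[m] * self.V)
            dydt[j * n:(j + 1) * n] = dcdt
            k = self.n_blocks * n + 3 * j
            dydt[k] = 2.0 * math.pi * G[0]                    # root uptake
            dydt[k + 2] = 2.0 * math.pi * G[-1]               # outer influx

        if self.has_precip:
            rate = scn.precip.k * precip_driving(
                cs["Ca"], cs["S"], scn.precip.Ksp) ** 2
            jp = len(self.names) * n
            dydt[jp:jp + n] = rate
            for m in ("Ca", "S"):
                j = self.names.index(m)
                dydt[j * n:(j + 1) * n] -= rate / self.beta[m]

        if hairs_on and self.hair_mask is not None:
            mask = self.hair_mask
            for j, m in enumerate(self.names):
                spec = scn.nutrients[m]
                cm = np.maximum(cs[m][mask], 0.0)
                Q = self.hair_pref * spec.Fmh * cm / (spec.Kmh + cm)
                dydt[j * n:(j + 1) * n][mask] -= Q / self.beta[m]
                k = self.n_blocks * n + 3 * j
                dydt[k + 1] = 2.0 * math.pi * np.sum(Q * self.V[mask])
        return dydt

    # -- Jacobian sparsity --------------------------------------------------

    def jac_sparsity(self) -> sparse.csr_matrix:
        n, names = self.n, self.names
        J = sparse.lil_matrix((self.n_state, self.n_state))
        for j, _ in enumerate(names):
            sl = slice(j * n, (j + 1) * n)
            block = sparse.diags_array([np.ones(n - 1), np.ones(n),
                                        np.ones(n - 1)], offsets=(-1, 0, 1))
            J[sl, sl] = block
            k = self.n_blocks * n + 3 * j
            J[k, j * n] = 1                      # root uptake <- surface conc
            J[k + 2, (j + 1) * n - 1] = 1        # outer influx <- last cell
            if self.hair_mask is not None:
                idx = np.flatnonzero(self.hair_mask)
                J[k + 1, j * n + idx] = 1
        if self.has_precip:
            iCa, iS = names.index("Ca"), names.index("S")
            jp = len(names) * n
            d = np.arange(n)
            for src in (iCa, iS):
                J[jp + d, src * n + d] = 1                       # pool <- c
                for dst in (iCa, iS):
                    J[dst * n + d, src * n + d] = 1              # cross sink
        return J.tocsr()


def initial_state(scenario: Scenario, grid: RadialGrid) -> StateField:
    """Uniform initial condition at the substrate's pore-water concentrations."""
    n = grid.n
    c = {m: np.full(n, scenario.c_pw_ini(m)) for m in scenario.nutrients}
    precip = np.zeros(n) if scenario.precip is not None else None
    zeros = {m: 0.0 for m in scenario.nutrients}
    return StateField(t=0.0, c=c, precip=precip, cum_root=dict(zeros),
                      cum_hair=dict(zeros), cum_outer=dict(zeros))


def _integrate(system: _System, state: StateField, t_end: float,
               t_eval: np.ndarray | None, rtol: float, atol: float,
               max_step: float, method: str) -> tuple[list[StateField], StateField]:
    """Integrate from ``state.t`` to ``t_end``, splitting at hair expiry."""
    scn = system.scn
    hair_end = (scn.hair.lifetime_seconds
                if (scn.hair is not None and scn.segment.has_hairs)
                else state.t)
    breaks = [state.t]
    if state.t < hair_end < t_end:
        breaks.append(hair_end)
    breaks.append(t_end)

    sparsity = system.jac_sparsity()
    saved: list[StateField] = []
    y = system.pack(state)
    t0 = state.t
    for t1 in breaks[1:]:
        if t1 <= t0:
            continue
        hairs_on = t0 < hair_end
        wanted = (t_eval[(t_eval > t0) & (t_eval <= t1)]
                  if t_eval is not None else np.empty(0))
        eval_pts = np.unique(np.append(wanted, t1))
        sol = solve_ivp(
            lambda t, yy: system.rhs(t, yy, hairs_on),
            (t0, t1), y, method=method, rtol=rtol, atol=atol,
            max_step=max_step, t_eval=eval_pts, jac_sparsity=sparsity)
        if not sol.success:
            raise RuntimeError(
                f"stiff integrator failed on scenario {scn.id!r} at "
                f"t in ({t0:.0f}, {t1:.0f}) s: {sol.message}")
        for i, ts in enumerate(sol.t):
            if np.any(np.isclose(ts, wanted)):
                saved.append(system.unpack(ts, sol.y[:, i]))
        y = sol.y[:, -1]
        t0 = t1
    final = system.unpack(t0, y)
    return saved, final


def advance_state(state: StateField, scenario: Scenario, dt: float, *,
                  grid: RadialGrid | None = None, rtol: float = 1e-8,
                  atol: float = 1e-14, max_step: float = 3600.0,
                  method: str = "BDF") -> StateField:
    """Advance a model state by ``dt`` seconds and return the new state."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if grid is None:
        grid = RadialGrid.make(scenario.segment.a, scenario.R_out)
    system = _System(scenario, grid)
    _, final = _integrate(system, state, state.t + dt, None, rtol, atol,
                          max_step, method)
    _check_nonnegative(final, scenario)
    return final


def _check_nonnegative(state: StateField, scenario: Scenario,
                       tol: float = 1e-10) -> None:
    for m, c in state.c.items():
        if c.min() < -tol:
            raise RuntimeError(
                f"negative concentration {c.min():.3e} for {m} in scenario "
                f"{scenario.id!r}; tighten solver tolerances")
        np.clip(c, 0.0, None, out=c)


# ---------------------------------------------------------------------------
# results


@dataclass
class SimulationResult:
    """Profile time series, pools and uptake diagnostics for one scenario."""

    scenario: Scenario
    grid: RadialGrid
    times: np.ndarray                          # s, saved states
    conc: dict[str, np.ndarray]                # (T, n) pore-water conc
    precip: np.ndarray | None                  # (T, n) CaSO4 pool
    cum_root: dict[str, np.ndarray]            # (T,), mol per cm root
    cum_hair: dict[str, np.ndarray]
    cum_outer: dict[str, np.ndarray]

    MAPPED_QUANTITY = {"Ca": "sorbed+precipitated", "S": "sorbed+precipitated",
                       "P": "sorbed"}

    def cumulative_uptake(self, nutrient: str, when: int = -1) -> float:
        """Total root + hair uptake, mol per cm root length."""
        return float(self.cum_root[nutrient][when]
                     + self.cum_hair[nutrient][when])

    def profile(self, nutrient: str, quantity: str = "mapped",
                when: int = -1) -> np.ndarray:
        """A radial profile per soil volume (mol cm⁻³ soil) at a saved time.

        Quantities: ``pore_water`` (per solution volume), ``dissolved``
        (theta·c), ``sorbed`` (b·c), ``precipitated``, ``total``
        (dissolved + sorbed + precipitated) and ``mapped`` — the quantity an
        element map images: sorbed + precipitated for Ca and S, sorbed for P.
        """
        scn = self.scenario
        c = self.conc[nutrient][when]
        theta = scn.substrate.theta
        b = scn.nutrients[nutrient].b
        p = (self.precip[when] if (self.precip is not None
                                   and nutrient in ("Ca", "S"))
             else np.zeros_like(c))
        if quantity == "pore_water":
            return c.copy()
        if quantity == "dissolved":
            return theta * c
        if quantity == "sorbed":
            return b * c
        if quantity == "precipitated":
            return p.copy()
        if quantity == "total":
            return (theta + b) * c + p
        if quantity == "mapped":
            base = b * c
            if self.MAPPED_QUANTITY.get(nutrient) == "sorbed+precipitated":
                base = base + p
            return base
        raise ValueError(f"unknown quantity {quantity!r}")

    def bulk_reference(self, nutrient: str, quantity: str = "mapped") -> float:
        """The bulk (initial / outer-boundary) value of ``quantity``."""
        scn = self.scenario
        c0 = scn.c_pw_ini(nutrient)
        theta = scn.substrate.theta
        b = scn.nutrients[nutrient].b
        return {"pore_water": c0, "dissolved": theta * c0, "sorbed": b * c0,
                "precipitated": 0.0, "total": (theta + b) * c0,
                "mapped": b * c0}[quantity]

    def total_mass(self, nutrient: str, when: int = -1) -> float:
        """Nutrient mass in the domain, mol per cm root length (all pools)."""
        scn = self.scenario
        beta = scn.substrate.theta + scn.nutrients[nutrient].b
        V = self.grid.volumes
        mass = 2.0 * math.pi * float(np.sum(beta * self.conc[nutrient][when] * V))
        if self.precip is not None and nutrient in ("Ca", "S"):
            mass += 2.0 * math.pi * float(np.sum(self.precip[when] * V))
        return mass

    def mass_balance_residual(self, nutrient: str) -> float:
        """Relative closure error of domain mass + uptake − boundary influx."""
        m0 = self.total_mass(nutrient, 0)
        worst = 0.0
        for i in range(len(self.times)):
            m = (self.total_mass(nutrient, i)
                 + self.cum_root[nutrient][i] + self.cum_hair[nutrient][i]
                 - self.cum_outer[nutrient][i])
            worst = max(worst, abs(m - m0) / m0)
        return worst


def run_simulation(scenario: Scenario, *, grid: RadialGrid | None = None,
                   rtol: float = 1e-8, atol: float = 1e-14,
                   max_step: float = 3600.0, method: str = "BDF",
                   save_every_days: float = 1.0) -> SimulationResult:
    """Run one scenario from its uniform initial state to t = T_sim.

    States are saved every ``save_every_days`` days plus the final time; the
    final time is 24·T_sim hours after the midnight at which the simulation
    starts, so the diurnal water-flux cycle completes a whole number of
    periods.
    """
    if grid is None:
        grid = RadialGrid.make(scenario.segment.a, scenario.R_out)
    system = _System(scenario, grid)
    state = initial_state(scenario, grid)
    T = scenario.segment.T_sim_seconds
    t_eval = np.arange(0.0, T, save_every_days * 86400.0)
    t_eval = np.unique(np.append(t_eval, T))
    saved, final = _integrate(system, state, T, t_eval, rtol, atol,
                              max_step, method)
    _check_nonnegative(final, scenario)
    states = [state] + saved
    if not states or states[-1].t < final.t:
        states.append(final)

    times = np.array([s.t for s in states])
    conc = {m: np.stack([s.c[m] for s in states]) for m in scenario.nutrients}
    precip = (np.stack([s.precip for s in states])
              if scenario.precip is not None else None)

    def series(attr, m):
        return np.array([getattr(s, attr)[m] for s in states])

    return SimulationResult(
        scenario=scenario, grid=grid, times=times, conc=conc, precip=precip,
        cum_root={m: series("cum_root", m) for m in scenario.nutrients},
        cum_hair={m: series("cum_hair", m) for m in scenario.nutrients},
        cum_outer={m: series("cum_outer", m) for m in scenario.nutrients},
    )


def pools_per_soil_volume(result: SimulationResult, when: int = -1):
    """Tidy per-node pool table (mol cm⁻³ soil) at a saved time."""
    import pandas as pd

    rows = []
    for m in result.scenario.nutrients:
        rows.append(pd.DataFrame({
            "scenario": result.scenario.id,
            "nutrient": m,
            "time_s": result.times[when],
            "r_cm": result.grid.centers,
            "c_pw": result.profile(m, "pore_water", when),
            "dissolved": result.profile(m, "dissolved", when),
            "sorbed": result.profile(m, "sorbed", when),
            "precipitated": result.profile(m, "precipitated", when),
            "mapped": result.profile(m, "mapped", when),
        }))
    return pd.concat(rows, ignore_index=True)
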