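"""Model parameterization: typed parameter containers and derivations.

All quantities are stored in the internal cm / s / mol system.  The packaged
default parameter set (``data/parameters.yaml``) holds the measured substrate
properties and the literature transport/uptake constants for a maize
rhizosphere; every entry carries a unit string that is validated and
converted on load.

Besides the containers this module implements the standard derivations used
to set up the model:

* initial pore-water concentration from a total (dissolved + sorbed) pool,
  ``c_pw = c_tot / (theta + b)``;
* the mean water flux at the root surface from whole-plant root water uptake,
  root length and mean root radius;
* buffer-power scaling with clay content between substrates;
* the half-mean distance between neighbouring roots from root length density,
  ``r_half = (pi * RLD)^(-1/2)`` (Gardner / Newman root-spacing statistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal

import pandas as pd
import yaml

from .units import to_internal

__all__ = [
    "NutrientSpec",
    "Substrate",
    "RootSegment",
    "RootHairSpec",
    "PrecipitationSpec",
    "ParameterSet",
    "load_parameters",
    "pore_water_init",
    "jw_from_rwu",
    "buffer_from_clay",
    "half_mean_root_distance",
    "derivation_report",
]

NUTRIENTS = ("Ca", "S", "P")


class ParameterError(ValueError):
    """Invalid or inconsistent model parameter."""


def _positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ParameterError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class NutrientSpec:
    """Transport and uptake constants for one nutrient in one substrate.

    Units: D cm² s⁻¹; b dimensionless; Fm, Fmh mol cm⁻² s⁻¹; Km, Kmh mol cm⁻³.
    Root hairs are assumed to share the root's uptake kinetics (Kmh = Km,
    Fmh = Fm) unless a reduced hair capacity is modelled (Fmh = Fm/2).
    """

    name: str
    D: float
    b: float
    Fm: float
    Km: float
    Fmh: float
    Kmh: float

    def __post_init__(self) -> None:
        if self.name not in NUTRIENTS:
            raise ParameterError(f"unknown nutrient {self.name!r}")
        _positive(D=self.D, b=self.b, Km=self.Km, Kmh=self.Kmh)
        # zero uptake is a valid degenerate limit (fixed-point/conservation runs)
        if self.Fm < 0 or self.Fmh < 0:
            raise ParameterError("uptake rates must be non-negative")

    def with_hair_rate_factor(self, factor: float) -> "NutrientSpec":
        """Return a copy with Fmh = factor * Fm (e.g. 0.5 for half-rate hairs)."""
        if factor < 0:
            raise ParameterError("factor must be non-negative")
        return replace(self, Fmh=factor * self.Fm)


@dataclass(frozen=True)
class Substrate:
    """A growth substrate: water content, impedance, pools and buffer powers."""

    name: str
    theta: float                      # volumetric water content, cm3 cm-3
    f: float                          # diffusion impedance factor, -
    c_tot_ini: dict[str, float]       # total initial pools, mol cm-3 soil
    b: dict[str, float]               # buffer powers per nutrient, -
    Jw_daily: float                   # daily-mean water flux to the root, cm s-1
    l_rh: float                       # mean root hair length, cm
    N_hairs: float                    # hairs per unit root length, cm-1
    a_primary: float                  # primary root radius, cm
    a_tip: float                      # root tip radius, cm
    RL_tot: float = 0.0               # total root length, cm (day 21)
    RWU21: float = 0.0                # root water uptake day 20->21, cm3 s-1

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ParameterError(f"theta must be in (0, 1), got {self.theta}")
        _positive(f=self.f, l_rh=self.l_rh, N_hairs=self.N_hairs,
                  a_primary=self.a_primary, a_tip=self.a_tip)
        for n in NUTRIENTS:
            _positive(**{f"c_tot_ini[{n}]": self.c_tot_ini[n],
                         f"b[{n}]": self.b[n]})
        if self.Jw_daily < 0:
            raise ParameterError("Jw_daily must be non-negative")

    def c_pw_ini(self, nutrient: str) -> float:
        """Initial pore-water concentration of ``nutrient``, mol cm⁻³ solution."""
        return pore_water_init(self.c_tot_ini[nutrient], self.theta,
                               self.b[nutrient])


@dataclass(frozen=True)
class RootSegment:
    """One simulated root segment: radius, duration, hair status."""

    a: float                          # root radius, cm
    T_sim: float                      # simulated duration, d
    has_hairs: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        _positive(a=self.a, T_sim=self.T_sim)

    @property
    def T_sim_seconds(self) -> float:
        return self.T_sim * 86400.0


@dataclass(frozen=True)
class RootHairSpec:
    """Geometry of the homogenized root-hair population.

    ``l`` (the inter-hair spacing) is derived from the root radius and the
    hair density as the side of the square of root surface area associated
    with one hair: l = sqrt(2·pi·a_root / N).  An alternative convention
    using the hair radius instead of the root radius is selectable.
    """

    a_h: float                        # hair radius, cm
    N: float                          # hairs per unit root length, cm-1
    l_rh: float                       # mean hair length, cm
    lifetime: float                   # functional lifetime, d
    L: float                          # characteristic root length, cm
    spacing_convention: Literal["root_radius", "hair_radius"] = "root_radius"

    def __post_init__(self) -> None:
        _positive(a_h=self.a_h, N=self.N, l_rh=self.l_rh,
                  lifetime=self.lifetime, L=self.L)

    @property
    def lifetime_seconds(self) -> float:
        return self.lifetime * 86400.0

    def spacing(self, a_root: float) -> float:
        from .model import hair_spacing  # avoid circular import at module load
        return hair_spacing(a_root, self.N, a_h=self.a_h,
                            convention=self.spacing_convention)


@dataclass(frozen=True)
class PrecipitationSpec:
    """Second-order gypsum (CaSO₄) precipitation kinetics.

    Precipitation proceeds at rate k·M² where M is the supersaturation
    driving concentration; it is irreversible and occurs only where both the
    Ca and S pore-water concentrations exceed sqrt(Ksp).
    """

    k: float                          # cm3 mol-1 s-1
    Ksp: float                        # mol2 cm-6

    def __post_init__(self) -> None:
        _positive(k=self.k, Ksp=self.Ksp)

    @property
    def sqrt_Ksp(self) -> float:
        """Saturation concentration, mol cm⁻³ solution."""
        return math.sqrt(self.Ksp)


@dataclass(frozen=True)
class ParameterSet:
    """The full packaged parameter set for both substrates and all nutrients."""

    substrates: dict[str, Substrate]
    D: dict[str, float]
    Fm: dict[str, float]
    Km: dict[str, float]
    precip: PrecipitationSpec
    hair: RootHairSpec
    R_out: float
    extent_threshold: float           # mol cm-3 soil
    column_diameter: float
    column_height: float

    def nutrient(self, name: str, substrate: str,
                 hair_rate_factor: float = 1.0) -> NutrientSpec:
        sub = self.substrates[substrate]
        spec = NutrientSpec(
            name=name, D=self.D[name], b=sub.b[name],
            Fm=self.Fm[name], Km=self.Km[name],
            Fmh=self.Fm[name], Kmh=self.Km[name],
        )
        if hair_rate_factor != 1.0:
            spec = spec.with_hair_rate_factor(hair_rate_factor)
        return spec

    @property
    def column_volume(self) -> float:
        return math.pi * (self.column_diameter / 2.0) ** 2 * self.column_height


def _q(node: dict) -> float:
    """Read a {value, unit} leaf and convert to the internal unit system."""
    return to_internal(float(node["value"]), str(node["unit"]))


def load_parameters(path: str | None = None) -> ParameterSet:
    """Load a parameter file (default: the packaged maize set)."""
    if path is None:
        text = (resources.files("rhizoextent") / "data" / "parameters.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    substrates: dict[str, Substrate] = {}
    for name, m in raw["measured"].items():
        substrates[name] = Substrate(
            name=name,
            theta=_q(m["theta"]),
            f=_q(raw["model"]["f_impedance"]),
            c_tot_ini={n: _q(m["c_tot_ini"][n]) for n in NUTRIENTS},
            b={n: float(raw["literature"]["b"][name][n]) for n in NUTRIENTS},
            Jw_daily=_q(m["Jw_daily"]),
            l_rh=_q(m["l_rh"]),
            N_hairs=_q(m["N_hairs"]),
            a_primary=_q(m["a_primary"]),
            a_tip=_q(m["a_tip"]),
            RL_tot=_q(m["RL_tot"]),
            RWU21=_q(m["RWU21"]),
        )

    lit = raw["literature"]
    return ParameterSet(
        substrates=substrates,
        D={n: _q(lit["D"][n]) for n in NUTRIENTS},
        Fm={n: _q(lit["Fm"][n]) for n in NUTRIENTS},
        Km={n: _q(lit["Km"][n]) for n in NUTRIENTS},
        precip=PrecipitationSpec(k=_q(lit["k_reaction"]),
                                 Ksp=_q(lit["Ksp_CaSO4"])),
        hair=RootHairSpec(a_h=_q(lit["a_h"]), N=_q(raw["measured"]["loam"]["N_hairs"]),
                          l_rh=_q(raw["measured"]["loam"]["l_rh"]),
                          lifetime=float(lit["rh_lifetime"]["value"]),
                          L=_q(lit["L_char"]),
                          spacing_convention="hair_radius"),
        R_out=_q(raw["model"]["R_out"]),
        extent_threshold=_q(raw["model"]["extent_threshold"]),
        column_diameter=_q(raw["column"]["inner_diameter"]),
        column_height=_q(raw["column"]["fill_height"]),
    )


# ---------------------------------------------------------------------------
# derivations


def pore_water_init(c_tot_ini: float, theta: float, b: float) -> float:
    """Initial pore-water (dissolved) concentration from the total pool.

    c_pw = c_tot / (theta + b), mol cm⁻³ solution.  The total pool is the sum
    of dissolved (theta·c_pw) and linearly sorbed (b·c_pw) nutrient per soil
    volume.
    """
    _positive(c_tot_ini=c_tot_ini, theta=theta)
    if b < 0:
        raise ParameterError("buffer power must be non-negative")
    denom = theta + b
    if denom <= 0:
        raise ParameterError("theta + b must be positive")
    return c_tot_ini / denom


def jw_from_rwu(RWU21: float, RL21: float, a_mean: float) -> float:
    """Mean water flux at the root surface, cm s⁻¹.

    Distributes the whole-plant root water uptake RWU21 (cm³ s⁻¹) evenly over
    the root surface area RL21 · 2·pi·a_mean.  The mean root radius is an
    explicit input: it is a measured quantity of the root system, not a
    packaged constant.
    """
    _positive(RWU21=RWU21, a_mean=a_mean)
    if RL21 <= 0:
        raise ParameterError("root length must be positive")
    return RWU21 / (RL21 * 2.0 * math.pi * a_mean)


def buffer_from_clay(b_reference: float, clay_ratio: float) -> float:
    """Scale a buffer power to another substrate in proportion to clay content."""
    _positive(b_reference=b_reference, clay_ratio=clay_ratio)
    return b_reference * clay_ratio


def half_mean_root_distance(RL_total: float, column_volume: float) -> float:
    """Half the mean distance between neighbouring roots, cm.

    r_half = (pi · RLD)^(-1/2) with root length density RLD = RL / V.
    """
    _positive(RL_total=RL_total, column_volume=column_volume)
    rld = RL_total / column_volume
    return 1.0 / math.sqrt(math.pi * rld)


def derivation_report(params: ParameterSet) -> pd.DataFrame:
    """Tabulate the standard parameter derivations for both substrates."""
    rows = []
    for name, sub in params.substrates.items():
        for n in NUTRIENTS:
            rows.append(dict(
                substrate=name, quantity=f"c_pw_ini[{n}]",
                formula="c_tot_ini / (theta + b)",
                inputs=f"c_tot={sub.c_tot_ini[n]:.3e}, theta={sub.theta}, b={sub.b[n]}",
                value=sub.c_pw_ini(n), unit="mol cm-3"))
        rows.append(dict(
            substrate=name, quantity="r_half",
            formula="(pi * RL/V)^(-1/2)",
            inputs=f"RL={sub.RL_tot:.0f} cm, V={params.column_volume:.1f} cm3",
            value=half_mean_root_distance(sub.RL_tot, params.column_volume),
            unit="cm"))
    rows.append(dict(
        substrate="-", quantity="sqrt_Ksp",
        formula="sqrt(Ksp)", inputs=f"Ksp={params.precip.Ksp:.2e} mol2 cm-6",
        value=params.precip.sqrt_Ksp, unit="mol cm-3"))
    return pd.DataFrame(rows)
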