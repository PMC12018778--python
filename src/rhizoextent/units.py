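"""Exact unit conversions for the cm / s / mol internal unit system.

The transport model mixes literature values printed in litre-based units
(reaction rate constants in l mol⁻¹ min⁻¹, solubility products in mol² l⁻²)
with the centimetre-based units the equations are solved in.  Conversions are
table-driven and exact (rational factors), so round trips are identities up
to floating point.
"""

from __future__ import annotations

__all__ = ["convert_units", "UnitError", "canonical_unit"]


class UnitError(ValueError):
    """Raised for unknown units or a conversion between incompatible units."""


# unit string -> (dimension, factor to the canonical unit of that dimension)
_UNITS: dict[str, tuple[str, float]] = {
    # time
    "s": ("time", 1.0),
    "min": ("time", 60.0),
    "h": ("time", 3600.0),
    "d": ("time", 86400.0),
    # length
    "cm": ("length", 1.0),
    "mm": ("length", 0.1),
    "um": ("length", 1e-4),
    # amount
    "mol": ("amount", 1.0),
    "mmol": ("amount", 1e-3),
    "umol": ("amount", 1e-6),
    # concentration (per solution or soil volume)
    "mol cm-3": ("conc", 1.0),
    "mmol cm-3": ("conc", 1e-3),
    "umol cm-3": ("conc", 1e-6),
    "mol l-1": ("conc", 1e-3),
    "mmol l-1": ("conc", 1e-6),
    # second-order rate constant (volume per amount per time)
    "cm3 mol-1 s-1": ("rate2", 1.0),
    "l mol-1 min-1": ("rate2", 1000.0 / 60.0),
    "l mol-1 s-1": ("rate2", 1000.0),
    # solubility product
    "mol2 cm-6": ("ksp", 1.0),
    "mol2 l-2": ("ksp", 1e-6),
    # volumetric flow
    "cm3 s-1": ("volflow", 1.0),
    "cm3 d-1": ("volflow", 1.0 / 86400.0),
    # pass-through units used in the parameter files (no alternatives needed)
    "cm2 s-1": ("diffusivity", 1.0),
    "mol cm-2 s-1": ("areal_rate", 1.0),
    "cm s-1": ("velocity", 1.0),
    "cm-1": ("per_length", 1.0),
    "cm3 cm-3": ("fraction", 1.0),
    "-": ("dimensionless", 1.0),
}

_CANONICAL = {
    "time": "s",
    "length": "cm",
    "amount": "mol",
    "conc": "mol cm-3",
    "rate2": "cm3 mol-1 s-1",
    "ksp": "mol2 cm-6",
    "volflow": "cm3 s-1",
    "diffusivity": "cm2 s-1",
    "areal_rate": "mol cm-2 s-1",
    "velocity": "cm s-1",
    "per_length": "cm-1",
    "fraction": "cm3 cm-3",
    "dimensionless": "-",
}


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two supported units of the same dimension."""
    try:
        dim_from, f_from = _UNITS[from_unit]
    except KeyError:
        raise UnitError(f"unknown unit {from_unit!r}") from None
    try:
        dim_to, f_to = _UNITS[to_unit]
    except KeyError:
        raise UnitError(f"unknown unit {to_unit!r}") from None
    if dim_from != dim_to:
        raise UnitError(
            f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
        )
    return value * (f_from / f_to)


def canonical_unit(unit: str) -> str:
    """Return the internal (cm/s/mol) unit that ``unit`` converts to."""
    try:
        dim, _ = _UNITS[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None
    return _CANONICAL[dim]


def to_internal(value: float, unit: str) -> float:
    """Convert ``value`` from ``unit`` into the internal canonical unit."""
    return convert_units(value, unit, canonical_unit(unit))
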