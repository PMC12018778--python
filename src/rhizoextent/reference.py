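"""Independent explicit finite-difference reference solver.

A deliberately simple cross-check for the production finite-volume/BDF
solver: a node-centred finite-difference discretization of the radial
transport equation on a uniform fine grid, marched with forward (explicit)
Euler steps.  It shares no discretization code with :mod:`rhizoextent.model`
— fluxes are expanded in non-conservative form, the root boundary condition
is imposed through a ghost node, and time stepping is explicit — so
agreement between the two is meaningful evidence of correctness.

Single-nutrient problems only (optionally with the homogenized hair sink);
the gypsum-coupled pair is outside its scope.
"""

from __future__ import annotations

import math

import numpy as np

from .model import Scenario, water_flux_at
from .params import ParameterError

__all__ = ["explicit_reference_profile"]


def explicit_reference_profile(scenario: Scenario, nutrient: str,
                               t_end: float, dr: float = 1e-3,
                               dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """March one nutrient to ``t_end`` seconds; return (radii, pore-water conc).

    ``dr`` is the uniform node spacing (cm) and ``dt`` the Euler step (s);
    ``dt`` must respect the diffusive stability limit beta·dr²/(2·De).
    """
    if scenario.precip is not None:
        raise ParameterError("reference solver does not support the "
                             "gypsum-coupled pair")
    spec = scenario.nutrients[nutrient]
    sub = scenario.substrate
    a = scenario.segment.a
    De = spec.D * sub.theta * sub.f
    beta = sub.theta + spec.b

    limit = beta * dr * dr / (2.0 * De)
    if dt > limit:
        raise ParameterError(f"dt={dt} exceeds stability limit {limit:.3f} s")

    n = int(round((scenario.R_out - a) / dr))
    r = a + dr * np.arange(n + 1)
    c = np.full(n + 1, scenario.c_pw_ini(nutrient))
    c_out = c[-1]

    hairs = scenario.hair if scenario.segment.has_hairs else None
    if hairs is not None:
        l = hairs.spacing(a)
        pref = (hairs.L / l) * (2.0 * math.pi * hairs.a_h / l ** 2)
        hair_zone = (r - a) < hairs.l_rh
        hair_end = hairs.lifetime_seconds

    n_steps = int(round(t_end / dt))
    inv_2dr = 1.0 / (2.0 * dr)
    inv_dr2 = 1.0 / (dr * dr)
    for step in range(n_steps):
        t = step * dt
        Jw = water_flux_at(t / 3600.0, scenario.Jw_daily)
        aJw = a * Jw
        # ghost node below the surface encodes De dc/dr + Jw c = Fm c/(Km+c)
        c0 = max(c[0], 0.0)
        grad = (spec.Fm * c0 / (spec.Km + c0) - Jw * c0) / De
        ghost = c[1] - 2.0 * dr * grad
        cm1 = np.concatenate(([ghost], c[:-1]))
        cp1 = np.concatenate((c[1:], [c_out]))
        lap = (cp1 - 2.0 * c + cm1) * inv_dr2
        dcdr = (cp1 - cm1) * inv_2dr
        dcdt = (De * (lap + dcdr / r) + aJw * dcdr / r) / beta
        if hairs is not None and t < hair_end:
            cc = np.maximum(c, 0.0)
            Q = np.where(hair_zone,
                         pref * spec.Fmh * cc / (spec.Kmh + cc), 0.0)
            dcdt = dcdt - Q / beta
        c = c + dt * dcdt
        c[-1] = c_out
    return r, c
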