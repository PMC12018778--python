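import numpy as np
import pytest
from dataclasses import replace

from rhizoextent.model import (RadialGrid, Scenario, advance_state,
                               initial_state, mm_uptake_flux,
                               pools_per_soil_volume, run_simulation)
from rhizoextent.reference import explicit_reference_profile
from rhizoextent.scenarios import build_matrix, run_scenario


def _short(scenario, days, **changes):
    seg = replace(scenario.segment, T_sim=days)
    return replace(scenario, segment=seg, **changes)


@pytest.fixture(scope="module")
def loam_tip_wt(params):
    return next(s for s in build_matrix(params) if s.id == "loam-tip-WT-full")


@pytest.fixture(scope="module")
def loam_tip_rth3(params):
    return next(s for s in build_matrix(params) if s.id == "loam-tip-rth3")


class TestGrid:
    def test_geometry_contract(self):
        g = RadialGrid.make(0.05, 6.0)
        assert g.faces[0] == 0.05 and g.faces[-1] == 6.0
        assert np.all(np.diff(g.faces) > 0)
        assert g.faces[1] - g.faces[0] <= 5e-4 + 1e-12
        # cell volumes tile the annulus exactly
        assert g.volumes.sum() == pytest.approx((6.0 ** 2 - 0.05 ** 2) / 2)

    def test_refined_near_root(self):
        g = RadialGrid.make(0.0095, 6.0)
        widths = np.diff(g.faces)
        assert widths[0] < widths[-1]
        assert np.all(np.diff(widths)[:-1] > -1e-15)


class TestDegenerateLimits:
    def test_zero_driving_is_a_fixed_point(self, params, loam_tip_rth3):
        dead = {m: replace(spec, Fm=0.0, Fmh=0.0)
                for m, spec in loam_tip_rth3.nutrients.items()}
        scn = _short(loam_tip_rth3, 1.0, nutrients=dead, precip=None,
                     Jw_daily=0.0)
        res = run_simulation(scn)
        for m in scn.nutrients:
            c0 = scn.c_pw_ini(m)
            assert res.conc[m][-1] == pytest.approx(c0, rel=1e-9)
            assert res.cumulative_uptake(m) == 0.0

    def test_zero_buffer_gives_no_sorbed_pool(self, params, loam_tip_rth3):
        scn = _short(loam_tip_rth3, 0.5)
        res = run_scenario(scn)
        table = pools_per_soil_volume(res)
        np.testing.assert_allclose(
            table.sorbed,
            table.c_pw * [scn.nutrients[m].b for m in table.nutrient], rtol=1e-12)
        # dissolved/sorbed ratio equals theta/b in a uniform initial state
        t0 = pools_per_soil_volume(res, when=0)
        ca = t0[t0.nutrient == "Ca"]
        assert np.allclose(ca.dissolved / ca.sorbed,
                           scn.substrate.theta / scn.nutrients["Ca"].b)


class TestConservation:
    def test_closed_domain_with_all_sinks(self, loam_tip_wt):
        scn = _short(loam_tip_wt, 2.0, outer_bc="closed")
        res = run_scenario(scn)
        for m in scn.nutrients:
            assert res.mass_balance_residual(m) < 1e-3

    def test_closed_domain_without_sinks_conserves_mass(self, loam_tip_rth3):
        dead = {m: replace(spec, Fm=0.0, Fmh=0.0)
                for m, spec in loam_tip_rth3.nutrients.items()}
        scn = _short(loam_tip_rth3, 1.0, nutrients=dead, precip=None,
                     outer_bc="closed")
        res = run_simulation(scn)
        for m in scn.nutrients:
            m0 = res.total_mass(m, 0)
            assert res.total_mass(m, -1) == pytest.approx(m0, rel=1e-3)

    def test_open_domain_residual_closes_with_boundary_influx(
            self, core_matrix_results):
        for res in core_matrix_results:
            for m in res.scenario.nutrients:
                assert res.mass_balance_residual(m) < 1e-3


class TestOracleEquivalence:
    def test_implicit_matches_explicit_euler_one_day(self, loam_tip_wt):
        """Production FV/BDF solver vs an independent FD/explicit-Euler
        scheme on a one-day single-nutrient case with hairs and advection."""
        scn = _short(loam_tip_wt, 1.0,
                     nutrients={"Ca": loam_tip_wt.nutrients["Ca"]},
                     precip=None)
        res = run_simulation(scn)
        r_o, c_o = explicit_reference_profile(scn, "Ca", 86400.0,
                                              dr=1e-3, dt=2.0)
        c_i = np.interp(r_o, res.grid.centers, res.conc["Ca"][-1])
        linf = np.max(np.abs(c_i - c_o)) / np.max(np.abs(c_o))
        assert linf < 0.01


class TestMonotonicityAndBounds:
    def test_cumulative_uptake_nondecreasing(self, core_matrix_results):
        for res in core_matrix_results[:3]:
            for m in res.scenario.nutrients:
                total = res.cum_root[m] + res.cum_hair[m]
                assert np.all(np.diff(total) >= -1e-18)

    def test_precipitated_pool_nondecreasing(self, core_matrix_results):
        res = core_matrix_results[0]
        assert np.all(np.diff(res.precip.sum(axis=1)) >= -1e-18)

    def test_uptake_flux_saturation_bound(self, core_matrix_results):
        for res in core_matrix_results[:3]:
            for m, spec in res.scenario.nutrients.items():
                surf = res.conc[m][:, 0]
                flux = mm_uptake_flux(np.clip(surf, 0, None), spec.Fm, spec.Km)
                assert np.all(flux <= spec.Fm * (1 + 1e-12))

    def test_cumulative_uptake_upper_bound(self, core_matrix_results):
        for res in core_matrix_results:
            scn = res.scenario
            T = scn.segment.T_sim_seconds
            for m, spec in scn.nutrients.items():
                root_cap = spec.Fm * 2 * np.pi * scn.segment.a * T
                assert res.cum_root[m][-1] <= root_cap * (1 + 1e-9)

    def test_hairs_increase_cumulative_uptake(self, params):
        wt = next(s for s in build_matrix(params) if s.id == "loam-tip-WT-full")
        rt = next(s for s in build_matrix(params) if s.id == "loam-tip-rth3")
        res_wt = run_scenario(_short(wt, 2.0))
        res_rt = run_scenario(_short(rt, 2.0))
        for m in ("Ca", "S", "P"):
            assert (res_wt.cumulative_uptake(m)
                    > res_rt.cumulative_uptake(m) * (1 - 1e-9))

    def test_concentrations_stay_nonnegative(self, core_matrix_results):
        for res in core_matrix_results:
            for m in res.scenario.nutrients:
                assert res.conc[m].min() >= -1e-10


class TestAdvanceState:
    def test_two_half_steps_match_one_full_step(self, loam_tip_rth3):
        scn = _short(loam_tip_rth3, 1.0)
        grid = RadialGrid.make(scn.segment.a, scn.R_out)
        s0 = initial_state(scn, grid)
        mid = advance_state(s0, scn, 43200.0, grid=grid)
        end = advance_state(mid, scn, 43200.0, grid=grid)
        assert mid.t == pytest.approx(43200.0)
        ref = run_simulation(scn, grid=grid)
        for m in scn.nutrients:
            np.testing.assert_allclose(end.c[m], ref.conc[m][-1], rtol=1e-5,
                                       atol=1e-16)

    def test_rejects_nonpositive_step(self, loam_tip_rth3):
        grid = RadialGrid.make(0.0095, 6.0)
        s0 = initial_state(loam_tip_rth3, grid)
        with pytest.raises(Exception):
            advance_state(s0, loam_tip_rth3, 0.0, grid=grid)


class TestScenarioQualitativeBehaviour:
    """Directional checks on the packaged matrix: accumulation of Ca/S at
    thick roots, no accumulation at hairy loam tips, P depletion always."""

    def test_ca_accumulates_at_loam_primary(self, core_matrix_results):
        res = next(r for r in core_matrix_results
                   if r.scenario.id == "loam-primary-WT-full")
        prof = res.profile("Ca", "mapped")
        assert prof[0] > res.bulk_reference("Ca", "mapped")

    def test_no_surface_accumulation_at_hairy_loam_tip(self,
                                                       core_matrix_results):
        res = next(r for r in core_matrix_results
                   if r.scenario.id == "loam-tip-WT-full")
        r = res.grid.centers
        for m in ("Ca", "S"):
            prof = res.profile(m, "mapped")
            far = prof[np.argmin(np.abs(r - 3.0))]
            assert prof[0] < far

    def test_p_depleted_at_surface_everywhere(self, core_matrix_results):
        for res in core_matrix_results:
            prof = res.profile("P", "sorbed")
            far = prof[np.argmin(np.abs(res.grid.centers - 3.0))]
            assert prof[0] < far

    def test_sorbed_exceeds_dissolved_in_bulk(self, core_matrix_results):
        res = core_matrix_results[0]
        table = pools_per_soil_volume(res)
        bulk = table[np.isclose(table.r_cm, table.r_cm.max())]
        assert np.all(bulk.sorbed > bulk.dissolved)
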