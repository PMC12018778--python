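import numpy as np
import pandas as pd
import pytest

from rhizoextent.synthmaps import MapRecipe, generate_map, generate_profile_fixture
from rhizoextent.xrf import (bulk_stats, distance_map, extent_estimate,
                             radial_profile)


def brute_force_profile(counts, distances, root, pore, width):
    """Per-pixel group-by oracle for the binned radial statistics."""
    ok = ~root & ~pore
    df = pd.DataFrame({"b": (distances[ok] // width).astype(int),
                       "v": counts[ok]})
    g = df.groupby("b")["v"]
    return g.mean(), g.std(ddof=0), g.size()


class TestDistanceMap:
    def test_four_and_diagonal_neighbours(self):
        root = np.zeros((5, 5), dtype=bool)
        root[2, 2] = True
        d = distance_map(root, 20.0)
        assert d[2, 2] == 0.0
        assert d[2, 3] == pytest.approx(20.0)
        assert d[3, 3] == pytest.approx(20.0 * np.sqrt(2))

    def test_all_root_is_all_zero(self):
        d = distance_map(np.ones((4, 4), dtype=bool), 20.0)
        assert np.all(d == 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            distance_map(np.zeros((4, 4), dtype=bool))


class TestRadialProfile:
    def test_constant_map_statistics(self):
        root = np.zeros((21, 21), dtype=bool)
        root[10, 10] = True
        counts = np.full((21, 21), 7.0)
        d = distance_map(root, 20.0)
        prof = radial_profile(counts, d, root)
        ok = prof.weight > 0
        assert np.allclose(prof.mean[ok], 7.0)
        assert np.allclose(prof.sd[ok], 0.0)
        assert prof.weight.sum() == 21 * 21 - 1

    def test_fully_pore_masked_bin_has_zero_weight(self):
        root = np.zeros((9, 9), dtype=bool)
        root[4, 4] = True
        pore = np.zeros((9, 9), dtype=bool)
        d = distance_map(root, 20.0)
        pore[(d >= 20.0) & (d < 40.0)] = True
        prof = radial_profile(np.ones((9, 9)), d, root, pore)
        assert prof.weight[1] == 0 and np.isnan(prof.mean[1])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        shape = (40, 40)
        root = np.zeros(shape, dtype=bool)
        root[18:22, 18:22] = True
        pore = rng.random(shape) < 0.2
        pore[root] = False
        counts = rng.poisson(50.0, shape).astype(float)
        d = distance_map(root, 20.0)
        prof = radial_profile(counts, d, root, pore)
        mean, sd, n = brute_force_profile(counts, d, root, pore, 20.0)
        for b in mean.index:
            assert prof.weight[b] == n[b]
            assert prof.mean[b] == pytest.approx(mean[b], rel=1e-12)
            assert prof.sd[b] == pytest.approx(sd[b], rel=1e-9, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        root = np.zeros((4, 4), dtype=bool)
        root[0, 0] = True
        with pytest.raises(ValueError):
            radial_profile(np.ones((5, 5)), np.ones((4, 4)), root)


class TestBulkStats:
    def test_equal_weights(self):
        prof = generate_profile_fixture(weights=[1, 1, 1], values=[1, 2, 3],
                                        bin_width=500.0)
        mean, sd = bulk_stats(prof, inner_cut=0.0)
        assert mean == pytest.approx(2.0)

    def test_zero_weight_bins_ignored(self):
        prof = generate_profile_fixture(weights=[1, 1, 0, 1],
                                        values=[5.0, 1.0, 99.0, 3.0],
                                        bin_width=1000.0)
        mean, sd = bulk_stats(prof)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_weighted_moments_against_direct_formula(self, rng):
        w = rng.integers(1, 100, 80).astype(float)
        v = rng.uniform(10, 20, 80)
        prof = generate_profile_fixture(weights=w, values=v, bin_width=50.0)
        mean, sd = bulk_stats(prof, inner_cut=1000.0)
        sel = slice(20, None)                   # bins starting at 1000 um
        m = np.average(v[sel], weights=w[sel])
        s = np.sqrt(np.average((v[sel] - m) ** 2, weights=w[sel]))
        assert mean == pytest.approx(m, rel=1e-12)
        assert sd == pytest.approx(s, rel=1e-12)

    def test_no_bulk_bins_rejected(self):
        prof = generate_profile_fixture(weights=[1, 1], values=[1.0, 2.0],
                                        bin_width=20.0)
        with pytest.raises(ValueError):
            bulk_stats(prof)


class TestExtentEstimate:
    def test_profile_inside_band_everywhere(self):
        prof = generate_profile_fixture(weights=np.ones(60),
                                        values=np.full(60, 100.0))
        est = extent_estimate(prof, (100.0, 1.0))
        assert est.extent_um == 0.0 and not est.ambiguous

    def test_single_monotone_crossing(self):
        centers_value = np.full(60, 100.0)
        centers_value[:15] = 100.0 + 80.0 * np.exp(-np.arange(15) / 4.0)
        prof = generate_profile_fixture(weights=np.ones(60),
                                        values=centers_value)
        est = extent_estimate(prof, (100.0, 2.0))
        assert len(est.crossings) == 1
        assert not est.ambiguous
        # band edge 104: crossing between the bins bracketing 104 counts
        assert 200 < est.extent_um < 320

    def test_undulating_profile_persistence_rule(self):
        # outside the band (150) with re-entries at ~189, ~349 and ~529 um;
        # only the middle re-entry is followed by a persistent in-band run
        v = np.array([150.0] * 9 + [100.0] * 2 + [150.0] * 6 + [100.0] * 7
                     + [150.0] * 2 + [100.0] * 1 + [150.0] * 2)
        prof = generate_profile_fixture(weights=np.ones(v.size), values=v)
        est = extent_estimate(prof, (100.0, 1.0), persistence_run=5)
        assert len(est.crossings) == 3
        assert est.ambiguous and est.truncated
        assert est.extent_um == pytest.approx(349.2, abs=1.0)
        assert est.crossings[0] == pytest.approx(189.2, abs=1.0)
        assert est.crossings[2] == pytest.approx(529.2, abs=1.0)

    def test_depletion_direction(self):
        v = np.full(60, 100.0)
        v[:8] = 40.0
        prof = generate_profile_fixture(weights=np.ones(60), values=v)
        est = extent_estimate(prof, (100.0, 1.0), direction="depletion")
        assert est.extent_um > 0 and est.cutoff == pytest.approx(98.0)

    def test_zero_sd_constant_map_guard(self):
        prof = generate_profile_fixture(weights=np.ones(60),
                                        values=np.full(60, 42.0))
        est = extent_estimate(prof, (42.0, 0.0))
        assert est.extent_um == 0.0

    def test_end_to_end_on_noiseless_step_map(self):
        recipe = MapRecipe(style="loam", seed=3, envelope="step", extent=500.0,
                           poisson=False, pore_fraction=0.02)
        counts, masks, truth = generate_map(recipe)
        d = distance_map(masks.root, recipe.pixel_size)
        prof = radial_profile(counts, d, masks.root, masks.pore,
                              pixel_size=recipe.pixel_size)
        est = extent_estimate(prof, bulk_stats(prof), "accumulation")
        assert abs(est.extent_um - 500.0) <= recipe.pixel_size
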