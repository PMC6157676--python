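from __future__ import annotations

import numpy as np
import pytest

import charcomp as cc
from charcomp.composite import _GridSmoother, _grid_arrays, _pool_records
from conftest import make_transformed


def small_config(**kw) -> cc.CompositeConfig:
    kw.setdefault("target_step", 100.0)
    kw.setdefault("n_boot", 50)
    kw.setdefault("seed", 3)
    return cc.CompositeConfig(**kw)


class TestSmoothPooled:
    def test_constant_signal_preserved(self):
        ages = np.arange(0, 5000, 100.0)
        out = cc.smooth_pooled(ages, np.full(ages.size, 2.5), ages, 250.0)
        np.testing.assert_allclose(out, 2.5)

    def test_linear_signal_reproduced_exactly(self):
        ages = np.arange(0, 5000, 100.0)
        z = 0.3 + 0.0002 * ages
        targets = ages[5:-5]
        out = cc.smooth_pooled(ages, z, targets, 250.0)
        np.testing.assert_allclose(out, 0.3 + 0.0002 * targets, rtol=1e-10)

    def test_single_point_window_returns_that_value(self):
        out = cc.smooth_pooled([1000.0], [0.7], [1100.0], 250.0)
        np.testing.assert_allclose(out, [0.7])

    def test_empty_window_is_nan(self):
        out = cc.smooth_pooled([1000.0], [0.7], [5000.0], 250.0)
        assert np.isnan(out[0])


class TestCompositeMean:
    def test_single_record_identity(self):
        rec = make_transformed("A", np.arange(50, 3000, 100.0), np.sin(np.arange(50, 3000, 100.0) / 500))
        config = small_config(analysis_window=(3000.0, 0.0))
        curve = cc.composite_mean([rec], config)
        own = cc.smooth_pooled(rec.bin_ages, rec.z, config.target_ages, 250.0)
        np.testing.assert_allclose(curve.mean_z, own, equal_nan=True)

    def test_duplicate_records_change_nothing(self):
        grid = np.arange(50, 3000, 100.0)
        rec = make_transformed("A", grid, np.cos(grid / 300))
        rec2 = make_transformed("B", grid, np.cos(grid / 300))
        config = small_config(analysis_window=(3000.0, 0.0))
        one = cc.composite_mean([rec], config)
        two = cc.composite_mean([rec, rec2], config)
        np.testing.assert_allclose(one.mean_z, two.mean_z, equal_nan=True)
        assert two.n_sites.max() == 2

    def test_symmetric_records_cancel(self):
        grid = np.arange(50, 3000, 100.0)
        up = make_transformed("U", grid, np.ones(grid.size))
        down = make_transformed("D", grid, -np.ones(grid.size))
        curve = cc.composite_mean([up, down], small_config(analysis_window=(3000.0, 0.0)))
        np.testing.assert_allclose(curve.mean_z[curve.defined], 0.0, atol=1e-12)

    def test_record_order_never_changes_output(self, rng):
        grids = [np.arange(50, 6000, 100.0)[rng.random(60) < 0.8] for _ in range(5)]
        recs = [
            make_transformed(f"S{i}", g, rng.normal(size=g.size))
            for i, g in enumerate(grids)
        ]
        config = small_config(analysis_window=(6000.0, 0.0))
        a = cc.composite_mean(recs, config)
        b = cc.composite_mean(list(reversed(recs)), config)
        np.testing.assert_array_equal(a.mean_z, b.mean_z)
        np.testing.assert_array_equal(a.n_sites, b.n_sites)

    def test_mean_between_window_extremes(self, rng):
        grid = np.arange(50, 6000, 100.0)
        recs = [
            make_transformed(f"S{i}", grid, rng.normal(size=grid.size))
            for i in range(4)
        ]
        config = small_config(analysis_window=(6000.0, 0.0))
        curve = cc.composite_mean(recs, config)
        ages, z = _pool_records(recs)
        for k, t in enumerate(curve.ages):
            if not curve.defined[k]:
                continue
            m = np.abs(ages - t) <= 250.0
            lo, hi = z[m].min(), z[m].max()
            rng_w = hi - lo
            assert lo - rng_w <= curve.mean_z[k] <= hi + rng_w

    def test_empty_record_set_rejected(self):
        with pytest.raises(cc.ValidationError):
            cc.composite_mean([], small_config())


class TestGridFastPath:
    def test_matches_generic_smoother(self, rng):
        """The bootstrap's vectorized smoother must agree with smooth_pooled."""
        config = small_config(analysis_window=(12000.0, 0.0))
        grid_all = config.target_ages
        recs = []
        for i in range(8):
            keep = rng.random(grid_all.size) < rng.uniform(0.3, 0.9)
            if keep.sum() < 2:
                keep[:2] = True
            recs.append(
                make_transformed(f"S{i}", grid_all[keep], rng.normal(size=int(keep.sum())))
            )
        centers, occ, val = _grid_arrays(recs, config)
        sm = _GridSmoother(centers, config.target_ages, config.half_window)
        counts = occ.sum(axis=0)
        sums = np.where(occ > 0, val, 0.0).sum(axis=0)
        bmin = np.min(np.where(occ > 0, val, np.inf), axis=0)
        bmax = np.max(np.where(occ > 0, val, -np.inf), axis=0)
        fast = sm.smooth(counts, sums, bmin, bmax)
        ages, z = _pool_records(recs)
        generic = cc.smooth_pooled(ages, z, config.target_ages, config.half_window)
        np.testing.assert_allclose(fast, generic, rtol=0, atol=1e-10, equal_nan=True)


class TestBootstrap:
    def test_identical_records_collapse_band(self):
        grid = np.arange(50, 4000, 100.0)
        z = np.sin(grid / 700)
        recs = [make_transformed(f"S{i}", grid, z) for i in range(5)]
        config = small_config(analysis_window=(4000.0, 0.0), n_boot=40)
        curve = cc.bootstrap_composite(recs, config)
        d = curve.defined
        np.testing.assert_array_equal(curve.ci_low[d], curve.mean_z[d])
        np.testing.assert_array_equal(curve.ci_high[d], curve.mean_z[d])

    def test_same_seed_bitwise_reproducible(self, rng):
        grid = np.arange(50, 4000, 100.0)
        recs = [
            make_transformed(f"S{i}", grid, rng.normal(size=grid.size))
            for i in range(6)
        ]
        config = small_config(analysis_window=(4000.0, 0.0), seed=11)
        a = cc.bootstrap_composite(recs, config)
        b = cc.bootstrap_composite(recs, config)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)
        np.testing.assert_array_equal(a.mean_z, b.mean_z)

    def test_band_ordered_and_brackets_mean_estimate(self, rng):
        grid = np.arange(50, 4000, 100.0)
        recs = [
            make_transformed(f"S{i}", grid, rng.normal(size=grid.size))
            for i in range(10)
        ]
        curve = cc.bootstrap_composite(
            recs, small_config(analysis_window=(4000.0, 0.0), n_boot=200)
        )
        d = curve.defined
        assert np.all(curve.ci_low[d] <= curve.ci_high[d])

    def test_band_narrows_with_more_identical_replicates(self, rng):
        grid = np.arange(50, 4000, 100.0)
        base = [
            make_transformed(f"S{i}", grid, rng.normal(size=grid.size))
            for i in range(4)
        ]
        config = small_config(analysis_window=(4000.0, 0.0), n_boot=200, seed=5)
        few = cc.bootstrap_composite(base, config)
        many = cc.bootstrap_composite(base * 4, config)
        d = few.defined & many.defined
        width_few = np.mean((few.ci_high - few.ci_low)[d])
        width_many = np.mean((many.ci_high - many.ci_low)[d])
        assert width_many < width_few

    def test_point_estimate_matches_composite_mean(self, rng):
        grid = np.arange(50, 4000, 100.0)
        recs = [
            make_transformed(f"S{i}", grid, rng.normal(size=grid.size))
            for i in range(5)
        ]
        config = small_config(analysis_window=(4000.0, 0.0), n_boot=10)
        boot = cc.bootstrap_composite(recs, config)
        mean = cc.composite_mean(recs, config)
        np.testing.assert_allclose(boot.mean_z, mean.mean_z, atol=1e-10, equal_nan=True)

    def test_invalid_n_boot_rejected(self):
        with pytest.raises(cc.ValidationError):
            cc.CompositeConfig(n_boot=0)
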