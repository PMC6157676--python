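from __future__ import annotations

import numpy as np
import pytest

import charcomp as cc


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_record(site_id: str, ages, values) -> cc.CharcoalRecord:
    return cc.canonicalize_record(
        cc.CharcoalRecord(
            site_id,
            [cc.CharcoalSample(a, v) for a, v in zip(ages, values)],
        )
    )


def make_transformed(site_id: str, bin_ages, z, basis="base-period") -> cc.TransformedRecord:
    bin_ages = np.asarray(bin_ages, float)
    z = np.asarray(z, float)
    return cc.TransformedRecord(
        site_id=site_id,
        bin_ages=bin_ages,
        z=z,
        lambda_hat=1.0,
        basis=basis,
        sample_ages=bin_ages,
        sample_z=z,
    )


@pytest.fixture()
def fixture_grid_scheme() -> cc.BiomeScheme:
    """4x4 ten-degree grid over lon [0,40), lat [0,40): codes 1..4 by column."""
    codes = np.tile(np.array([1, 2, 3, 4]), (4, 1))
    grid = cc.BiomeGrid(codes, xll=0.0, yll=0.0, cellsize=10.0, nodata=-9999)
    return cc.BiomeScheme(
        name="FIX", mode="grid", target_classes=frozenset({3, 4}), grid=grid,
        forest_classes=frozenset({1}),
    )


@pytest.fixture()
def small_dataset() -> cc.Dataset:
    """Five sites, three inside the fixture scheme's target cells."""
    sites = [
        cc.SiteInfo("A", 25.0, 5.0, "Africa", "Tropical savanna"),
        cc.SiteInfo("B", 35.0, 15.0, "Africa", "Tropical savanna"),
        cc.SiteInfo("C", 21.0, 35.0, "Eurasia", "Temperate grassland"),
        cc.SiteInfo("D", 5.0, 5.0, "Africa", "Tropical forest"),
        cc.SiteInfo("E", 15.0, 25.0, "Eurasia", "Temperate forest"),
    ]
    rng = np.random.default_rng(7)
    records = []
    for s in sites:
        ages = np.sort(rng.uniform(0, 11000, 40))
        values = rng.lognormal(0.0, 1.0, 40)
        records.append(make_record(s.site_id, ages, values))
    return cc.Dataset(records=records, sites=sites)
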