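"""Synthetic charcoal datasets with known biomass-burning structure.

The generator emulates the statistical shape of sedimentary charcoal
compilations: nonnegative, irregularly sampled series spanning (parts of)
the last 12,000 years, with order-of-magnitude between-site scale
differences, multiplicative sample noise, and occasional exact zeros.
Each sample value is

    value = exp( c * g(age) + log s_i + eps ),    eps ~ N(0, noise_sd^2)

where ``g`` is the hidden burning trend on the Z-scale, ``c`` a fixed
trend-amplitude constant, and ``s_i`` a lognormal per-site scale factor.
The multiplicative structure makes the min-max/Box-Cox stages of the
transform chain load-bearing in tests rather than decorative.  Sample ages
follow a renewal process (exponential gaps) inside a per-site span, the
analog of variable sediment accumulation and sampling resolution.  Ages
are exact: no age-model uncertainty is simulated.

The paired :class:`SyntheticTruth` exposes the trend on the bin grid, the
true changepoint ages and the per-site factors, so recovery experiments
can score the pipeline against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .biomes import BiomeScheme
from .errors import ValidationError
from .io import CharcoalRecord, CharcoalSample, Dataset, SiteInfo, canonicalize_record

# ---------------------------------------------------------------------------
# trend functions on the Z-scale


@dataclass(frozen=True)
class ConstantTrend:
    level: float = 0.0

    def __call__(self, ages) -> np.ndarray:
        return np.full(np.shape(ages), self.level)

    @property
    def changepoint_ages(self) -> tuple[float, ...]:
        return ()


@dataclass(frozen=True)
class LinearTrend:
    """Linear in time: positive slope = burning increases toward the present."""

    slope_per_kyr: float

    def __call__(self, ages) -> np.ndarray:
        return -self.slope_per_kyr * np.asarray(ages, float) / 1000.0

    @property
    def changepoint_ages(self) -> tuple[float, ...]:
        return ()


@dataclass(frozen=True)
class StepTrend:
    """Level shift of ``size`` for ages younger than ``age``."""

    age: float
    size: float

    def __call__(self, ages) -> np.ndarray:
        return np.where(np.asarray(ages, float) < self.age, self.size, 0.0)

    @property
    def changepoint_ages(self) -> tuple[float, ...]:
        return (self.age,)


@dataclass(frozen=True)
class PiecewiseTrend:
    """Piecewise-constant levels: ``pieces`` is ((age, level), ...) meaning the
    level holds for all ages younger than ``age`` until the next piece."""

    pieces: tuple[tuple[float, float], ...]

    def __call__(self, ages) -> np.ndarray:
        a = np.asarray(ages, float)
        out = np.zeros(a.shape)
        for age, level in sorted(self.pieces, reverse=True):
            out = np.where(a < age, level, out)
        return out

    @property
    def changepoint_ages(self) -> tuple[float, ...]:
        return tuple(sorted((age for age, _ in self.pieces), reverse=True))


# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Generation conditions for one synthetic compilation.

    Defaults describe a mid-sized global compilation: 40 sites, ~100-year
    mean sampling resolution, spans covering most of the Holocene,
    order-of-magnitude site-scale spread (site_scale_sd = 1 on the log
    scale), 50% multiplicative sample noise and 5% exact zeros.
    """

    n_sites: int = 40
    span: tuple[float, float] = (12000.0, 0.0)
    trend: object = field(default_factory=ConstantTrend)
    trend_scale: float = 1.0
    site_scale_sd: float = 1.0
    noise_sd: float = 0.5
    zero_prob: float = 0.05
    mean_spacing: float = 100.0
    oldest_range: tuple[float, float] = (9000.0, 12000.0)
    youngest_range: tuple[float, float] = (0.0, 500.0)
    bin_width: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if not (0.0 <= self.zero_prob <= 1.0):
            raise ValidationError("zero_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.site_scale_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.mean_spacing <= 0:
            raise ValidationError("mean_spacing must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, reproducible from the spec alone."""

    bin_ages: np.ndarray
    trend_on_grid: np.ndarray
    changepoint_ages: tuple[float, ...]
    site_scales: dict[str, float]
    seed: int


_CONTINENT_BOXES = (
    # crude rectangles, checked in order; good enough for fixture metadata
    ("North America", -170.0, -30.0, 13.0, 85.0),
    ("South America", -90.0, -30.0, -60.0, 13.0),
    ("Africa", -20.0, 52.0, -35.0, 37.0),
    ("Oceania", 110.0, 180.0, -50.0, -9.0),
    ("Eurasia", -12.0, 180.0, 5.0, 82.0),
)


def continent_of(lon: float, lat: float) -> str:
    """Continent label from a fixed rectangle table (fixture-grade, not GIS)."""
    for name, w, e, s, n in _CONTINENT_BOXES:
        if w <= lon <= e and s <= lat <= n:
            return name
    return "unknown"


def _sample_ages(rng: np.random.Generator, young: float, old: float, spacing: float) -> np.ndarray:
    ages = [young]
    a = young
    # renewal process with exponential gaps, marching back in time
    while True:
        a += rng.exponential(spacing)
        if a > old:
            break
        ages.append(a)
    if len(ages) < 2:  # degenerate span: force two endpoints
        ages = [young, old]
    return np.asarray(ages)


def generate_dataset(spec: SyntheticSpec) -> tuple[Dataset, SyntheticTruth]:
    """Draw one synthetic compilation plus its ground truth.

    Deterministic given ``spec.seed``; the emitted :class:`Dataset` always
    passes :mod:`charcomp.io` validation.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.trend
    records: list[CharcoalRecord] = []
    sites: list[SiteInfo] = []
    scales: dict[str, float] = {}
    for i in range(spec.n_sites):
        site_id = f"S{i:03d}"
        young = rng.uniform(*spec.youngest_range)
        old = rng.uniform(*spec.oldest_range)
        ages = _sample_ages(rng, young, old, spec.mean_spacing)
        log_scale = rng.normal(0.0, spec.site_scale_sd)
        eps = rng.normal(0.0, spec.noise_sd, ages.size)
        values = np.exp(spec.trend_scale * g(ages) + log_scale + eps)
        zeros = rng.random(ages.size) < spec.zero_prob
        values = np.where(zeros, 0.0, values)
        rec = canonicalize_record(
            CharcoalRecord(
                site_id, [CharcoalSample(a, v) for a, v in zip(ages, values)]
            )
        )
        records.append(rec)
        scales[site_id] = float(np.exp(log_scale))
        lon = rng.uniform(-180.0, 180.0)
        lat = rng.uniform(-55.0, 70.0)
        sites.append(
            SiteInfo(site_id, lon, lat, continent_of(lon, lat), "synthetic")
        )
    old_b, young_b = spec.span
    bin_ages = np.arange(young_b + spec.bin_width / 2.0, old_b, spec.bin_width)
    truth = SyntheticTruth(
        bin_ages=bin_ages,
        trend_on_grid=spec.trend_scale * np.asarray(g(bin_ages), float),
        changepoint_ages=g.changepoint_ages,
        site_scales=scales,
        seed=spec.seed,
    )
    return Dataset(records=records, sites=sites), truth


def generate_site_table(
    spec: SyntheticSpec,
    scheme: BiomeScheme,
    n_in_target: int,
    n_outside: int,
    seed: int | None = None,
) -> list[SiteInfo]:
    """Site metadata with selection counts known by construction.

    Places ``n_in_target`` sites uniformly inside grid cells whose code is
    in ``scheme.target_classes`` and ``n_outside`` sites in classified
    non-target cells, so ``select_sites`` on the scheme must return
    exactly ``n_in_target`` sites.
    """
    if scheme.mode != "grid":
        raise ValidationError("generate_site_table requires a grid-mode scheme")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    grid = scheme.grid
    in_cells = np.argwhere(np.isin(grid.codes, list(scheme.target_classes)))
    out_mask = ~np.isin(grid.codes, list(scheme.target_classes)) & (
        grid.codes != grid.nodata
    )
    out_cells = np.argwhere(out_mask)
    if n_in_target > 0 and in_cells.size == 0:
        raise ValidationError("scheme grid has no target cells")
    if n_outside > 0 and out_cells.size == 0:
        raise ValidationError("scheme grid has no classified non-target cells")

    def draw(cells: np.ndarray, count: int, prefix: str) -> list[SiteInfo]:
        out = []
        for k in range(count):
            r, c = cells[rng.integers(0, len(cells))]
            # interior point of the half-open cell (row r counts from north)
            lon = grid.xll + (c + rng.uniform(0.05, 0.95)) * grid.cellsize
            lat = grid.yll + (grid.nrows - 1 - r + rng.uniform(0.05, 0.95)) * grid.cellsize
            out.append(
                SiteInfo(f"{prefix}{k:03d}", lon, lat, continent_of(lon, lat), "synthetic")
            )
        return out

    return draw(in_cells, n_in_target, "T") + draw(out_cells, n_outside, "O")
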