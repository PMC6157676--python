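"""Recovery and calibration experiments run against synthetic ground truth.

These drivers wire generator -> transform -> composite -> inference at
desk scale and score the results against the known structure, exactly the
validation loop a compilation study should run before trusting its
composites.  Problem sizes (bin width 50-100 yr, a few hundred bootstrap
replicates) are chosen so a full battery runs in minutes on one core;
docs/methods.md discusses the choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composite import CompositeConfig, bootstrap_composite, composite_mean, smooth_pooled
from .synthetic import LinearTrend, StepTrend, SyntheticSpec, generate_dataset
from .transform import TransformConfig, transform_dataset
from .trends import detect_changepoints, spearman_trend


def composite_from_spec(
    spec: SyntheticSpec, bin_width: float = 50.0
) -> tuple[object, list]:
    """Generate, transform and composite one synthetic dataset (point estimate)."""
    dataset, _ = generate_dataset(spec)
    transformed, _ = transform_dataset(
        dataset.records, TransformConfig(bin_width=bin_width)
    )
    config = CompositeConfig(target_step=bin_width)
    return composite_mean(transformed, config), transformed


def trend_recovery(
    seeds,
    n_sites: int = 40,
    slope_per_kyr: float = 0.1,
    noise_sd: float = 0.5,
    bin_width: float = 50.0,
) -> list[float]:
    """Composite Spearman rho vs time for a linear burning increase, per seed."""
    rhos = []
    for seed in seeds:
        spec = SyntheticSpec(
            n_sites=n_sites,
            trend=LinearTrend(slope_per_kyr),
            noise_sd=noise_sd,
            seed=int(seed),
        )
        curve, _ = composite_from_spec(spec, bin_width)
        rhos.append(spearman_trend(curve).rho)
    return rhos


def step_recovery(
    seeds,
    step_age: float = 4000.0,
    step_size: float = 1.0,
    n_sites: int = 40,
    noise_sd: float = 0.3,
    bin_width: float = 50.0,
    penalty: float = 5.0,
    min_seg: int = 5,
    max_cp: int = 10,
) -> list[float]:
    """Distance (yr) from the true step age to the nearest detected changepoint."""
    errors = []
    for seed in seeds:
        spec = SyntheticSpec(
            n_sites=n_sites,
            trend=StepTrend(step_age, step_size),
            noise_sd=noise_sd,
            seed=int(seed),
        )
        curve, _ = composite_from_spec(spec, bin_width)
        res = detect_changepoints(curve, penalty=penalty, min_seg=min_seg, max_cp=max_cp)
        if res.change_ages.size == 0:
            errors.append(np.inf)
        else:
            errors.append(float(np.min(np.abs(res.change_ages - step_age))))
    return errors


@dataclass
class CoverageResult:
    coverage: float
    n_sims: int
    n_cells: int


def bootstrap_coverage(
    n_sims: int = 200,
    n_sites: int = 30,
    conf: float = 0.95,
    n_boot: int = 200,
    noise_sd: float = 0.5,
    bin_width: float = 100.0,
    seed: int = 0,
) -> CoverageResult:
    """Pointwise coverage of the smoothed true curve by the bootstrap band.

    Sites are i.i.d. around a known smooth curve on the common bin grid
    (per-bin Gaussian noise), the cleanest regime in which the percentile
    band's nominal level can be checked.  Coverage is pooled over
    simulations and defined ages.
    """
    from .transform import TransformedRecord

    config = CompositeConfig(
        target_step=bin_width, n_boot=n_boot, conf=conf, seed=seed
    )
    grid = config.target_ages
    truth_curve = np.sin(grid / 1800.0) - 0.3 * grid / 12000.0
    truth_smoothed = smooth_pooled(grid, truth_curve, grid, config.half_window)
    master = np.random.default_rng(seed)
    hits = 0
    cells = 0
    for s in range(n_sims):
        rng = np.random.default_rng(master.integers(2**31))
        records = [
            TransformedRecord(
                site_id=f"S{i}",
                bin_ages=grid,
                z=truth_curve + rng.normal(0.0, noise_sd, grid.size),
                lambda_hat=0.0,
                basis="base-period",
                sample_ages=grid,
                sample_z=truth_curve,
            )
            for i in range(n_sites)
        ]
        curve = bootstrap_composite(records, config, rng=rng)
        d = curve.defined
        hits += int(
            np.sum(
                (curve.ci_low[d] <= truth_smoothed[d])
                & (truth_smoothed[d] <= curve.ci_high[d])
            )
        )
        cells += int(d.sum())
    return CoverageResult(coverage=hits / cells, n_sims=n_sims, n_cells=cells)
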