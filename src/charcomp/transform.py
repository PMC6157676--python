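"""Per-record standardization: min-max rescale, Box-Cox, base-period Z-score, binning.

Raw charcoal quantities are not comparable across sites — taphonomy, basin
geometry and laboratory protocol all set a record's absolute scale.  The
chain applied here removes that scale while preserving each record's
internal ordering:

1. min-max rescale to [0, 1];
2. add a small positive shift (Box-Cox needs strictly positive input and
   min-max produces an exact zero);
3. Box-Cox power transform, with the exponent lambda fitted per record by
   profile-likelihood grid search;
4. Z-score against the base period 12,000-250 cal yr BP, so the industrial
   era does not inflate the reference variance;
5. average into regular half-open age bins inside the analysis window.

Every stage is strictly increasing in the charcoal value, so within-record
ranks — the only cross-site comparable content of a record — survive the
whole chain exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import boxcox as _scipy_boxcox

from .errors import DegenerateRecordError, EstimationError, ValidationError
from .io import CharcoalRecord


@dataclass(frozen=True)
class TransformConfig:
    """Knobs of the standardization chain.

    base_period
        (old, young) bounds in cal yr BP of the window supplying the
        Z-score mean and standard deviation.  Default (12000, 250).
    boxcox_shift
        Constant added after min-max rescaling so Box-Cox sees positive
        input; 0.01 keeps the distortion of the unit interval small.
    lambda_grid
        (lo, hi, step) of the Box-Cox exponent search grid.
    bin_width
        Width in years of the half-open pre-binning bins.
    analysis_window
        (old, young) bounds of ages kept for compositing.
    """

    base_period: tuple[float, float] = (12000.0, 250.0)
    boxcox_shift: float = 0.01
    lambda_grid: tuple[float, float, float] = (-2.0, 2.0, 0.01)
    bin_width: float = 20.0
    analysis_window: tuple[float, float] = (12000.0, 0.0)

    def __post_init__(self) -> None:
        if self.base_period[0] <= self.base_period[1]:
            raise ValidationError("base_period must be (old, young) with old > young")
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if self.boxcox_shift <= 0:
            raise ValidationError("boxcox_shift must be positive")


@dataclass
class TransformedRecord:
    """A record after the full chain, on the regular bin grid.

    ``bin_ages`` are occupied bin centers, strictly increasing (larger =
    older); ``z`` the mean Z-score per bin.  ``sample_ages``/``sample_z``
    keep the pre-binning series for Hovmoller-style audits, and ``basis``
    records whether the standardization moments came from the base period
    or (fallback) the full record.
    """

    site_id: str
    bin_ages: np.ndarray
    z: np.ndarray
    lambda_hat: float
    basis: str  # "base-period" | "full-record"
    sample_ages: np.ndarray
    sample_z: np.ndarray


def minmax_rescale(values) -> np.ndarray:
    """Rescale to [0, 1]; endpoints map exactly to 0 and 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateRecordError("need at least 2 values to rescale")
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise DegenerateRecordError("constant series cannot be min-max rescaled")
    return (v - lo) / (hi - lo)


def boxcox(values, lam: float) -> np.ndarray:
    """Box-Cox power transform: (x^lam - 1)/lam, or ln x at lam = 0."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValidationError("Box-Cox requires strictly positive input")
    return _scipy_boxcox(v, lam)


def _profile_loglik(values: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Normal-model profile log-likelihood of Box-Cox at each lambda.

    Closed form: -n/2 * log(sigma2_mle(lam)) + (lam - 1) * sum(log x).
    Vectorized over the lambda grid.
    """
    n = values.size
    logx = np.log(values)
    sum_logx = logx.sum()
    lams = np.asarray(lams, dtype=float)
    out = np.empty(lams.shape)
    nz = lams != 0.0
    with np.errstate(over="ignore"):
        y = np.expm1(np.outer(lams[nz], logx)) / lams[nz, None]
    var_nz = y.var(axis=1)
    out[nz] = -0.5 * n * np.log(var_nz) + (lams[nz] - 1.0) * sum_logx
    if (~nz).any():
        out[~nz] = -0.5 * n * np.log(logx.var()) - sum_logx
    out[~np.isfinite(out)] = -np.inf
    return out


def fit_boxcox_lambda(
    values, grid: tuple[float, float, float] = (-2.0, 2.0, 0.01)
) -> float:
    """Profile-likelihood grid search for the Box-Cox exponent.

    Ties on the grid are broken toward 0 (the log transform), the least
    aggressive member of the family.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise EstimationError("need at least 3 values to fit lambda")
    if np.any(v <= 0):
        raise ValidationError("Box-Cox requires strictly positive input")
    lo, hi, step = grid
    n_steps = int(round((hi - lo) / step))
    lams = lo + step * np.arange(n_steps + 1)
    llf = _profile_loglik(v, lams)
    best = llf.max()
    if not np.isfinite(best):
        raise EstimationError("profile likelihood degenerate on the whole grid")
    candidates = lams[llf == best]
    return float(candidates[np.argmin(np.abs(candidates))])


def zscore_base_period(
    ages, values, base_period: tuple[float, float] = (12000.0, 250.0)
) -> tuple[np.ndarray, str]:
    """Z-score all samples using base-period moments; full-record fallback.

    Moments (mean and n-1 standard deviation) come from samples with
    age in [young, old]; they standardize *every* sample, including those
    outside the base period.  Records with fewer than two base-period
    samples, or zero base-period variance, fall back to full-record
    moments and are flagged ``basis="full-record"``.
    """
    a = np.asarray(ages, dtype=float)
    v = np.asarray(values, dtype=float)
    if a.shape != v.shape:
        raise ValidationError("ages and values must be aligned")
    if v.size < 2:
        raise DegenerateRecordError("need at least 2 samples to z-score")
    old, young = base_period
    in_base = (a >= young) & (a <= old)
    basis = "base-period"
    ref = v[in_base]
    if ref.size < 2 or np.std(ref, ddof=1) == 0.0:
        basis = "full-record"
        ref = v
    s = np.std(ref, ddof=1)
    if s == 0.0:
        raise DegenerateRecordError("zero variance under both standardization windows")
    return (v - ref.mean()) / s, basis


def bin_record(
    ages,
    z,
    bin_width: float = 20.0,
    analysis_window: tuple[float, float] = (12000.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Average samples into half-open age bins [k*w, (k+1)*w).

    Samples outside the analysis window are discarded; empty bins are
    omitted; bin ages are reported at bin centers, increasing.
    """
    a = np.asarray(ages, dtype=float)
    v = np.asarray(z, dtype=float)
    old, young = analysis_window
    keep = (a >= young) & (a <= old)
    a, v = a[keep], v[keep]
    if a.size == 0:
        return np.empty(0), np.empty(0)
    idx = np.floor(a / bin_width).astype(int)
    uniq, inverse = np.unique(idx, return_inverse=True)
    sums = np.bincount(inverse, weights=v)
    counts = np.bincount(inverse)
    centers = uniq * bin_width + bin_width / 2.0
    return centers, sums / counts


def transform_record(
    record: CharcoalRecord, config: TransformConfig = TransformConfig()
) -> TransformedRecord:
    """Run the full chain on one canonicalized record.

    Raises :class:`DegenerateRecordError` for records the chain cannot
    standardize (constant series); callers exclude those from composites
    with a logged count.
    """
    ages = record.ages
    scaled = minmax_rescale(record.values) + config.boxcox_shift
    lam = fit_boxcox_lambda(scaled, config.lambda_grid)
    transformed = boxcox(scaled, lam)
    z, basis = zscore_base_period(ages, transformed, config.base_period)
    bin_ages, binned = bin_record(ages, z, config.bin_width, config.analysis_window)
    return TransformedRecord(
        site_id=record.site_id,
        bin_ages=bin_ages,
        z=binned,
        lambda_hat=lam,
        basis=basis,
        sample_ages=ages,
        sample_z=z,
    )


def transform_dataset(
    records, config: TransformConfig = TransformConfig()
) -> tuple[list[TransformedRecord], list[str]]:
    """Transform many records, collecting (not raising) degenerate ones."""
    out: list[TransformedRecord] = []
    degenerate: list[str] = []
    for rec in records:
        try:
            tr = transform_record(rec, config)
        except (DegenerateRecordError, EstimationError):
            degenerate.append(rec.site_id)
            continue
        if tr.bin_ages.size == 0:
            degenerate.append(rec.site_id)
            continue
        out.append(tr)
    return out, degenerate
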