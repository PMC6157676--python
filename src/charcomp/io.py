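"""Tabular input/output for charcoal records, site metadata and composites.

Charcoal data arrive as long ("tidy") tables with one measured sample per
row (``site_id,age,value``), ages in calendar years before present
(cal yr BP, present = 1950 CE, larger = older) and charcoal quantities in
whatever units the contributing record uses — counts, concentrations,
influx.  Units are never converted across records; the standardization
chain in :mod:`charcomp.transform` removes them.

Reading canonicalizes each site's series: rows with a missing value are
dropped (and counted), samples are sorted by age, and replicate samples at
the same age are merged by their arithmetic mean.  Records left with fewer
than two samples are unusable downstream and are dropped with a count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

CONTINENTS = (
    "North America",
    "South America",
    "Eurasia",
    "Africa",
    "Oceania",
    "unknown",
)


@dataclass(frozen=True)
class CharcoalSample:
    """One dated charcoal measurement: age in cal yr BP, value in record units."""

    age: float
    value: float


@dataclass
class CharcoalRecord:
    """One site's charcoal series, ages nondecreasing, >= 2 samples."""

    site_id: str
    samples: list[CharcoalSample]

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.samples], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([s.value for s in self.samples], dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class SiteInfo:
    """Site metadata: coordinates, continent, and the contributor's biome label."""

    site_id: str
    lon: float
    lat: float
    continent: str = "unknown"
    contributor_biome: str = "unknown"


@dataclass
class Dataset:
    """Charcoal records plus their site metadata, keyed by site_id."""

    records: list[CharcoalRecord]
    sites: list[SiteInfo]

    def __post_init__(self) -> None:
        site_ids = [s.site_id for s in self.sites]
        if len(set(site_ids)) != len(site_ids):
            raise ValidationError("duplicate site_id in site table")
        known = set(site_ids)
        for rec in self.records:
            if rec.site_id not in known:
                raise ValidationError(
                    f"record {rec.site_id!r} has no site metadata entry"
                )

    @property
    def site_index(self) -> dict[str, SiteInfo]:
        return {s.site_id: s for s in self.sites}

    @property
    def site_ids(self) -> list[str]:
        return [r.site_id for r in self.records]


@dataclass
class ReadReport:
    """Row accounting for one table read: rows_in == rows_used + rows_dropped."""

    rows_in: int = 0
    rows_used: int = 0
    rows_dropped: int = 0
    records_dropped: int = 0
    dropped_record_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TableDialect:
    """CSV dialect options: field delimiter and decimal mark."""

    delimiter: str = ","
    decimal: str = "."


def canonicalize_record(record: CharcoalRecord) -> CharcoalRecord:
    """Sort samples by age and merge duplicate-age samples by mean value.

    Idempotent: applying it twice gives the same record.
    """
    ages = record.ages
    values = record.values
    order = np.argsort(ages, kind="stable")
    ages, values = ages[order], values[order]
    uniq, inverse = np.unique(ages, return_inverse=True)
    sums = np.bincount(inverse, weights=values)
    counts = np.bincount(inverse)
    merged = sums / counts
    samples = [CharcoalSample(a, v) for a, v in zip(uniq, merged)]
    return CharcoalRecord(record.site_id, samples)


def _require_columns(df: pd.DataFrame, required: Iterable[str]) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")


def read_charcoal_table(
    source, dialect: TableDialect = TableDialect()
) -> tuple[list[CharcoalRecord], ReadReport]:
    """Read a long-format charcoal table into canonicalized records.

    Parameters
    ----------
    source
        Path or text stream with a CSV holding columns ``site_id, age, value``.
    dialect
        Delimiter / decimal-mark options.

    Returns
    -------
    records, report
        One :class:`CharcoalRecord` per surviving site (input order of first
        appearance), and a :class:`ReadReport` with row accounting.
    """
    df = pd.read_csv(
        source,
        sep=dialect.delimiter,
        decimal=dialect.decimal,
        float_precision="round_trip",
    )
    _require_columns(df, ("site_id", "age", "value"))
    report = ReadReport(rows_in=len(df))

    df = df.copy()
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    bad = df["value"].isna() | df["age"].isna()
    report.rows_dropped = int(bad.sum())
    kept = df.loc[~bad]
    report.rows_used = len(kept)

    neg = kept.index[kept["value"] < 0]
    if len(neg):
        row = int(neg[0])
        site = kept.loc[row, "site_id"]
        raise ValidationError(
            f"negative charcoal value at row {row} (site {site!r})"
        )

    records: list[CharcoalRecord] = []
    for site_id, grp in kept.groupby("site_id", sort=False):
        rec = canonicalize_record(
            CharcoalRecord(
                str(site_id),
                [CharcoalSample(a, v) for a, v in zip(grp["age"], grp["value"])],
            )
        )
        if len(rec) < 2:
            report.records_dropped += 1
            report.dropped_record_ids.append(str(site_id))
            continue
        records.append(rec)
    return records, report


def read_site_table(source, dialect: TableDialect = TableDialect()) -> list[SiteInfo]:
    """Read site metadata (``site_id,lon,lat[,continent][,contributor_biome]``)."""
    df = pd.read_csv(
        source,
        sep=dialect.delimiter,
        decimal=dialect.decimal,
        float_precision="round_trip",
    )
    _require_columns(df, ("site_id", "lon", "lat"))
    if df["site_id"].duplicated().any():
        dup = df["site_id"][df["site_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate site_id: {dup!r}")
    sites = []
    for idx, row in df.iterrows():
        lon, lat = float(row["lon"]), float(row["lat"])
        if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
            raise ValidationError(f"lat/lon out of bounds at row {idx}")
        continent = str(row["continent"]) if "continent" in df.columns and pd.notna(row.get("continent")) else "unknown"
        biome = (
            str(row["contributor_biome"])
            if "contributor_biome" in df.columns and pd.notna(row.get("contributor_biome"))
            else "unknown"
        )
        sites.append(SiteInfo(str(row["site_id"]), lon, lat, continent, biome))
    return sites


def write_charcoal_table(records: Sequence[CharcoalRecord], sink) -> None:
    """Write records back to the long CSV layout (round-trips with the reader)."""
    rows = [
        {"site_id": r.site_id, "age": s.age, "value": s.value}
        for r in records
        for s in r.samples
    ]
    pd.DataFrame(rows, columns=["site_id", "age", "value"]).to_csv(
        sink, index=False, float_format="%.17g"
    )


def write_site_table(sites: Sequence[SiteInfo], sink) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "lon": s.lon,
            "lat": s.lat,
            "continent": s.continent,
            "contributor_biome": s.contributor_biome,
        }
        for s in sites
    ]
    pd.DataFrame(
        rows, columns=["site_id", "lon", "lat", "continent", "contributor_biome"]
    ).to_csv(sink, index=False, float_format="%.17g")


COMPOSITE_COLUMNS = ("age", "mean_z", "ci_low", "ci_high", "n_sites")


def write_composite(curve, sink) -> None:
    """Write a composite curve as ``age,mean_z,ci_low,ci_high,n_sites`` CSV."""
    n = len(curve.ages)
    ci_low = curve.ci_low if curve.ci_low is not None else np.full(n, np.nan)
    ci_high = curve.ci_high if curve.ci_high is not None else np.full(n, np.nan)
    df = pd.DataFrame(
        {
            "age": curve.ages,
            "mean_z": curve.mean_z,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "n_sites": curve.n_sites,
        }
    )
    try:
        df.to_csv(sink, index=False, float_format="%.17g")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing composite to {sink}: {exc}") from exc


def read_composite(source):
    """Read a composite CSV written by :func:`write_composite`."""
    from .composite import CompositeCurve

    df = pd.read_csv(source, float_precision="round_trip")
    _require_columns(df, COMPOSITE_COLUMNS)
    ci_low = df["ci_low"].to_numpy(float)
    ci_high = df["ci_high"].to_numpy(float)
    if np.all(np.isnan(ci_low)):
        ci_low = ci_high = None
    return CompositeCurve(
        ages=df["age"].to_numpy(float),
        mean_z=df["mean_z"].to_numpy(float),
        ci_low=ci_low,
        ci_high=ci_high,
        n_sites=df["n_sites"].to_numpy(int),
    )
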