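"""Biome classification schemes and grassland site selection.

A *scheme* assigns every site a categorical vegetation class, either by
looking its coordinates up in a regular lon/lat grid of integer class codes
(the shape of published global biome maps) or by mapping the free-text biome
label supplied by the record's contributor.  The scheme also names the set
of codes it treats as "grassland" (grasslands, dry shrublands, savannas and
dry woodlands under the megabiome groupings used to harmonize map products);
selection is simple membership of a site's class in that set.

Grid containment is half-open [west, east) x [south, north), with points on
the grid's northern/eastern outer boundary assigned to the last cell and
longitudes wrapped by 360 degrees into the grid domain.  Points outside
coverage get the grid's no-data code — a sentinel, never an exception — so
coastline misses stay auditable instead of fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .errors import FormatError, ValidationError
from .io import Dataset


@dataclass
class BiomeGrid:
    """Regular lon/lat raster of integer class codes (Esri ASCII-grid layout).

    ``codes`` is row-major from the north: ``codes[0]`` is the northernmost
    row.  ``xll, yll`` are the west/south edges of the grid's coverage.
    """

    codes: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise ValidationError("grid codes must be 2-D")
        if self.cellsize <= 0:
            raise ValidationError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.codes.shape[0]

    @property
    def ncols(self) -> int:
        return self.codes.shape[1]

    @property
    def xur(self) -> float:
        return self.xll + self.ncols * self.cellsize

    @property
    def yur(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def lookup(self, lon: float, lat: float) -> int:
        """Class code of the cell containing (lon, lat); nodata outside coverage."""
        lon = _wrap_lon(lon, self.xll, self.xur)
        if not (self.xll <= lon <= self.xur) or not (self.yll <= lat <= self.yur):
            return self.nodata
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_s = int(np.floor((lat - self.yll) / self.cellsize))  # from south
        # boundary points on the outer north/east edge belong to the last cell
        col = min(col, self.ncols - 1)
        row_s = min(row_s, self.nrows - 1)
        return int(self.codes[self.nrows - 1 - row_s, col])


def _wrap_lon(lon: float, west: float, east: float) -> float:
    """Shift lon by multiples of 360 into [west, east] when possible."""
    if west <= lon <= east:
        return lon
    for shifted in (lon + 360.0, lon - 360.0):
        if west <= shifted <= east:
            return shifted
    return lon


def read_ascii_grid(source) -> BiomeGrid:
    """Read a plain-text raster in the Esri ASCII-grid dialect.

    Header: ncols, nrows, xllcorner, yllcorner, cellsize, [nodata_value],
    followed by row-major integer codes, northern row first.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header: dict[str, float] = {}
    i = 0
    for ln in lines:
        parts = ln.split()
        key = parts[0].lower()
        if len(parts) == 2 and key in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[key] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"ASCII grid header missing {req!r}")
    body = " ".join(lines[i:]).split()
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(body) != ncols * nrows:
        raise FormatError(
            f"ASCII grid body has {len(body)} cells, expected {ncols * nrows}"
        )
    codes = np.array([int(float(v)) for v in body]).reshape(nrows, ncols)
    return BiomeGrid(
        codes,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=int(header.get("nodata_value", -9999)),
    )


def write_ascii_grid(grid: BiomeGrid, sink) -> None:
    lines = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {grid.xll:g}",
        f"yllcorner {grid.yll:g}",
        f"cellsize {grid.cellsize:g}",
        f"nodata_value {grid.nodata}",
    ]
    for row in grid.codes:
        lines.append(" ".join(str(int(v)) for v in row))
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


@dataclass
class BiomeScheme:
    """A named classification plus the class codes it calls grassland."""

    name: str
    mode: str  # "grid" | "site-label"
    target_classes: frozenset[int]
    grid: BiomeGrid | None = None
    label_map: Mapping[str, int] | None = None
    forest_classes: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.target_classes = frozenset(int(c) for c in self.target_classes)
        self.forest_classes = frozenset(int(c) for c in self.forest_classes)
        if not self.target_classes:
            raise ValidationError("target_classes must be nonempty")
        if self.mode == "grid":
            if self.grid is None or self.label_map is not None:
                raise ValidationError("grid mode requires grid and no label_map")
            if self.grid.nodata in self.target_classes:
                raise ValidationError("nodata code cannot be a target class")
        elif self.mode == "site-label":
            if self.label_map is None or self.grid is not None:
                raise ValidationError("site-label mode requires label_map and no grid")
        else:
            raise ValidationError(f"unknown scheme mode {self.mode!r}")

    def classify_site(self, site) -> int | None:
        """Class code for a site, or None when it cannot be classified."""
        if self.mode == "grid":
            code = self.grid.lookup(site.lon, site.lat)
            return None if code == self.grid.nodata else code
        code = self.label_map.get(site.contributor_biome)
        return None if code is None else int(code)


def lookup_class(scheme: BiomeScheme, lon: float, lat: float) -> int:
    """Grid-cell class code at (lon, lat); the grid's nodata code outside coverage."""
    if scheme.mode != "grid":
        raise ValidationError("lookup_class requires a grid-mode scheme")
    if not (-90.0 <= lat <= 90.0):
        raise ValidationError(f"latitude {lat} out of bounds")
    return scheme.grid.lookup(lon, lat)


@dataclass
class SelectionSummary:
    """Outcome of selecting one scheme's grassland sites from a dataset."""

    scheme: str
    selected: list[str]
    not_selected: list[str]
    not_classified: list[str]
    continent_counts: dict[str, int]
    universe: frozenset[str] = field(default_factory=frozenset)

    @property
    def total(self) -> int:
        return len(self.selected)

    @property
    def continent_percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.continent_counts}
        return {
            k: 100.0 * v / self.total for k, v in self.continent_counts.items()
        }


def select_sites(dataset: Dataset, scheme: BiomeScheme) -> SelectionSummary:
    """Select the sites whose class under ``scheme`` is a grassland class.

    Sites a label-mode scheme cannot map, or that fall on a grid no-data
    cell, go to ``not_classified`` rather than raising, so scheme
    comparisons stay auditable.
    """
    selected: list[str] = []
    not_selected: list[str] = []
    not_classified: list[str] = []
    continent_counts: dict[str, int] = {}
    for site in dataset.sites:
        code = scheme.classify_site(site)
        if code is None:
            not_classified.append(site.site_id)
        elif code in scheme.target_classes:
            selected.append(site.site_id)
            continent_counts[site.continent] = continent_counts.get(site.continent, 0) + 1
        else:
            not_selected.append(site.site_id)
    return SelectionSummary(
        scheme=scheme.name,
        selected=selected,
        not_selected=not_selected,
        not_classified=not_classified,
        continent_counts=continent_counts,
        universe=frozenset(s.site_id for s in dataset.sites),
    )


@dataclass
class OverlapReport:
    """Pairwise Jaccard fractions and the share of the union in every scheme."""

    pairwise: dict[tuple[str, str], float]
    global_fraction: float


def scheme_overlap(summaries: Sequence[SelectionSummary]) -> OverlapReport:
    """Set agreement between scheme selections over the same dataset."""
    if len(summaries) < 2:
        raise ValidationError("need at least two selections to compare")
    universes = {s.universe for s in summaries}
    if len(universes) != 1:
        raise ValidationError("selections come from different datasets")
    sets = {s.scheme: set(s.selected) for s in summaries}
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in combinations(sets, 2):
        union = sets[a] | sets[b]
        pairwise[(a, b)] = len(sets[a] & sets[b]) / len(union) if union else 1.0
    union_all: set[str] = set().union(*sets.values())
    inter_all = set.intersection(*sets.values()) if sets else set()
    global_fraction = len(inter_all) / len(union_all) if union_all else 1.0
    return OverlapReport(pairwise=pairwise, global_fraction=global_fraction)
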