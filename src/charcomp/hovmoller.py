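"""Site-by-time matrices of Z-score bands (Hovmoller-style displays).

Each binned sample is classified into one of five contiguous Z-score bands
centered on -1, -0.5, 0, 0.5 and 1 (half-width 0.25): dark blue, light
blue, gray, light red, dark red.  The extreme bands are unbounded, so
values beyond +/-1.25 clamp into them and the five bands partition the
reals.  Cells with no binned sample carry the NONE code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import SiteInfo
from .transform import TransformedRecord

BANDS = ("DB", "LB", "GY", "LR", "DR")
NONE_BAND = "NONE"
#: lower edges of LB, GY, LR, DR; DB is everything below -0.75
_EDGES = np.array([-0.75, -0.25, 0.25, 0.75])


def classify_zscore_band(z: float) -> str:
    """Band code for one Z-score; bands are [lower, upper) and clamp at the ends."""
    if not np.isfinite(z):
        raise ValidationError(f"non-finite z-score: {z}")
    return BANDS[int(np.searchsorted(_EDGES, z, side="right"))]


def classify_zscore_bands(z) -> np.ndarray:
    """Vectorized :func:`classify_zscore_band`."""
    zz = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(zz)):
        raise ValidationError("non-finite z-score in input")
    return np.array(BANDS, dtype="<U4")[np.searchsorted(_EDGES, zz, side="right")]


@dataclass
class HovmollerMatrix:
    """Band code per (site, time bin); NONE where the site has no sample."""

    site_order: list[str]
    bin_ages: np.ndarray
    cells: np.ndarray  # (#sites, #bins) of band codes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells,
            index=pd.Index(self.site_order, name="site_id"),
            columns=[f"{a:g}" for a in self.bin_ages],
        )

    def write(self, sink) -> None:
        self.to_frame().to_csv(sink)


def build_matrix(
    records: Sequence[TransformedRecord],
    order_key: str = "record_span",
    sites: Sequence[SiteInfo] | None = None,
    bin_width: float = 20.0,
    analysis_window: tuple[float, float] = (12000.0, 0.0),
) -> HovmollerMatrix:
    """Assemble the site-by-bin band matrix over the full analysis window.

    ``order_key`` sets row order: ``record_span`` (longest span first, the
    sites that contribute most on top), ``latitude`` (requires ``sites``,
    north first), or ``input`` (as given).
    """
    if not records:
        raise ValidationError("no records")
    old, young = analysis_window
    centers = np.arange(young + bin_width / 2.0, old, bin_width)
    index = {round(float(c), 6): j for j, c in enumerate(centers)}

    recs = list(records)
    if order_key == "record_span":
        recs.sort(
            key=lambda r: (r.bin_ages.max() - r.bin_ages.min()) if r.bin_ages.size else 0.0,
            reverse=True,
        )
    elif order_key == "latitude":
        if sites is None:
            raise ValidationError("latitude ordering requires site metadata")
        lat = {s.site_id: s.lat for s in sites}
        recs.sort(key=lambda r: lat.get(r.site_id, -999.0), reverse=True)
    elif order_key != "input":
        raise ValidationError(f"unknown order_key {order_key!r}")

    cells = np.full((len(recs), centers.size), NONE_BAND, dtype="<U4")
    for i, rec in enumerate(recs):
        if rec.bin_ages.size == 0:
            continue
        cols = [index[round(float(a), 6)] for a in rec.bin_ages if round(float(a), 6) in index]
        bands = classify_zscore_bands(rec.z)
        kept = [k for k, a in enumerate(rec.bin_ages) if round(float(a), 6) in index]
        cells[i, cols] = bands[kept]
    return HovmollerMatrix(
        site_order=[r.site_id for r in recs], bin_ages=centers, cells=cells
    )
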