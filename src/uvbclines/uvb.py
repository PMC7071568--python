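"""Map sample-set coordinates to half-degree raster cells, compute mean annual
noontime 305 nm irradiance per location and per group, and compare groups.

Cell convention: cells are addressed by their centers (…, −0.25, 0.25, 0.75,
…). A point location belongs to the cell whose center is nearest; a point
exactly on a cell boundary goes to the northern/eastern cell. A latitude-range
location uses all cells at the set's longitude whose centers fall inside the
closed range (``range_mode="all"``, the default) or the single cell at the
range midpoint (``range_mode="midpoint"``); an empty range selection falls
back to the cell nearest the midpoint.

Group comparison reuses the cohort-weighted ANOVA / Tukey-Kramer machinery
with the sample set as the unit and cohort size as the weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import GROUPS, DataValidationError, SampleSet, UVBRaster, CELL_SIZE
from .groupstats import (
    AnovaResult,
    WeightedGroups,
    tukey_kramer,
    weighted_anova,
)

logger = logging.getLogger(__name__)


def cell_center(coord: float) -> float:
    """Center of the half-degree cell containing ``coord``.

    A coordinate exactly on a boundary belongs to the cell above it
    (north/east), so center(43.0) == 43.25.
    """
    return math.floor(coord / CELL_SIZE + 1e-9) * CELL_SIZE + CELL_SIZE / 2.0


def _centers_in_range(lo: float, hi: float) -> list[float]:
    first = math.ceil((lo - CELL_SIZE / 2.0) / CELL_SIZE - 1e-9)
    out = []
    c = first * CELL_SIZE + CELL_SIZE / 2.0
    while c <= hi + 1e-9:
        if c >= lo - 1e-9:
            out.append(round(c, 6))
        c += CELL_SIZE
    return out


def cells_for_location(
    sample_set: SampleSet, range_mode: str = "all"
) -> list[tuple[float, float]] | None:
    """Half-degree cells covering a sample set's location.

    Returns None (with a logged warning) for sets lacking coordinates, which
    are excluded from UVB aggregation only.
    """
    if range_mode not in ("all", "midpoint"):
        raise DataValidationError(f"unknown range_mode {range_mode!r}")
    if not sample_set.has_coordinates:
        logger.warning(
            "sample set %s has no coordinates; excluded from UVB aggregation",
            sample_set.id,
        )
        return None
    lon_c = round(cell_center(sample_set.lon), 6)
    if sample_set.lat_min == sample_set.lat_max or range_mode == "midpoint":
        lat = (
            sample_set.lat_mid
            if range_mode == "midpoint"
            else sample_set.lat_min
        )
        return [(round(cell_center(lat), 6), lon_c)]
    lats = _centers_in_range(sample_set.lat_min, sample_set.lat_max)
    if not lats:  # degenerate: range narrower than the grid spacing
        lats = [round(cell_center(sample_set.lat_mid), 6)]
    return [(lat, lon_c) for lat in lats]


def mean_annual_uvb(
    cells: Sequence[tuple[float, float]], raster: UVBRaster
) -> float:
    """Arithmetic mean of all daily values across the selected cells.

    Cells absent from the raster contribute nothing; returns NaN when no
    selected cell holds data.
    """
    chunks = [c for lat, lon in cells if (c := raster.values(lat, lon)).size]
    if not chunks:
        return float("nan")
    return float(np.concatenate(chunks).mean())


@dataclass
class UVBSummary:
    """Per-set and per-group mean annual 305 nm irradiance plus comparisons."""

    per_set: pd.DataFrame  # index set id; columns group, n, n_cells, mean_uvb
    group_means: dict[str, float]           # unweighted mean of member sets
    group_means_weighted: dict[str, float]  # cohort-size-weighted
    anova: AnovaResult | None
    pairwise_p: dict[tuple[str, str], float]
    range_mode: str
    period_label: str = "1978-1993"


def summarize_uvb(
    sets: Sequence[SampleSet],
    raster: UVBRaster,
    range_mode: str = "all",
) -> UVBSummary:
    """Mean annual UVB per sample set and per geographic group."""
    rows = []
    for s in sets:
        cells = cells_for_location(s, range_mode=range_mode)
        if cells is None:
            rows.append((s.id, s.group, s.n, 0, float("nan")))
            continue
        rows.append((s.id, s.group, s.n, len(cells), mean_annual_uvb(cells, raster)))
    per_set = pd.DataFrame(
        rows, columns=["id", "group", "n", "n_cells", "mean_uvb"]
    ).set_index("id")
    located = per_set.dropna(subset=["mean_uvb"])
    group_means: dict[str, float] = {}
    group_means_weighted: dict[str, float] = {}
    for g in GROUPS:
        sub = located[located.group == g]
        if len(sub):
            group_means[g] = float(sub.mean_uvb.mean())
            group_means_weighted[g] = float(
                np.average(sub.mean_uvb, weights=sub.n)
            )
    anova_res: AnovaResult | None = None
    pairwise: dict[tuple[str, str], float] = {}
    usable_groups = [
        g for g in GROUPS if (located.group == g).sum() >= 2
    ]
    sub = located[located.group.isin(usable_groups)]
    if len(usable_groups) >= 2 and len(sub) > len(usable_groups):
        wg = WeightedGroups(
            y=sub.mean_uvb.to_numpy(),
            w=sub.n.to_numpy(dtype=float),
            groups=sub.group.to_numpy(dtype=object),
        )
        anova_res = weighted_anova(wg)
        pairwise = tukey_kramer(anova_res)
    else:
        logger.warning("fewer than two groups with >= 2 located sets; comparisons missing")
    return UVBSummary(
        per_set=per_set,
        group_means=group_means,
        group_means_weighted=group_means_weighted,
        anova=anova_res,
        pairwise_p=pairwise,
        range_mode=range_mode,
    )


def uvb_ascending_order(summary: UVBSummary) -> tuple[str, ...]:
    """Groups ordered by ascending mean annual UVB (for cline classification)."""
    known = [g for g in GROUPS if g in summary.group_means]
    return tuple(sorted(known, key=summary.group_means.get))
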