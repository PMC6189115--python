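"""Annual snowmelt dates from weekly per-cell snow-cover series.

A grid cell's snowmelt date is the day after its continuous winter snow-cover
period.  Coverage arrives as an ordered weekly series of booleans; the
"continuous snow cover period" is resolved as the maximal run of consecutive
covered weeks containing a winter anchor day (default 1 March, day-of-year
60).  If the anchor week is uncovered the first covered run after the anchor
is used; if snow disappeared before the anchor, the last run before it.
Weekly granularity forces a day convention: snowmelt is the day after the
last calendar day of the run's final week.

Site-level dates are plain means over a chosen set of cells (e.g. the two
cells closest to a field site).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR_DOY = 60  # 1 March in a non-leap year


class NoSnowSeasonError(ValueError):
    """Raised when a cell-year has no snow-covered week at all."""


@dataclass(frozen=True)
class SnowSeries:
    """Weekly snow-cover series for one grid cell and year.

    ``weeks`` is an ordered list of ``(week_start_doy, covered)`` with
    consecutive weeks 7 days apart.
    """

    cell_id: str
    year: int
    weeks: tuple

    def __post_init__(self):
        starts = [w[0] for w in self.weeks]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("weeks must be sorted and non-overlapping")


def _runs(weeks):
    """Maximal runs of consecutive covered weeks, as (first_start, last_start)."""
    runs = []
    current = None
    prev_start = None
    for start, covered in weeks:
        covered = bool(covered)
        if covered:
            if current is not None and prev_start is not None and start == prev_start + 7:
                current = (current[0], start)
            else:
                if current is not None:
                    runs.append(current)
                current = (start, start)
        else:
            if current is not None:
                runs.append(current)
                current = None
        prev_start = start
    if current is not None:
        runs.append(current)
    return runs


def cell_snowmelt(series: SnowSeries, anchor_doy: int = DEFAULT_ANCHOR_DOY) -> int:
    """Snowmelt day-of-year for one cell-year.

    Returns the day after the last day of the anchored covered run.  If the
    run extends to the end of the series the melt was not observed; the
    day after the last covered day is still returned, with a warning
    (right-censored estimate).
    """
    runs = _runs(series.weeks)
    if not runs:
        raise NoSnowSeasonError(
            f"cell {series.cell_id} year {series.year}: no snow-covered week"
        )
    anchored = None
    for first, last in runs:
        if first <= anchor_doy <= last + 6:           # anchor inside the run
            anchored = (first, last)
            break
    if anchored is None:                               # first run after anchor
        after = [r for r in runs if r[0] > anchor_doy]
        anchored = after[0] if after else runs[-1]     # else last run before it
    melt = anchored[1] + 7                             # day after run's final week
    last_start = series.weeks[-1][0]
    if anchored[1] == last_start:
        warnings.warn(
            f"cell {series.cell_id} year {series.year}: snow covered to end of "
            "series; melt date right-censored",
            stacklevel=2,
        )
    return int(melt)


def site_snowmelt(cell_dates: dict, cells: list) -> float:
    """Mean snowmelt date over the requested cells for one year.

    ``cell_dates`` maps cell_id -> day-of-year.  Cells with no date are
    dropped with a warning; at least one must remain.
    """
    present = [cell_dates[c] for c in cells if c in cell_dates and cell_dates[c] is not None]
    missing = [c for c in cells if c not in cell_dates or cell_dates[c] is None]
    if missing:
        logger.warning("site mean: dropping cells with no snowmelt date: %s", missing)
    if not present:
        raise NoSnowSeasonError("no requested cell has a snowmelt date")
    return float(np.mean(present))


def snowmelt_table(snow: pd.DataFrame, anchor_doy: int = DEFAULT_ANCHOR_DOY,
                   site_cells: list | None = None) -> pd.DataFrame:
    """Per-cell (and optional site-mean) snowmelt dates from a snow table.

    ``snow`` has columns cell_id, year, week_start_doy, covered (0/1), one
    row per cell-week.  Returns a table with columns year, cell_id,
    snowmelt_doy plus, when ``site_cells`` is given, rows with
    cell_id == "site" holding the mean over those cells.
    """
    out = []
    for (cell, year), grp in snow.groupby(["cell_id", "year"], sort=True):
        grp = grp.sort_values("week_start_doy")
        series = SnowSeries(
            cell_id=str(cell), year=int(year),
            weeks=tuple(zip(grp["week_start_doy"].astype(int), grp["covered"].astype(int))),
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                doy = cell_snowmelt(series, anchor_doy)
        except NoSnowSeasonError:
            logger.warning("cell %s year %s: no snow season", cell, year)
            continue
        out.append({"year": int(year), "cell_id": str(cell), "snowmelt_doy": doy})
    table = pd.DataFrame(out)
    if site_cells is not None and len(table):
        rows = []
        for year, grp in table.groupby("year"):
            dates = dict(zip(grp["cell_id"], grp["snowmelt_doy"]))
            rows.append({"year": int(year), "cell_id": "site",
                         "snowmelt_doy": site_snowmelt(dates, site_cells)})
        table = pd.concat([table, pd.DataFrame(rows)], ignore_index=True)
    return table
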