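"""Phytotoxic ozone dose (POD) accumulation.

The dose metric is POD3IAM: stomatal ozone flux above a threshold of
3 nmol m-2 s-1, integrated over time, in mmol m-2.  The primary input is a
cube of *daily* POD increments (mmol m-2 d-1) as produced by a chemical
transport model with an embedded stomatal-conductance scheme; a convenience
path integrates hourly stomatal flux (nmol m-2 s-1) over the threshold.
Seasonal dose is the 90-day sum before harvest, on fixed Julian day-of-year
windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "FluxCube",
    "SeasonWindow",
    "PODField",
    "hourly_to_daily_pod",
    "accumulate_pod",
    "season_presets",
    "POD_THRESHOLD_DEFAULT",
]

#: default stomatal-flux threshold, nmol m-2 s-1 (the "3" in POD3)
POD_THRESHOLD_DEFAULT = 3.0


@dataclass(frozen=True)
class SeasonWindow:
    """Inclusive Julian day-of-year accumulation window."""

    name: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_day <= self.end_day <= 366):
            raise ValueError("require 1 <= start_day <= end_day <= 366")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1

    def days(self) -> np.ndarray:
        return np.arange(self.start_day, self.end_day + 1)


def season_presets() -> dict[str, SeasonWindow]:
    """The three 90-day harvest-anchored windows used for Ugandan beans.

    Season 1 (bimodal sub-regions) runs April–June, season 2 mid-September to
    mid-December; the unimodal Karamoja season runs July–September.
    """
    return {
        "season1": SeasonWindow("season1", 91, 180),
        "season2": SeasonWindow("season2", 257, 346),
        "karamoja": SeasonWindow("karamoja", 182, 271),
    }


@dataclass
class FluxCube:
    """Gridded ozone flux/dose time series.

    ``mode`` is ``"daily"`` (values are POD increments, mmol m-2 d-1) or
    ``"hourly"`` (values are stomatal flux, nmol m-2 s-1).  ``time`` is a
    DatetimeIndex aligned with ``values`` along axis 0; axes 1, 2 are the
    grid's (row, col).
    """

    grid: GridSpec
    time: pd.DatetimeIndex
    values: np.ndarray
    mode: str = "daily"

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("daily", "hourly"):
            raise ValueError("mode must be 'daily' or 'hourly'")
        if self.values.shape != (len(self.time),) + self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(time={len(self.time)},) + grid {self.grid.shape}"
            )
        if len(self.time) and not self.time.is_monotonic_increasing:
            raise ValueError("time axis must be strictly increasing")
        if self.time.has_duplicates:
            raise ValueError("time axis has duplicate stamps")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValueError("flux/dose values must be non-negative")

    @property
    def units(self) -> str:
        return "mmol m-2 d-1" if self.mode == "daily" else "nmol m-2 s-1"


@dataclass
class PODField:
    """Accumulated seasonal dose, mmol m-2, with the window it came from."""

    grid: GridSpec
    window: SeasonWindow
    values: np.ndarray  # NaN = missing
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValueError("POD must be non-negative")


def hourly_to_daily_pod(cube: FluxCube, threshold: float = POD_THRESHOLD_DEFAULT) -> FluxCube:
    """Integrate hourly stomatal flux over the threshold into daily increments.

    Per cell and calendar day the increment is
    ``sum_hours max(flux - threshold, 0) * 3600 * 1e-6`` in mmol m-2 d-1
    (nmol -> mmol is the 1e-6; each hourly flux sample stands for 3600 s).
    Days on which every hour is missing come out missing; partially missing
    days integrate the hours that are present.
    """
    if cube.mode != "hourly":
        raise ValueError("hourly_to_daily_pod requires an hourly-mode cube")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    over = np.clip(cube.values - threshold, 0.0, None) * 3600e-6
    frame = pd.DataFrame(
        over.reshape(len(cube.time), -1), index=cube.time.normalize()
    )
    valid = frame.notna().groupby(level=0).sum()
    daily = frame.groupby(level=0).sum(min_count=1)
    daily = daily.where(valid > 0)
    days = daily.index
    values = daily.to_numpy().reshape((len(days),) + cube.grid.shape)
    return FluxCube(grid=cube.grid, time=pd.DatetimeIndex(days), values=values,
                    mode="daily")


def accumulate_pod(
    cube: FluxCube,
    window: SeasonWindow,
    year: int,
    missing_policy: str = "error",
) -> PODField:
    """Sum daily POD increments over a seasonal window for one year.

    ``missing_policy`` governs cells/days with missing data inside the window:
    ``"error"`` refuses if any window day is absent from the cube (the loud
    default), ``"skip"`` sums the days present, ``"scale"`` additionally
    rescales each cell's partial sum by 90-day-equivalent
    ``window.n_days / n_valid_days``.
    """
    if cube.mode != "daily":
        raise ValueError("accumulate_pod requires a daily-mode cube")
    if missing_policy not in ("error", "skip", "scale"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    doy = cube.time.dayofyear.to_numpy()
    in_window = (cube.time.year.to_numpy() == year) & \
        (doy >= window.start_day) & (doy <= window.end_day)
    present_days = set(doy[in_window].tolist())
    wanted = set(window.days().tolist())
    absent = sorted(wanted - present_days)
    if absent and missing_policy == "error":
        raise ValueError(
            f"window {window.name!r} of {year} is missing {len(absent)} day(s) "
            f"from the cube: days of year {absent[:10]}"
            + ("..." if len(absent) > 10 else "")
        )
    sel = cube.values[in_window]
    if sel.size == 0:
        raise ValueError(f"cube has no data in window {window.name!r} of {year}")
    valid = np.isfinite(sel)
    n_valid = valid.sum(axis=0)
    total = np.where(valid, sel, 0.0).sum(axis=0)
    if missing_policy == "error" and not valid.all():
        n_bad = int((~valid).any(axis=0).sum())
        raise ValueError(
            f"{n_bad} cell(s) have missing days inside window {window.name!r}; "
            "use missing_policy='skip' or 'scale' to accept partial coverage"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        if missing_policy == "scale":
            total = np.where(n_valid > 0, total * window.n_days / n_valid, np.nan)
        else:
            total = np.where(n_valid > 0, total, np.nan)
    return PODField(grid=cube.grid, window=window, values=total, year=year)
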