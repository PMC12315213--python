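"""Time-slice and ensemble bookkeeping shared by every product.

Annual per-member statistics are reduced in a fixed two-stage order:
first a within-slice statistic per ensemble member (mean over the years
of the slice, by default), then a central value across members (the
median, following the published convention for multi-model summaries)
with the member min/max retained as spread.  Change maps difference two
such summaries per cell, absolutely or proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import AlignmentError, CoverageError, InputError


@dataclass(frozen=True)
class TimeSliceSummary:
    """Cross-member summary of one statistic at one cell over one slice."""

    cell_id: str
    scenario_id: str
    slice_years: tuple[int, int]
    statistic_name: str
    member_values: dict[int, float]  # member_id -> within-slice statistic
    central: float  # median across members by default
    spread: tuple[float, float]  # (min, max) across members


def summarize(
    annual: pd.DataFrame,
    slice_years: tuple[int, int],
    statistic: Literal["mean", "median", "sum"] = "mean",
    central: Literal["median", "mean"] = "median",
    statistic_name: str | None = None,
    scenario_id: str = "unknown",
    value_column: str = "value",
) -> list[TimeSliceSummary]:
    """Two-stage reduction of tidy annual values.

    ``annual`` needs columns ``cell_id``, ``member_id``, ``year`` and the
    value column.  Every member must cover every year of the slice at
    every cell; a hole raises a coverage error naming the member and the
    missing years.
    """
    start, end = slice_years
    if end - start + 1 < 2:
        raise InputError("slice must span at least 2 years")
    required = {"cell_id", "member_id", "year", value_column}
    missing_cols = required - set(annual.columns)
    if missing_cols:
        raise InputError(f"annual frame missing columns: {sorted(missing_cols)}")
    sliced = annual[(annual["year"] >= start) & (annual["year"] <= end)]
    want_years = set(range(start, end + 1))

    out: list[TimeSliceSummary] = []
    for cell_id, cell_df in sliced.groupby("cell_id", sort=True):
        member_values: dict[int, float] = {}
        for member_id, m_df in cell_df.groupby("member_id", sort=True):
            have = set(m_df["year"])
            holes = sorted(want_years - have)
            if holes:
                raise CoverageError(
                    f"member {member_id} at cell {cell_id} is missing years "
                    f"{holes}"
                )
            vals = m_df[value_column].to_numpy(float)
            member_values[int(member_id)] = float(
                getattr(np, statistic)(vals)
            )
        member_arr = np.array(list(member_values.values()))
        out.append(
            TimeSliceSummary(
                cell_id=str(cell_id),
                scenario_id=scenario_id,
                slice_years=slice_years,
                statistic_name=statistic_name or f"{statistic}_{value_column}",
                member_values=member_values,
                central=float(getattr(np, central)(member_arr)),
                spread=(float(member_arr.min()), float(member_arr.max())),
            )
        )
    if not out:
        raise InputError(f"no annual values fall inside slice {slice_years}")
    return out


def summaries_to_frame(summaries: list[TimeSliceSummary]) -> pd.DataFrame:
    rows = [
        dict(
            cell_id=s.cell_id,
            scenario_id=s.scenario_id,
            slice_start=s.slice_years[0],
            slice_end=s.slice_years[1],
            statistic=s.statistic_name,
            central=s.central,
            spread_min=s.spread[0],
            spread_max=s.spread[1],
            n_members=len(s.member_values),
        )
        for s in summaries
    ]
    return pd.DataFrame(rows)


def change_map(
    baseline: list[TimeSliceSummary],
    future: list[TimeSliceSummary],
    mode: Literal["absolute", "proportional"] = "absolute",
) -> pd.DataFrame:
    """Per-cell change of the central value between two slices.

    Absolute mode is ``future - baseline``; proportional mode is
    ``100 (future - baseline) / baseline`` %, with zero-baseline cells
    flagged undefined (NaN + ``undefined`` column) rather than infinite.
    """
    b = {s.cell_id: s for s in baseline}
    f = {s.cell_id: s for s in future}
    if set(b) != set(f):
        diff = sorted(set(b).symmetric_difference(f))
        raise AlignmentError(f"cells differ between baseline and future: {diff}")
    stats_b = {s.statistic_name for s in baseline}
    stats_f = {s.statistic_name for s in future}
    if stats_b != stats_f or len(stats_b) != 1:
        raise InputError(
            f"summaries must share one statistic (got {stats_b} vs {stats_f})"
        )

    rows = []
    for cell_id in sorted(b):
        base, fut = b[cell_id].central, f[cell_id].central
        undefined = False
        if mode == "absolute":
            change = fut - base
        elif mode == "proportional":
            if base == 0.0:
                change, undefined = float("nan"), True
            else:
                change = 100.0 * (fut - base) / base
        else:
            raise InputError(f"unknown change mode {mode!r}")
        rows.append(
            dict(
                cell_id=cell_id,
                baseline=base,
                future=fut,
                change=change,
                undefined=undefined,
            )
        )
    return pd.DataFrame(rows).set_index("cell_id")
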