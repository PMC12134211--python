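"""Per-lineage fluorescence traces from segmented, tracked cells.

Segmentation and tracking are consumed as input: a cell-observation
table with one row per cell per fluorescence frame, carrying the raw
total intensity inside the cell outline, the cell area, parent links,
and the mean fluorescence density of the cell's immediate
surroundings.  This module background-subtracts, sums each founder's
descendants frame by frame into a single lineage trace (two daughters,
four granddaughters, ... summed per time point), and applies the
study's inclusion filters: lineages must exist at the medium swap and
be tracked to the end, and their in-cell density must be on average at
least 3-fold above the surroundings (rejecting traps contaminated by
bleed-through from bright neighbours).

Times are stored relative to the chloramphenicol swap (t = 0 at swap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LineageTrace",
    "total_cell_fluorescence",
    "aggregate_lineage",
    "aggregate_lineages",
    "bleed_filter",
    "filter_lineages",
]

REQUIRED_COLUMNS = (
    "time_min",
    "trap_id",
    "lineage_id",
    "cell_id",
    "parent_id",
    "area_px",
    "raw_total_intensity",
    "surroundings_mean_density",
)


@dataclass
class LineageTrace:
    """Background-subtracted trace of one lineage.

    ``times`` are minutes relative to the swap; ``fluorescence`` is the
    descendant-summed, background-subtracted total; ``density`` is
    fluorescence / area.  ``pre_chl_mean`` is the mean total
    fluorescence over the last three frames before the swap (NaN when
    fewer than three pre-swap frames exist).
    """

    lineage_id: str
    trap_id: int
    times: np.ndarray
    fluorescence: np.ndarray
    area: np.ndarray
    surroundings_density: np.ndarray

    @property
    def density(self) -> np.ndarray:
        return self.fluorescence / self.area

    @property
    def pre_chl_mean(self) -> float:
        pre = self.times < 0
        if pre.sum() < 3:
            return float("nan")
        return float(self.fluorescence[pre][-3:].mean())

    def post_chl(self) -> tuple[np.ndarray, np.ndarray]:
        post = self.times >= 0
        return self.times[post], self.fluorescence[post]


def total_cell_fluorescence(pixels: np.ndarray, bg_mean: float) -> float:
    """Sum of background-subtracted pixel intensities inside a cell
    outline: sum(pixel - bg_mean), i.e. sum(pixel) - bg_mean * area."""
    if bg_mean < 0:
        raise ValueError("bg_mean must be >= 0")
    px = np.asarray(pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty cell mask")
    return float(px.sum() - bg_mean * px.size)


def _founder_descendants(cells: pd.DataFrame) -> dict[str, set[str]]:
    """Map each founder cell_id to the set of its descendant cell_ids
    (itself included), following parent links. Raises on broken links."""
    ids = set(cells.cell_id)
    parent = dict(zip(cells.cell_id, cells.parent_id))
    broken = [c for c, p in parent.items() if p not in ("", None) and not pd.isna(p) and p not in ids]
    if broken:
        raise ValueError(f"broken parent links for cell_id(s): {sorted(broken)[:10]}")
    root: dict[str, str] = {}

    def find_root(c: str) -> str:
        chain = []
        while True:
            p = parent[c]
            if p in ("", None) or pd.isna(p):
                break
            chain.append(c)
            c = p
        for x in chain:
            root[x] = c
        return c

    out: dict[str, set[str]] = {}
    for c in ids:
        r = root.get(c) or find_root(c)
        out.setdefault(r, set()).add(c)
        out[r].add(r)
    return out


def aggregate_lineage(cells: pd.DataFrame, bg_mean: float = 0.0) -> LineageTrace:
    """Aggregate one lineage's cell observations into a single trace.

    Expects observations of exactly one founder and its descendants;
    per frame, areas and background-subtracted total fluorescence of
    all living descendants are summed.
    """
    _check_columns(cells)
    if cells.lineage_id.nunique() != 1:
        raise ValueError("aggregate_lineage expects a single lineage")
    desc = _founder_descendants(cells)
    if len(desc) != 1:
        raise ValueError(f"expected one founder, found {len(desc)}")
    lid = cells.lineage_id.iloc[0]
    trap = int(cells.trap_id.iloc[0])
    fluor = cells.raw_total_intensity - bg_mean * cells.area_px
    g = (
        cells.assign(_fluor=fluor)
        .groupby("time_min", sort=True)
        .agg(
            fluorescence=("_fluor", "sum"),
            area=("area_px", "sum"),
            surroundings=("surroundings_mean_density", "mean"),
        )
    )
    return LineageTrace(
        lineage_id=lid,
        trap_id=trap,
        times=g.index.to_numpy(dtype=float),
        fluorescence=g.fluorescence.to_numpy(),
        area=g.area.to_numpy(),
        surroundings_density=g.surroundings.to_numpy(),
    )


def aggregate_lineages(cells: pd.DataFrame, bg_mean: float = 0.0) -> list[LineageTrace]:
    """Aggregate every lineage in a cell-observation table."""
    _check_columns(cells)
    return [
        aggregate_lineage(sub, bg_mean=bg_mean)
        for _, sub in cells.groupby("lineage_id", sort=True)
    ]


def bleed_filter(trace: LineageTrace, min_ratio: float = 3.0) -> bool:
    """Include a lineage iff its in-cell density is on average at least
    ``min_ratio``-fold above its immediate surroundings.

    Frames with zero surroundings density but nonzero cell density
    count as infinitely clean; a lineage whose surroundings are always
    zero is included.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = trace.density / trace.surroundings_density
    ratio = ratio[~np.isnan(ratio)]  # 0/0 frames carry no information
    if ratio.size == 0:
        return True
    return bool(np.mean(ratio) >= min_ratio)


def filter_lineages(
    traces: list[LineageTrace],
    t_chl: float = 0.0,
    t_end: float | None = None,
    end_tolerance: float | None = None,
) -> list[LineageTrace]:
    """Keep lineages that existed at the swap and were tracked to the end.

    A lineage qualifies if it has an observation at or before ``t_chl``
    and its last observation reaches ``t_end`` (within ``end_tolerance``,
    defaulting to the trace's own sampling interval). ``t_end`` defaults
    to the latest time observed across all traces.
    """
    if not traces:
        return []
    if t_end is None:
        t_end = max(t.times.max() for t in traces)
    if t_chl >= t_end:
        raise ValueError("t_chl must be before t_end")
    out = []
    for t in traces:
        tol = end_tolerance
        if tol is None:
            tol = float(np.min(np.diff(t.times))) if t.times.size > 1 else 0.0
        if t.times.min() <= t_chl and t.times.max() >= t_end - tol / 2:
            out.append(t)
    return out


def _check_columns(cells: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
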