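"""Topographic maps of band power over a multichannel skull array.

Per-channel dB values are interpolated over the planar electrode layout
with a thin-plate-spline radial basis (exact at electrode sites and exact
for planar fields); the map is masked outside the convex hull of the
electrodes — no extrapolation beyond the array — and clipped to the range
of the channel values so the interpolant cannot invent extrema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay, QhullError

from .signal_io import ChannelLayout

__all__ = ["TopoMap", "interpolate_map", "band_maps"]

logger = logging.getLogger(__name__)


@dataclass
class TopoMap:
    grid: np.ndarray        # (resolution, resolution) dB, NaN outside hull
    x: np.ndarray           # mm, grid columns
    y: np.ndarray           # mm, grid rows
    mask: np.ndarray        # True inside the electrode hull
    channel_values: dict[str, float]
    band: str | None = None
    group: str | None = None

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.grid, index=self.y, columns=self.x).to_csv(
            path, sep="\t", na_rep="nan")


def interpolate_map(channel_values: dict[str, float], layout: ChannelLayout,
                    resolution: int = 64, band: str | None = None,
                    group: str | None = None) -> TopoMap:
    """Interpolate per-channel values over the array plane.

    Requires at least 3 non-collinear electrodes. Values are reproduced
    exactly (to numerical precision) at electrode coordinates; the output
    is clipped to [min, max] of the inputs with a log message when the
    spline overshoots between electrodes.
    """
    ids = list(channel_values)
    if len(ids) < 3:
        raise ValueError("need at least 3 channels to interpolate a map")
    pts = layout.coords(ids)
    vals = np.array([channel_values[c] for c in ids], dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError(f"degenerate (collinear?) electrode layout: {e}") from None

    rbf = RBFInterpolator(pts, vals, kernel="thin_plate_spline")
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), resolution)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), resolution)
    mx, my = np.meshgrid(gx, gy)
    flat = np.column_stack([mx.ravel(), my.ravel()])
    inside = tri.find_simplex(flat) >= 0
    grid = np.full(flat.shape[0], np.nan)
    grid[inside] = rbf(flat[inside])
    grid = grid.reshape(resolution, resolution)
    lo, hi = vals.min(), vals.max()
    over = np.nansum((grid < lo - 1e-9) | (grid > hi + 1e-9))
    if over:
        logger.info("clipping %d interpolated points outside [%g, %g] dB",
                    over, lo, hi)
        grid = np.clip(grid, lo, hi)
    return TopoMap(grid, gx, gy, inside.reshape(resolution, resolution),
                   dict(channel_values), band, group)


def band_maps(table: pd.DataFrame, layout: ChannelLayout,
              resolution: int = 64) -> dict[tuple[str, str], TopoMap]:
    """One topographic map per (band, group).

    ``table`` is tidy with columns animal_id, group, channel_id, band,
    value (dB); channel values are per-animal means averaged across the
    animals of each group.
    """
    need = {"animal_id", "group", "channel_id", "band", "value"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"band table missing columns {sorted(missing)}")
    unknown = set(table["channel_id"]) - set(layout.positions)
    if unknown:
        raise ValueError(f"channels missing from layout: {sorted(unknown)}")
    out = {}
    per_animal = table.groupby(
        ["group", "band", "channel_id", "animal_id"])["value"].mean()
    per_channel = per_animal.groupby(level=["group", "band", "channel_id"]).mean()
    for (group, band), sub in per_channel.groupby(level=["group", "band"]):
        values = {cid: float(v) for (_, _, cid), v in sub.items()}
        out[(band, group)] = interpolate_map(values, layout, resolution,
                                             band=band, group=group)
    return out
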