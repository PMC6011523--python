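"""Central places, diel displacement, and activity-seascape fusion.

The central place is the daytime core area of a central-place-foraging
shark, defined either as the 50 % contour of the planar utilization
distribution or as the receiver where >= 80 % of detections occurred
plus a 1000-m buffer.  The activity seascape weights each space-time
voxel of the movement UD by the diel probability of the high-activity
HMM state at that voxel's time of day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .hmm import ActivityCurve, cyclic_interp
from .movement import (
    DetectionSeries,
    PlanarUD,
    ReceiverArray,
    SpaceTimeUD,
    VoxelGrid,
    ud_contour,
)

__all__ = [
    "CentralPlace",
    "DisplacementSeries",
    "ActivitySeascape",
    "central_place_udcontour",
    "central_place_receiver",
    "displacement_series",
    "average_displacement",
    "fuse_activity",
    "group_volume",
    "min_detection_filter",
]


@dataclass
class CentralPlace:
    """Core daytime region: a UD-contour cell set or a buffered disc."""

    method: str  # "ud_contour" | "receiver_buffer"
    individual_id: str | None = None
    grid: VoxelGrid | None = None
    cells: np.ndarray | None = None  # boolean (nx, ny) mask
    center: tuple[float, float] | None = None
    radius: float | None = None
    below_threshold: bool = False
    receiver_id: str | None = None

    def __post_init__(self):
        if self.method == "ud_contour":
            if self.cells is None or self.grid is None or not self.cells.any():
                raise ValueError("ud_contour central place needs a non-empty cell mask")
        elif self.method == "receiver_buffer":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise ValueError("receiver_buffer central place needs a centre and radius")
        else:
            raise ValueError(f"unknown central-place method: {self.method}")

    def distance_to(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Euclidean distance (m) to the region boundary; 0 inside."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if self.method == "receiver_buffer":
            d = np.hypot(x - self.center[0], y - self.center[1]) - self.radius
            return np.maximum(d, 0.0)
        # distance to the nearest member-cell rectangle
        g = self.grid
        ii, jj = np.nonzero(self.cells)
        xlo = g.x0 + g.cell * ii
        ylo = g.y0 + g.cell * jj
        # clamp each point into each rectangle, take the minimum distance
        cx = np.clip(x[:, None], xlo[None, :], xlo[None, :] + g.cell)
        cy = np.clip(y[:, None], ylo[None, :], ylo[None, :] + g.cell)
        d = np.hypot(x[:, None] - cx, y[:, None] - cy).min(axis=1)
        return d

    def to_geojson_dict(self) -> dict:
        """GeoJSON-style description in planar coordinates."""
        props = {
            "method": self.method,
            "individual_id": self.individual_id,
            "below_threshold": self.below_threshold,
        }
        if self.method == "receiver_buffer":
            geom = {
                "type": "Point",
                "coordinates": list(self.center),
                "buffer_radius_m": self.radius,
            }
            props["receiver_id"] = self.receiver_id
        else:
            g = self.grid
            ii, jj = np.nonzero(self.cells)
            polys = [
                [
                    [
                        [g.x0 + g.cell * i, g.y0 + g.cell * j],
                        [g.x0 + g.cell * (i + 1), g.y0 + g.cell * j],
                        [g.x0 + g.cell * (i + 1), g.y0 + g.cell * (j + 1)],
                        [g.x0 + g.cell * i, g.y0 + g.cell * (j + 1)],
                        [g.x0 + g.cell * i, g.y0 + g.cell * j],
                    ]
                ]
                for i, j in zip(ii.tolist(), jj.tolist())
            ]
            geom = {"type": "MultiPolygon", "coordinates": polys}
        return {"type": "Feature", "geometry": geom, "properties": props}


@dataclass
class DisplacementSeries:
    """Hour-of-day bins -> mean distance from the central place."""

    hours: np.ndarray  # bin start hours
    mean_m: np.ndarray  # NaN where the bin holds no detections
    n: np.ndarray

    def __post_init__(self):
        self.hours = np.asarray(self.hours, dtype=float)
        self.mean_m = np.asarray(self.mean_m, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (self.hours.shape == self.mean_m.shape == self.n.shape):
            raise ValueError("hours, mean_m and n must align")
        if np.any(self.mean_m[np.isfinite(self.mean_m)] < 0):
            raise ValueError("displacement distances must be non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame({"hour": self.hours, "mean_m": self.mean_m, "n": self.n}).to_csv(
            path, index=False
        )


@dataclass
class ActivitySeascape:
    """Space-time UD weighted by P(high-activity state) per time bin."""

    grid: VoxelGrid
    values: np.ndarray
    p_state2: np.ndarray  # per time bin, the applied weights

    def to_xarray(self) -> "xr.DataArray":
        g = self.grid
        da = xr.DataArray(
            self.values,
            dims=("x", "y", "time_of_day"),
            coords={
                "x": g.x_centers,
                "y": g.y_centers,
                "time_of_day": g.tbin_centers_hours,
            },
            name="activity_seascape",
            attrs={
                "cell_size_m": g.cell,
                "time_bin_minutes": g.tbin_minutes,
                "fused_with": "P(state 2) diel activity curve",
            },
        )
        return da

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")


def central_place_udcontour(planar: PlanarUD, level: float = 0.5, individual_id=None) -> CentralPlace:
    """Central place as the ``level`` (default 50 %) UD contour."""
    mask = ud_contour(planar, level)
    return CentralPlace(
        method="ud_contour", individual_id=individual_id, grid=planar.grid, cells=mask
    )


def central_place_receiver(
    det: DetectionSeries,
    array: ReceiverArray,
    buffer: float = 1000.0,
    share_threshold: float = 0.8,
) -> CentralPlace:
    """Central place as the dominant receiver plus a buffer disc.

    The receiver with the largest detection share wins (lexicographic id
    tie-break); the result is flagged ``below_threshold`` when that
    share is strictly below ``share_threshold`` (the 80 % rule is
    inclusive at exactly 0.8).
    """
    if len(det) == 0:
        raise ValueError("empty detection series")
    if det.receiver_id is None:
        raise ValueError("detections carry no receiver ids")
    ids, counts = np.unique(det.receiver_id.astype(str), return_counts=True)
    share = counts / counts.sum()
    best_share = share.max()
    candidates = sorted(ids[share == best_share])
    winner = candidates[0]
    pos = {str(r): (float(x), float(y)) for r, x, y in zip(array.ids, array.x, array.y)}
    if winner not in pos:
        raise ValueError(f"receiver {winner!r} not present in the array")
    return CentralPlace(
        method="receiver_buffer",
        individual_id=det.individual_id,
        center=pos[winner],
        radius=buffer,
        below_threshold=bool(best_share < share_threshold),
        receiver_id=winner,
    )


def displacement_series(
    det: DetectionSeries, place: CentralPlace, bin_hours: float = 1.0
) -> DisplacementSeries:
    """Mean distance to the central place per hour-of-day bin (all days folded).

    Detections inside the region score 0; outside, the Euclidean
    distance to the region boundary.
    """
    if len(det) == 0:
        raise ValueError("empty detection series")
    if abs((24.0 / bin_hours) - round(24.0 / bin_hours)) > 1e-9:
        raise ValueError("24 h must be divisible by the bin width")
    nbins = int(round(24.0 / bin_hours))
    d = place.distance_to(det.x, det.y)
    hod = (det.timestamps / 3600.0) % 24.0
    idx = np.minimum((hod / bin_hours).astype(int), nbins - 1)
    mean = np.full(nbins, np.nan)
    n = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        sel = idx == b
        n[b] = int(sel.sum())
        if n[b]:
            mean[b] = float(d[sel].mean())
    return DisplacementSeries(hours=np.arange(nbins) * bin_hours, mean_m=mean, n=n)


def average_displacement(series: list[DisplacementSeries]) -> DisplacementSeries:
    """Unweighted mean across individuals per bin.

    A bin is missing in the average only when it is missing in every
    individual.
    """
    if not series:
        raise ValueError("need at least one displacement series")
    hours = series[0].hours
    for s in series[1:]:
        if not np.array_equal(s.hours, hours):
            raise ValueError("displacement series are on mismatched bins")
    stack = np.vstack([s.mean_m for s in series])
    ns = np.vstack([s.n for s in series])
    any_obs = np.isfinite(stack).any(axis=0)
    mean = np.full(hours.shape, np.nan)
    mean[any_obs] = np.nanmean(stack[:, any_obs], axis=0)
    return DisplacementSeries(hours=hours, mean_m=mean, n=ns.sum(axis=0))


def fuse_activity(volume: SpaceTimeUD, curve: ActivityCurve) -> ActivitySeascape:
    """Voxel-by-voxel product of the space-time UD with P(state 2).

    The activity curve is interpolated cyclically to the centres of the
    grid's time bins; no renormalization is applied, so the seascape is
    bounded above by the UD voxelwise.
    """
    if curve.hours.size == 0:
        raise ValueError("empty activity curve")
    p = np.asarray(curve.p_state2, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("activity probabilities must lie in [0, 1]")
    pbin = cyclic_interp(volume.grid.tbin_centers_hours, curve.hours, p)
    values = volume.values * pbin[None, None, :]
    return ActivitySeascape(grid=volume.grid, values=values, p_state2=pbin)


def group_volume(volumes: list[SpaceTimeUD]) -> SpaceTimeUD:
    """Unweighted voxelwise mean across individuals, renormalized."""
    if not volumes:
        raise ValueError("need at least one volume")
    grid = volumes[0].grid
    for v in volumes[1:]:
        if v.grid != grid:
            raise ValueError("volumes are on mismatched grids")
    mean = np.mean([v.values for v in volumes], axis=0)
    mean /= mean.sum()
    return SpaceTimeUD(grid=grid, values=mean)


def min_detection_filter(
    individuals: dict[str, DetectionSeries] | list[DetectionSeries], min_n: int = 100
) -> tuple[list[DetectionSeries], dict]:
    """Retain individuals with at least ``min_n`` detections (inclusive)."""
    if isinstance(individuals, dict):
        individuals = list(individuals.values())
    retained, dropped = [], {}
    for det in individuals:
        if len(det) >= min_n:
            retained.append(det)
        else:
            dropped[det.individual_id] = len(det)
    report = {
        "min_n": min_n,
        "n_input": len(individuals),
        "n_retained": len(retained),
        "dropped": dropped,
    }
    return retained, report
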