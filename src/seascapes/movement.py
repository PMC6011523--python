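"""Brownian-bridge utilization distributions from acoustic detections.

Consecutive detections of an individual (located at the coordinates of
the receiver that heard them) are linked by conditional random walks.
Between detections at ``z_a`` (time ``t_a``) and ``z_b`` (``t_b``), the
position at time fraction ``alpha`` is Gaussian per axis with

    mean = (1 - alpha) z_a + alpha z_b
    var  = alpha (1 - alpha) T sigma_m^2 + ((1 - alpha)^2 + alpha^2) sigma_loc^2

where ``T = t_b - t_a``, ``sigma_m^2`` is the Brownian motion variance
(estimated by leave-one-out maximum likelihood) and ``sigma_loc`` is the
location error standard deviation (default 300 m, the average receiver
detection range).

Bridge mass is accumulated into a diel space-time voxel grid
(default 100 m x 100 m x 10 min): timestamps are folded modulo 24 h so
months of telemetry stack onto one diel cycle, and the whole volume is
normalized to total probability mass 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import optimize
from scipy.special import ndtr

__all__ = [
    "DetectionSeries",
    "ReceiverArray",
    "VoxelGrid",
    "BridgeParams",
    "SpaceTimeUD",
    "PlanarUD",
    "estimate_motion_variance",
    "bridge_moments",
    "bridge_density",
    "spacetime_ud",
    "planar_ud",
    "ud_contour",
]

DAY_S = 86400.0


@dataclass
class ReceiverArray:
    """Omni-directional receivers with planar coordinates (m)."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    detection_range: np.ndarray | float = 300.0

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(set(self.ids)) != self.ids.size:
            raise ValueError("receiver ids must be unique")
        if self.x.shape != self.ids.shape or self.y.shape != self.ids.shape:
            raise ValueError("coordinate arrays must match ids")
        self.detection_range = np.broadcast_to(
            np.asarray(self.detection_range, dtype=float), self.ids.shape
        ).copy()
        if np.any(self.detection_range <= 0):
            raise ValueError("detection_range must be positive")

    def __len__(self) -> int:
        return self.ids.size


@dataclass
class DetectionSeries:
    """Ordered acoustic detections of one individual."""

    individual_id: str
    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    receiver_id: np.ndarray | None = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.timestamps.shape or self.y.shape != self.timestamps.shape:
            raise ValueError("coordinates must match timestamps")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.receiver_id is not None:
            self.receiver_id = np.asarray(self.receiver_id, dtype=object)
            if self.receiver_id.shape != self.timestamps.shape:
                raise ValueError("receiver_id must match timestamps")

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class VoxelGrid:
    """Half-open space-time voxel grid: x, y (m) by time of day."""

    x0: float
    y0: float
    nx: int
    ny: int
    cell: float = 100.0
    tbin_minutes: int = 10

    def __post_init__(self):
        if self.cell <= 0 or self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if (24 * 60) % self.tbin_minutes != 0:
            raise ValueError("24 h must be exactly divisible by the time bin")

    @property
    def n_tbins(self) -> int:
        return (24 * 60) // self.tbin_minutes

    @property
    def tbin_seconds(self) -> float:
        return self.tbin_minutes * 60.0

    @property
    def x_edges(self) -> np.ndarray:
        return self.x0 + self.cell * np.arange(self.nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.y0 + self.cell * np.arange(self.ny + 1)

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + self.cell * (np.arange(self.nx) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + self.cell * (np.arange(self.ny) + 0.5)

    @property
    def tbin_centers_hours(self) -> np.ndarray:
        return (np.arange(self.n_tbins) + 0.5) * self.tbin_minutes / 60.0

    @classmethod
    def from_extent(
        cls,
        xmin: float,
        xmax: float,
        ymin: float,
        ymax: float,
        cell: float = 100.0,
        tbin_minutes: int = 10,
    ) -> "VoxelGrid":
        nx = int(np.ceil((xmax - xmin) / cell))
        ny = int(np.ceil((ymax - ymin) / cell))
        return cls(x0=xmin, y0=ymin, nx=nx, ny=ny, cell=cell, tbin_minutes=tbin_minutes)


@dataclass
class BridgeParams:
    """Brownian-bridge parameters."""

    sigma_loc: float = 300.0
    sigma_m2: float = 0.1
    max_gap: float = 12 * 3600.0

    def __post_init__(self):
        if self.sigma_loc <= 0:
            raise ValueError("sigma_loc must be positive")
        if self.sigma_m2 < 0:
            raise ValueError("sigma_m2 must be non-negative")


@dataclass
class SpaceTimeUD:
    """Diel voxel volume of movement probability (total mass 1)."""

    grid: VoxelGrid
    values: np.ndarray  # (nx, ny, n_tbins)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.grid.nx, self.grid.ny, self.grid.n_tbins)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid shape {expected}")
        if np.any(self.values < 0):
            raise ValueError("voxel values must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    def to_xarray(self, name: str = "probability") -> xr.DataArray:
        g = self.grid
        return xr.DataArray(
            self.values,
            dims=("x", "y", "time_of_day"),
            coords={
                "x": g.x_centers,
                "y": g.y_centers,
                "time_of_day": g.tbin_centers_hours,
            },
            name=name,
            attrs={
                "cell_size_m": g.cell,
                "time_bin_minutes": g.tbin_minutes,
                "normalization": "whole-volume",
            },
        )

    def to_netcdf(self, path, name: str = "probability") -> None:
        # scipy backend -> plain netCDF3, no compiled netCDF4 dependency
        self.to_xarray(name).to_netcdf(path, engine="scipy")

    def slice_csv(self, path) -> None:
        da = self.to_xarray()
        da.to_dataframe().reset_index().to_csv(path, index=False)


@dataclass
class PlanarUD:
    """2-D utilization distribution on the same spatial grid."""

    grid: VoxelGrid
    values: np.ndarray  # (nx, ny)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nx, self.grid.ny):
            raise ValueError("planar UD shape does not match grid")


# ---------------------------------------------------------------------------
# motion variance (Horne-style leave-one-out ML)


def _loo_terms(det: DetectionSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per odd-indexed detection: alpha, T, squared residual per axis summed."""
    t, x, y = det.timestamps, det.x, det.y
    idx = np.arange(1, len(det) - 1, 2)
    ta, tb = t[idx - 1], t[idx + 1]
    T = tb - ta
    ok = T > 0
    idx, ta, tb, T = idx[ok], ta[ok], tb[ok], T[ok]
    alpha = (t[idx] - ta) / T
    mx = (1 - alpha) * x[idx - 1] + alpha * x[idx + 1]
    my = (1 - alpha) * y[idx - 1] + alpha * y[idx + 1]
    r2 = (x[idx] - mx) ** 2 + (y[idx] - my) ** 2
    return alpha, T, r2


def estimate_motion_variance(
    det: DetectionSeries, sigma_loc: float = 300.0, upper: float | None = None
) -> float:
    """Brownian motion variance sigma_m^2 (m^2/s) by leave-one-out ML.

    Every odd-indexed detection is predicted by the bridge joining its
    two neighbours; sigma_m^2 maximizes the product of those Gaussian
    likelihoods given the location error ``sigma_loc``.
    """
    if len(det) < 3:
        raise ValueError("need at least 3 detections to estimate sigma_m^2")
    alpha, T, r2 = _loo_terms(det)
    if alpha.size == 0:
        raise ValueError("no usable detection triples (all zero time gaps)")
    # residual error = bridge + interpolated endpoint error + the held-out
    # detection's own location error
    base = ((1 - alpha) ** 2 + alpha**2 + 1.0) * sigma_loc**2
    bridge = alpha * (1 - alpha) * T

    def nll(s2: float) -> float:
        v = bridge * s2 + base
        # 2 independent axes with common per-axis variance v
        return float(np.sum(np.log(v) + r2 / (2.0 * v)))

    if upper is None:
        scale = float(np.max(r2 / np.maximum(bridge, 1e-9)))
        upper = max(10.0 * scale, 1.0)
    res = optimize.minimize_scalar(nll, bounds=(0.0, upper), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# bridges


def bridge_moments(
    za: np.ndarray, zb: np.ndarray, ta: float, tb: float, alpha: float, params: BridgeParams
) -> tuple[np.ndarray, float]:
    """Mean (2-vector) and per-axis variance of the bridge at ``alpha``."""
    if tb <= ta:
        raise ValueError("t_b must exceed t_a")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    za = np.asarray(za, dtype=float)
    zb = np.asarray(zb, dtype=float)
    T = tb - ta
    mean = (1.0 - alpha) * za + alpha * zb
    var = alpha * (1.0 - alpha) * T * params.sigma_m2 + (
        (1.0 - alpha) ** 2 + alpha**2
    ) * params.sigma_loc**2
    return mean, float(var)


def _cell_masses_1d(mean: float, sd: float, edges: np.ndarray) -> np.ndarray:
    return np.diff(ndtr((edges - mean) / sd))


def bridge_density(
    za: np.ndarray,
    zb: np.ndarray,
    ta: float,
    tb: float,
    alpha: float,
    params: BridgeParams,
    grid: VoxelGrid,
) -> np.ndarray:
    """Cell-integrated Gaussian bridge slice on the grid's spatial cells.

    Mass per cell is the exact product of per-axis CDF differences; on a
    grid large enough to contain the density the result sums to ~1.
    """
    mean, var = bridge_moments(za, zb, ta, tb, alpha, params)
    sd = np.sqrt(var)
    px = _cell_masses_1d(mean[0], sd, grid.x_edges)
    py = _cell_masses_1d(mean[1], sd, grid.y_edges)
    return np.outer(px, py)


def _deposit(
    acc: np.ndarray, grid: VoxelGrid, mean: np.ndarray, sd: float, tbin: int, weight: float
) -> None:
    """Add a truncated (+-5 sd) Gaussian cell mass into one time slice."""
    xe, ye = grid.x_edges, grid.y_edges
    i0 = int(np.clip(np.searchsorted(xe, mean[0] - 5 * sd) - 1, 0, grid.nx))
    i1 = int(np.clip(np.searchsorted(xe, mean[0] + 5 * sd) + 1, 0, grid.nx))
    j0 = int(np.clip(np.searchsorted(ye, mean[1] - 5 * sd) - 1, 0, grid.ny))
    j1 = int(np.clip(np.searchsorted(ye, mean[1] + 5 * sd) + 1, 0, grid.ny))
    if i1 <= i0 or j1 <= j0:
        return
    px = _cell_masses_1d(mean[0], sd, xe[i0 : i1 + 1])
    py = _cell_masses_1d(mean[1], sd, ye[j0 : j1 + 1])
    acc[i0:i1, j0:j1, tbin] += weight * np.outer(px, py)


def spacetime_ud(
    det: DetectionSeries,
    grid: VoxelGrid,
    params: BridgeParams,
    per_slice_norm: bool = False,
) -> SpaceTimeUD:
    """Diel space-time utilization distribution from one detection series.

    For each consecutive detection pair with ``0 < gap <= max_gap`` the
    bridge's Gaussian slice is evaluated at the midpoint of the overlap
    with every 10-min absolute time bin the pair spans, weighted by the
    overlap duration, and accumulated into the corresponding
    time-of-day bin.  The volume is normalized to total mass 1 (or per
    time slice if ``per_slice_norm``).
    """
    if len(det) < 2:
        raise ValueError("need at least 2 detections")
    t, x, y = det.timestamps, det.x, det.y
    binsec = grid.tbin_seconds
    ntb = grid.n_tbins
    acc = np.zeros((grid.nx, grid.ny, ntb))
    n_pairs = 0
    for k in range(len(det) - 1):
        ta, tb = t[k], t[k + 1]
        gap = tb - ta
        if gap <= 0 or gap > params.max_gap:
            continue
        n_pairs += 1
        za = np.array([x[k], y[k]])
        zb = np.array([x[k + 1], y[k + 1]])
        first = int(np.floor(ta / binsec))
        last = int(np.ceil(tb / binsec))
        for b in range(first, last):
            lo = max(ta, b * binsec)
            hi = min(tb, (b + 1) * binsec)
            w = hi - lo
            if w <= 0:
                continue
            tm = 0.5 * (lo + hi)
            alpha = (tm - ta) / gap
            mean, var = bridge_moments(za, zb, ta, tb, alpha, params)
            _deposit(acc, grid, mean, np.sqrt(var), b % ntb, w)
    if n_pairs == 0:
        raise ValueError(
            "no eligible detection pairs after gap filtering "
            f"(n={len(det)}, max_gap={params.max_gap} s)"
        )
    if per_slice_norm:
        slice_mass = acc.sum(axis=(0, 1), keepdims=True)
        nz = slice_mass > 0
        acc = np.divide(acc, slice_mass, where=nz, out=np.zeros_like(acc))
        acc /= acc.sum() if acc.sum() > 0 else 1.0
    else:
        total = acc.sum()
        if total <= 0:
            raise ValueError("all bridge mass fell outside the grid")
        acc /= total
    return SpaceTimeUD(grid=grid, values=acc)


def planar_ud(volume: SpaceTimeUD) -> PlanarUD:
    """Projection onto the two geographic dimensions, renormalized."""
    v = volume.values.sum(axis=2)
    total = v.sum()
    if total > 0:
        v = v / total
    return PlanarUD(grid=volume.grid, values=v)


def ud_contour(planar: PlanarUD | np.ndarray, level: float = 0.5) -> np.ndarray:
    """Smallest cell set whose cumulative mass reaches ``level``.

    Greedy by descending mass with a deterministic flat-index tie-break;
    returns a boolean mask of the planar grid.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    values = planar.values if isinstance(planar, PlanarUD) else np.asarray(planar, dtype=float)
    flat = values.ravel()
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    n_needed = int(np.searchsorted(cum, level * flat.sum() - 1e-12)) + 1
    n_needed = min(n_needed, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_needed]] = True
    return mask.reshape(values.shape)
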