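"""Readers and writers for the pipeline's tabular and volume formats.

Tabular data are CSV; timestamps are ISO-8601 and stored UTC.  Diel
binning uses hours computed from epoch seconds, so a configurable
local-time offset can be applied when reading detections (analyses of
island systems want local solar time).  Volumes go to netCDF (scipy
backend, netCDF3) with dims (x, y, time_of_day).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .accel import ODBASeries, RawAccel
from .hmm import ActivityCurve
from .movement import DetectionSeries, ReceiverArray, SpaceTimeUD, VoxelGrid

__all__ = [
    "read_receivers",
    "write_receivers_csv",
    "read_detections",
    "write_detections_csv",
    "read_accel_csv",
    "write_accel_csv",
    "read_odba_csv",
    "write_odba_csv",
    "write_activity_curve_csv",
    "read_scenario_csv",
    "read_spacetime_ud",
]


def write_receivers_csv(array: ReceiverArray, path) -> None:
    pd.DataFrame(
        {
            "receiver_id": array.ids.astype(str),
            "x_m": array.x,
            "y_m": array.y,
            "detection_range_m": array.detection_range,
        }
    ).to_csv(path, index=False)


def read_receivers(path) -> ReceiverArray:
    df = pd.read_csv(path)
    required = {"receiver_id", "x_m", "y_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"receiver table needs columns {sorted(required)}")
    rng = df["detection_range_m"].to_numpy() if "detection_range_m" in df.columns else 300.0
    return ReceiverArray(
        ids=df["receiver_id"].astype(str).to_numpy(dtype=object),
        x=df["x_m"].to_numpy(float),
        y=df["y_m"].to_numpy(float),
        detection_range=rng,
    )


def write_detections_csv(series: DetectionSeries | list[DetectionSeries], path) -> None:
    """Columns: individual_id, timestamp (ISO-8601 UTC), receiver_id."""
    if isinstance(series, DetectionSeries):
        series = [series]
    frames = []
    for det in series:
        ts = pd.to_datetime(det.timestamps, unit="s", utc=True)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": det.individual_id,
                    "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "receiver_id": (
                        det.receiver_id.astype(str)
                        if det.receiver_id is not None
                        else np.repeat("", len(det))
                    ),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_detections(
    path, receivers: ReceiverArray, tz_offset_hours: float = 0.0
) -> dict[str, DetectionSeries]:
    """Per-individual detection series joined to receiver coordinates.

    Unknown receiver ids and unparseable timestamps are rejected with
    the offending row number (1-based, excluding the header).
    ``tz_offset_hours`` shifts the stored UTC instants so that diel
    folding downstream happens in local time.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "receiver_id": str})
    required = {"individual_id", "timestamp", "receiver_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"detection table needs columns {sorted(required)}")
    out: dict[str, DetectionSeries] = {}
    if df.empty:
        return out
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"unparseable timestamp at row {row}")
    pos = {str(r): (float(x), float(y)) for r, x, y in zip(receivers.ids, receivers.x, receivers.y)}
    unknown = ~df["receiver_id"].isin(pos.keys())
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
        raise ValueError(
            f"unknown receiver id {df['receiver_id'].iloc[row - 1]!r} at row {row}"
        )
    seconds = ts.astype("int64").to_numpy() / 1e9 + tz_offset_hours * 3600.0
    df = df.assign(_t=seconds)
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = sub.sort_values("_t", kind="stable")
        xy = np.array([pos[r] for r in sub["receiver_id"]])
        out[str(ind)] = DetectionSeries(
            individual_id=str(ind),
            timestamps=sub["_t"].to_numpy(),
            x=xy[:, 0],
            y=xy[:, 1],
            receiver_id=sub["receiver_id"].to_numpy(dtype=object),
        )
    return out


def write_accel_csv(raw: RawAccel, path) -> None:
    pd.DataFrame(
        {"timestamp": raw.timestamps, "ax": raw.ax, "ay": raw.ay, "az": raw.az}
    ).to_csv(path, index=False)


def read_accel_csv(path) -> RawAccel:
    df = pd.read_csv(path)
    required = {"timestamp", "ax", "ay", "az"}
    if not required.issubset(df.columns):
        raise ValueError(f"accelerometer table needs columns {sorted(required)}")
    return RawAccel(
        timestamps=df["timestamp"].to_numpy(float),
        ax=df["ax"].to_numpy(float),
        ay=df["ay"].to_numpy(float),
        az=df["az"].to_numpy(float),
    )


def write_odba_csv(series: ODBASeries, path) -> None:
    pd.DataFrame({"timestamp": series.timestamps, "odba": series.odba}).to_csv(path, index=False)


def read_odba_csv(path) -> ODBASeries:
    df = pd.read_csv(path)
    return ODBASeries(df["timestamp"].to_numpy(float), df["odba"].to_numpy(float))


def write_activity_curve_csv(curve: ActivityCurve, path) -> None:
    pd.DataFrame(
        {
            "hour": curve.hours,
            "tide": curve.tide if curve.tide is not None else "",
            "p_state2": curve.p_state2,
            "lo95": curve.lo95,
            "hi95": curve.hi95,
        }
    ).to_csv(path, index=False)


def read_scenario_csv(path) -> pd.DataFrame:
    """Energetics scenario table: hour, temp_C, speed_ms."""
    df = pd.read_csv(path)
    required = {"hour", "temp_C", "speed_ms"}
    if not required.issubset(df.columns):
        raise ValueError(f"scenario table needs columns {sorted(required)}")
    return df.sort_values("hour").reset_index(drop=True)


def read_spacetime_ud(path) -> SpaceTimeUD:
    """Round-trip reader for volumes written by SpaceTimeUD.to_netcdf."""
    da = xr.open_dataarray(path, engine="scipy")
    cell = float(da.attrs["cell_size_m"])
    tbin = int(da.attrs["time_bin_minutes"])
    x = da["x"].to_numpy()
    y = da["y"].to_numpy()
    grid = VoxelGrid(
        x0=float(x[0] - cell / 2),
        y0=float(y[0] - cell / 2),
        nx=x.size,
        ny=y.size,
        cell=cell,
        tbin_minutes=tbin,
    )
    values = da.to_numpy()
    da.close()
    return SpaceTimeUD(grid=grid, values=values)
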