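"""Raw tri-axial acceleration to the 1-s ODBA series the HMM consumes.

Overall dynamic body acceleration (ODBA) is the sum over the three body
axes of the absolute dynamic (gravity-removed) acceleration.  Gravity is
separated with a centred box-car moving average per axis (default 3 s,
suitable for shark tail-beat frequencies); at the series edges the
window shrinks rather than padding with fabricated samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RawAccel",
    "ODBASeries",
    "separate_gravity",
    "compute_odba",
    "block_average",
    "trim_initial",
]


@dataclass
class RawAccel:
    """Regularly sampled tri-axial acceleration in g (default 20 Hz)."""

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        for name in ("ax", "ay", "az"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != self.timestamps.shape:
                raise ValueError(f"channel {name} length does not match timestamps")
        if self.timestamps.size >= 2:
            dt = np.diff(self.timestamps)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling interval must be constant")
            if dt[0] <= 0:
                raise ValueError("timestamps must be strictly increasing")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        if self.timestamps.size < 2:
            raise ValueError("cannot infer sampling rate from < 2 samples")
        return 1.0 / float(self.timestamps[1] - self.timestamps[0])

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class ODBASeries:
    """Timestamped non-negative activity values."""

    timestamps: np.ndarray
    odba: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.odba = np.asarray(self.odba, dtype=float)
        if self.odba.shape != self.timestamps.shape:
            raise ValueError("odba length does not match timestamps")
        if np.any(self.odba < 0):
            raise ValueError("odba must be non-negative")

    def __len__(self) -> int:
        return self.timestamps.size


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    # centred box-car; the window shrinks at the edges (min_periods=1)
    return (
        pd.Series(x).rolling(window=n, center=True, min_periods=1).mean().to_numpy()
    )


def separate_gravity(raw: RawAccel, window: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Split raw acceleration into static (gravity) and dynamic parts.

    Parameters
    ----------
    window:
        Moving-average length in seconds; must cover at least 2 samples
        and no more than the series length.

    Returns
    -------
    (static, dynamic):
        Two (3, T) arrays, axes ordered (x, y, z); static + dynamic
        reconstructs the raw input exactly.
    """
    n = int(round(window * raw.fs))
    if n < 2:
        raise ValueError("window must span at least 2 samples")
    if n > len(raw):
        raise ValueError("window longer than the series")
    channels = np.vstack([raw.ax, raw.ay, raw.az])
    static = np.vstack([_moving_average(c, n) for c in channels])
    dynamic = channels - static
    return static, dynamic


def compute_odba(dynamic: np.ndarray, timestamps: np.ndarray | None = None) -> ODBASeries:
    """ODBA at the native sampling rate: |dx| + |dy| + |dz|."""
    dynamic = np.asarray(dynamic, dtype=float)
    if dynamic.ndim != 2 or dynamic.shape[0] != 3:
        raise ValueError("dynamic must be a (3, T) array")
    odba = np.abs(dynamic).sum(axis=0)
    if timestamps is None:
        timestamps = np.arange(odba.size, dtype=float)
    return ODBASeries(timestamps=np.asarray(timestamps, dtype=float), odba=odba)


def block_average(series: ODBASeries, block: float = 1.0, fs: float | None = None) -> ODBASeries:
    """Non-overlapping block means (default 1-s); trailing partial block dropped."""
    if len(series) == 0:
        return ODBASeries(np.empty(0), np.empty(0))
    if fs is None:
        if len(series) < 2:
            raise ValueError("cannot infer sampling rate from < 2 samples")
        fs = 1.0 / float(series.timestamps[1] - series.timestamps[0])
    n = block * fs
    if abs(n - round(n)) > 1e-9 or round(n) < 1:
        raise ValueError("block must be a positive multiple of the sampling interval")
    n = int(round(n))
    nblocks = len(series) // n
    vals = series.odba[: nblocks * n].reshape(nblocks, n).mean(axis=1)
    t = series.timestamps[: nblocks * n : n]
    return ODBASeries(timestamps=t, odba=vals)


def trim_initial(series: ODBASeries, hours: float = 4.0) -> ODBASeries:
    """Drop all samples earlier than ``hours`` after the first timestamp.

    Removes the post-tagging stress period before behavioural inference.
    """
    if len(series) == 0 or hours <= 0:
        return ODBASeries(series.timestamps.copy(), series.odba.copy())
    cutoff = series.timestamps[0] + hours * 3600.0
    keep = series.timestamps >= cutoff
    return ODBASeries(series.timestamps[keep], series.odba[keep])
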