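"""ROI quantification: image stacks + label masks -> background-corrected traces.

Mirrors standard two-excitation-channel ratio-imaging analysis: for every
region of interest (ROI) and channel, the per-frame mean pixel intensity is
corrected by subtracting the per-frame mean of a cell-free background region.
The background estimate is per frame and per channel, so lamp drift and
background bleaching are absorbed.

File formats: multi-page TIFF stacks (pages ordered ex400 then ex480 per time
point) with a JSON metadata sidecar, label-mask TIFF with a CSV ROI table, and
tidy trace CSVs with columns (roi, compartment, channel, frame, time_min,
intensity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CHANNELS = ("ex400", "ex480")

__all__ = [
    "CHANNELS",
    "ImageStack",
    "CompartmentMask",
    "IntensityTrace",
    "extract_traces",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_traces",
    "read_traces",
    "trace_pairs",
]


@dataclass
class ImageStack:
    """Time x channel x row x col fluorescence intensities with metadata."""

    data: np.ndarray
    dt: float              # minutes per frame
    stim_time: float       # minutes
    channels: tuple[str, str] = CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("stack data must be (time, channel, row, col)")
        if self.data.shape[1] != len(self.channels) or len(self.channels) != 2:
            raise ValueError("both excitation channels must be present")
        if self.data.shape[0] < 2:
            raise ValueError("stack needs at least 2 time points")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.data.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in stack {self.channels}") from None


@dataclass
class CompartmentMask:
    """Integer label image; 0 is cell-free background, k > 0 are ROIs."""

    labels: np.ndarray
    roi_table: pd.DataFrame    # columns: label, cell, compartment

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label image must be integer typed")
        if not (self.labels == 0).any():
            raise ValueError("mask has no cell-free background pixels (label 0)")
        present = set(np.unique(self.labels)) - {0}
        table = set(self.roi_table["label"].astype(int))
        if present != table:
            raise ValueError(
                f"mask labels {sorted(present)} do not match roi_table {sorted(table)}"
            )
        if self.roi_table["label"].duplicated().any():
            raise ValueError("duplicate labels in roi_table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def background(self) -> np.ndarray:
        return self.labels == 0

    def info(self, label: int) -> tuple[int, str]:
        row = self.roi_table.loc[self.roi_table["label"] == label]
        if row.empty:
            raise KeyError(f"label {label} not in roi_table")
        return int(row["cell"].iloc[0]), str(row["compartment"].iloc[0])


@dataclass
class IntensityTrace:
    """Per-frame background-corrected mean intensity of one ROI and channel."""

    values: np.ndarray
    channel: str
    roi: int
    dt: float
    stim_time: float
    compartment: str | None = None
    cell: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace values must be a non-empty 1-D array")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def nonpositive(self) -> np.ndarray:
        """Flags for frames whose corrected value is <= 0 (kept, not dropped)."""
        return self.values <= 0


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_traces(stack: ImageStack, mask: CompartmentMask) -> list[IntensityTrace]:
    """Background-corrected per-ROI, per-channel mean intensity traces.

    trace[frame] = mean(ROI pixels) - mean(background pixels), with the
    background estimated independently for every frame and channel.
    """
    if mask.shape != stack.frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack frames {stack.frame_shape}"
        )
    bg_mean = stack.data[:, :, mask.background].mean(axis=-1)   # (T, 2)
    traces = []
    for row in mask.roi_table.itertuples():
        idx = mask.labels == row.label
        if not idx.any():
            raise ValueError(f"ROI label {row.label} has no pixels")
        roi_mean = stack.data[:, :, idx].mean(axis=-1)          # (T, 2)
        corrected = roi_mean - bg_mean
        for ch, channel in enumerate(stack.channels):
            traces.append(
                IntensityTrace(
                    values=corrected[:, ch],
                    channel=channel,
                    roi=int(row.label),
                    cell=int(row.cell),
                    compartment=str(row.compartment),
                    dt=stack.dt,
                    stim_time=stack.stim_time,
                )
            )
    return traces


def trace_pairs(traces) -> dict[int, tuple[IntensityTrace, IntensityTrace]]:
    """Group traces by ROI into (I400, I480) pairs."""
    by_roi: dict[int, dict[str, IntensityTrace]] = {}
    for tr in traces:
        by_roi.setdefault(tr.roi, {})[tr.channel] = tr
    pairs = {}
    for roi, chans in sorted(by_roi.items()):
        if set(chans) != set(CHANNELS):
            raise ValueError(f"ROI {roi} is missing a channel: has {sorted(chans)}")
        pairs[roi] = (chans["ex400"], chans["ex480"])
    return pairs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF (ex400 then ex480 per time point)
    plus a JSON metadata sidecar."""
    path = Path(path)
    t, c, h, w = stack.data.shape
    tifffile.imwrite(path, stack.data.reshape(t * c, h, w), photometric="minisblack")
    meta = {
        "n_frames": t,
        "channels": list(stack.channels),
        "dt_min": stack.dt,
        "stim_time_min": stack.stim_time,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF stack written by :func:`write_stack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_channels = len(meta["channels"])
    if pages.shape[0] % n_channels:
        raise ValueError(
            f"TIFF page count {pages.shape[0]} is not divisible by the "
            f"channel count {n_channels}"
        )
    t = pages.shape[0] // n_channels
    if t != meta["n_frames"]:
        raise ValueError(
            f"TIFF holds {t} time points but sidecar declares {meta['n_frames']}"
        )
    data = pages.reshape(t, n_channels, *pages.shape[1:])
    return ImageStack(
        data=data,
        dt=float(meta["dt_min"]),
        stim_time=float(meta["stim_time_min"]),
        channels=tuple(meta["channels"]),
    )


def write_mask(mask: CompartmentMask, path) -> None:
    path = Path(path)
    if mask.labels.max(initial=0) >= 2 ** 16:
        raise ValueError("too many labels for uint16 mask TIFF")
    tifffile.imwrite(path, mask.labels.astype(np.uint16), photometric="minisblack")
    mask.roi_table.to_csv(path.with_suffix(".csv"), index=False)


def read_mask(path) -> CompartmentMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    table_path = path.with_suffix(".csv")
    if not table_path.exists():
        raise FileNotFoundError(f"ROI table not found: {table_path}")
    labels = tifffile.imread(path).astype(np.int32)
    roi_table = pd.read_csv(table_path)
    return CompartmentMask(labels=labels, roi_table=roi_table)


TRACE_COLUMNS = ["roi", "compartment", "channel", "frame", "time_min", "intensity"]


def traces_to_frame(traces) -> pd.DataFrame:
    """Tidy long-format DataFrame with one row per (roi, channel, frame)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "roi": tr.roi,
                    "compartment": tr.compartment,
                    "channel": tr.channel,
                    "frame": np.arange(len(tr)),
                    "time_min": tr.time,
                    "intensity": tr.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRACE_COLUMNS]


def write_traces(traces, path) -> None:
    traces_to_frame(traces).to_csv(Path(path), index=False)


def read_traces(path, stim_time: float) -> list[IntensityTrace]:
    """Read a tidy trace CSV back into :class:`IntensityTrace` objects.

    The CSV stores absolute times, so the frame interval is recovered from the
    time column; the stimulus time is experiment metadata and must be given.
    """
    df = pd.read_csv(Path(path))
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV is missing columns: {sorted(missing)}")
    traces = []
    for (roi, channel), grp in df.groupby(["roi", "channel"], sort=True):
        grp = grp.sort_values("frame")
        times = grp["time_min"].to_numpy()
        if len(times) < 2:
            raise ValueError(f"ROI {roi} channel {channel} has fewer than 2 frames")
        steps = np.diff(times)
        if not np.allclose(steps, steps[0]):
            raise ValueError(f"non-uniform frame times for ROI {roi}")
        compartment = grp["compartment"].iloc[0]
        traces.append(
            IntensityTrace(
                values=grp["intensity"].to_numpy(),
                channel=str(channel),
                roi=int(roi),
                compartment=None if pd.isna(compartment) else str(compartment),
                dt=float(steps[0]),
                stim_time=float(stim_time),
            )
        )
    return traces
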