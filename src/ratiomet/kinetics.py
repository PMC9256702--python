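"""Trace-level response statistics for ratiometric biosensor recordings.

Implements the standard analysis chain for excitation-ratiometric kinase
activity reporters:

* excitation ratio R(t) = I480(t) / I400(t) per ROI,
* baseline normalization R/R0 with R0 the mean ratio before drug addition,
* maximum ratio change dR/R0 = (Rmax - R0) / R0,
* time-to-half-maximum t1/2 (first upward crossing, linearly interpolated),
* per-cell signal-to-noise ratio SNR = dR/R0 divided by the baseline SD,
* population Z-factor Z = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|,
* descriptive group summaries and the Welch two-sample t test.

All statistics are invariant to a common multiplicative gain applied to both
excitation channels, since only the ratio enters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import first_crossing_time
from .quantify import IntensityTrace

LN2 = math.log(2.0)

__all__ = [
    "RatioTrace",
    "ResponseMetrics",
    "AssayFitness",
    "WelchResult",
    "compute_ratio",
    "normalize",
    "max_ratio_change",
    "time_to_half_max",
    "snr",
    "z_factor",
    "compute_metrics",
    "metrics_frame",
    "summarize_group",
    "welch_t",
]


@dataclass
class RatioTrace:
    """Per-frame Ex480/400 ratio of one ROI.

    ``mask`` flags frames excluded from all statistics (non-positive channel
    intensity).  After :func:`normalize`, ``r_norm`` holds R/R0 and ``r0`` the
    baseline mean; the mean of ``r_norm`` over the baseline window is 1 by
    construction.
    """

    r: np.ndarray
    dt: float
    stim_time: float
    roi: int
    compartment: str | None = None
    mask: np.ndarray | None = None
    r0: float | None = None
    r_norm: np.ndarray | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.mask is None:
            self.mask = np.zeros(self.r.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.r.shape:
            raise ValueError("mask shape must match ratio shape")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def __len__(self) -> int:
        return self.r.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.r.size) * self.dt

    @property
    def is_normalized(self) -> bool:
        return self.r_norm is not None

    @property
    def baseline_frames(self) -> np.ndarray:
        """Default baseline window: all unmasked frames strictly pre-stimulus."""
        return (self.time < self.stim_time) & ~self.mask

    @property
    def post_frames(self) -> np.ndarray:
        return (self.time >= self.stim_time) & ~self.mask


@dataclass
class ResponseMetrics:
    """Per-cell response statistics of one normalized ratio trace."""

    roi: int
    compartment: str | None
    dr_over_r0: float
    r_max: float           # raw-ratio scale maximum, = r0 * (1 + dr_over_r0)
    r0: float
    t_half: float          # minutes; NaN for non-responders
    snr: float
    baseline_sd: float
    responder: bool

    def to_dict(self) -> dict:
        return dict(
            roi=self.roi,
            compartment=self.compartment,
            dr_over_r0=self.dr_over_r0,
            r_max=self.r_max,
            r0=self.r0,
            t_half_min=self.t_half,
            snr=self.snr,
            baseline_sd=self.baseline_sd,
            responder=self.responder,
        )


@dataclass
class AssayFitness:
    """Population assay-window statistic.

    ``mu_pos``/``sigma_pos`` summarize per-cell maximal normalized responses
    of the positive population; ``mu_neg``/``sigma_neg`` the negative
    (baseline / phospho-null) population.  Z = 1 - 3 (sigma_pos + sigma_neg)
    / |mu_pos - mu_neg|; Z near 1 indicates a wide assay window.
    """

    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    z_factor: float

    def to_dict(self) -> dict:
        return dict(
            mu_pos=self.mu_pos,
            sigma_pos=self.sigma_pos,
            mu_neg=self.mu_neg,
            sigma_neg=self.sigma_neg,
            z_factor=self.z_factor,
        )


class WelchResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


# ---------------------------------------------------------------------------
# ratio + normalization
# ---------------------------------------------------------------------------

def compute_ratio(i480: IntensityTrace, i400: IntensityTrace) -> RatioTrace:
    """Excitation ratio R(t) = I480(t) / I400(t) for one ROI.

    Frames with non-positive intensity in either channel are masked and
    excluded from every downstream statistic.
    """
    if i480.channel != "ex480" or i400.channel != "ex400":
        raise ValueError("pass (i480, i400) with channels ex480 and ex400")
    if i480.roi != i400.roi:
        raise ValueError(f"mismatched ROIs: {i480.roi} vs {i400.roi}")
    if len(i480) != len(i400):
        raise ValueError("channel traces differ in length")
    if i480.dt != i400.dt or i480.stim_time != i400.stim_time:
        raise ValueError("channel traces disagree on dt or stim_time")
    mask = (i400.values <= 0) | (i480.values <= 0)
    if mask.all():
        raise ValueError(f"ROI {i400.roi}: every frame is masked (non-positive)")
    r = np.empty_like(i480.values)
    r[~mask] = i480.values[~mask] / i400.values[~mask]
    r[mask] = np.nan
    return RatioTrace(
        r=r,
        dt=i480.dt,
        stim_time=i480.stim_time,
        roi=i480.roi,
        compartment=i480.compartment,
        mask=mask,
    )


def normalize(
    ratio: RatioTrace,
    baseline_window: Sequence[int] | None = None,
    min_baseline_frames: int = 3,
) -> RatioTrace:
    """Normalize a ratio trace to its pre-stimulus baseline mean R0.

    ``baseline_window`` is an iterable of frame indices; it defaults to every
    unmasked pre-stimulus frame and must lie strictly before the stimulus.
    """
    if baseline_window is None:
        window = np.flatnonzero(ratio.baseline_frames)
    else:
        window = np.asarray(list(baseline_window), dtype=int)
        if window.size and ratio.time[window].max() >= ratio.stim_time:
            raise ValueError("baseline window overlaps post-stimulus frames")
        window = window[~ratio.mask[window]]
    if window.size < min_baseline_frames:
        raise ValueError(
            f"baseline window has {window.size} unmasked frames; "
            f"need at least {min_baseline_frames}"
        )
    r0 = float(ratio.r[window].mean())
    out = RatioTrace(
        r=ratio.r,
        dt=ratio.dt,
        stim_time=ratio.stim_time,
        roi=ratio.roi,
        compartment=ratio.compartment,
        mask=ratio.mask.copy(),
        r0=r0,
    )
    out.r_norm = ratio.r / r0
    return out


def _require_normalized(trace: RatioTrace):
    if not trace.is_normalized:
        raise ValueError("trace must be normalized first (call normalize)")


def _smooth(values: np.ndarray, window: int | None) -> np.ndarray:
    if window is None or window <= 1:
        return values
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


# ---------------------------------------------------------------------------
# response metrics
# ---------------------------------------------------------------------------

def max_ratio_change(trace: RatioTrace, smooth_window: int | None = None) -> float:
    """Maximum ratio change dR/R0 = (Rmax - R0) / R0.

    Rmax is the raw post-stimulus maximum by default; an optional centered
    odd-width rolling mean can be applied first.  Negative values (inhibition)
    are permitted.
    """
    _require_normalized(trace)
    post = trace.post_frames
    if not post.any():
        raise ValueError("no unmasked post-stimulus frames")
    values = _smooth(trace.r_norm, smooth_window)
    return float(np.nanmax(values[post]) - 1.0)


def time_to_half_max(
    trace: RatioTrace,
    responder_threshold: float = 0.1,
    smooth_window: int | None = None,
) -> tuple[float, bool]:
    """Time-to-half-maximum t1/2, measured from the stimulus time.

    The threshold is halfway between the normalized baseline (1) and the
    normalized maximum; the first upward crossing is located by linear
    interpolation between the bracketing frames (a step straight out of
    baseline is assigned to the step frame).  Traces whose dR/R0 does not
    exceed ``responder_threshold`` are non-responders: returns (nan, False)
    instead of a garbage time.
    """
    _require_normalized(trace)
    dr = max_ratio_change(trace, smooth_window=smooth_window)
    if dr <= responder_threshold:
        return (float("nan"), False)
    post = trace.post_frames
    threshold = 1.0 + 0.5 * dr
    t_cross = first_crossing_time(
        trace.time[post], trace.r_norm[post], threshold, baseline=1.0
    )
    if t_cross is None:   # unreachable for the max-derived threshold; kept as a guard
        return (float("nan"), False)
    return (t_cross - trace.stim_time, True)


def snr(trace: RatioTrace, smooth_window: int | None = None) -> float:
    """Per-cell SNR: dR/R0 divided by the baseline SD of the normalized ratio."""
    _require_normalized(trace)
    base = trace.baseline_frames
    if base.sum() < 2:
        raise ValueError("need at least 2 unmasked baseline frames for SNR")
    sd = float(trace.r_norm[base].std(ddof=1))
    if sd == 0:
        raise ValueError("baseline SD is zero (degenerate noiseless input)")
    return max_ratio_change(trace, smooth_window=smooth_window) / sd


def compute_metrics(
    i480: IntensityTrace,
    i400: IntensityTrace,
    baseline_window: Sequence[int] | None = None,
    responder_threshold: float = 0.1,
    smooth_window: int | None = None,
) -> ResponseMetrics:
    """Full per-cell metric set from one pair of channel traces."""
    norm = normalize(compute_ratio(i480, i400), baseline_window)
    dr = max_ratio_change(norm, smooth_window=smooth_window)
    t_half, responder = time_to_half_max(
        norm, responder_threshold=responder_threshold, smooth_window=smooth_window
    )
    base = norm.baseline_frames
    baseline_sd = float(norm.r_norm[base].std(ddof=1)) if base.sum() >= 2 else float("nan")
    snr_value = dr / baseline_sd if baseline_sd and baseline_sd > 0 else float("nan")
    return ResponseMetrics(
        roi=norm.roi,
        compartment=norm.compartment,
        dr_over_r0=dr,
        r_max=norm.r0 * (1.0 + dr),
        r0=norm.r0,
        t_half=t_half,
        snr=snr_value,
        baseline_sd=baseline_sd,
        responder=responder,
    )


def metrics_frame(metrics: Sequence[ResponseMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.to_dict() for m in metrics])


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

def z_factor(pos_samples, neg_samples) -> AssayFitness:
    """Assay Z-factor from positive and negative per-cell response samples.

    Z = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|, the standard
    mean-separation assay statistic (sample SD, n-1 denominator).  Undefined
    when the two means coincide.
    """
    pos = np.asarray(pos_samples, dtype=float)
    neg = np.asarray(neg_samples, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each sample set needs at least 2 values")
    mu_pos, mu_neg = float(pos.mean()), float(neg.mean())
    if mu_pos == mu_neg:
        raise ValueError("Z-factor undefined: population means coincide")
    sigma_pos = float(pos.std(ddof=1))
    sigma_neg = float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (sigma_pos + sigma_neg) / abs(mu_pos - mu_neg)
    return AssayFitness(
        mu_pos=mu_pos,
        sigma_pos=sigma_pos,
        mu_neg=mu_neg,
        sigma_neg=sigma_neg,
        z_factor=z,
    )


def summarize_group(df: pd.DataFrame, value: str, by: str) -> pd.DataFrame:
    """Mean, SD, SEM and n of ``value`` per level of ``by`` (NaNs dropped)."""
    rows = []
    for key, grp in df.groupby(by, sort=True, dropna=False):
        vals = grp[value].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {key!r} has fewer than 2 values for {value!r}")
        sd = float(vals.std(ddof=1))
        rows.append(
            {
                by: key,
                "mean": float(vals.mean()),
                "sd": sd,
                "sem": sd / math.sqrt(vals.size),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def welch_t(a, b) -> WelchResult:
    """Unpaired two-tailed Welch t test (Satterthwaite degrees of freedom)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:   # identical constant groups: no variance, no difference
        return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return WelchResult(float(res.statistic), float(df), float(res.pvalue))
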