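"""Fluorescence recovery after photobleaching (FRAP): normalization + fitting.

A bleached compartment refills by molecular exchange with the unbleached pool;
for a single well-mixed pool the recovery is a single exponential,

    y(x) = a (1 - exp(-b x)) + c,

with x the time since the bleach, b the exchange rate (1/min), c the
post-bleach offset and a the recovered span.  The recovery half-time is
t1/2 = ln2 / b and the mobile fraction is a / bleach_depth.

The model/results split follows statsmodels: :class:`ExponentialRecovery` is
built from a :class:`FRAPTrace` and its :meth:`~ExponentialRecovery.fit`
returns an :class:`ExponentialRecoveryResults` carrying estimates, standard
errors, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

LN2 = math.log(2.0)

__all__ = [
    "FRAPTrace",
    "ExponentialRecovery",
    "ExponentialRecoveryResults",
    "normalize_frap",
    "fit_exponential_recovery",
    "half_time",
    "mobile",
    "fit_frap_csv",
]


@dataclass
class FRAPTrace:
    """Pre-bleach-normalized FRAP trace.

    ``bleach_frame`` indexes the first post-bleach frame; frames before it are
    the pre-bleach window, whose normalized mean is 1 by construction.  For
    fitting, post-bleach time is re-zeroed to the first post-bleach frame.
    """

    values: np.ndarray
    dt: float
    bleach_frame: int
    roi: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0 < self.bleach_frame < self.values.size:
            raise ValueError(
                f"bleach_frame {self.bleach_frame} must be interior to the "
                f"series of length {self.values.size}"
            )

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def pre_values(self) -> np.ndarray:
        return self.values[: self.bleach_frame]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.bleach_frame:]

    @property
    def post_time(self) -> np.ndarray:
        """Time since the first post-bleach frame (fit abscissa x)."""
        t = self.time
        return t[self.bleach_frame:] - t[self.bleach_frame]


def normalize_frap(
    raw_values,
    bleach_frame: int,
    dt: float,
    reference=None,
    roi: int | None = None,
    min_prebleach: int = 3,
) -> FRAPTrace:
    """Normalize a raw FRAP trace to its pre-bleach mean.

    With ``reference`` (an unbleached control ROI recorded simultaneously),
    the trace is first divided by the reference's own pre-bleach-normalized
    course, cancelling acquisition photobleaching exactly (double
    normalization); off by default.
    """
    values = np.asarray(raw_values, dtype=np.float64)
    if not 0 < bleach_frame < values.size:
        raise ValueError("bleach_frame must be interior to the series")
    if bleach_frame < min_prebleach:
        raise ValueError(
            f"need at least {min_prebleach} pre-bleach frames, got {bleach_frame}"
        )
    if reference is not None:
        ref = np.asarray(reference, dtype=np.float64)
        if ref.shape != values.shape:
            raise ValueError("reference trace must match the raw trace in length")
        if np.any(ref <= 0):
            raise ValueError("reference trace must be strictly positive")
        values = values / (ref / ref[:bleach_frame].mean())
    pre_mean = values[:bleach_frame].mean()
    if pre_mean <= 0:
        raise ValueError("non-positive pre-bleach mean")
    return FRAPTrace(values=values / pre_mean, dt=dt, bleach_frame=bleach_frame, roi=roi)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _recovery(params, x):
    a, b, c = params
    return a * -np.expm1(-b * x) + c


class ExponentialRecovery:
    """Single-exponential recovery model y = a (1 - exp(-b x)) + c.

    Fit over the post-bleach frames of a :class:`FRAPTrace` by bounded
    nonlinear least squares (b > 0).  Initialization is deterministic:
    c0 = first post-bleach value, a0 = last value - c0, and b0 from a
    log-linear regression of (plateau - y); a multi-start fallback
    (b0 x {0.2, 1, 5}) runs before declaring non-convergence.
    """

    #: parameter box over which noiseless fits are exact to machine precision
    PARAM_BOX = {"a": (0.05, 1.0), "b": (0.01, 5.0), "c": (0.0, 0.95)}

    def __init__(self, trace: FRAPTrace, min_post_frames: int = 6):
        if len(trace.post_values) < min_post_frames:
            raise ValueError(
                f"need at least {min_post_frames} post-bleach frames, "
                f"got {len(trace.post_values)}"
            )
        self.trace = trace

    def _initial_guess(self):
        x, y = self.trace.post_time, self.trace.post_values
        c0 = y[0]
        a0 = max(y[-1] - c0, 1e-3)
        plateau = y.max() + 0.05 * max(abs(y.max()), 1.0)
        resid = np.clip(plateau - y, 1e-12, None)
        slope = np.polyfit(x, np.log(resid), 1)[0]
        b0 = -slope
        if not np.isfinite(b0) or b0 <= 0:
            b0 = 1.0 / max(x[-1] - x[0], 1e-9)
        return a0, b0, c0

    def fit(self, multi_start: bool = True) -> "ExponentialRecoveryResults":
        x, y = self.trace.post_time, self.trace.post_values
        a0, b0, c0 = self._initial_guess()
        b_lo = 1e-9
        best = None
        starts = (1.0, 0.2, 5.0) if multi_start else (1.0,)
        for factor in starts:
            try:
                res = least_squares(
                    lambda p: _recovery(p, x) - y,
                    x0=[a0, max(b0 * factor, 2 * b_lo), c0],
                    bounds=([-np.inf, b_lo, -np.inf], [np.inf, np.inf, np.inf]),
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            return ExponentialRecoveryResults(
                self, np.array([a0, b0, c0]), None, float("nan"), converged=False
            )
        a, b, c = best.x
        converged = bool(best.success) and b > 10 * b_lo
        sse = float(2.0 * best.cost)
        dof = max(len(y) - 3, 1)
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (sse / dof)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = None
        return ExponentialRecoveryResults(self, best.x, bse, sse, converged=converged)


class ExponentialRecoveryResults:
    """Estimates and diagnostics of a fitted single-exponential recovery."""

    def __init__(self, model, params, bse, sse, converged):
        self.model = model
        self.params = pd.Series(np.asarray(params, dtype=float), index=["a", "b", "c"])
        self.bse = (
            pd.Series(np.asarray(bse, dtype=float), index=["a", "b", "c"])
            if bse is not None
            else None
        )
        self.sse = sse
        self.converged = converged
        self.nobs = len(model.trace.post_values)

    @property
    def a(self) -> float:
        return float(self.params["a"])

    @property
    def b(self) -> float:
        return float(self.params["b"])

    @property
    def c(self) -> float:
        return float(self.params["c"])

    @property
    def t_half(self) -> float:
        """Recovery half-time ln2 / b (minutes)."""
        if not self.converged:
            raise ValueError("half-time undefined: fit did not converge")
        return LN2 / self.b

    @property
    def plateau(self) -> float:
        return self.a + self.c

    def mobile(self, bleach_depth: float, tol: float = 0.05) -> float:
        """Mobile fraction: recovered span over bleach depth, clipped to [0, 1+tol]."""
        if not self.converged:
            raise ValueError("mobile fraction undefined: fit did not converge")
        if not 0 < bleach_depth <= 1:
            raise ValueError("bleach_depth must be in (0, 1]")
        return float(np.clip(self.a / bleach_depth, 0.0, 1.0 + tol))

    def predict(self, x=None) -> np.ndarray:
        if x is None:
            x = self.model.trace.post_time
        return _recovery(self.params.to_numpy(), np.asarray(x, dtype=float))

    def summary(self) -> str:
        lines = [
            "Single-exponential FRAP recovery fit",
            "  y(x) = a (1 - exp(-b x)) + c",
            f"  post-bleach frames: {self.nobs}   converged: {self.converged}",
        ]
        for name in ("a", "b", "c"):
            se = f" +/- {self.bse[name]:.4g}" if self.bse is not None else ""
            unit = " 1/min" if name == "b" else ""
            lines.append(f"  {name} = {self.params[name]:.6g}{se}{unit}")
        if self.converged:
            lines.append(f"  t1/2 = {self.t_half:.4g} min   plateau = {self.plateau:.4g}")
        lines.append(f"  SSE = {self.sse:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data + fitted curve on the post-bleach axis (simple QC figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        trace = self.model.trace
        ax.plot(trace.post_time, trace.post_values, ".", label="data")
        xs = np.linspace(0, trace.post_time[-1], 200)
        ax.plot(xs, self.predict(xs), "-", label="fit")
        ax.set_xlabel("time since bleach (min)")
        ax.set_ylabel("normalized intensity")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional conveniences
# ---------------------------------------------------------------------------

def fit_exponential_recovery(trace: FRAPTrace, **kwargs) -> ExponentialRecoveryResults:
    return ExponentialRecovery(trace).fit(**kwargs)


def half_time(fit: ExponentialRecoveryResults) -> float:
    return fit.t_half


def mobile(fit: ExponentialRecoveryResults, bleach_depth: float) -> float:
    return fit.mobile(bleach_depth)


FRAP_CSV_COLUMNS = ["roi", "frame", "time_min", "intensity", "bleach_frame"]


def fit_frap_csv(path) -> pd.DataFrame:
    """Fit every ROI in a FRAP trace CSV; returns one row of estimates per ROI.

    Input columns: roi, frame, time_min, intensity, bleach_frame.  Output
    columns: roi, a, b, c, t_half_min, mobile_fraction, sse, converged.
    The mobile fraction uses the observed bleach depth 1 - first post-bleach
    value of the normalized trace.
    """
    df = pd.read_csv(path)
    missing = set(FRAP_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"FRAP CSV is missing columns: {sorted(missing)}")
    rows = []
    for roi, grp in df.groupby("roi", sort=True):
        grp = grp.sort_values("frame")
        times = grp["time_min"].to_numpy()
        dt = float(np.diff(times)[0])
        trace = normalize_frap(
            grp["intensity"].to_numpy(),
            bleach_frame=int(grp["bleach_frame"].iloc[0]),
            dt=dt,
            roi=int(roi),
        )
        fit = fit_exponential_recovery(trace)
        depth = 1.0 - trace.post_values[0]
        rows.append(
            {
                "roi": int(roi),
                "a": fit.a,
                "b": fit.b,
                "c": fit.c,
                "t_half_min": fit.t_half if fit.converged else float("nan"),
                "mobile_fraction": (
                    fit.mobile(depth) if fit.converged and 0 < depth <= 1 else float("nan")
                ),
                "sse": fit.sse,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
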