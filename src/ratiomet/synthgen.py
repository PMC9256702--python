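"""Synthetic excitation-ratiometric biosensor data with known ground truth.

Single-fluorophore excitation-ratiometric kinase activity reporters (cpGFP-based
sensors such as ExRai-type AMPK reporters) emit more under 480 nm excitation and
less under 400 nm excitation as the sensor is phosphorylated, so the Ex480/400
ratio R rises with the phosphorylated fraction f of the sensor pool.  This
module generates the whole measurement chain with known truth:

1. per-cell phosphorylation-fraction kinetics f(t) (drug addition, optional
   inhibitor reversal, lognormal cell-to-cell heterogeneity),
2. paired two-channel intensity traces with photobleaching, shot noise and
   read noise,
3. label-mask geometries (nucleus, cytoplasm, lysosomal puncta, mitochondrial
   filaments) and rendered multi-channel image stacks,
4. fluorescence-recovery-after-photobleaching (FRAP) traces following a single
   exponential recovery.

Every stochastic operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from ._util import quantize_intensity, spawn_seeds
from .quantify import CHANNELS, CompartmentMask, ImageStack, IntensityTrace

LN2 = math.log(2.0)

logger = logging.getLogger(__name__)

__all__ = [
    "KineticParams",
    "SensorParams",
    "GeometryParams",
    "FRAPGroundTruth",
    "ActivitySet",
    "simulate_activity",
    "render_traces",
    "make_masks",
    "render_stack",
    "simulate_frap",
    "simulate_trace_population",
    "simulate_imaging_dataset",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Drug-induced activation kinetics of the sensor pool.

    The phosphorylated fraction is zero before ``stim_time`` and approaches a
    plateau exponentially afterwards, f(t) = A (1 - exp(-k (t - stim_time))).
    ``true_t_half`` = ln2 / ``rise_rate`` is the generator's ground-truth
    time-to-half-maximum.  Per-cell amplitude and rate are drawn lognormally
    around the population values with coefficient of variation ``cell_cv``.

    Defaults describe a strong stimulus (full activation, plateau 1.0) with a
    population half-time of 3.09 min and 16% cell-to-cell variability.
    """

    stim_time: float = 5.0            # minutes
    amplitude: float = 1.0            # phospho-fraction plateau, in [0, 1]
    rise_rate: float = LN2 / 3.09     # 1/min
    inhibitor_time: float | None = None   # minutes
    decay_rate: float | None = None       # 1/min, used after inhibitor_time
    cell_cv: float = 0.16             # unitless CV of per-cell A and k

    def __post_init__(self):
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"amplitude must be in [0, 1], got {self.amplitude}")
        if self.rise_rate <= 0:
            raise ValueError("rise_rate must be > 0")
        if self.cell_cv < 0:
            raise ValueError("cell_cv must be >= 0")
        if self.inhibitor_time is not None:
            if self.inhibitor_time <= self.stim_time:
                raise ValueError("inhibitor_time must be later than stim_time")
            if self.decay_rate is None or self.decay_rate <= 0:
                raise ValueError("decay_rate > 0 required with inhibitor_time")

    @property
    def true_t_half(self) -> float:
        """Ground-truth time-to-half-maximum, ln2 / rise_rate (minutes)."""
        return LN2 / self.rise_rate


@dataclass(frozen=True)
class SensorParams:
    """Optical model of the two-excitation-channel readout.

    The intrinsic excitation ratio is affine in the phosphorylated fraction,
    R(f) = r_min + (r_max - r_min) f.  The 480 nm channel rises linearly with
    f, I480 = b480 (1 + alpha480 f); the 400 nm channel falls so the ratio
    stays exactly affine, I400 = b400 (1 + alpha480 f) / (1 + rho f) with
    rho = r_max/r_min - 1.  ``alpha480`` defaults to rho/2, splitting the
    dynamic range between a rise of the 480 channel and a fall of the 400
    channel.  Both channels bleach exponentially; shot noise (variance = mean)
    and Gaussian read noise are added per frame when enabled.

    Default r_max/r_min = 2.8 gives a full-activation maximum ratio change
    dR/R0 of 1.8; default brightness of 5000 photons gives a baseline ratio
    standard deviation near sqrt(2/5000) ~ 0.02.
    """

    r_min: float = 1.0                # intrinsic ratio at f = 0
    r_max: float = 2.8                # intrinsic ratio at f = 1
    b400: float = 5000.0              # photons/frame at f = 0, 400 nm ex
    b480: float | None = None         # photons/frame at f = 0; default r_min*b400
    bleach_rate: float | tuple[float, float] = 0.002   # 1/min, (400, 480) or both
    read_noise_sd: float = 3.0        # photons
    shot_noise: bool = True
    alpha480: float | None = None     # relative rise of the 480 channel at f=1

    def __post_init__(self):
        if not self.r_max > self.r_min > 0:
            raise ValueError("need r_max > r_min > 0")
        if self.b400 <= 0:
            raise ValueError("b400 must be > 0")
        if self.b480 is None:
            object.__setattr__(self, "b480", self.r_min * self.b400)
        if self.b480 <= 0:
            raise ValueError("b480 must be > 0")
        rates = self.bleach_rate
        if np.isscalar(rates):
            rates = (float(rates), float(rates))
        else:
            rates = (float(rates[0]), float(rates[1]))
        if min(rates) < 0:
            raise ValueError("bleach_rate must be >= 0")
        object.__setattr__(self, "bleach_rate", rates)
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.alpha480 is None:
            object.__setattr__(self, "alpha480", self.dynamic_range / 2.0)
        if not 0 <= self.alpha480 < self.dynamic_range:
            # alpha480 >= rho would force the mean 400 nm intensity upward
            raise ValueError("alpha480 must lie in [0, r_max/r_min - 1)")

    @property
    def dynamic_range(self) -> float:
        """rho = r_max/r_min - 1, the full-activation dR/R0."""
        return self.r_max / self.r_min - 1.0

    def noiseless(self) -> "SensorParams":
        """Copy with shot noise, read noise and bleaching switched off."""
        return dataclasses.replace(
            self, shot_noise=False, read_noise_sd=0.0, bleach_rate=0.0
        )


@dataclass(frozen=True)
class GeometryParams:
    """Schematic cell geometry for mask and stack rendering.

    Cells are discs on a jittered lattice; each contains a nuclear disc, a
    cytoplasmic annulus, ``n_puncta`` small lysosomal discs and ``n_filaments``
    curvilinear mitochondrial paths.  Geometry is deliberately schematic -
    only ROI pixel statistics matter downstream.
    """

    image_shape: tuple[int, int] = (128, 128)
    n_cells: int = 4
    nucleus_radius: int = 6
    cell_radius: int = 14
    n_puncta: int = 5
    n_filaments: int = 3
    background_level: float = 100.0   # photons

    def __post_init__(self):
        if not self.nucleus_radius < self.cell_radius:
            raise ValueError("need nucleus_radius < cell_radius")
        if min(self.image_shape) <= 0:
            raise ValueError("image_shape must be positive")
        if min(self.n_cells, self.n_puncta, self.n_filaments) < 0:
            raise ValueError("counts must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")


@dataclass(frozen=True)
class FRAPGroundTruth:
    """Ground truth for a simulated photobleaching-recovery experiment.

    Intensity is 1 before ``bleach_time``, drops to 1 - ``bleach_depth`` at the
    bleach pulse, and recovers as c + a (1 - exp(-b (t - t_bleach))) with
    b = ``exchange_rate``, c = 1 - bleach_depth and plateau
    1 - immobile_fraction * bleach_depth.  The default exchange rate
    ln2/8.84 per min matches a nuclear-import half-time of 8.84 min.
    """

    bleach_time: float = 5.0              # minutes
    bleach_depth: float = 0.8             # fraction of intensity removed, (0, 1]
    exchange_rate: float = LN2 / 8.84     # 1/min; true recovery rate b
    immobile_fraction: float = 0.0        # [0, 1)

    def __post_init__(self):
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError(f"bleach_depth must be in (0, 1], got {self.bleach_depth}")
        if self.exchange_rate <= 0:
            raise ValueError("exchange_rate must be > 0")
        if not 0.0 <= self.immobile_fraction < 1.0:
            raise ValueError("immobile_fraction must be in [0, 1)")

    @property
    def true_t_half(self) -> float:
        return LN2 / self.exchange_rate


# ---------------------------------------------------------------------------
# activity kinetics
# ---------------------------------------------------------------------------

@dataclass
class ActivitySet:
    """Per-cell phospho-fraction series plus the drawn ground-truth parameters."""

    time: np.ndarray          # (T,) minutes
    f: np.ndarray             # (n_cells, T) phospho fraction in [0, 1]
    truth: pd.DataFrame       # cell, amplitude, rise_rate, t_half_true, clipped


def _lognormal_factors(rng, cv, size):
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def simulate_activity(
    params: KineticParams, time_grid, seed: int, n_cells: int = 1
) -> ActivitySet:
    """Simulate per-cell phosphorylation-fraction time courses.

    ``f(t) = 0`` before the stimulus, then an exponential approach to the
    per-cell plateau; after an optional inhibitor addition the fraction decays
    exponentially.  Per-cell amplitudes and rates are lognormal around the
    population values (mean preserved); amplitude draws above 1 are clipped to
    1 and logged.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0:
        raise ValueError("time_grid is empty")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("time_grid must be strictly increasing")
    rng = np.random.default_rng(seed)

    amp = params.amplitude * _lognormal_factors(rng, params.cell_cv, n_cells)
    rate = params.rise_rate * _lognormal_factors(rng, params.cell_cv, n_cells)
    clipped = amp > 1.0
    if clipped.any():
        logger.warning(
            "clipped %d/%d amplitude draws exceeding 1", int(clipped.sum()), n_cells
        )
        amp = np.minimum(amp, 1.0)

    dt_post = np.clip(t - params.stim_time, 0.0, None)
    f = amp[:, None] * -np.expm1(-rate[:, None] * dt_post[None, :])
    f[:, t < params.stim_time] = 0.0

    if params.inhibitor_time is not None:
        t_inh = params.inhibitor_time
        f_at_inh = amp * -np.expm1(-rate * (t_inh - params.stim_time))
        post = t > t_inh
        f[:, post] = f_at_inh[:, None] * np.exp(
            -params.decay_rate * (t[None, post] - t_inh)
        )

    f = np.clip(f, 0.0, 1.0)
    truth = pd.DataFrame(
        {
            "cell": np.arange(n_cells),
            "amplitude": amp,
            "rise_rate": rate,
            "t_half_true": LN2 / rate,
            "clipped": clipped,
        }
    )
    return ActivitySet(time=t, f=f, truth=truth)


# ---------------------------------------------------------------------------
# two-channel rendering
# ---------------------------------------------------------------------------

def render_traces(f, sensor: SensorParams, dt: float, seed: int | None = None):
    """Render phospho-fraction series into paired (I400, I480) intensities.

    ``f`` may be 1-D (one trace) or 2-D (cells x frames); time runs along the
    last axis with frame spacing ``dt`` minutes.  Returns two arrays of the
    same shape, quantized onto the exact-arithmetic intensity grid.
    """
    f = np.asarray(f, dtype=float)
    if f.size == 0:
        raise ValueError("empty phospho-fraction input")
    if f.min() < 0 or f.max() > 1:
        raise ValueError("phospho fraction must lie in [0, 1]")
    rho = sensor.dynamic_range
    t = np.arange(f.shape[-1]) * float(dt)
    lam400, lam480 = sensor.bleach_rate

    shape_term = 1.0 + sensor.alpha480 * f
    m480 = sensor.b480 * shape_term * np.exp(-lam480 * t)
    m400 = sensor.b400 * shape_term / (1.0 + rho * f) * np.exp(-lam400 * t)
    # means are strictly positive by construction (alpha480 < rho, b > 0)

    if sensor.shot_noise or sensor.read_noise_sd > 0:
        rng = np.random.default_rng(seed)
        i400, i480 = m400.copy(), m480.copy()
        if sensor.shot_noise:
            i400 += rng.normal(0.0, np.sqrt(m400))
            i480 += rng.normal(0.0, np.sqrt(m480))
        if sensor.read_noise_sd > 0:
            i400 += rng.normal(0.0, sensor.read_noise_sd, size=m400.shape)
            i480 += rng.normal(0.0, sensor.read_noise_sd, size=m480.shape)
    else:
        i400, i480 = m400, m480
    return quantize_intensity(i400), quantize_intensity(i480)


def intrinsic_ratio(f, sensor: SensorParams):
    """Noise-free intrinsic ratio R(f) = r_min + (r_max - r_min) f."""
    return sensor.r_min + (sensor.r_max - sensor.r_min) * np.asarray(f, dtype=float)


# ---------------------------------------------------------------------------
# geometry / masks
# ---------------------------------------------------------------------------

def _disc(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def _cell_centers(geom: GeometryParams, rng):
    h, w = geom.image_shape
    margin = geom.cell_radius + 2
    spacing = 2 * geom.cell_radius + 4
    n_cols = max(1, (w - 2 * margin) // spacing + 1)
    centers = []
    for i in range(geom.n_cells):
        r, c = divmod(i, n_cols)
        cy = margin + r * spacing + int(rng.integers(-1, 2))
        cx = margin + c * spacing + int(rng.integers(-1, 2))
        if cy + geom.cell_radius >= h or cx + geom.cell_radius >= w:
            raise ValueError(
                f"image_shape {geom.image_shape} too small for {geom.n_cells} "
                f"cells of radius {geom.cell_radius}"
            )
        centers.append((cy, cx))
    return centers


def _sample_in_annulus(rng, center, r_lo, r_hi):
    radius = math.sqrt(rng.uniform(r_lo ** 2, r_hi ** 2))
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return (center[0] + radius * math.sin(theta), center[1] + radius * math.cos(theta))


def make_masks(geom: GeometryParams, seed: int) -> CompartmentMask:
    """Build a label image with background 0 and per-cell compartment ROIs.

    Each cell contributes up to four ROIs: nucleus (disc), cytoplasm (cell
    disc minus everything else), a lysosome ROI made of ``n_puncta`` disjoint
    puncta, and a mitochondria ROI made of ``n_filaments`` curvilinear paths.
    Labels are disjoint by construction (one label per pixel).
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(geom.image_shape, dtype=np.int32)
    rows = []
    next_label = 1
    punct_r = 2

    for cell_id, center in enumerate(_cell_centers(geom, rng)):
        cell = _disc(geom.image_shape, center, geom.cell_radius)
        nucleus = _disc(geom.image_shape, center, geom.nucleus_radius)
        cytoplasm = cell & ~nucleus

        lyso = np.zeros_like(cell)
        placed = []
        for _ in range(geom.n_puncta):
            for _attempt in range(500):
                p = _sample_in_annulus(
                    rng, center,
                    geom.nucleus_radius + punct_r + 1,
                    geom.cell_radius - punct_r - 1,
                )
                if all(
                    (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 > (2 * punct_r + 1) ** 2
                    for q in placed
                ):
                    placed.append(p)
                    lyso |= _disc(geom.image_shape, p, punct_r) & cytoplasm
                    break
            else:
                raise ValueError(
                    f"could not place {geom.n_puncta} non-overlapping puncta "
                    f"inside cell {cell_id}; enlarge the cell or reduce n_puncta"
                )

        mito = np.zeros_like(cell)
        for _ in range(geom.n_filaments):
            y, x = _sample_in_annulus(
                rng, center, geom.nucleus_radius + 2, geom.cell_radius - 2
            )
            theta = rng.uniform(0.0, 2.0 * math.pi)
            for _step in range(2 * geom.cell_radius):
                iy, ix = int(round(y)), int(round(x))
                rr = (iy - center[0]) ** 2 + (ix - center[1]) ** 2
                if (
                    geom.nucleus_radius ** 2 < rr < geom.cell_radius ** 2
                    and not lyso[iy, ix]
                ):
                    mito[iy, ix] = True
                theta += rng.normal(0.0, 0.3)
                y += math.sin(theta)
                x += math.cos(theta)

        cytoplasm = cytoplasm & ~lyso & ~mito
        for compartment, region in (
            ("nucleus", nucleus),
            ("cytoplasm", cytoplasm),
            ("lysosome", lyso),
            ("mitochondria", mito),
        ):
            if not region.any():
                continue
            labels[region] = next_label
            rows.append(
                {"label": next_label, "cell": cell_id, "compartment": compartment}
            )
            next_label += 1

    if not (labels == 0).any():
        raise ValueError("geometry leaves no cell-free background pixels")
    roi_table = pd.DataFrame(rows, columns=["label", "cell", "compartment"])
    return CompartmentMask(labels=labels, roi_table=roi_table)


def count_components(mask: CompartmentMask, label: int) -> int:
    """Number of connected components in one ROI (8-connectivity)."""
    _, n = ndimage.label(mask.labels == label, structure=np.ones((3, 3)))
    return int(n)


# ---------------------------------------------------------------------------
# stack rendering
# ---------------------------------------------------------------------------

def render_stack(
    mask: CompartmentMask,
    traces: Mapping[int, tuple[np.ndarray, np.ndarray]],
    background_level: float = 100.0,
    dt: float = 0.5,
    stim_time: float = 5.0,
    seed: int | None = None,
    shot_noise: bool = True,
    read_noise_sd: float = 3.0,
) -> ImageStack:
    """Render per-ROI (I400, I480) traces into a two-channel image stack.

    Every pixel of an ROI carries that ROI's per-frame mean intensity on top
    of the cell-free background level; per-pixel shot noise (variance = mean)
    and Gaussian read noise are added when enabled, so ROI-mean noise shrinks
    with the square root of ROI area.  Without noise the render is exactly
    reversible by :func:`ratiomet.quantify.extract_traces`.
    """
    roi_labels = list(mask.roi_table["label"])
    for label in roi_labels:
        if label not in traces:
            raise KeyError(f"no trace supplied for mask label {label}")
    lengths = {len(traces[lab][0]) for lab in roi_labels} | {
        len(traces[lab][1]) for lab in roi_labels
    }
    if len(lengths) != 1:
        raise ValueError("all ROI traces must have equal length")
    (n_frames,) = lengths

    bg = float(quantize_intensity(background_level))
    data = np.full((n_frames, 2, *mask.shape), bg, dtype=np.float64)
    for label in roi_labels:
        idx = mask.labels == label
        i400, i480 = traces[label]
        data[:, 0, idx] = bg + np.asarray(i400, dtype=float)[:, None]
        data[:, 1, idx] = bg + np.asarray(i480, dtype=float)[:, None]

    if shot_noise or read_noise_sd > 0:
        rng = np.random.default_rng(seed)
        if shot_noise:
            data = data + rng.normal(0.0, np.sqrt(np.clip(data, 0.0, None)))
        if read_noise_sd > 0:
            data = data + rng.normal(0.0, read_noise_sd, size=data.shape)
        data = np.clip(quantize_intensity(data), 0.0, None)
    return ImageStack(data=data, dt=dt, stim_time=stim_time, channels=CHANNELS)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def simulate_frap(
    truth: FRAPGroundTruth, time_grid, noise_sd: float = 0.0, seed: int | None = None
) -> np.ndarray:
    """Simulate a normalized FRAP trace (pre-bleach mean 1).

    The noiseless trace equals 1 before the bleach and
    c + a (1 - exp(-b (t - t_bleach))) afterwards, with b the exchange rate,
    c = 1 - bleach_depth and plateau 1 - immobile_fraction * bleach_depth.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0 or not np.all(np.diff(t) > 0):
        raise ValueError("time_grid must be non-empty and strictly increasing")
    if not t[0] < truth.bleach_time <= t[-1]:
        raise ValueError("bleach_time must lie inside the time grid")
    c = 1.0 - truth.bleach_depth
    a = truth.bleach_depth * (1.0 - truth.immobile_fraction)
    post = t >= truth.bleach_time
    values = np.ones_like(t)
    values[post] = c + a * -np.expm1(
        -truth.exchange_rate * (t[post] - truth.bleach_time)
    )
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
    return values


# ---------------------------------------------------------------------------
# experiment-level conveniences
# ---------------------------------------------------------------------------

def simulate_trace_population(
    kin: KineticParams,
    sensor: SensorParams,
    n_cells: int,
    t_total: float = 30.0,
    dt: float = 0.5,
    seed: int = 0,
):
    """Simulate a population of per-cell (I400, I480) trace pairs.

    Returns ``(pairs, truth)`` where ``pairs`` is a list of
    (:class:`IntensityTrace`, :class:`IntensityTrace`) per cell and ``truth``
    records the drawn per-cell amplitude, rate, half-time and the implied
    maximum ratio change ``true_dr_over_r0`` = (r_max/r_min - 1) * amplitude.
    """
    act_seed, render_seed = spawn_seeds(seed, 2)
    time = np.arange(0.0, t_total + 0.5 * dt, dt)
    activity = simulate_activity(kin, time, seed=act_seed, n_cells=n_cells)
    i400, i480 = render_traces(activity.f, sensor, dt=dt, seed=render_seed)
    pairs = []
    for cell in range(n_cells):
        common = dict(roi=cell, cell=cell, compartment="cell",
                      dt=dt, stim_time=kin.stim_time)
        pairs.append(
            (
                IntensityTrace(values=i400[cell], channel="ex400", **common),
                IntensityTrace(values=i480[cell], channel="ex480", **common),
            )
        )
    truth = activity.truth.copy()
    truth["true_dr_over_r0"] = sensor.dynamic_range * truth["amplitude"]
    return pairs, truth


def simulate_imaging_dataset(
    kin: KineticParams,
    sensor: SensorParams,
    geom: GeometryParams,
    t_total: float = 30.0,
    dt: float = 0.5,
    seed: int = 0,
    shot_noise: bool = True,
    read_noise_sd: float = 3.0,
):
    """Render a full synthetic experiment: stack + masks + per-ROI ground truth.

    Per-ROI mean traces are rendered noiselessly (pixel noise is added in the
    stack, which is what ROI averaging then suppresses).  Every ROI of a cell
    shares that cell's activity kinetics.

    Returns ``(stack, mask, traces, truth)`` with ``traces`` the noiseless
    per-label (I400, I480) arrays and ``truth`` one row per ROI.
    """
    act_seed, mask_seed, stack_seed = spawn_seeds(seed, 3)
    time = np.arange(0.0, t_total + 0.5 * dt, dt)
    activity = simulate_activity(kin, time, seed=act_seed, n_cells=geom.n_cells)
    i400, i480 = render_traces(activity.f, sensor.noiseless(), dt=dt)
    mask = make_masks(geom, seed=mask_seed)

    traces = {
        int(row.label): (i400[int(row.cell)], i480[int(row.cell)])
        for row in mask.roi_table.itertuples()
    }
    stack = render_stack(
        mask,
        traces,
        background_level=geom.background_level,
        dt=dt,
        stim_time=kin.stim_time,
        seed=stack_seed,
        shot_noise=shot_noise,
        read_noise_sd=read_noise_sd,
    )
    truth = mask.roi_table.merge(activity.truth, on="cell")
    truth["true_dr_over_r0"] = sensor.dynamic_range * truth["amplitude"]
    return stack, mask, traces, truth
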