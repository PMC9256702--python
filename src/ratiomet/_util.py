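"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np

#: Spacing of the intensity grid, in photons.
#:
#: Every rendered intensity is rounded to an integer multiple of this grid.
#: On-grid float64 values below ~2**33 photons add and average without rounding
#: error, which makes the noiseless render -> ROI-mean-extraction round trip
#: exactly reversible.
INTENSITY_GRID = 2.0 ** -20


def quantize_intensity(x):
    """Round intensities onto the exact-arithmetic grid (~1e-6 photons)."""
    x = np.asarray(x, dtype=np.float64)
    return np.round(x / INTENSITY_GRID) * INTENSITY_GRID


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan one integer seed out into ``n`` reproducible child seeds (< 2**31)."""
    ss = np.random.SeedSequence(int(seed))
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(int(n))]


def first_crossing_time(time, values, threshold, baseline):
    """Time of the first upward crossing of ``threshold``.

    Linearly interpolates between the two bracketing samples, except when the
    sample before the crossing sits at or below ``baseline``: a jump straight
    out of baseline carries no evidence that the rise started earlier, so the
    crossing is assigned to the crossing sample itself.

    Returns ``None`` when the series never reaches the threshold.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    above = values >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0 or values[i - 1] <= baseline:
        return float(time[i])
    v0, v1 = values[i - 1], values[i]
    frac = (threshold - v0) / (v1 - v0)
    return float(time[i - 1] + frac * (time[i] - time[i - 1]))
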