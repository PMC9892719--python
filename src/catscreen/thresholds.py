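"""Valley (antimode) detection on bimodal log-intensity distributions.

Several gates in the pipeline are data-derived thresholds between two
fluorescence populations: live/dead on PI, hyperpolarized/depolarized on
the membrane-potential dye, responder/non-responder on Fluo-4.  All of
them use the same primitive: a kernel-density estimate of log10(1+x) and
the minimum between the two dominant modes.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

__all__ = ["UnimodalError", "log1p10", "find_antimode", "antimode_threshold"]


class UnimodalError(ValueError):
    """Distribution has no detectable second mode; set a manual threshold."""


def log1p10(x: np.ndarray) -> np.ndarray:
    """log10(1 + x): the display/gating transform, tolerant of zeros."""
    return np.log10(1.0 + np.asarray(x, dtype=float))


def find_antimode(
    values: np.ndarray,
    grid_size: int = 512,
    min_prominence: float = 0.05,
    max_valley_ratio: float = 0.8,
) -> float:
    """Valley position between the two dominant modes of ``values``.

    ``values`` are already on the analysis (log) scale.  A mode counts if
    its density exceeds ``min_prominence`` of the global maximum; the
    distribution is accepted as bimodal only if the density at the valley
    is below ``max_valley_ratio`` times the lower of the two peaks.

    Raises :class:`UnimodalError` otherwise.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10 or np.ptp(v) == 0:
        raise UnimodalError("too few distinct values for density estimation")
    kde = gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), grid_size)
    dens = kde(grid)
    peaks = argrelmax(dens)[0]
    peaks = peaks[dens[peaks] >= min_prominence * dens.max()]
    if peaks.size < 2:
        raise UnimodalError(
            "log-intensity distribution looks unimodal; supply a manual threshold"
        )
    # two highest peaks, in position order
    top2 = np.sort(peaks[np.argsort(dens[peaks])[-2:]])
    lo, hi = top2
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    if dens[valley] > max_valley_ratio * min(dens[lo], dens[hi]):
        raise UnimodalError(
            "no clear valley between candidate modes; supply a manual threshold"
        )
    return float(grid[valley])


def antimode_threshold(intensities: np.ndarray, **kwargs) -> float:
    """Antimode of linear-scale intensities, returned on the linear scale."""
    t_log = find_antimode(log1p10(intensities), **kwargs)
    return float(10.0**t_log - 1.0)
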