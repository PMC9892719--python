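"""Per-sample CatSper-opening readouts.

Three readouts quantify EGTA-triggered membrane depolarization (a proxy
for CatSper conductance) or the related capacitation Ca2+ rise:

* :func:`score_em` — flow cytometry: time-resolved mean of the
  high-fluorescence ("DiSC3(5)+", hyperpolarized) population normalized
  to its basal value, and the fraction of that population that migrates
  below the threshold after EGTA;
* :func:`delta_afu` — spectrofluorometry: step amplitude
  ``F_EGTA - F_R`` of a cuvette fluorescence trace;
* :func:`fluo4_summary` — flow cytometry: control-normalized median
  Fluo-4 intensity and percent responders above a control-derived
  threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import KineticTrace
from .thresholds import UnimodalError, antimode_threshold, find_antimode, log1p10

__all__ = [
    "EmResponse",
    "DeltaAfu",
    "CalciumResult",
    "set_disc3_threshold",
    "score_em",
    "score_all_barcodes",
    "delta_afu",
    "fluo4_summary",
]

DEFAULT_T_EGTA_S = 30.0
DEFAULT_T_END_S = 180.0
DEFAULT_BIN_WIDTH_S = 10.0
# post-EGTA share is evaluated once the exponential migration lag has
# largely played out; 30 s after EGTA at the default 10 s lag leaves <5%
# of eventual migrators still high.
DEFAULT_POST_SETTLE_S = 30.0
MIN_EVENTS_PER_WINDOW = 200


@dataclass
class EmResponse:
    """Membrane-potential kinetics of one barcoded sample.

    ``normalized_mean`` is the per-bin mean intensity of the current
    DiSC3(5)+ population divided by the first (basal) bin's mean, so the
    first bin is 1 by construction.  ``migration_fraction`` is the share
    of the basal DiSC3(5)+ population that has left the high-fluorescence
    subset in the post-EGTA window (clipped to [0, 1]).
    """

    sample_id: str
    f0: float
    bin_centers_s: np.ndarray
    normalized_mean: np.ndarray
    n_events_per_bin: np.ndarray
    basal_plus_share: float
    post_plus_share: float
    migration_fraction: float | None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def qc_pass(self) -> bool:
        return not self.qc_flags


def set_disc3_threshold(
    neg_control_events: pd.DataFrame, t_egta: float = DEFAULT_T_EGTA_S
) -> float:
    """DiSC3(5)+ threshold (the "dashed line") from a negative control.

    The valley of the bimodal basal-window log-intensity density of the
    negative control, reused for every sample in the same tube.  Raises
    :class:`~catscreen.thresholds.UnimodalError` when no valley exists
    (e.g. fully depolarized or fully hyperpolarized input).
    """
    basal = neg_control_events.loc[neg_control_events["time"] < t_egta, "disc3"]
    if len(basal) < 10:
        raise ValueError("too few basal-window events to set a threshold")
    return antimode_threshold(basal.to_numpy(dtype=float))


def score_em(
    events: pd.DataFrame,
    threshold: float,
    t_egta: float = DEFAULT_T_EGTA_S,
    t_end: float = DEFAULT_T_END_S,
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    post_settle: float = DEFAULT_POST_SETTLE_S,
    min_events: int = MIN_EVENTS_PER_WINDOW,
    sample_id: str = "",
) -> EmResponse:
    """Score EGTA-triggered depolarization for one sample's events.

    DiSC3(5)+ membership is re-evaluated per time bin against the fixed
    ``threshold``; ``migration_fraction = 1 - post_share / basal_share``
    where the post window starts ``post_settle`` seconds after EGTA.
    Samples with fewer than ``min_events`` in the basal or post window are
    flagged and receive no migration score.
    """
    t = events["time"].to_numpy(dtype=float)
    x = events["disc3"].to_numpy(dtype=float)
    plus = x > threshold

    edges = np.arange(0.0, t_end + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(t, edges) - 1
    n_bins = len(centers)
    mean_plus = np.full(n_bins, np.nan)
    n_per_bin = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = (which == b) & plus
        n_per_bin[b] = int(sel.sum())
        if n_per_bin[b]:
            mean_plus[b] = float(x[sel].mean())
    f0 = mean_plus[0]
    normalized = mean_plus / f0 if np.isfinite(f0) and f0 > 0 else mean_plus * np.nan

    basal = t < t_egta
    post = t >= t_egta + post_settle
    flags: list[str] = []
    if int(basal.sum()) < min_events:
        flags.append("low_basal_events")
    if int(post.sum()) < min_events:
        flags.append("low_post_events")
    basal_share = float(plus[basal].mean()) if basal.any() else np.nan
    post_share = float(plus[post].mean()) if post.any() else np.nan
    if flags or not np.isfinite(basal_share) or basal_share == 0:
        migration = None
        if not flags:
            flags.append("no_basal_plus_population")
    else:
        migration = float(np.clip(1.0 - post_share / basal_share, 0.0, 1.0))
    return EmResponse(
        sample_id=sample_id,
        f0=float(f0) if np.isfinite(f0) else np.nan,
        bin_centers_s=centers,
        normalized_mean=normalized,
        n_events_per_bin=n_per_bin,
        basal_plus_share=basal_share,
        post_plus_share=post_share,
        migration_fraction=migration,
        qc_flags=flags,
    )


def score_all_barcodes(
    events: pd.DataFrame, threshold: float, **kwargs
) -> dict[str, EmResponse]:
    """Apply :func:`score_em` to every assigned barcode in a labeled tube."""
    out = {}
    for sig, grp in events.groupby("barcode", sort=True):
        if sig in ("", "unassigned"):
            continue
        out[sig] = score_em(grp, threshold, sample_id=str(sig), **kwargs)
    return out


@dataclass
class DeltaAfu:
    """Spectrofluorometric depolarization amplitude."""

    f_r: float
    f_egta: float
    delta: float
    t_stable_s: float
    stable_found: bool
    normalized: float | None = None


def delta_afu(
    trace: KineticTrace,
    control_deltas: np.ndarray | list[float] | None = None,
    pre_window_s: float = 60.0,
    stable_after_s: float = 60.0,
    slope_window_s: float = 10.0,
    slope_tolerance: float = 0.01,
) -> DeltaAfu:
    """Step amplitude F_EGTA - F_R of a cuvette trace.

    ``F_R`` is the mean of the ``pre_window_s`` seconds before EGTA.
    ``F_EGTA`` is read at the first time at least ``stable_after_s``
    seconds after EGTA where the rolling slope falls below
    ``slope_tolerance`` of the provisional step amplitude per
    ``slope_window_s``; if no point qualifies the end of the trace is
    used and a warning is emitted.  ``normalized`` is delta divided by
    the mean of ``control_deltas`` when controls are supplied.
    """
    t = np.asarray(trace.time_s, dtype=float)
    f = np.asarray(trace.fluorescence, dtype=float)
    t_egta = trace.t_egta_s
    if t_egta - t[0] < pre_window_s or t[-1] - t_egta < stable_after_s:
        raise ValueError("trace must span the pre- and post-EGTA analysis windows")
    pre = (t >= t_egta - pre_window_s) & (t < t_egta)
    f_r = float(f[pre].mean())
    post = t >= t_egta
    amplitude_est = float(np.max(np.abs(f[post] - f_r)))
    dt = t[1] - t[0]
    half = max(int(round(slope_window_s / dt)) // 2, 1)
    candidates = np.flatnonzero(t >= t_egta + stable_after_s)
    t_stable, f_egta, found = float(t[-1]), float(f[-1]), False
    for i in candidates:
        lo, hi = max(i - half, 0), min(i + half + 1, len(t))
        slope = np.polyfit(t[lo:hi], f[lo:hi], 1)[0]
        if abs(slope) * slope_window_s <= slope_tolerance * max(amplitude_est, 1e-12):
            t_stable, f_egta, found = float(t[i]), float(f[lo:hi].mean()), True
            break
    if not found:
        warnings.warn("no stable post-EGTA point found; using trace end value")
        lo = max(len(t) - 2 * half - 1, 0)
        f_egta = float(f[lo:].mean())
    delta = f_egta - f_r
    normalized = None
    if control_deltas is not None:
        ctrl = float(np.mean(np.asarray(control_deltas, dtype=float)))
        if ctrl == 0:
            raise ValueError("control delta mean is zero; cannot normalize")
        normalized = delta / ctrl
    return DeltaAfu(
        f_r=f_r, f_egta=f_egta, delta=delta,
        t_stable_s=t_stable, stable_found=found, normalized=normalized,
    )


@dataclass
class CalciumResult:
    """Control-normalized intracellular Ca2+ summary (Fluo-4)."""

    normalized_median: float
    percent_responders: float
    responder_threshold: float
    control_percent_responders: float


def fluo4_summary(
    sample_intensities: np.ndarray | pd.Series,
    control_intensities: np.ndarray | pd.Series,
    fallback_quantile: float = 0.90,
) -> CalciumResult:
    """Normalized median Fluo-4 intensity and percent responders.

    The responder threshold marks the control condition's high-[Ca2+]
    mode: the valley of the control's bimodal log-intensity density, or
    the ``fallback_quantile`` of the control when no valley is found.
    The same threshold is then applied ("extrapolated") to the sample.
    """
    s = np.asarray(sample_intensities, dtype=float)
    c = np.asarray(control_intensities, dtype=float)
    if s.size == 0 or c.size == 0:
        raise ValueError("sample and control intensities must be non-empty")
    med_c = float(np.median(c))
    if med_c == 0:
        raise ValueError("control median is zero; cannot normalize")
    try:
        thr_log = find_antimode(log1p10(c))
        thr = float(10.0**thr_log - 1.0)
    except UnimodalError:
        thr = float(np.quantile(c, fallback_quantile))
    return CalciumResult(
        normalized_median=float(np.median(s)) / med_c,
        percent_responders=100.0 * float(np.mean(s > thr)),
        responder_threshold=thr,
        control_percent_responders=100.0 * float(np.mean(c > thr)),
    )
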