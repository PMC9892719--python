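"""Compensation, hierarchical gating and barcode deconvolution.

The analysis hierarchy mirrors the acquisition software workflow:

    all events -> sperm (FSC-A/SSC-A region) -> singlets (FSC-A ~ FSC-H band)
               -> live (PI-negative) -> one population per barcode signature

Spectral spillover between the four fluorescence channels (CFSE/FITC,
CellTrace Violet, DiSC3(5)/APC, PI/PerCP) is estimated from single-stained
controls and inverted per event before any gating on fluorescence.

Barcode deconvolution estimates per-tube level centroids by 1-D Gaussian
mixture fits on each dye's log-intensity (the number of levels is known
from the scheme; absolute instrument gain is not), then assigns each live
singlet to the nearest signature centroid in (log Violet, log CFSE) space
within a configurable radius.  Events farther than the radius stay
"unassigned" and are excluded from downstream scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .plate import BarcodeScheme
from .thresholds import UnimodalError, antimode_threshold, log1p10

__all__ = [
    "FLUOR_CHANNELS",
    "SpilloverMatrix",
    "SpilloverError",
    "GateSet",
    "GatingReport",
    "default_spillover",
    "estimate_spillover",
    "compensate",
    "gate_sperm",
    "exclude_doublets",
    "gate_live",
    "assign_barcodes",
    "preprocess_tube",
    "UNASSIGNED",
]

FLUOR_CHANNELS = ("cfse", "violet", "disc3", "pi")
UNASSIGNED = "unassigned"


class SpilloverError(ValueError):
    """Spillover estimation failed (missing or degenerate control)."""


@dataclass(frozen=True)
class SpilloverMatrix:
    """Linear mixing matrix: entry (i, j) = fraction of dye i read in channel j."""

    matrix: np.ndarray
    channels: tuple[str, ...] = FLUOR_CHANNELS

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        k = len(self.channels)
        if m.shape != (k, k):
            raise ValueError(f"spillover matrix must be {k}x{k}")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover diagonal must be 1")
        off = m[~np.eye(k, dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValueError("off-diagonal spillover must be in [0, 1)")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("spillover matrix is singular")

    @classmethod
    def identity(cls, channels: tuple[str, ...] = FLUOR_CHANNELS) -> "SpilloverMatrix":
        return cls(np.eye(len(channels)), channels)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.channels), columns=list(self.channels))


def default_spillover() -> SpilloverMatrix:
    """Modest default bleed: CFSE→PI 10%, Violet→CFSE 5%, DiSC3→PI 5%."""
    s = np.eye(4)
    idx = {c: i for i, c in enumerate(FLUOR_CHANNELS)}
    s[idx["cfse"], idx["pi"]] = 0.10
    s[idx["violet"], idx["cfse"]] = 0.05
    s[idx["disc3"], idx["pi"]] = 0.05
    return SpilloverMatrix(s)


def estimate_spillover(
    single_stain_tables: dict[str, pd.DataFrame],
    channels: tuple[str, ...] = FLUOR_CHANNELS,
) -> SpilloverMatrix:
    """Least-squares spillover from one single-stained tube per dye.

    For each dye the off-channel signal is regressed (with intercept, so
    autofluorescence background does not bias the slope) on the primary
    channel over the brighter half of the events; the slope is the
    spillover coefficient.  Diagonal is normalized to 1.
    """
    k = len(channels)
    s = np.eye(k)
    for i, dye in enumerate(channels):
        if dye not in single_stain_tables:
            raise SpilloverError(f"missing single-stain control for dye {dye!r}")
        tab = single_stain_tables[dye]
        x = np.asarray(tab[dye], dtype=float)
        bright = x >= np.median(x)
        if x[bright].std() < 1e-9 * max(1.0, abs(float(x.mean()))):
            raise SpilloverError(
                f"single-stain control for dye {dye!r} has no signal variation "
                "in its primary channel (singular system)"
            )
        for j, ch in enumerate(channels):
            if j == i:
                continue
            y = np.asarray(tab[ch], dtype=float)
            slope = np.polyfit(x[bright], y[bright], 1)[0]
            s[i, j] = max(slope, 0.0)
    try:
        return SpilloverMatrix(s, channels)
    except ValueError as exc:
        raise SpilloverError(f"estimated spillover matrix invalid: {exc}") from exc


def compensate(events: pd.DataFrame, spillover: SpilloverMatrix) -> pd.DataFrame:
    """Invert linear spectral mixing per event.

    Observed = true @ S, so the fluorescence block is right-multiplied by
    S^-1.  Scatter and time are untouched.  Negative compensated values
    are legitimate (background subtraction noise) and preserved.
    """
    chans = list(spillover.channels)
    out = events.copy()
    obs = out[chans].to_numpy(dtype=float)
    true = np.linalg.solve(spillover.matrix.T, obs.T).T
    out[chans] = true
    return out


@dataclass
class GateSet:
    """Parameters of the gating hierarchy.

    Scatter bounds are on log10(1+x); defaults match the bundled event
    simulator and are expected to be overridden for real instrument data.
    ``disc3_threshold`` (the "dashed line") is data-derived from the
    negative control — see :func:`catscreen.assays.set_disc3_threshold`.
    """

    fsc_a_log_range: tuple[float, float] = (4.3, 5.5)
    ssc_a_log_range: tuple[float, float] = (4.0, 5.0)
    doublet_ratio_tol: float = 0.30
    pi_threshold: float | None = 300.0
    pi_fallback_quantile: float = 0.99
    disc3_threshold: float | None = None
    barcode_radius: float = 0.45
    barcode_min_separation: float = 0.20
    min_events: int = 200

    def __post_init__(self) -> None:
        if self.doublet_ratio_tol <= 0:
            raise ValueError("doublet_ratio_tol must be > 0")
        if self.barcode_radius <= 0:
            raise ValueError("barcode_radius must be > 0")


@dataclass
class GatingReport:
    """Event counts along the hierarchy plus barcode assignment quality."""

    n_total: int = 0
    n_sperm: int = 0
    n_singlet: int = 0
    n_live: int = 0
    per_barcode: dict[str, int] = field(default_factory=dict)
    n_unassigned: int = 0
    assignment_purity: float | None = None
    assignment_yield: float | None = None
    flags: list[str] = field(default_factory=list)

    def validate_monotone(self) -> None:
        counts = [self.n_total, self.n_sperm, self.n_singlet, self.n_live]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError(f"gating hierarchy counts not monotone: {counts}")
        if sum(self.per_barcode.values()) > self.n_live:
            raise AssertionError("barcode counts exceed live count")


def gate_sperm(events: pd.DataFrame, gates: GateSet | None = None) -> pd.DataFrame:
    """Keep events inside the sperm scatter region (FSC-A x SSC-A, log scale)."""
    gates = gates or GateSet()
    lf = log1p10(events["fsc_a"].to_numpy())
    ls = log1p10(events["ssc_a"].to_numpy())
    m = (
        (lf >= gates.fsc_a_log_range[0]) & (lf <= gates.fsc_a_log_range[1])
        & (ls >= gates.ssc_a_log_range[0]) & (ls <= gates.ssc_a_log_range[1])
    )
    return events.loc[m]


def exclude_doublets(events: pd.DataFrame, gates: GateSet | None = None) -> pd.DataFrame:
    """Drop events off the singlet FSC-A ~ FSC-H line.

    The singlet slope is estimated robustly as the median FSC-A/FSC-H
    ratio of the input; events whose ratio deviates more than
    ``doublet_ratio_tol`` (relative) are removed.
    """
    gates = gates or GateSet()
    if len(events) == 0:
        return events
    ratio = events["fsc_a"].to_numpy() / np.maximum(events["fsc_h"].to_numpy(), 1e-12)
    slope = float(np.median(ratio))
    m = np.abs(ratio / slope - 1.0) <= gates.doublet_ratio_tol
    return events.loc[m]


def gate_live(events: pd.DataFrame, gates: GateSet | None = None) -> pd.DataFrame:
    """Keep PI-negative (live) events.

    With ``gates.pi_threshold=None`` the threshold is the valley of the
    bimodal log-PI density; if no valley is found, the configured
    fallback quantile of the PI distribution is used instead.
    """
    gates = gates or GateSet()
    if len(events) == 0:
        return events
    pi = events["pi"].to_numpy(dtype=float)
    thr = gates.pi_threshold
    if thr is None:
        try:
            thr = antimode_threshold(pi)
        except UnimodalError:
            thr = float(np.quantile(pi, gates.pi_fallback_quantile))
    return events.loc[pi < thr]


def _level_centroids(
    log_values: np.ndarray, n_levels: int, max_fit_events: int = 20_000
) -> np.ndarray:
    """Sorted per-level centroids of one dye's log-intensities (1-D GMM)."""
    if n_levels == 1 or np.ptp(log_values) < 1e-12:
        return np.array([float(np.median(log_values))] * n_levels)[:n_levels]
    sub = log_values
    if log_values.size > max_fit_events:
        idx = np.linspace(0, log_values.size - 1, max_fit_events).astype(int)
        sub = np.sort(log_values)[idx]
    gm = GaussianMixture(n_components=n_levels, random_state=0, n_init=2,
                         covariance_type="full", reg_covar=1e-4)
    gm.fit(sub.reshape(-1, 1))
    return np.sort(gm.means_.ravel())


def assign_barcodes(
    events: pd.DataFrame,
    scheme: BarcodeScheme,
    gates: GateSet | None = None,
) -> tuple[pd.DataFrame, GatingReport]:
    """Label each event with its barcode signature (or ``"unassigned"``).

    Returns a copy of ``events`` with a ``barcode`` column, plus a report
    holding per-barcode counts and — when ground-truth columns are
    present — assignment purity and yield.
    """
    gates = gates or GateSet()
    report = GatingReport(n_total=len(events))
    out = events.copy()
    if len(events) == 0:
        out["barcode"] = pd.Series(dtype=str)
        return out, report
    lv = log1p10(events["violet"].to_numpy(dtype=float).clip(min=0.0))
    lc = log1p10(events["cfse"].to_numpy(dtype=float).clip(min=0.0))
    cv = _level_centroids(lv, len(scheme.violet_levels_um))
    cc = _level_centroids(lc, len(scheme.cfse_levels_um))
    for name, cents in (("violet", cv), ("cfse", cc)):
        if cents.size > 1 and np.min(np.diff(cents)) < gates.barcode_min_separation:
            msg = (
                f"{name} level centroids closer than {gates.barcode_min_separation} "
                "log units; scheme may not be resolvable"
            )
            warnings.warn(msg)
            report.flags.append(f"overlapping_{name}_centroids")
    dv = np.abs(lv[:, None] - cv[None, :])
    vi = dv.argmin(axis=1)
    dc = np.abs(lc[:, None] - cc[None, :])
    cj = dc.argmin(axis=1)
    dist = np.hypot(dv[np.arange(len(lv)), vi], dc[np.arange(len(lc)), cj])
    ids = np.array(
        [[scheme.signature_id(i, j) for j in range(len(scheme.cfse_levels_um))]
         for i in range(len(scheme.violet_levels_um))]
    )
    barcode = ids[vi, cj]
    barcode = np.where(dist <= gates.barcode_radius, barcode, UNASSIGNED)
    out["barcode"] = barcode
    assigned = barcode != UNASSIGNED
    counts = pd.Series(barcode[assigned]).value_counts()
    report.per_barcode = {k: int(v) for k, v in counts.items()}
    report.n_unassigned = int((~assigned).sum())
    if "true_barcode" in events.columns:
        truth = events["true_barcode"].to_numpy()
        scoreable = assigned & (truth != "")
        if scoreable.any():
            report.assignment_purity = float(
                np.mean(barcode[scoreable] == truth[scoreable])
            )
            report.assignment_yield = float(np.mean(assigned[truth != ""]))
    return out, report


def preprocess_tube(
    events: pd.DataFrame,
    scheme: BarcodeScheme | None = None,
    gates: GateSet | None = None,
    spillover: SpilloverMatrix | None = None,
) -> tuple[pd.DataFrame, GatingReport]:
    """Full preprocessing chain for one pooled tube.

    Compensation (if a spillover matrix is given), sperm scatter gate,
    doublet exclusion, live gate, then barcode assignment (if a scheme is
    given).  The report records counts at every hierarchy level.
    """
    gates = gates or GateSet()
    n_total = len(events)
    if spillover is not None:
        events = compensate(events, spillover)
    sperm = gate_sperm(events, gates)
    singlets = exclude_doublets(sperm, gates)
    live = gate_live(singlets, gates)
    if scheme is not None:
        labeled, report = assign_barcodes(live, scheme, gates)
    else:
        labeled = live.copy()
        labeled["barcode"] = "" if len(live) else pd.Series(dtype=str)
        report = GatingReport()
    report.n_total = n_total
    report.n_sperm = len(sperm)
    report.n_singlet = len(singlets)
    report.n_live = len(live)
    report.validate_monotone()
    return labeled, report
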