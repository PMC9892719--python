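"""Synthetic flow-cytometry event streams and spectrofluorometric traces.

The generator emulates the statistical structure the analysis pipeline
assumes for a barcoded sperm membrane-potential experiment:

* scatter — log-normal sperm singlets with a tight FSC-A ~ FSC-H relation,
  doublets at ~2x FSC-A for the same FSC-H, and low-scatter debris;
* viability — a dead subpopulation with high propidium-iodide signal;
* barcodes — per-well log-normal CellTrace Violet / CFSE intensities whose
  medians follow the dye concentration of the well's signature;
* membrane potential — a bimodal DiSC3(5) distribution (hyperpolarized
  high-fluorescence mode and depolarized low mode); after EGTA addition
  each hyperpolarized live cell depolarizes with probability ``p_mig``
  following an exponential lag;
* spectral spillover — a linear mixing matrix applied to the true dye
  signals, so compensation is a well-posed inverse problem.

Every draw goes through one :class:`numpy.random.Generator`; a fixed seed
reproduces tables bit-for-bit.  Ground-truth columns (``is_sperm``,
``is_doublet``, ``is_dead``, ``true_barcode``, ``em_state``) make the
generator usable as an oracle for gating, deconvolution and scoring tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate import BarcodeScheme, PlateLayout
from .preprocess import FLUOR_CHANNELS, SpilloverMatrix, default_spillover

__all__ = [
    "WellSimSpec",
    "SimDefaults",
    "KineticTrace",
    "simulate_well",
    "simulate_plate",
    "simulate_trace",
    "single_stain_controls",
    "signature_intensity",
]

# AFU medians: intensity = background + scale * concentration(µM)
DYE_BACKGROUND_AFU = 30.0
CFSE_SCALE_AFU_PER_UM = 800.0
VIOLET_SCALE_AFU_PER_UM = 100.0

SINGLET_FSCA_RATIO = 1.05
DOUBLET_FSCA_RATIO = 2.10

EVENT_COLUMNS = [
    "time", "fsc_a", "fsc_h", "ssc_a", "cfse", "violet", "disc3", "pi",
    "is_sperm", "is_doublet", "is_dead", "true_barcode", "em_state",
]


def signature_intensity(violet_um: float, cfse_um: float) -> tuple[float, float]:
    """Median (violet, cfse) AFU for a well stained at the given dye levels."""
    return (
        DYE_BACKGROUND_AFU + VIOLET_SCALE_AFU_PER_UM * violet_um,
        DYE_BACKGROUND_AFU + CFSE_SCALE_AFU_PER_UM * cfse_um,
    )


def _lognormal(rng: np.random.Generator, median: float, cv: float, size: int) -> np.ndarray:
    """Log-normal draw parameterized by linear-scale median and CV."""
    if cv <= 0:
        return np.full(size, float(median))
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=size)


@dataclass(frozen=True)
class WellSimSpec:
    """Event-level generative parameters for one well (one barcoded sample)."""

    n_events: int = 20_000
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.05
    dead_fraction: float = 0.10
    signature: str = ""
    violet_median_afu: float = DYE_BACKGROUND_AFU
    cfse_median_afu: float = DYE_BACKGROUND_AFU
    barcode_cv: float = 0.25
    disc3_high_median_afu: float = 1500.0
    disc3_low_median_afu: float = 150.0
    disc3_cv: float = 0.30
    disc3_high_fraction: float = 0.80
    p_mig: float = 0.8
    lag_tau_s: float = 10.0
    t_egta_s: float = 30.0
    t_end_s: float = 180.0
    spillover: SpilloverMatrix | None = None

    def __post_init__(self) -> None:
        for name in (
            "debris_fraction", "doublet_fraction", "dead_fraction",
            "disc3_high_fraction", "p_mig",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.doublet_fraction + self.dead_fraction > 1.0:
            raise ValueError("doublet_fraction + dead_fraction exceeds 1")
        if not self.t_egta_s < self.t_end_s:
            raise ValueError("t_egta_s must be < t_end_s")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")


def simulate_well(
    spec: WellSimSpec, seed: int | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw one well's event table.  See module docstring for the model."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = spec.n_events
    p_debris = spec.debris_fraction
    p_doub = (1.0 - p_debris) * spec.doublet_fraction
    p_dead = (1.0 - p_debris) * spec.dead_fraction
    p_live = max(1.0 - p_debris - p_doub - p_dead, 0.0)
    cat = rng.choice(4, size=n, p=np.array([p_debris, p_doub, p_dead, p_live]) /
                     (p_debris + p_doub + p_dead + p_live))
    debris = cat == 0
    doublet = cat == 1
    dead = cat == 2
    sperm = ~debris
    live = sperm & ~dead

    time = rng.uniform(0.0, spec.t_end_s, size=n)

    fsc_h = np.empty(n)
    fsc_a = np.empty(n)
    ssc_a = np.empty(n)
    n_sp = int(sperm.sum())
    fsc_h[sperm] = _lognormal(rng, 5e4, 0.15, n_sp)
    ratio = np.where(doublet[sperm], DOUBLET_FSCA_RATIO, SINGLET_FSCA_RATIO)
    fsc_a[sperm] = fsc_h[sperm] * ratio * _lognormal(rng, 1.0, 0.05, n_sp)
    ssc_a[sperm] = _lognormal(rng, 3e4, 0.25, n_sp)
    n_db = int(debris.sum())
    fsc_h[debris] = _lognormal(rng, 4e3, 0.5, n_db)
    fsc_a[debris] = fsc_h[debris] * _lognormal(rng, 1.0, 0.3, n_db)
    ssc_a[debris] = _lognormal(rng, 2.5e3, 0.5, n_db)

    violet = np.empty(n)
    cfse = np.empty(n)
    violet[sperm] = _lognormal(rng, spec.violet_median_afu, spec.barcode_cv, n_sp)
    cfse[sperm] = _lognormal(rng, spec.cfse_median_afu, spec.barcode_cv, n_sp)
    mult = np.where(doublet[sperm], 2.0, 1.0)
    violet[sperm] *= mult
    cfse[sperm] *= mult
    violet[debris] = _lognormal(rng, DYE_BACKGROUND_AFU, 0.5, n_db)
    cfse[debris] = _lognormal(rng, DYE_BACKGROUND_AFU, 0.5, n_db)

    # membrane-potential dye: bimodal among live sperm, EGTA-triggered switch
    disc3 = np.empty(n)
    high = np.zeros(n, dtype=bool)
    high[live] = rng.random(int(live.sum())) < spec.disc3_high_fraction
    migrator = np.zeros(n, dtype=bool)
    migrator[high] = rng.random(int(high.sum())) < spec.p_mig
    switch_time = np.full(n, np.inf)
    switch_time[migrator] = spec.t_egta_s + rng.exponential(
        spec.lag_tau_s, size=int(migrator.sum())
    )
    depolarized_now = migrator & (time >= switch_time)
    is_high_now = high & ~depolarized_now
    disc3[live & is_high_now] = _lognormal(
        rng, spec.disc3_high_median_afu, spec.disc3_cv, int((live & is_high_now).sum())
    )
    low_now = live & ~is_high_now
    disc3[low_now] = _lognormal(rng, spec.disc3_low_median_afu, spec.disc3_cv, int(low_now.sum()))
    disc3[dead] = _lognormal(rng, 2.0 * spec.disc3_low_median_afu, 0.8, int(dead.sum()))
    disc3[debris] = _lognormal(rng, 0.5 * spec.disc3_low_median_afu, 0.8, n_db)

    pi = np.empty(n)
    pi[live] = _lognormal(rng, 20.0, 0.4, int(live.sum()))
    pi[dead] = _lognormal(rng, 2000.0, 0.3, int(dead.sum()))
    pi[debris] = _lognormal(rng, 15.0, 0.5, n_db)

    true = np.column_stack([cfse, violet, disc3, pi])
    spill = spec.spillover
    observed = true @ spill.matrix if spill is not None else true

    em_state = np.where(live & is_high_now, "hyperpolarized",
                        np.where(live, "depolarized", ""))
    df = pd.DataFrame(
        {
            "time": time,
            "fsc_a": fsc_a, "fsc_h": fsc_h, "ssc_a": ssc_a,
            "cfse": observed[:, 0], "violet": observed[:, 1],
            "disc3": observed[:, 2], "pi": observed[:, 3],
            "is_sperm": sperm, "is_doublet": doublet, "is_dead": dead & sperm,
            "true_barcode": np.where(sperm, spec.signature, ""),
            "em_state": em_state,
        }
    )
    df.sort_values("time", inplace=True, kind="mergesort")
    df.reset_index(drop=True, inplace=True)
    return df


@dataclass(frozen=True)
class SimDefaults:
    """Plate-level simulation conditions.

    Negative controls (and untreated/inert compounds) depolarize with a
    per-well migration probability drawn uniformly in
    ``inert_p_mig_range``; positive controls (full CatSper block) use
    ``pos_control_p_mig``.  ``p_mig_overrides`` maps compound id → p_mig
    for injected actives.
    """

    n_events_per_well: int = 20_000
    well: WellSimSpec = field(default_factory=WellSimSpec)
    neg_control_p_mig_range: tuple[float, float] = (0.7, 0.9)
    inert_p_mig_range: tuple[float, float] = (0.7, 0.9)
    pos_control_p_mig: float = 0.02
    p_mig_overrides: dict[str, float] = field(default_factory=dict)
    no_sperm_event_factor: float = 0.05
    well_weights: dict[str, float] | None = None
    spillover: SpilloverMatrix = field(default_factory=default_spillover)


def simulate_plate(
    layout: PlateLayout, sim: SimDefaults | None = None, seed: int = 0
) -> dict[int, pd.DataFrame]:
    """Simulate every well of ``layout`` and pool each matrix into one tube.

    Returns matrix id → event table with wells interleaved in acquisition
    time (events sorted by ``time``); a ``true_well`` column records the
    generating well.  Per-well event counts follow ``sim.well_weights``
    (multinomial draw over the matrix total) or are equal by default.
    """
    sim = sim or SimDefaults()
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    order = sorted(layout.wells)
    child_rngs = {
        wid: np.random.default_rng(s) for wid, s in zip(order, ss.spawn(len(order) + 1)[1:])
    }

    p_mig: dict[str, float] = {}
    for wid in order:
        w = layout.wells[wid]
        if w.role == "negative_control":
            p_mig[wid] = master.uniform(*sim.neg_control_p_mig_range)
        elif w.role == "positive_control":
            p_mig[wid] = sim.pos_control_p_mig
        elif w.role == "no_sperm":
            p_mig[wid] = 0.0
        else:
            if w.compound_id in sim.p_mig_overrides:
                p_mig[wid] = sim.p_mig_overrides[w.compound_id]
            else:
                p_mig[wid] = master.uniform(*sim.inert_p_mig_range)

    tubes: dict[int, pd.DataFrame] = {}
    for mid in layout.matrix_ids:
        wells = sorted(layout.matrix_wells(mid), key=lambda w: w.well_id)
        if sim.well_weights:
            weights = np.array([sim.well_weights.get(w.well_id, 1.0) for w in wells])
            weights = weights / weights.sum()
            counts = master.multinomial(sim.n_events_per_well * len(wells), weights)
        else:
            counts = np.full(len(wells), sim.n_events_per_well)
        parts = []
        for w, n_ev in zip(wells, counts):
            v_um, c_um = layout.scheme.levels_of(w.signature)
            v_afu, c_afu = signature_intensity(v_um, c_um)
            base = sim.well
            if w.role == "no_sperm":
                spec = dataclasses.replace(
                    base,
                    n_events=max(1, int(round(n_ev * sim.no_sperm_event_factor))),
                    debris_fraction=1.0, doublet_fraction=0.0, dead_fraction=0.0,
                    signature=w.signature, p_mig=0.0, spillover=sim.spillover,
                )
            else:
                spec = dataclasses.replace(
                    base,
                    n_events=int(n_ev), signature=w.signature,
                    violet_median_afu=v_afu, cfse_median_afu=c_afu,
                    p_mig=p_mig[w.well_id], spillover=sim.spillover,
                )
            part = simulate_well(spec, rng=child_rngs[w.well_id])
            part["true_well"] = w.well_id
            parts.append(part)
        tube = pd.concat(parts, ignore_index=True)
        tube.sort_values("time", inplace=True, kind="mergesort")
        tube.reset_index(drop=True, inplace=True)
        tubes[mid] = tube
    return tubes


def single_stain_controls(
    spillover: SpilloverMatrix | None = None,
    n_events: int = 5000,
    seed: int = 0,
    median_afu: float = 2000.0,
    cv: float = 0.3,
) -> dict[str, pd.DataFrame]:
    """Synthetic single-stained compensation tubes, one per fluorescence channel.

    Each tube carries one dye at high intensity plus autofluorescence
    background in every channel, mixed through ``spillover`` — the inputs
    :func:`catscreen.preprocess.estimate_spillover` expects.
    """
    spillover = spillover or default_spillover()
    rng = np.random.default_rng(seed)
    out = {}
    for i, dye in enumerate(FLUOR_CHANNELS):
        true = np.column_stack(
            [
                _lognormal(rng, median_afu if j == i else DYE_BACKGROUND_AFU, cv, n_events)
                for j in range(len(FLUOR_CHANNELS))
            ]
        )
        observed = true @ spillover.matrix
        df = pd.DataFrame(observed, columns=list(FLUOR_CHANNELS))
        df.insert(0, "time", np.sort(rng.uniform(0, 30, n_events)))
        out[dye] = df
    return out


@dataclass(frozen=True)
class KineticTrace:
    """Uniformly sampled cuvette fluorescence recording."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    t_egta_s: float

    def __post_init__(self) -> None:
        if len(self.time_s) != len(self.fluorescence):
            raise ValueError("time and fluorescence lengths differ")
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("trace must be uniformly sampled")


def simulate_trace(
    amplitude: float,
    noise_sd: float = 0.0,
    t_egta: float = 120.0,
    seed: int | None = None,
    baseline: float = 100.0,
    duration: float = 300.0,
    dt: float = 0.5,
    rise_tau: float = 5.0,
) -> KineticTrace:
    """Spectrofluorometric trace: baseline, then a saturating step after EGTA.

    ``rise_tau`` is the exponential rise time constant in seconds;
    ``rise_tau=0`` gives an instantaneous step of exactly ``amplitude``.
    White Gaussian noise of SD ``noise_sd`` is superimposed.
    """
    if not np.isfinite(amplitude):
        raise ValueError("amplitude must be finite")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    f = np.full_like(t, float(baseline))
    post = t >= t_egta
    if rise_tau > 0:
        f[post] += amplitude * -np.expm1(-(t[post] - t_egta) / rise_tau)
    else:
        f[post] += amplitude
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=t.size)
    return KineticTrace(time_s=t, fluorescence=np.maximum(f, 0.0), t_egta_s=t_egta)
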