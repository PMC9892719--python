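"""Plate-level screening: inhibition scores, hit calls and QC.

Each pooled tube ("matrix") carries its own vehicle (negative) and
CatSper-inhibitor (positive) control.  A compound's inhibition score is
its migration fraction placed linearly between the two controls of its
own matrix::

    score = (m_neg - m_well) / (m_neg - m_pos), clipped to [0, 1]

so 0 means "behaves like vehicle" and 1 "behaves like full block".
Compounds scoring at or above the (configurable) hit threshold are
flagged.  Plate QC summarizes control dispersion across matrices and a
Z'-style separation statistic; matrices with inverted or under-powered
controls are excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import EmResponse, score_all_barcodes, set_disc3_threshold
from .plate import PlateLayout
from .preprocess import GateSet, GatingReport, SpilloverMatrix, preprocess_tube

__all__ = [
    "WellResult",
    "QCReport",
    "PlateReport",
    "ControlInversionError",
    "inhibition_score",
    "call_hits",
    "qc_plate",
    "run_screen",
    "ScreenConfig",
]

DEFAULT_HIT_THRESHOLD = 0.5


class ControlInversionError(ValueError):
    """Negative control migrated no more than positive: matrix fails QC."""


@dataclass
class WellResult:
    well_id: str
    matrix_id: int
    signature: str
    role: str
    compound_id: str | None
    response: EmResponse | None
    inhibition_score: float | None = None
    hit: bool = False
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    neg_migrations: dict[int, float] = field(default_factory=dict)
    pos_migrations: dict[int, float] = field(default_factory=dict)
    neg_mean: float = np.nan
    neg_sd: float = np.nan
    neg_cv: float = np.nan
    pos_mean: float = np.nan
    pos_sd: float = np.nan
    z_prime: float = np.nan
    failed_matrices: dict[int, str] = field(default_factory=dict)

    @property
    def passed_matrices(self) -> list[int]:
        return [m for m in self.neg_migrations if m not in self.failed_matrices]


@dataclass
class PlateReport:
    wells: list[WellResult]
    qc: QCReport
    gating: dict[int, GatingReport]
    hit_threshold: float = DEFAULT_HIT_THRESHOLD

    @property
    def hits(self) -> list[str]:
        return sorted(
            w.compound_id for w in self.wells
            if w.hit and w.role == "compound" and w.compound_id
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            rows.append(
                {
                    "well": w.well_id, "matrix": w.matrix_id, "signature": w.signature,
                    "role": w.role, "compound": w.compound_id or "",
                    "migration_fraction": (
                        w.response.migration_fraction if w.response else None
                    ),
                    "inhibition_score": w.inhibition_score,
                    "hit": w.hit,
                    "qc_flags": ";".join(w.qc_flags),
                }
            )
        return pd.DataFrame(rows).sort_values(["matrix", "well"]).reset_index(drop=True)


def inhibition_score(well: EmResponse, neg: EmResponse, pos: EmResponse) -> float:
    """Linear placement of a well between its matrix controls (0=neg, 1=pos)."""
    for r, name in ((well, "well"), (neg, "negative control"), (pos, "positive control")):
        if r.migration_fraction is None:
            raise ValueError(f"{name} has no migration score (QC: {r.qc_flags})")
    m_neg, m_pos, m_well = (
        neg.migration_fraction, pos.migration_fraction, well.migration_fraction,
    )
    if m_neg <= m_pos:
        raise ControlInversionError(
            f"negative control migration {m_neg:.3f} <= positive {m_pos:.3f}"
        )
    return float(np.clip((m_neg - m_well) / (m_neg - m_pos), 0.0, 1.0))


def call_hits(
    results: list[WellResult], threshold: float = DEFAULT_HIT_THRESHOLD
) -> list[str]:
    """Compound ids whose inhibition score reaches ``threshold``.

    Controls and unscored (QC-failed) wells are never hits.  Mutates the
    ``hit`` flag of the passed results.
    """
    hits = []
    for w in results:
        w.hit = (
            w.role == "compound"
            and w.inhibition_score is not None
            and w.inhibition_score >= threshold
        )
        if w.hit and w.compound_id:
            hits.append(w.compound_id)
    return sorted(hits)


def qc_plate(
    control_migrations: dict[int, tuple[float | None, float | None]],
) -> QCReport:
    """Plate QC from per-matrix (negative, positive) control migrations.

    Computes control means/SD/CV across matrices and the Z'-style
    separation ``1 - 3 (sd_pos + sd_neg) / |mean_neg - mean_pos|``;
    matrices with missing or inverted controls are flagged as failed.
    """
    qc = QCReport()
    for mid, (m_neg, m_pos) in sorted(control_migrations.items()):
        if m_neg is None or m_pos is None:
            qc.failed_matrices[mid] = "control_unscored"
            continue
        qc.neg_migrations[mid] = m_neg
        qc.pos_migrations[mid] = m_pos
        if m_neg <= m_pos:
            qc.failed_matrices[mid] = "controls_inverted"
    ok = qc.passed_matrices
    if ok:
        neg = np.array([qc.neg_migrations[m] for m in ok])
        pos = np.array([qc.pos_migrations[m] for m in ok])
        qc.neg_mean, qc.neg_sd = float(neg.mean()), float(neg.std(ddof=0))
        qc.pos_mean, qc.pos_sd = float(pos.mean()), float(pos.std(ddof=0))
        qc.neg_cv = qc.neg_sd / qc.neg_mean if qc.neg_mean else np.nan
        denom = abs(qc.neg_mean - qc.pos_mean)
        qc.z_prime = 1.0 - 3.0 * (qc.pos_sd + qc.neg_sd) / denom if denom else -np.inf
    return qc


@dataclass
class ScreenConfig:
    gates: GateSet = field(default_factory=GateSet)
    spillover: SpilloverMatrix | None = None  # None: no compensation
    hit_threshold: float = DEFAULT_HIT_THRESHOLD
    t_egta_s: float = 30.0
    t_end_s: float = 180.0
    # a barcode absent from the layout is a hard error only above this share
    # of the tube's assigned events; below it is stray misassignment noise
    stray_signature_max_share: float = 0.005


def run_screen(
    layout: PlateLayout,
    tubes: dict[int, pd.DataFrame],
    config: ScreenConfig | None = None,
) -> PlateReport:
    """Score a whole plate of pooled matrix tubes against its layout.

    Per matrix: preprocess (compensate/gate/deconvolve), derive the
    DiSC3(5)+ threshold from the matrix's own negative control, score
    every barcode, then place compounds between the matrix controls.  A
    barcode observed in a tube with no layout entry is a hard error; a
    matrix whose controls fail QC yields unscored wells.
    """
    config = config or ScreenConfig()
    layout.validate(screening=True)
    wells: list[WellResult] = []
    gating: dict[int, GatingReport] = {}
    control_migrations: dict[int, tuple[float | None, float | None]] = {}
    per_matrix_results: dict[int, list[WellResult]] = {}

    for mid in layout.matrix_ids:
        if mid not in tubes:
            raise KeyError(f"no event stream supplied for matrix {mid}")
        labeled, report = preprocess_tube(
            tubes[mid], scheme=layout.scheme, gates=config.gates,
            spillover=config.spillover,
        )
        gating[mid] = report
        n_assigned = max(sum(report.per_barcode.values()), 1)
        for sig, count in report.per_barcode.items():
            try:
                layout.well_by_signature(mid, sig)
            except KeyError:
                if count / n_assigned > config.stray_signature_max_share:
                    raise
                report.flags.append(f"stray_events:{sig}")
        neg_well = layout.control_well(mid, "negative_control")
        pos_well = layout.control_well(mid, "positive_control")
        neg_events = labeled.loc[labeled["barcode"] == neg_well.signature]
        threshold = config.gates.disc3_threshold
        if threshold is None:
            threshold = set_disc3_threshold(neg_events, t_egta=config.t_egta_s)
        responses = score_all_barcodes(
            labeled, threshold,
            t_egta=config.t_egta_s, t_end=config.t_end_s,
            min_events=config.gates.min_events,
        )
        neg_resp = responses.get(neg_well.signature)
        pos_resp = responses.get(pos_well.signature)
        m_neg = neg_resp.migration_fraction if neg_resp else None
        m_pos = pos_resp.migration_fraction if pos_resp else None
        control_migrations[mid] = (m_neg, m_pos)

        matrix_results = []
        for w in sorted(layout.matrix_wells(mid), key=lambda w: w.well_id):
            resp = responses.get(w.signature)
            wr = WellResult(
                well_id=w.well_id, matrix_id=mid, signature=w.signature,
                role=w.role, compound_id=w.compound_id, response=resp,
            )
            if resp is None:
                wr.qc_flags.append(
                    "no_events" if w.role != "no_sperm" else "no_sperm_well"
                )
            elif resp.qc_flags:
                wr.qc_flags.extend(resp.qc_flags)
            matrix_results.append(wr)
        per_matrix_results[mid] = matrix_results
        wells.extend(matrix_results)

    qc = qc_plate(control_migrations)
    for mid, matrix_results in per_matrix_results.items():
        if mid in qc.failed_matrices:
            for wr in matrix_results:
                wr.qc_flags.append(f"matrix_qc_failed:{qc.failed_matrices[mid]}")
            continue
        m_neg, m_pos = control_migrations[mid]
        for wr in matrix_results:
            if wr.role != "compound" or wr.response is None:
                continue
            if wr.response.migration_fraction is None:
                continue
            wr.inhibition_score = float(
                np.clip(
                    (m_neg - wr.response.migration_fraction) / (m_neg - m_pos),
                    0.0, 1.0,
                )
            )
    call_hits(wells, threshold=config.hit_threshold)
    return PlateReport(wells=wells, qc=qc, gating=gating, hit_threshold=config.hit_threshold)
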