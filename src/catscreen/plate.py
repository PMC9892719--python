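"""Barcoding scheme, 96-well plate layout and dilution arithmetic.

A fluorescent-cell-barcoding (FCB) screen labels each sample with a unique
pair of dye intensities — here CellTrace Violet (four levels) × CellTrace
CFSE (three levels), giving twelve signatures per pooled tube ("matrix").
Eight 12-well matrices tile a 96-well plate; with one positive and one
negative control per matrix, 80 compounds are screened per plate.

Dye levels are stored as the *nominal* final concentration (the 3X-stock
convention: stock/3).  Because the 5 µl compound aliquot makes the true
mixing ratio 30/95 rather than 1/3, the exact mixed concentration is also
available via :func:`mixing_concentration`; reports default to nominal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import yaml

__all__ = [
    "BarcodeScheme",
    "DilutionStep",
    "Well",
    "PlateLayout",
    "make_scheme",
    "final_concentration",
    "mixing_concentration",
    "well_volume",
    "pooled_volume",
    "plate_capacity",
    "default_screen_layout",
    "DEFAULT_CFSE_LEVELS_UM",
    "DEFAULT_VIOLET_LEVELS_UM",
]

# Final (nominal) barcoding dye concentrations, µM
DEFAULT_CFSE_LEVELS_UM = (0.001, 0.25, 1.0)
DEFAULT_VIOLET_LEVELS_UM = (0.025, 1.0, 5.0, 20.0)

ROLES = ("compound", "positive_control", "negative_control", "no_sperm")


def _check_increasing(levels: Iterable[float], name: str) -> tuple[float, ...]:
    t = tuple(float(x) for x in levels)
    if not t:
        raise ValueError(f"{name} must be non-empty")
    if any(b <= a for a, b in zip(t, t[1:])):
        raise ValueError(f"{name} must be strictly increasing, got {t}")
    return t


@dataclass(frozen=True)
class BarcodeScheme:
    """Grid of dye levels; signature ids are "V<i>-C<j>" (1-based, dye1=Violet)."""

    violet_levels_um: tuple[float, ...]
    cfse_levels_um: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "violet_levels_um", _check_increasing(self.violet_levels_um, "violet_levels")
        )
        object.__setattr__(
            self, "cfse_levels_um", _check_increasing(self.cfse_levels_um, "cfse_levels")
        )

    @property
    def n_signatures(self) -> int:
        return len(self.violet_levels_um) * len(self.cfse_levels_um)

    def signature_id(self, violet_idx: int, cfse_idx: int) -> str:
        if not (0 <= violet_idx < len(self.violet_levels_um)):
            raise IndexError(f"violet level index {violet_idx} out of range")
        if not (0 <= cfse_idx < len(self.cfse_levels_um)):
            raise IndexError(f"cfse level index {cfse_idx} out of range")
        return f"V{violet_idx + 1}-C{cfse_idx + 1}"

    def signatures(self) -> list[tuple[str, float, float]]:
        """All (id, violet µM, cfse µM), dye1 (Violet) major, dye2 minor."""
        return [
            (self.signature_id(i, j), v, c)
            for i, v in enumerate(self.violet_levels_um)
            for j, c in enumerate(self.cfse_levels_um)
        ]

    def levels_of(self, signature: str) -> tuple[float, float]:
        """(violet µM, cfse µM) for a signature id like "V2-C3"."""
        try:
            v_s, c_s = signature.split("-")
            vi, cj = int(v_s[1:]) - 1, int(c_s[1:]) - 1
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed signature id {signature!r}") from exc
        self.signature_id(vi, cj)  # bounds check
        return self.violet_levels_um[vi], self.cfse_levels_um[cj]


def make_scheme(
    cfse_levels_um: Iterable[float] = DEFAULT_CFSE_LEVELS_UM,
    violet_levels_um: Iterable[float] = DEFAULT_VIOLET_LEVELS_UM,
) -> BarcodeScheme:
    """Build a two-dye barcode scheme from strictly increasing level lists."""
    return BarcodeScheme(tuple(violet_levels_um), tuple(cfse_levels_um))


@dataclass(frozen=True)
class DilutionStep:
    """One addition of a stock into a well: concentrations in any consistent unit."""

    stock_concentration: float
    volume_added_ul: float
    total_volume_ul: float

    def __post_init__(self) -> None:
        if self.total_volume_ul <= 0:
            raise ValueError("total volume must be > 0")
        if self.volume_added_ul < 0 or self.volume_added_ul > self.total_volume_ul:
            raise ValueError("volume added must be in [0, total volume]")


def final_concentration(step: DilutionStep) -> float:
    """Concentration after dilution: stock × v_added / v_total."""
    return step.stock_concentration * step.volume_added_ul / step.total_volume_ul


def mixing_concentration(stock_3x: float, volume_added_ul: float = 30.0,
                         total_volume_ul: float = 95.0) -> float:
    """Exact mixed concentration of a nominal-3X dye stock in the assay well."""
    return final_concentration(DilutionStep(stock_3x, volume_added_ul, total_volume_ul))


@dataclass
class Well:
    well_id: str
    matrix_id: int
    signature: str
    role: str
    compound_id: str | None = None
    # component volumes in µl; the post-incubation medium top-up is kept
    # separate so the assay-mix volume (95 µl) and the pooled per-well
    # volume (300 µl) are both recoverable.
    volumes_ul: dict[str, float] = field(
        default_factory=lambda: {"sperm": 30.0, "violet": 30.0, "cfse": 30.0, "compound": 5.0}
    )
    topup_ul: float = 205.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        for k, v in self.volumes_ul.items():
            if v < 0:
                raise ValueError(f"negative volume for {k}")


@dataclass
class PlateLayout:
    scheme: BarcodeScheme
    wells: dict[str, Well]

    def matrix_wells(self, matrix_id: int) -> list[Well]:
        return [w for w in self.wells.values() if w.matrix_id == matrix_id]

    @property
    def matrix_ids(self) -> list[int]:
        return sorted({w.matrix_id for w in self.wells.values()})

    def validate(self, screening: bool = True) -> None:
        for mid in self.matrix_ids:
            ws = self.matrix_wells(mid)
            sigs = [w.signature for w in ws]
            if len(sigs) != len(set(sigs)):
                raise ValueError(f"duplicate signatures in matrix {mid}")
            if screening:
                n_pos = sum(w.role == "positive_control" for w in ws)
                n_neg = sum(w.role == "negative_control" for w in ws)
                if n_pos != 1 or n_neg != 1:
                    raise ValueError(
                        f"matrix {mid} needs exactly one positive and one negative "
                        f"control (got {n_pos} / {n_neg})"
                    )

    def control_well(self, matrix_id: int, role: str) -> Well:
        for w in self.matrix_wells(matrix_id):
            if w.role == role:
                return w
        raise KeyError(f"matrix {matrix_id} has no {role} well")

    def well_by_signature(self, matrix_id: int, signature: str) -> Well:
        for w in self.matrix_wells(matrix_id):
            if w.signature == signature:
                return w
        raise KeyError(f"no layout entry for signature {signature!r} in matrix {matrix_id}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scheme": {
                "violet_levels_um": list(self.scheme.violet_levels_um),
                "cfse_levels_um": list(self.scheme.cfse_levels_um),
            },
            "wells": {wid: asdict(w) for wid, w in sorted(self.wells.items())},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateLayout":
        scheme = BarcodeScheme(
            tuple(d["scheme"]["violet_levels_um"]), tuple(d["scheme"]["cfse_levels_um"])
        )
        wells = {wid: Well(**wd) for wid, wd in d["wells"].items()}
        return cls(scheme=scheme, wells=wells)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PlateLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def plate_map(self) -> "pandas.DataFrame":  # noqa: F821 - typing only
        import pandas as pd

        rows = []
        for wid, w in sorted(self.wells.items()):
            v_um, c_um = self.scheme.levels_of(w.signature)
            rows.append(
                {
                    "well": wid, "matrix": w.matrix_id, "signature": w.signature,
                    "role": w.role, "compound": w.compound_id or "",
                    "violet_um": v_um, "cfse_um": c_um,
                    "assay_volume_ul": well_volume(self, wid),
                }
            )
        return pd.DataFrame(rows)


def well_volume(layout: PlateLayout, well_id: str) -> float:
    """Assay-mix volume of a well in µl (sum of component volumes)."""
    return float(sum(layout.wells[well_id].volumes_ul.values()))


def pooled_volume(layout: PlateLayout, matrix_id: int, carrier_volume_ul: float = 5000.0) -> float:
    """Volume (µl) of the pooled matrix tube: per-well totals plus carrier medium."""
    total = carrier_volume_ul
    for w in layout.matrix_wells(matrix_id):
        total += sum(w.volumes_ul.values()) + w.topup_ul
    return total


def plate_capacity(n_wells: int = 96, matrix_size: int = 12, controls_per_matrix: int = 2) -> int:
    """Number of test compounds per plate given the matrix/control design."""
    if matrix_size <= 0 or n_wells % matrix_size:
        raise ValueError("n_wells must be a positive multiple of matrix_size")
    if controls_per_matrix > matrix_size:
        raise ValueError("more controls than wells per matrix")
    return (matrix_size - controls_per_matrix) * (n_wells // matrix_size)


def default_screen_layout(
    compound_ids: Iterable[str] | None = None,
    scheme: BarcodeScheme | None = None,
    n_matrices: int = 8,
    negative_signature: str = "V1-C1",
    positive_signature: str = "V3-C1",
    no_sperm_signature: str | None = None,
) -> PlateLayout:
    """96-well screening layout: ``n_matrices`` pooled tubes of 12 barcodes.

    Controls occupy a fixed signature in every matrix (vehicle at V1-C1,
    CatSper inhibitor at V3-C1 by default, both configurable); remaining
    signatures take compounds in order.  ``no_sperm_signature`` optionally
    reserves one signature per matrix as an empty-well identification
    control.
    """
    scheme = scheme or make_scheme()
    reserved = {negative_signature, positive_signature}
    if no_sperm_signature:
        reserved.add(no_sperm_signature)
    if len(reserved) < 2 + bool(no_sperm_signature):
        raise ValueError("control signatures must be distinct")
    free_per_matrix = scheme.n_signatures - len(reserved)
    if compound_ids is None:
        compound_ids = [f"C{i + 1:03d}" for i in range(free_per_matrix * n_matrices)]
    compound_ids = list(compound_ids)
    if len(compound_ids) > free_per_matrix * n_matrices:
        raise ValueError(
            f"{len(compound_ids)} compounds exceed plate capacity "
            f"{free_per_matrix * n_matrices}"
        )
    wells: dict[str, Well] = {}
    it = iter(compound_ids)
    rows = "ABCDEFGH"
    for m in range(1, n_matrices + 1):
        for k, (sig, _, _) in enumerate(scheme.signatures()):
            wid = f"{rows[(m - 1) % len(rows)]}{k + 1:02d}"
            if sig == negative_signature:
                w = Well(wid, m, sig, "negative_control", compound_id=None)
            elif sig == positive_signature:
                w = Well(wid, m, sig, "positive_control", compound_id=None)
            elif no_sperm_signature and sig == no_sperm_signature:
                w = Well(wid, m, sig, "no_sperm", compound_id=None)
            else:
                cid = next(it, None)
                if cid is None:
                    continue  # plate not full
                w = Well(wid, m, sig, "compound", compound_id=cid)
            wells[wid] = w
    layout = PlateLayout(scheme=scheme, wells=wells)
    layout.validate(screening=True)
    return layout
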