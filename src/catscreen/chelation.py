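"""Ca2+/Mg2+–EGTA equilibrium solver.

The depolarization assay triggers CatSper-mediated Na+ influx by chelating
extracellular divalent cations with EGTA.  The free Ca2+ remaining after
EGTA addition is what matters biologically, and it depends strongly on pH,
temperature and ionic strength because EGTA's two amine nitrogens are
partially protonated near physiological pH.

This module computes proton-corrected ("apparent") binding constants and
solves the simultaneous Ca/Mg/EGTA mass-balance system, in the style of the
classic chelator calculators.  Corrections applied to the shipped reference
constants (see ``data/egta_constants.json``):

* ionic strength — extended Debye–Hückel (Davies) activity coefficients,
  with the Debye slope evaluated at the working temperature;
* temperature — van't Hoff with per-reaction enthalpies from the data file;
* pH scale — a pH-meter reading is a H+ *activity*; it is converted to a
  concentration with the Davies single-ion coefficient before being used
  together with concentration-based constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "BufferComposition",
    "ChelatorConstants",
    "ChelationResult",
    "ChelationError",
    "ConfigurationError",
    "apparent_kd",
    "solve_equilibrium",
    "load_constants",
]

R_GAS = 8.31446  # J / (mol K)


class ChelationError(RuntimeError):
    """Solver failed to reach the requested mass-balance residual."""


class ConfigurationError(ValueError):
    """Constant set incomplete or inconsistent for the requested metal."""


@dataclass(frozen=True)
class BufferComposition:
    """Total (analytical) composition of an aqueous buffer.

    Concentrations are molar; ``ph`` is the pH-meter reading of the final
    medium; ``temperature`` in degrees Celsius.  ``ionic_strength`` is the
    working ionic strength in M — for a typical physiological saline
    (~120–150 mM monovalent salt) 0.15 M is a reasonable default.
    """

    total_ca: float
    total_mg: float
    total_egta: float
    ph: float = 7.4
    temperature: float = 37.0
    ionic_strength: float = 0.15

    def __post_init__(self) -> None:
        for name in ("total_ca", "total_mg", "total_egta", "ionic_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.ph < 14.0:
            raise ValueError("ph must be in (0, 14)")


@dataclass(frozen=True)
class MetalConstants:
    charge: int
    log_k_ml: float
    delta_h_ml_kj: float
    log_k_mhl: float | None = None
    delta_h_mhl_kj: float = 0.0


@dataclass(frozen=True)
class ChelatorConstants:
    """Stepwise association constants for one chelator.

    ``log_k_protonation`` are stepwise constants L+H=HL, HL+H=H2L, ... on
    log10 scale at (``ref_temperature``, ``ref_ionic_strength``);
    ``metals`` maps metal name → :class:`MetalConstants` where ``log_k_ml``
    is M+L=ML and ``log_k_mhl`` is M+HL=MHL.
    """

    name: str
    ligand_charge: int
    log_k_protonation: tuple[float, ...]
    delta_h_protonation_kj: tuple[float, ...]
    metals: Mapping[str, MetalConstants]
    ref_temperature: float = 20.0
    ref_ionic_strength: float = 0.1

    def __post_init__(self) -> None:
        if len(self.log_k_protonation) != len(self.delta_h_protonation_kj):
            raise ConfigurationError("protonation constants and enthalpies differ in length")
        for v in self.log_k_protonation:
            if not math.isfinite(v):
                raise ConfigurationError("non-finite protonation constant")


def load_constants(path: str | None = None) -> ChelatorConstants:
    """Load a chelator constant set from JSON (the shipped EGTA set by default)."""
    if path is None:
        text = resources.files("catscreen.data").joinpath("egta_constants.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    metals = {
        name: MetalConstants(
            charge=int(m["charge"]),
            log_k_ml=float(m["log_k_ml"]),
            delta_h_ml_kj=float(m.get("delta_h_ml_kj", 0.0)),
            log_k_mhl=(float(m["log_k_mhl"]) if m.get("log_k_mhl") is not None else None),
            delta_h_mhl_kj=float(m.get("delta_h_mhl_kj", 0.0)),
        )
        for name, m in raw["metals"].items()
    }
    return ChelatorConstants(
        name=raw["chelator"],
        ligand_charge=int(raw["ligand_charge"]),
        log_k_protonation=tuple(float(p["log_k"]) for p in raw["protonation"]),
        delta_h_protonation_kj=tuple(float(p["delta_h_kj"]) for p in raw["protonation"]),
        metals=metals,
        ref_temperature=float(raw["reference_temperature_c"]),
        ref_ionic_strength=float(raw["reference_ionic_strength_m"]),
    )


@dataclass(frozen=True)
class ChelationResult:
    """Equilibrium speciation of a metal/chelator buffer (all molar)."""

    free_ca: float
    free_mg: float
    free_egta: float  # unbound chelator, summed over protonation states
    bound: Mapping[str, float] = field(default_factory=dict)
    residual: float = 0.0  # max absolute mass-balance error (M)

    @property
    def free_ca_nm(self) -> float:
        return self.free_ca * 1e9


# ---------------------------------------------------------------------------
# activity / temperature corrections


def _debye_slope(temperature_c: float) -> float:
    """Debye–Hückel A coefficient (log10 basis) for water at ``temperature_c``."""
    t = temperature_c
    # static dielectric constant of water (Malmberg & Maryott fit)
    eps = 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3
    tk = t + 273.15
    return 1.824829e6 * (eps * tk) ** -1.5


def _davies_f(ionic_strength: float) -> float:
    s = math.sqrt(ionic_strength)
    return s / (1.0 + s) - 0.3 * ionic_strength


def _corrected_log_k(
    log_k_ref: float,
    delta_h_kj: float,
    charge_product_q: int,
    temperature_c: float,
    ionic_strength: float,
    ref_temperature_c: float,
    ref_ionic_strength: float,
) -> float:
    """Move one stepwise association constant to working T and I.

    ``charge_product_q`` is z_a^2 + z_b^2 - z_ab^2 for the association
    a + b = ab; the Davies correction lowers the concentration constant as
    ionic strength rises.
    """
    a_ref = _debye_slope(ref_temperature_c)
    a_work = _debye_slope(temperature_c)
    log_k = log_k_ref - charge_product_q * (
        a_work * _davies_f(ionic_strength) - a_ref * _davies_f(ref_ionic_strength)
    )
    t1 = ref_temperature_c + 273.15
    t2 = temperature_c + 273.15
    log_k += delta_h_kj * 1e3 / (math.log(10.0) * R_GAS) * (1.0 / t1 - 1.0 / t2)
    return log_k


def _h_concentration(ph: float, temperature_c: float, ionic_strength: float) -> float:
    """Convert a pH-meter (activity) reading to [H+] in M."""
    log_gamma_h = -_debye_slope(temperature_c) * _davies_f(ionic_strength)
    return 10.0 ** (-ph) / (10.0**log_gamma_h)


def _proton_charge_q(step: int, ligand_charge: int) -> int:
    """q for protonation step ``step`` (1-based): H+ + H_(k-1)L -> H_k L."""
    z_l = ligand_charge + (step - 1)
    z_hl = z_l + 1
    return 1 + z_l**2 - z_hl**2


def _working_constants(
    constants: ChelatorConstants, temperature: float, ionic_strength: float
) -> tuple[list[float], dict[str, tuple[float, float | None]]]:
    """Return protonation K's and per-metal (K_ML, K_MHL) at working T, I."""
    k_h = []
    for i, (log_k, dh) in enumerate(
        zip(constants.log_k_protonation, constants.delta_h_protonation_kj)
    ):
        q = _proton_charge_q(i + 1, constants.ligand_charge)
        k_h.append(
            10.0
            ** _corrected_log_k(
                log_k, dh, q, temperature, ionic_strength,
                constants.ref_temperature, constants.ref_ionic_strength,
            )
        )
    z_l = constants.ligand_charge
    out: dict[str, tuple[float, float | None]] = {}
    for name, m in constants.metals.items():
        q_ml = m.charge**2 + z_l**2 - (m.charge + z_l) ** 2
        k_ml = 10.0 ** _corrected_log_k(
            m.log_k_ml, m.delta_h_ml_kj, q_ml, temperature, ionic_strength,
            constants.ref_temperature, constants.ref_ionic_strength,
        )
        k_mhl = None
        if m.log_k_mhl is not None:
            z_hl = z_l + 1
            q_mhl = m.charge**2 + z_hl**2 - (m.charge + z_hl) ** 2
            k_mhl = 10.0 ** _corrected_log_k(
                m.log_k_mhl, m.delta_h_mhl_kj, q_mhl, temperature, ionic_strength,
                constants.ref_temperature, constants.ref_ionic_strength,
            )
        out[name] = (k_ml, k_mhl)
    return k_h, out


def _alpha_h(k_h: list[float], h: float) -> float:
    """Protonation polynomial 1 + K1[H] + K1K2[H]^2 + ..."""
    alpha = 1.0
    cum = 1.0
    for k in k_h:
        cum *= k * h
        alpha += cum
    return alpha


def apparent_kd(
    constants: ChelatorConstants,
    metal: str,
    ph: float,
    temperature: float = 37.0,
    ionic_strength: float = 0.15,
) -> float:
    """Apparent (proton-corrected) dissociation constant of metal–chelator, in M.

    ``Kd_app = alpha_H / (K_ML + K_MHL * K_H1 * [H+])`` where ``alpha_H`` is
    the protonation polynomial of the free ligand.  As pH rises the
    protonation terms vanish and ``Kd_app`` approaches the intrinsic
    ``1 / K_ML`` (slightly modified by the MHL term).
    """
    if metal not in constants.metals:
        raise ConfigurationError(
            f"no binding constants for metal {metal!r} in set {constants.name!r}"
        )
    k_h, metals = _working_constants(constants, temperature, ionic_strength)
    h = _h_concentration(ph, temperature, ionic_strength)
    k_ml, k_mhl = metals[metal]
    k_eff = k_ml
    if k_mhl is not None and k_h:
        k_eff += k_mhl * k_h[0] * h
    return _alpha_h(k_h, h) / k_eff


def solve_equilibrium(
    comp: BufferComposition,
    constants: ChelatorConstants | None = None,
    *,
    tol: float = 1e-15,
    max_iter: int = 200,
) -> ChelationResult:
    """Solve the simultaneous Ca/Mg/chelator mass-balance equilibrium.

    A single unknown — unbound chelator ``L_f`` (summed over protonation
    states) — closes the system: free metal follows from its total and
    apparent Kd, and the chelator balance ``L_f + sum(bound) = L_total`` is
    strictly increasing in ``L_f``.  Newton iteration with a bisection
    fallback; deterministic.
    """
    if constants is None:
        constants = load_constants()
    kd = {
        m: apparent_kd(constants, m, comp.ph, comp.temperature, comp.ionic_strength)
        for m in ("ca", "mg")
    }
    totals = {"ca": comp.total_ca, "mg": comp.total_mg}
    l_tot = comp.total_egta

    def free_metal(m: str, l_f: float) -> float:
        return totals[m] / (1.0 + l_f / kd[m])

    def g(l_f: float) -> float:
        bound = sum(totals[m] - free_metal(m, l_f) for m in totals)
        return l_f + bound - l_tot

    if l_tot == 0.0:
        l_f = 0.0
    else:
        l_f = l_tot  # upper bound; g(l_tot) >= 0
        lo, hi = 0.0, l_tot
        for _ in range(max_iter):
            val = g(l_f)
            if val > 0:
                hi = l_f
            else:
                lo = l_f
            dg = 1.0 + sum(
                totals[m] * (1.0 / kd[m]) / (1.0 + l_f / kd[m]) ** 2 for m in totals
            )
            step = val / dg
            nxt = l_f - step
            if not (lo < nxt < hi):
                nxt = 0.5 * (lo + hi)
            if abs(nxt - l_f) <= tol * max(l_f, 1e-30):
                l_f = nxt
                break
            l_f = nxt
        else:
            raise ChelationError(
                f"equilibrium solver did not converge; residual {g(l_f):.3e} M"
            )

    k_h, metals = _working_constants(constants, comp.temperature, comp.ionic_strength)
    h = _h_concentration(comp.ph, comp.temperature, comp.ionic_strength)
    alpha = _alpha_h(k_h, h)
    l_unprot = l_f / alpha
    bound: dict[str, float] = {}
    free = {}
    for m in ("ca", "mg"):
        fm = free_metal(m, l_f) if l_tot > 0 else totals[m]
        free[m] = fm
        k_ml, k_mhl = metals[m]
        bound[f"{m}_l"] = k_ml * fm * l_unprot
        if k_mhl is not None and k_h:
            bound[f"{m}_hl"] = k_mhl * k_h[0] * h * fm * l_unprot
    residual = max(
        abs(free["ca"] + bound["ca_l"] + bound.get("ca_hl", 0.0) - comp.total_ca),
        abs(free["mg"] + bound["mg_l"] + bound.get("mg_hl", 0.0) - comp.total_mg),
        abs(l_f + sum(bound.values()) - l_tot) if l_tot > 0 else 0.0,
    )
    if residual > 1e-12:
        raise ChelationError(f"mass-balance residual {residual:.3e} M exceeds 1e-12 M")
    return ChelationResult(
        free_ca=free["ca"], free_mg=free["mg"], free_egta=l_f,
        bound=bound, residual=residual,
    )
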