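"""Lumped 19-level vascular model of the preterm-infant brain.

The brain vasculature is summarised as 19 serial levels (9 arteriolar,
1 capillary, 9 venular); all vessels within a level are in parallel, so
the level resistance is the single-vessel resistance over the vessel
count.  An adult base table (per-level counts, lengths, diameters) is
rescaled to a 25-gestational-week infant by dividing counts, lengths and
diameters by ``12 - 1.22|i-10|``, ``1 + 0.14|i-10|`` and
``1 + 0.11|i-10|`` respectively; noncapillary vessels use Poiseuille
resistance with an apparent blood viscosity of 0.003 Pa*s.

The capillary level (i = 10) is split into two parallel lumped
networks: the germinal matrix -- the fragile, highly vascularised
periventricular region where most neonatal intraventricular haemorrhages
originate -- and the rest of the brain.  Their resistances come either
from explicit numbers or from :mod:`capnet.capnetsim` solves scaled by
capillary count.  The quantity of clinical interest is the pressure
drop across the germinal matrix, ``dp = Q * R10``, with ``Q`` the total
cerebral blood flow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import ConfigError
from .hemres import poiseuille_resistance
from .units import MMHG, UM, m3s_to_ml_min

__all__ = [
    "Table1Params",
    "VesselLevel",
    "BrainLumpModel",
    "capillary_counts",
    "infant_scaling",
    "combine_capillary_level",
    "total_resistance",
    "total_flow",
    "gm_pressure_drop",
    "load_base_table",
]

#: apparent whole-blood viscosity used for noncapillary levels, Pa*s
APPARENT_VISCOSITY = 0.003

#: index of the capillary level in the 19-level hierarchy
CAPILLARY_LEVEL = 10


@dataclass(frozen=True)
class Table1Params:
    """Morphometric and pressure parameters of a 25-week infant brain.

    ``N_A``/``w_A`` are adult capillary count and brain weight, ``w``
    the infant brain weight, ``p_GM`` the germinal-matrix weight
    fraction and ``kappa`` its capillary-density excess over average
    brain tissue; ``p_art``/``p_ven`` are arterial and venous pressures
    in Pa.
    """

    N_A: float = 756e6
    w_A: float = 1.2
    w: float = 0.1
    p_GM: float = 0.023
    kappa: float = 1.5
    p_art: float = 34 * MMHG
    p_ven: float = 5 * MMHG

    def __post_init__(self) -> None:
        if min(self.N_A, self.w_A, self.w, self.kappa) <= 0 or self.p_GM < 0:
            raise ConfigError("morphometric parameters must be positive")
        if self.p_art <= self.p_ven:
            raise ConfigError("arterial pressure must exceed venous pressure")

    @property
    def w_GM(self) -> float:
        """Germinal-matrix weight (kg)."""
        return self.p_GM * self.w


def capillary_counts(params: Table1Params) -> tuple[float, float]:
    """Capillary numbers of the germinal matrix and the rest of the
    brain, scaled from the adult capillary density:

        N_GM = kappa * w_GM * N_A / w_A,   N_B = (w - w_GM) * N_A / w_A.
    """
    n_gm = params.kappa * params.w_GM * params.N_A / params.w_A
    n_b = (params.w - params.w_GM) * params.N_A / params.w_A
    return n_gm, n_b


def infant_scaling(i: int) -> tuple[float, float, float]:
    """Divisors converting adult level ``i`` to the 25-week infant:
    (vessel count, length, diameter)."""
    if not 1 <= i <= 19:
        raise IndexError("level index must lie in 1..19")
    d = abs(i - CAPILLARY_LEVEL)
    return (12.0 - 1.22 * d, 1.0 + 0.14 * d, 1.0 + 0.11 * d)


def combine_capillary_level(R_GM: float, R_B: float) -> float:
    """Parallel combination of the germinal-matrix and rest-of-brain
    capillary networks, ``(1/R_GM + 1/R_B)^-1``."""
    if R_GM <= 0 or R_B <= 0:
        raise ValueError("lumped resistances must be positive")
    return 1.0 / (1.0 / R_GM + 1.0 / R_B)


@dataclass(frozen=True)
class VesselLevel:
    """One level of the hierarchy: ``N_i`` parallel vessels of
    single-vessel resistance ``R_bar`` (level resistance ``R_bar/N_i``)."""

    index: int
    N: float
    R_bar: float

    @property
    def R(self) -> float:
        return self.R_bar / self.N


def load_base_table(path: str | Path) -> list[dict]:
    """Read and validate an adult 19-level base table.

    Schema: JSON list of 19 records ``{level, count, length_um,
    diameter_um}``, levels 1..19 each appearing once.
    """
    try:
        records = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read base table {path}: {exc}") from None
    if not isinstance(records, list) or len(records) != 19:
        raise ConfigError("base table must list exactly 19 levels")
    seen = set()
    for rec in records:
        missing = {"level", "count", "length_um", "diameter_um"} - set(rec)
        if missing:
            raise ConfigError(f"base-table record missing fields: {sorted(missing)}")
        seen.add(int(rec["level"]))
        if min(rec["count"], rec["length_um"], rec["diameter_um"]) <= 0:
            raise ConfigError(f"nonpositive entry at level {rec['level']}")
    if seen != set(range(1, 20)):
        raise ConfigError("base table must cover levels 1..19 exactly once")
    return sorted(records, key=lambda r: int(r["level"]))


def noncapillary_levels(base_table: Sequence[dict]) -> list[VesselLevel]:
    """Infant-scaled levels 1..19 except the capillary level, with
    Poiseuille single-vessel resistances at the apparent viscosity."""
    levels = []
    for rec in base_table:
        i = int(rec["level"])
        if i == CAPILLARY_LEVEL:
            continue
        cdiv, ldiv, ddiv = infant_scaling(i)
        count = rec["count"] / cdiv
        length = rec["length_um"] * UM / ldiv
        radius = rec["diameter_um"] * UM / ddiv / 2.0
        r_bar = poiseuille_resistance(radius, length, APPARENT_VISCOSITY)
        levels.append(VesselLevel(index=i, N=count, R_bar=r_bar))
    return levels


def total_resistance(levels: Sequence[VesselLevel], R10: float) -> float:
    """Serial sum of the 18 noncapillary level resistances and the
    lumped capillary level ``R10``."""
    idx = sorted(lv.index for lv in levels)
    if idx != [i for i in range(1, 20) if i != CAPILLARY_LEVEL]:
        raise ConfigError("need exactly the 18 noncapillary levels 1..19")
    if R10 <= 0:
        raise ValueError("capillary level resistance must be positive")
    return sum(lv.R for lv in levels) + R10


def total_flow(params: Table1Params, R_T: float) -> float:
    """Total cerebral blood flow ``(p_art - p_ven)/R_T`` in m^3/s."""
    if R_T <= 0:
        raise ValueError("total resistance must be positive")
    return (params.p_art - params.p_ven) / R_T


def gm_pressure_drop(Q: float, R10: float) -> float:
    """Pressure drop (Pa) across the germinal matrix: ``Q * R10``."""
    if Q < 0 or R10 < 0:
        raise ValueError("flow and resistance must be nonnegative")
    return Q * R10


@dataclass(frozen=True)
class BrainLumpModel:
    """Assembled lumped model: capillary-level pair plus context.

    ``R_GM`` and ``R_B`` are the germinal-matrix and rest-of-brain
    lumped capillary resistances (Pa*s/m^3); ``Q`` may be supplied
    directly (measured CBF) or derived from a base table via
    :func:`total_resistance` and :func:`total_flow`.
    """

    params: Table1Params
    R_GM: float
    R_B: float
    levels: tuple[VesselLevel, ...] | None = None
    cbf: float | None = None  # m^3/s, overrides the base-table route

    @property
    def R10(self) -> float:
        return combine_capillary_level(self.R_GM, self.R_B)

    @property
    def R_T(self) -> float | None:
        if self.levels is None:
            return None
        return total_resistance(list(self.levels), self.R10)

    @property
    def Q(self) -> float:
        if self.cbf is not None:
            return self.cbf
        rt = self.R_T
        if rt is None:
            raise ConfigError("supply either a CBF value or a base table")
        return total_flow(self.params, rt)

    @property
    def dp(self) -> float:
        return gm_pressure_drop(self.Q, self.R10)

    def summary(self) -> dict:
        """Outputs with explicit units, JSON-ready."""
        out = {
            "R10_pa_s_per_m3": self.R10,
            "Q_m3_per_s": self.Q,
            "Q_ml_per_min": m3s_to_ml_min(self.Q),
            "dp_pa": self.dp,
            "dp_mmhg": self.dp / MMHG,
        }
        if self.levels is not None:
            out["RT_pa_s_per_m3"] = self.R_T
        return out
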