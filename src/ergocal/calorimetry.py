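"""Stoichiometric engine: substrate oxidation rates, resting EE, energy partition.

Indirect calorimetry recovers whole-body substrate use from gas exchange.
With V'O2 and V'CO2 in L min^-1 STPD and a protein oxidation rate Pox in
g min^-1, the oxidation rates are::

    fat = 1.67 * V'O2 - 1.67 * V'CO2 - 0.307 * Pox      [g min^-1]
    cho = 4.55 * V'CO2 - 3.21 * V'O2 - 0.459 * Pox      [g min^-1]

Protein oxidation is estimated from energy expenditure under the standard
assumption that it supplies ~12% of the energy of the period being analysed,
divided by the energy density of protein (16.74 kJ g^-1).  Resting energy
expenditure uses the Weir equation without protein correction,
``EE [kcal min^-1] = 3.941 V'O2 + 1.106 V'CO2``, converted at
4.184 kJ kcal^-1.

Raw stoichiometric rates are signed: at RER > 1 the fat equation goes
negative (net lipogenesis/buffering); reporting layers clip at zero and flag
the clip, keeping the signed values retrievable for diagnostics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DomainError
from .types import GasSeries

__all__ = [
    "ConversionFactors",
    "DEFAULT_FACTORS",
    "Substrate",
    "SubstrateRates",
    "EnergyPartition",
    "protein_oxidation_rate",
    "fat_oxidation_rate",
    "cho_oxidation_rate",
    "rates_from_gas",
    "gas_from_rates",
    "energy_partition",
    "grams_from_energy",
    "resting_ee_weir",
    "BmrResult",
    "analyze_bmr",
]

KCAL_TO_KJ = 4.184
WEIR_O2 = 3.941  # kcal per L O2
WEIR_CO2 = 1.106  # kcal per L CO2

# Stoichiometric coefficients of the two-equation system.
FAT_O2, FAT_CO2, FAT_POX = 1.67, -1.67, -0.307
CHO_O2, CHO_CO2, CHO_POX = -3.21, 4.55, -0.459


class Substrate(str, enum.Enum):
    FAT = "fat"
    CHO = "cho"
    PROTEIN = "protein"


@dataclass(frozen=True)
class ConversionFactors:
    """Energy densities and the protein-share assumption.

    kJ per gram for carbohydrate/protein (16.7) and fat (37.7); the protein
    oxidation estimate divides 12% of energy expenditure by 16.74 kJ g^-1.
    """

    kj_per_g_cho: float = 16.7
    kj_per_g_protein: float = 16.7
    kj_per_g_fat: float = 37.7
    kj_per_g_protein_pox_denominator: float = 16.74
    protein_fraction_of_ree: float = 0.12

    def __post_init__(self) -> None:
        for name in (
            "kj_per_g_cho",
            "kj_per_g_protein",
            "kj_per_g_fat",
            "kj_per_g_protein_pox_denominator",
            "protein_fraction_of_ree",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    def energy_density(self, substrate: Substrate) -> float:
        return {
            Substrate.FAT: self.kj_per_g_fat,
            Substrate.CHO: self.kj_per_g_cho,
            Substrate.PROTEIN: self.kj_per_g_protein,
        }[Substrate(substrate)]


DEFAULT_FACTORS = ConversionFactors()


@dataclass
class SubstrateRates:
    """Clipped oxidation rates (g min^-1) with signed raws for diagnostics."""

    fat: float
    cho: float
    protein: float
    raw_fat: float = None  # type: ignore[assignment]
    raw_cho: float = None  # type: ignore[assignment]
    clipped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.raw_fat is None:
            self.raw_fat = self.fat
        if self.raw_cho is None:
            self.raw_cho = self.cho
        if not self.clipped:
            self.clipped = {"fat": False, "cho": False, "protein": False}
        if min(self.fat, self.cho, self.protein) < 0:
            raise DomainError("reported (clipped) rates must be nonnegative")


def protein_oxidation_rate(
    ee_kj_min: float, factors: ConversionFactors = DEFAULT_FACTORS
) -> float:
    """Protein oxidation (g min^-1) = 0.12 x EE [kJ min^-1] / 16.74 [kJ g^-1].

    ``ee_kj_min`` is the energy expenditure of the period the estimate
    applies to (resting EE for basal/graded-test work; the window's own EE
    for prolonged submaximal exercise).
    """
    if ee_kj_min < 0:
        raise DomainError(f"energy expenditure must be nonnegative, got {ee_kj_min}")
    return factors.protein_fraction_of_ree * ee_kj_min / factors.kj_per_g_protein_pox_denominator


def fat_oxidation_rate(vo2: float, vco2: float, pox: float) -> float:
    """Signed raw fat oxidation rate (g min^-1); caller decides clipping."""
    _check_gas(vo2, vco2)
    return FAT_O2 * vo2 + FAT_CO2 * vco2 + FAT_POX * pox


def cho_oxidation_rate(vo2: float, vco2: float, pox: float) -> float:
    """Signed raw carbohydrate oxidation rate (g min^-1)."""
    _check_gas(vo2, vco2)
    return CHO_O2 * vo2 + CHO_CO2 * vco2 + CHO_POX * pox


def _check_gas(vo2, vco2) -> None:
    if not (np.all(np.isfinite(vo2)) and np.all(np.isfinite(vco2))):
        raise DomainError("gas values must be finite")
    if np.any(np.asarray(vo2) < 0) or np.any(np.asarray(vco2) < 0):
        raise DomainError("gas values must be nonnegative")


def rates_from_gas(
    vo2: float, vco2: float, pox: float, clip: bool = True
) -> SubstrateRates:
    """Full substrate-rate record from one (V'O2, V'CO2, Pox) triple."""
    raw_fat = fat_oxidation_rate(vo2, vco2, pox)
    raw_cho = cho_oxidation_rate(vo2, vco2, pox)
    fat = max(raw_fat, 0.0) if clip else raw_fat
    cho = max(raw_cho, 0.0) if clip else raw_cho
    return SubstrateRates(
        fat=fat,
        cho=cho,
        protein=pox,
        raw_fat=raw_fat,
        raw_cho=raw_cho,
        clipped={"fat": raw_fat < 0, "cho": raw_cho < 0, "protein": False},
    )


def gas_from_rates(fat: float, cho: float, pox: float = 0.0) -> tuple:
    """Invert the stoichiometry: (fat, cho, pox) -> (V'O2, V'CO2).

    The 2x2 linear map in (V'O2, V'CO2) is inverted exactly; used by the
    synthetic generator and as the numeric round-trip oracle.
    """
    m = np.array([[FAT_O2, FAT_CO2], [CHO_O2, CHO_CO2]])
    b = np.array([fat - FAT_POX * pox, cho - CHO_POX * pox])
    vo2, vco2 = np.linalg.solve(m, b)
    return float(vo2), float(vco2)


@dataclass(frozen=True)
class EnergyPartition:
    """Energy supply (kJ min^-1) split by substrate; total is the exact sum."""

    from_cho: float
    from_fat: float
    from_protein: float

    @property
    def total(self) -> float:
        return self.from_cho + self.from_fat + self.from_protein


def energy_partition(
    rates: SubstrateRates, factors: ConversionFactors = DEFAULT_FACTORS
) -> EnergyPartition:
    """kJ min^-1 per substrate = clipped rate x energy density."""
    if min(rates.fat, rates.cho, rates.protein) < 0:
        raise DomainError("energy_partition requires clipped (nonnegative) rates")
    return EnergyPartition(
        from_cho=rates.cho * factors.kj_per_g_cho,
        from_fat=rates.fat * factors.kj_per_g_fat,
        from_protein=rates.protein * factors.kj_per_g_protein,
    )


def grams_from_energy(
    ee_kj: float, substrate, factors: ConversionFactors = DEFAULT_FACTORS
) -> float:
    """Grams oxidized for a given energy supply: ee / energy density."""
    if ee_kj < 0:
        raise DomainError(f"energy must be nonnegative, got {ee_kj}")
    try:
        sub = Substrate(substrate)
    except ValueError as exc:
        raise DomainError(f"unknown substrate {substrate!r}") from exc
    return ee_kj / factors.energy_density(sub)


def resting_ee_weir(vo2: float, vco2: float) -> float:
    """Weir energy expenditure (kJ min^-1), no protein correction."""
    _check_gas(vo2, vco2)
    return KCAL_TO_KJ * (WEIR_O2 * vo2 + WEIR_CO2 * vco2)


@dataclass(frozen=True)
class BmrResult:
    """Basal metabolic rate from a canopy recording."""

    bmr_mj_day: float
    ee_kj_min: float
    vo2_mean: float
    vco2_mean: float
    rer: float
    n_used: int
    n_discarded: int


def analyze_bmr(series: GasSeries, discard_s: float = 600.0) -> BmrResult:
    """BMR from a ventilated-canopy recording.

    The first ``discard_s`` seconds (default 10 min) are excluded as
    adaptation to the canopy; V'O2 and V'CO2 are averaged over the remainder
    and converted with the Weir equation.
    """
    keep = series.t >= series.t[0] + discard_s
    n_used = int(keep.sum())
    if n_used == 0:
        raise DataError(
            f"discarding {discard_s} s leaves no samples (recording spans {series.duration} s)"
        )
    import logging

    logging.getLogger(__name__).info(
        "BMR analysis: discarded %d of %d samples (first %.0f s)",
        int((~keep).sum()), len(series), discard_s,
    )
    vo2 = float(series.vo2[keep].mean())
    vco2 = float(series.vco2[keep].mean())
    ee = resting_ee_weir(vo2, vco2)
    return BmrResult(
        bmr_mj_day=ee * 1440.0 / 1000.0,
        ee_kj_min=ee,
        vo2_mean=vo2,
        vco2_mean=vco2,
        rer=vco2 / vo2 if vo2 > 0 else float("nan"),
        n_used=n_used,
        n_discarded=len(series) - n_used,
    )
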