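"""Submaximal/training-session analysis: 5-min windows, totals, training load.

Substrate oxidation during a recorded session is computed over consecutive
half-open 5-min windows of the exercise phase (a trailing partial window is
retained with its true duration).  For prolonged exercise the protein
oxidation rate of each window defaults to 12% of that window's Weir energy
expenditure divided by 16.74 kJ g^-1, so the protein share tracks exercise
energy turnover; pass an explicit ``pox`` to hold it at the resting value
instead.  Session totals are window rates times window duration; heart-rate
load is summarised as the time-weighted mean, its %HRmax, and the share of
time at/above the high-intensity-interval cut (>= 85 %HRmax).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import calorimetry as cal
from .errors import DataError, DomainError
from .types import GasSeries, Subject

log = logging.getLogger(__name__)

__all__ = [
    "WindowRates",
    "SessionSummary",
    "window_rates",
    "summarize_session",
    "training_load",
]

HIIT_HR_CUT_PCT = 85.0


@dataclass(frozen=True)
class WindowRates:
    """Substrate rates and energy partition of one analysis window."""

    start: float  # s, window start (recording time)
    duration: float  # s, true covered duration
    vo2: float
    vco2: float
    rates: cal.SubstrateRates
    partition: cal.EnergyPartition

    @property
    def ee_kj(self) -> float:
        return self.partition.total * self.duration / 60.0


@dataclass
class SessionSummary:
    """Whole-session totals in the style of a substrate-oxidation table."""

    total_ee: float  # kJ
    ee_by_substrate: dict  # kJ per substrate
    grams_by_substrate: dict  # g per substrate (exact)
    duration_min: float
    mean_hr: Optional[float] = None
    mean_hr_pct_max: Optional[float] = None
    hiit_share: Optional[float] = None  # % of time at/above the HIIT HR cut
    clipped: dict = field(default_factory=dict)
    windows: list = field(default_factory=list)

    def rounded(self) -> dict:
        """Integer kJ / integer grams, mirroring published table precision."""
        return {
            "total_ee_kj": round(self.total_ee),
            "ee_cho_kj": round(self.ee_by_substrate["cho"]),
            "ee_fat_kj": round(self.ee_by_substrate["fat"]),
            "ee_protein_kj": round(self.ee_by_substrate["protein"]),
            "cho_g": round(self.grams_by_substrate["cho"]),
            "fat_g": round(self.grams_by_substrate["fat"]),
            "protein_g": round(self.grams_by_substrate["protein"]),
        }


def _window_pox(
    vo2: float, vco2: float, pox: Optional[float], factors: cal.ConversionFactors
) -> float:
    if pox is not None:
        return pox
    return cal.protein_oxidation_rate(cal.resting_ee_weir(vo2, vco2), factors)


def window_rates(
    series: GasSeries,
    pox: Optional[float] = None,
    window: float = 300.0,
    factors: cal.ConversionFactors = cal.DEFAULT_FACTORS,
) -> list:
    """Per-window gas means, substrate rates, and energy partition.

    Windows are half-open ``[start, start + window)`` over the exercise
    phase; the trailing partial window keeps its true duration.  ``pox``
    None derives each window's protein rate from its own energy expenditure.
    """
    if window <= 0:
        raise DomainError("window must be positive")
    ex = series.exercise()
    t0 = ex.t[0]
    t_end = ex.t[-1] + ex.dt_nominal
    out = []
    start = t0
    while start < t_end:
        end = min(start + window, t_end)
        mask = (ex.t >= start) & (ex.t < end)
        n = int(mask.sum())
        if n == 0:
            start += window
            continue
        vo2 = float(ex.vo2[mask].mean())
        vco2 = float(ex.vco2[mask].mean())
        p = _window_pox(vo2, vco2, pox, factors)
        rates = cal.rates_from_gas(vo2, vco2, p)
        out.append(
            WindowRates(
                start=float(start),
                duration=n * ex.dt_nominal,
                vo2=vo2,
                vco2=vco2,
                rates=rates,
                partition=cal.energy_partition(rates, factors),
            )
        )
        start += window
    if not out:
        raise DataError("exercise phase contains no samples")
    return out


def summarize_session(
    series: GasSeries,
    subject: Optional[Subject] = None,
    pox: Optional[float] = None,
    window: float = 300.0,
    hiit_cut: float = HIIT_HR_CUT_PCT,
    factors: cal.ConversionFactors = cal.DEFAULT_FACTORS,
) -> SessionSummary:
    """Whole-session substrate totals plus heart-rate load.

    Totals are sums over windows of rate x window minutes.  HR summaries
    need HR samples and (for %HRmax and the HIIT share) a subject with a
    recorded peak heart rate; they are left ``None`` otherwise.
    """
    wins = window_rates(series, pox=pox, window=window, factors=factors)
    grams = {"fat": 0.0, "cho": 0.0, "protein": 0.0}
    clipped = {"fat": False, "cho": False, "protein": False}
    for w in wins:
        mins = w.duration / 60.0
        grams["fat"] += w.rates.fat * mins
        grams["cho"] += w.rates.cho * mins
        grams["protein"] += w.rates.protein * mins
        for k in clipped:
            clipped[k] = clipped[k] or w.rates.clipped[k]
    ee = {
        "fat": grams["fat"] * factors.kj_per_g_fat,
        "cho": grams["cho"] * factors.kj_per_g_cho,
        "protein": grams["protein"] * factors.kj_per_g_protein,
    }
    summary = SessionSummary(
        total_ee=ee["fat"] + ee["cho"] + ee["protein"],
        ee_by_substrate=ee,
        grams_by_substrate=grams,
        duration_min=sum(w.duration for w in wins) / 60.0,
        clipped=clipped,
        windows=wins,
    )
    ex = series.exercise()
    if ex.hr is None or np.all(np.isnan(ex.hr)):
        log.info("session has no HR; load summary flagged absent")
        return summary
    hrmax = subject.hr_peak if subject is not None else None
    if hrmax:
        mean_hr, mean_pct, hiit_share, _ = training_load(series, hrmax, hiit_cut=hiit_cut)
        summary.mean_hr = mean_hr
        summary.mean_hr_pct_max = mean_pct
        summary.hiit_share = hiit_share
    else:
        hr = ex.hr[~np.isnan(ex.hr)]
        summary.mean_hr = float(hr.mean())
    return summary


def training_load(
    hr_series: GasSeries, hrmax: float, hiit_cut: float = HIIT_HR_CUT_PCT
) -> tuple:
    """(mean HR, mean %HRmax, HIIT share %, MICT share %) of a session.

    Shares partition exercise time at/above vs below ``hiit_cut`` %HRmax and
    sum to 100 exactly.
    """
    if hrmax <= 0:
        raise DomainError(f"hrmax must be positive, got {hrmax}")
    ex = hr_series.exercise()
    if ex.hr is None:
        raise DataError("series has no heart-rate channel")
    hr = ex.hr[~np.isnan(ex.hr)]
    if hr.size == 0:
        raise DataError("series has no valid heart-rate samples")
    mean_hr = float(hr.mean())
    mean_pct = 100.0 * mean_hr / hrmax
    hiit_share = 100.0 * float(np.mean(hr >= hiit_cut / 100.0 * hrmax))
    return mean_hr, mean_pct, hiit_share, 100.0 - hiit_share
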