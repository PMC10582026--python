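"""Energy-equated training prescription from a graded-test result.

Both trial arms expend the same conditioning energy per session,
20 kJ per kg fat-free mass (~1.4 MJ).  The combined (COMB) session is a
5-min warm-up at 50% V'O2peak, three 2-min bouts at 95% separated by 1-min
recoveries at 50%, then a continuous moderate block at 60% whose duration is
solved so the session meets the budget; the MICT session is a single
continuous block (default 40% V'O2peak) whose duration meets the same
budget.  Segment energy is predicted as V'O2 at the target intensity times a
fixed oxygen energy equivalent (default 20.9 kJ per L O2; an RER-dependent
equivalent is available).  The warm-up prepares the athlete and is excluded
from the conditioning budget, though it is part of the delivered session.

Heart-rate targets for each prescribed intensity are interpolated from the
stage (intensity, HR) pairs of the subject's own graded test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError, InfeasibleError
from .graded import GradedResult

__all__ = [
    "SegmentLabel",
    "SessionSegment",
    "SessionPlan",
    "hr_for_intensity",
    "vo2_at_intensity",
    "session_energy_target",
    "oxygen_energy_equivalent",
    "predicted_segment_ee",
    "design_comb_session",
    "design_mict_session",
]

KJ_PER_L_O2 = 20.9
ENERGY_BUDGET_KJ_PER_KG_FFM = 20.0


class SegmentLabel(str, enum.Enum):
    WARMUP = "WARMUP"
    HIIT = "HIIT"
    RECOVERY = "RECOVERY"
    MICT = "MICT"


@dataclass(frozen=True)
class SessionSegment:
    label: SegmentLabel
    intensity: float  # %V'O2peak
    duration: float  # s
    hr_target: Optional[float] = None
    speed: Optional[float] = None
    incline: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DomainError("segment duration must be positive")
        if not 0 < self.intensity <= 100:
            raise DomainError(f"segment intensity must be in (0, 100], got {self.intensity}")


@dataclass
class SessionPlan:
    """Ordered segments plus the energy book-keeping of the design."""

    segments: list = field(default_factory=list)
    energy_target: float = 0.0  # kJ (conditioning budget)
    predicted_energy: float = 0.0  # kJ over budgeted segments
    hiit_fraction: float = 0.0  # share of total session time at HIIT

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "energy_target_kj": self.energy_target,
            "predicted_energy_kj": self.predicted_energy,
            "hiit_fraction": self.hiit_fraction,
            "total_duration_min": self.total_duration / 60.0,
            "segments": [
                {
                    "label": s.label.value,
                    "intensity_pct": s.intensity,
                    "duration_s": s.duration,
                    "hr_target_bpm": s.hr_target,
                    "speed_ms": s.speed,
                    "incline_pct": s.incline,
                }
                for s in self.segments
            ],
        }


def hr_for_intensity(
    result: GradedResult,
    pct: float,
    hr_rest: Optional[float] = None,
) -> float:
    """Heart rate (bpm) at a prescribed %V'O2peak.

    Linear interpolation through the graded test's stage (intensity, HR)
    pairs; above the top stage the top two stages are extrapolated linearly.
    The value is clamped to ``[hr_rest, hrpeak]`` when those are known.
    """
    pairs = [(s.intensity, s.hr) for s in result.stages if s.hr is not None]
    if len(pairs) < 2:
        raise DomainError("hr_for_intensity needs >= 2 stages with HR")
    pairs.sort()
    xs = np.array([p[0] for p in pairs])
    ys = np.array([p[1] for p in pairs])
    if not xs[0] - 10.0 <= pct <= 100.0:
        raise DomainError(
            f"intensity {pct}% outside the supported range [{xs[0] - 10.0:.0f}, 100]"
        )
    if pct <= xs[-1]:
        hr = float(np.interp(pct, xs, ys))
    else:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        hr = float(ys[-1] + slope * (pct - xs[-1]))
    if result.hrpeak is not None:
        hr = min(hr, result.hrpeak)
    if hr_rest is not None:
        hr = max(hr, hr_rest)
    return hr


def vo2_at_intensity(result: GradedResult, pct: float) -> float:
    """V'O2 (L min^-1) at a fraction of the test's V'O2peak."""
    if not 0 < pct <= 100:
        raise DomainError(f"intensity must be in (0, 100], got {pct}")
    return pct / 100.0 * result.vo2peak


def session_energy_target(
    ffm: float, budget_kj_per_kg: float = ENERGY_BUDGET_KJ_PER_KG_FFM
) -> float:
    """Conditioning energy budget per session: 20 kJ per kg FFM."""
    if ffm <= 0:
        raise DomainError(f"ffm must be positive, got {ffm}")
    return budget_kj_per_kg * ffm


def oxygen_energy_equivalent(rer: float) -> float:
    """kJ per litre O2 as a linear function of RER.

    Interpolates between ~19.6 kJ L^-1 at RER 0.7 (pure fat) and
    ~21.1 kJ L^-1 at RER 1.0 (pure carbohydrate); optional alternative to
    the fixed 20.9 kJ L^-1 equivalent.
    """
    if not 0.6 <= rer <= 1.1:
        raise DomainError(f"RER {rer} outside supported range [0.6, 1.1]")
    return 19.6 + (21.1 - 19.6) * (min(rer, 1.0) - 0.7) / 0.3


def predicted_segment_ee(
    intensity: float,
    duration: float,
    result: GradedResult,
    kj_per_l_o2: float = KJ_PER_L_O2,
) -> float:
    """Predicted segment energy (kJ): V'O2 at intensity x minutes x kJ/L O2."""
    if duration < 0:
        raise DomainError("duration must be nonnegative")
    if duration == 0:
        return 0.0
    return vo2_at_intensity(result, intensity) * (duration / 60.0) * kj_per_l_o2


def _attach_hr(result: GradedResult, segments: list) -> list:
    has_hr = sum(s.hr is not None for s in result.stages) >= 2
    if not has_hr:
        return segments
    out = []
    for seg in segments:
        try:
            hr = round(hr_for_intensity(result, seg.intensity), 0)
        except DomainError:
            hr = None
        out.append(
            SessionSegment(
                label=seg.label,
                intensity=seg.intensity,
                duration=seg.duration,
                hr_target=hr,
                speed=seg.speed,
                incline=seg.incline,
            )
        )
    return out


def design_comb_session(
    result: GradedResult,
    ffm: float,
    kj_per_l_o2: float = KJ_PER_L_O2,
    budget_kj_per_kg: float = ENERGY_BUDGET_KJ_PER_KG_FFM,
    tol: float = 0.01,
) -> SessionPlan:
    """Combined session: warm-up + 3x2' @95% with 1' recoveries + MICT @60%.

    The moderate block's duration is solved in closed form so the budgeted
    segments (everything except the warm-up) meet the 20 kJ kg FFM^-1
    target exactly; infeasible when the interval block alone overshoots.
    """
    target = session_energy_target(ffm, budget_kj_per_kg)
    warmup = SessionSegment(SegmentLabel.WARMUP, 50.0, 300.0)
    fixed = []
    for rep in range(3):
        fixed.append(SessionSegment(SegmentLabel.HIIT, 95.0, 120.0))
        if rep < 2:
            fixed.append(SessionSegment(SegmentLabel.RECOVERY, 50.0, 60.0))
    fixed_ee = sum(
        predicted_segment_ee(s.intensity, s.duration, result, kj_per_l_o2) for s in fixed
    )
    per_min_mict = predicted_segment_ee(60.0, 60.0, result, kj_per_l_o2)
    remaining = target - fixed_ee
    if remaining <= 0:
        raise InfeasibleError(
            f"interval block alone predicts {fixed_ee:.0f} kJ, above the "
            f"{target:.0f} kJ budget; no feasible moderate-block duration"
        )
    mict_duration = remaining / per_min_mict * 60.0
    segments = [warmup] + fixed + [SessionSegment(SegmentLabel.MICT, 60.0, mict_duration)]
    segments = _attach_hr(result, segments)
    predicted = sum(
        predicted_segment_ee(s.intensity, s.duration, result, kj_per_l_o2)
        for s in segments
        if s.label != SegmentLabel.WARMUP
    )
    assert abs(predicted - target) <= tol * target
    total = sum(s.duration for s in segments)
    hiit_time = sum(s.duration for s in segments if s.label == SegmentLabel.HIIT)
    return SessionPlan(
        segments=segments,
        energy_target=target,
        predicted_energy=predicted,
        hiit_fraction=hiit_time / total,
    )


def design_mict_session(
    result: GradedResult,
    ffm: float,
    intensity: float = 40.0,
    kj_per_l_o2: float = KJ_PER_L_O2,
    budget_kj_per_kg: float = ENERGY_BUDGET_KJ_PER_KG_FFM,
) -> SessionPlan:
    """Continuous moderate session at ``intensity`` meeting the same budget.

    Default intensity is 40% V'O2peak; pass the subject's Fatmax to train at
    the maximal-fat-oxidation intensity instead.
    """
    if intensity <= 0:
        raise DomainError("intensity must be positive")
    target = session_energy_target(ffm, budget_kj_per_kg)
    per_min = predicted_segment_ee(intensity, 60.0, result, kj_per_l_o2)
    duration = target / per_min * 60.0
    segments = _attach_hr(result, [SessionSegment(SegmentLabel.MICT, intensity, duration)])
    return SessionPlan(
        segments=segments,
        energy_target=target,
        predicted_energy=target,
        hiit_fraction=0.0,
    )
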