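"""Domain types shared by every stage of the pipeline.

The package analyses breath-averaged gas-exchange recordings from metabolic
carts: ventilated-canopy rest measurements (1-min averages), graded treadmill
tests and submaximal training sessions (typically 5-s averages).  All gas
rates are STPD litres per minute; time is seconds from recording start and
every windowing operation uses half-open intervals ``[start, end)`` so that
adjacent windows never double-count a sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

__all__ = [
    "Group",
    "Phase",
    "Subject",
    "GasSample",
    "GasSeries",
    "Stage",
    "GradedProtocol",
    "TrialTable",
]


class Group(str, enum.Enum):
    """Trial arm: combined (HIIT + MICT) or continuous moderate training."""

    COMB = "COMB"
    MICT = "MICT"


class Phase(str, enum.Enum):
    REST = "REST"
    EXERCISE = "EXERCISE"
    MIXED = "MIXED"


@dataclass
class Subject:
    """Anthropometric record of one participant.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    group : Group
        Trial arm.
    age : float
        Years.
    stature : float
        Metres.
    body_mass : float
        Kilograms.
    ffm : float
        Fat-free mass, kg (``0 < ffm <= body_mass``).
    bmr : float, optional
        Basal metabolic rate, MJ per day; set once measured.
    hr_peak : float, optional
        Peak heart rate from the graded test, beats per minute.
    """

    subject_id: str
    group: Group
    age: float
    stature: float
    body_mass: float
    ffm: float
    bmr: Optional[float] = None
    hr_peak: Optional[float] = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.stature <= 0:
            raise DomainError(f"stature must be positive, got {self.stature}")
        if self.body_mass <= 0:
            raise DomainError(f"body_mass must be positive, got {self.body_mass}")
        if not 0 < self.ffm <= self.body_mass:
            raise DomainError(
                f"ffm must satisfy 0 < ffm <= body_mass, got ffm={self.ffm}, "
                f"body_mass={self.body_mass}"
            )
        if self.age <= 0:
            raise DomainError(f"age must be positive, got {self.age}")


@dataclass(frozen=True)
class GasSample:
    """One breath-averaged sample: V'O2/V'CO2 in L min^-1 STPD."""

    t: float
    vo2: float
    vco2: float
    hr: Optional[float] = None
    speed: Optional[float] = None
    incline: Optional[float] = None


def _as_array(x, n: int, name: str) -> Optional[np.ndarray]:
    if x is None:
        return None
    arr = np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise DataError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr


@dataclass
class GasSeries:
    """A timestamped gas-exchange recording.

    Stored column-wise as numpy arrays for efficient windowing; the
    row-wise :class:`GasSample` view is available through :meth:`samples`.
    """

    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    hr: Optional[np.ndarray] = None
    speed: Optional[np.ndarray] = None
    incline: Optional[np.ndarray] = None
    dt_nominal: float = 5.0
    phase: Phase = Phase.MIXED
    exercise_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size == 0:
            raise DataError("GasSeries must contain at least one sample")
        n = self.t.size
        self.vo2 = _as_array(self.vo2, n, "vo2")
        self.vco2 = _as_array(self.vco2, n, "vco2")
        self.hr = _as_array(self.hr, n, "hr")
        self.speed = _as_array(self.speed, n, "speed")
        self.incline = _as_array(self.incline, n, "incline")
        self.phase = Phase(self.phase)
        if np.any(np.diff(self.t) <= 0):
            i = int(np.argmax(np.diff(self.t) <= 0))
            raise DataError(f"time must be strictly increasing (violation near t={self.t[i + 1]})")
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise DataError("vo2 and vco2 must be nonnegative")
        if self.hr is not None:
            ok = np.isnan(self.hr) | ((self.hr >= 30) & (self.hr <= 230))
            if not np.all(ok):
                bad = self.hr[~ok][0]
                raise DataError(f"hr outside plausible range [30, 230]: {bad}")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Span covered by the recording, assuming each sample represents
        one nominal averaging interval ending at ``t + dt_nominal``."""
        return float(self.t[-1] - self.t[0] + self.dt_nominal)

    def samples(self) -> Iterator[GasSample]:
        for i in range(len(self)):
            yield GasSample(
                t=float(self.t[i]),
                vo2=float(self.vo2[i]),
                vco2=float(self.vco2[i]),
                hr=None if self.hr is None else float(self.hr[i]),
                speed=None if self.speed is None else float(self.speed[i]),
                incline=None if self.incline is None else float(self.incline[i]),
            )

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[GasSample],
        dt_nominal: float = 5.0,
        phase: Phase = Phase.MIXED,
        exercise_start_s: float = 0.0,
    ) -> "GasSeries":
        def col(name):
            vals = [getattr(s, name) for s in samples]
            return None if all(v is None for v in vals) else [np.nan if v is None else v for v in vals]

        return cls(
            t=[s.t for s in samples],
            vo2=[s.vo2 for s in samples],
            vco2=[s.vco2 for s in samples],
            hr=col("hr"),
            speed=col("speed"),
            incline=col("incline"),
            dt_nominal=dt_nominal,
            phase=phase,
            exercise_start_s=exercise_start_s,
        )

    def slice_time(self, start: float, end: float) -> "GasSeries":
        """Sub-series on the half-open window ``[start, end)``."""
        mask = (self.t >= start) & (self.t < end)
        if not np.any(mask):
            raise DataError(f"window [{start}, {end}) contains no samples")
        return self._masked(mask)

    def exercise(self) -> "GasSeries":
        """The exercise portion of the recording (``t >= exercise_start_s``
        for MIXED series; everything for EXERCISE; error for REST)."""
        if self.phase == Phase.EXERCISE:
            return self
        if self.phase == Phase.REST:
            raise DataError("series contains no exercise phase")
        mask = self.t >= self.exercise_start_s
        if not np.any(mask):
            raise DataError("series contains no exercise-phase samples")
        out = self._masked(mask)
        out.phase = Phase.EXERCISE
        return out

    def _masked(self, mask: np.ndarray) -> "GasSeries":
        return replace(
            self,
            t=self.t[mask],
            vo2=self.vo2[mask],
            vco2=self.vco2[mask],
            hr=None if self.hr is None else self.hr[mask],
            speed=None if self.speed is None else self.speed[mask],
            incline=None if self.incline is None else self.incline[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"t_s": self.t, "vo2_lmin": self.vo2, "vco2_lmin": self.vco2}
        if self.hr is not None:
            data["hr_bpm"] = self.hr
        if self.speed is not None:
            data["speed_ms"] = self.speed
        if self.incline is not None:
            data["incline_pct"] = self.incline
        return pd.DataFrame(data)


@dataclass(frozen=True)
class Stage:
    """One workload level of a graded protocol (treadmill walking)."""

    speed: float  # m s^-1
    incline: float  # % grade
    duration: float = 300.0  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DomainError("stage duration must be positive")
        if self.speed < 0 or self.incline < 0:
            raise DomainError("speed and incline must be nonnegative")


@dataclass(frozen=True)
class GradedProtocol:
    """Rest period + ordered walking stages, terminated at a heart-rate cap."""

    stages: tuple = ()
    rest_duration: float = 600.0  # s
    hr_stop: float = 180.0  # bpm

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if not self.stages:
            raise DomainError("protocol needs at least one stage")
        if self.hr_stop <= 100:
            raise DomainError("hr_stop must exceed 100 bpm")

    @property
    def exercise_duration(self) -> float:
        return float(sum(s.duration for s in self.stages))

    def stage_window(self, index: int) -> tuple:
        """Half-open ``[start, end)`` of stage ``index`` in recording time."""
        start = self.rest_duration + sum(s.duration for s in self.stages[:index])
        return (start, start + self.stages[index].duration)


ID_COLS = ["subject_id", "group", "timepoint"]
TIMEPOINTS = ("W0", "W3")


@dataclass
class TrialTable:
    """Subject x timepoint outcome matrix with declared units.

    ``data`` is a tidy frame with columns ``subject_id, group, timepoint``
    followed by outcome columns; ``units`` maps every outcome column to its
    unit string.
    """

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLS if c not in self.data.columns]
        if missing:
            raise DataError(f"TrialTable missing id columns: {missing}")
        dup = self.data.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            row = self.data.loc[dup.idxmax()]
            raise DataError(
                f"duplicate row for subject {row['subject_id']} at {row['timepoint']}"
            )
        for col in self.outcomes:
            if col not in self.units:
                raise DataError(f"outcome column {col!r} has no declared unit")

    @property
    def outcomes(self) -> list:
        return [c for c in self.data.columns if c not in ID_COLS]

    def wide(self, outcome: str) -> pd.DataFrame:
        """Pivot one outcome to subjects x timepoints, with a 'group' column."""
        if outcome not in self.outcomes:
            raise DataError(f"unknown outcome {outcome!r}")
        w = self.data.pivot(index="subject_id", columns="timepoint", values=outcome)
        groups = self.data.drop_duplicates("subject_id").set_index("subject_id")["group"]
        w["group"] = groups
        return w
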