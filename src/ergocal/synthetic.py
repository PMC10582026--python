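"""Synthetic metabolic-cart data with the statistical structure of the trial.

Everything the pipeline consumes can be generated here: subjects drawn from
group-level presets, ventilated-canopy BMR recordings, graded treadmill
tests and energy-equated submaximal sessions.  The generator is built for
*identifiability*: each simulated signal carries known ground truth (the
subject's BMR, V'O2peak, fat-oxidation curve landmarks), so that running the
analysis pipeline on noiseless output must recover the truth exactly, and on
noisy output must recover it on average.

Model summary
-------------
* Subjects: independent truncated normals per preset cell (no BM-FFM
  covariance beyond the FFM <= BM constraint — a documented simplification).
* Fat-oxidation truth: a scaled beta-shaped unimodal curve of intensity I
  (%V'O2peak) parameterised by its three landmarks — peak height MFO, peak
  location Fatmax = F, and crossover C where the curve reaches zero::

      f(I) = MFO * (I/F)**p * ((C-I)/(C-F))**q,  0 < I < C,  p = q*F/(C-F)

  with shape exponent q = 0.5 (broad plateau, steep final decline — the
  shape observed in walking fat-oxidation curves); f = 0 at I >= C.
* Gas exchange: per-segment steady targets with mono-exponential onset
  kinetics (tau = 40 s); V'CO2 is back-computed from the fat-curve truth by
  inverting the stoichiometric equations, so analysing a stage recovers the
  curve.  Multiplicative Gaussian noise (CV 4%) on V'O2/V'CO2, additive
  Gaussian noise (SD 3 bpm) on HR; RER is capped at 1.1.
* Heart rate: linear in V'O2 between the resting and peak values; the
  graded test is truncated when a 30-s smoothed HR reaches the 180-bpm stop
  criterion.
* Cohorts: paired W0/W3 draws per subject with within-subject correlation
  rho (default 0.8), giving change scores whose means equal the preset
  mean differences.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from . import calorimetry as cal
from .anthro import bmi, fat_mass
from .errors import ConfigurationError, DomainError
from .graded import default_grad_protocol, o2_pulse
from .prescription import KJ_PER_L_O2, SessionPlan
from .types import GasSeries, GradedProtocol, Group, Phase, Subject, TrialTable

log = logging.getLogger(__name__)

__all__ = [
    "Gauss",
    "GroupPreset",
    "NoiseModel",
    "SyntheticSubject",
    "PRESETS",
    "load_presets",
    "fat_curve",
    "make_subject",
    "simulate_bmr_recording",
    "simulate_graded_test",
    "simulate_submax_session",
    "simulate_cohort",
    "CohortBundle",
]

#: Steady-state V'O2 of each graded stage as a fraction of the subject's
#: V'O2peak: a light-to-peak walking progression over the 7 workloads.
STAGE_INTENSITY_FRACTIONS = (0.30, 0.40, 0.50, 0.60, 0.72, 0.86, 1.00)

REST_RER = 0.85
FAT_CURVE_Q = 0.5
HR_REST_DEFAULT = 70.0
ADAPT_DURATION_S = 480.0  # canopy adaptation transient, zero afterwards
ADAPT_AMPLITUDE = 0.30
RER_CEILING = 1.1


@dataclass(frozen=True)
class Gauss:
    """A (mean, sd) population cell."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("sd must be nonnegative")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.mean, self.sd)) if self.sd > 0 else self.mean


@dataclass(frozen=True)
class GroupPreset:
    """Group-level generating distribution for one arm x timepoint."""

    name: str
    group: Group
    timepoint: str
    age: Gauss
    stature: Gauss
    body_mass: Gauss
    ffm: Gauss
    bmr: Gauss  # MJ day^-1
    vo2peak: Gauss  # L min^-1
    hrpeak: Gauss  # bpm
    mfo: Gauss  # g min^-1
    fatmax: Gauss  # %V'O2peak
    crossover: Gauss  # %V'O2peak
    session_fat_gain: float = 1.0
    session_targets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fatmax.mean < self.crossover.mean <= 100.0:
            raise DomainError("preset must satisfy fatmax < crossover <= 100")

    def zero_noise(self) -> "GroupPreset":
        """Degenerate copy with every sd set to 0 (exact means each draw)."""
        kwargs = {}
        for f in (
            "age", "stature", "body_mass", "ffm", "bmr",
            "vo2peak", "hrpeak", "mfo", "fatmax", "crossover",
        ):
            kwargs[f] = Gauss(getattr(self, f).mean, 0.0)
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the simulated cart."""

    gas_cv: float = 0.04  # fractional SD on breath-averaged V'O2/V'CO2
    hr_sd: float = 3.0  # bpm
    onset_tau: float = 40.0  # s, mono-exponential kinetics at transitions
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.gas_cv, self.hr_sd, self.onset_tau) < 0:
            raise DomainError("noise parameters must be nonnegative")

    def noiseless(self) -> "NoiseModel":
        return NoiseModel(gas_cv=0.0, hr_sd=0.0, onset_tau=self.onset_tau, seed=self.seed)


DEFAULT_NOISE = NoiseModel()


@dataclass
class SyntheticSubject(Subject):
    """A drawn subject carrying its generating ground truth."""

    true_mfo: float = 0.35
    true_fatmax: float = 50.0
    true_crossover: float = 74.0
    true_vo2peak: float = 2.5
    hr_rest: float = HR_REST_DEFAULT
    session_fat_gain: float = 1.0

    @property
    def resting_ee_kj_min(self) -> float:
        if self.bmr is None:
            raise DomainError("subject has no measured BMR")
        return self.bmr * 1000.0 / 1440.0

    @property
    def resting_pox(self) -> float:
        return cal.protein_oxidation_rate(self.resting_ee_kj_min)

    @property
    def vo2_rest(self) -> float:
        """Resting V'O2 (L min^-1) consistent with BMR at RER 0.85."""
        denom = cal.KCAL_TO_KJ * (cal.WEIR_O2 + cal.WEIR_CO2 * REST_RER)
        return self.resting_ee_kj_min / denom


def _load_presets_file() -> dict:
    with importlib.resources.files("ergocal.data").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_presets() -> Dict[str, GroupPreset]:
    raw = _load_presets_file()
    out = {}
    for name, p in raw["presets"].items():
        cells = {
            k: Gauss(float(p[k]["mean"]), float(p[k]["sd"]))
            for k in (
                "age", "stature", "body_mass", "ffm", "bmr",
                "vo2peak", "hrpeak", "mfo", "fatmax", "crossover",
            )
        }
        out[name] = GroupPreset(
            name=name,
            group=Group(p["group"]),
            timepoint=p["timepoint"],
            session_fat_gain=float(p.get("session_fat_gain", 1.0)),
            session_targets={
                k: Gauss(float(v["mean"]), float(v["sd"]))
                for k, v in p.get("session_targets", {}).items()
            },
            **cells,
        )
    return out


PRESETS: Dict[str, GroupPreset] = load_presets()


def fat_curve(
    intensity: float, mfo: float, fatmax: float, crossover: float, q: float = FAT_CURVE_Q
):
    """Ground-truth fat oxidation rate (g min^-1) at %V'O2peak ``intensity``.

    Beta-shaped unimodal curve through the three landmarks; zero outside
    (0, crossover).  Accepts scalars or arrays.
    """
    if not 0 < fatmax < crossover:
        raise DomainError("need 0 < fatmax < crossover")
    i = np.asarray(intensity, dtype=float)
    p = q * fatmax / (crossover - fatmax)
    with np.errstate(invalid="ignore"):
        val = (
            mfo
            * np.power(np.clip(i / fatmax, 0, None), p)
            * np.power(np.clip((crossover - i) / (crossover - fatmax), 0, None), q)
        )
    val = np.where((i <= 0) | (i >= crossover), 0.0, val)
    return float(val) if np.isscalar(intensity) else val


def _rng(seed, noise: Optional[NoiseModel]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None and noise is not None:
        seed = noise.seed
    return np.random.default_rng(seed)


def make_subject(
    preset: GroupPreset,
    seed=None,
    subject_id: Optional[str] = None,
) -> SyntheticSubject:
    """Draw one subject from a preset; reproducible under ``seed``.

    Fields are independent normals truncated to physiological bounds
    (positive masses, FFM <= 95% of body mass, fatmax + 4 < crossover).
    """
    rng = _rng(seed, None)
    stature = max(preset.stature.draw(rng), 1.2)
    bm = max(preset.body_mass.draw(rng), 40.0)
    ffm = min(max(preset.ffm.draw(rng), 25.0), 0.95 * bm)
    bmr = max(preset.bmr.draw(rng), 3.0)
    vo2peak = max(preset.vo2peak.draw(rng), 1.0)
    hrpeak = float(np.clip(preset.hrpeak.draw(rng), 140.0, 210.0))
    mfo = max(preset.mfo.draw(rng), 0.05)
    fatmax = float(np.clip(preset.fatmax.draw(rng), 25.0, 70.0))
    crossover = float(np.clip(preset.crossover.draw(rng), fatmax + 4.0, 100.0))
    return SyntheticSubject(
        subject_id=subject_id or f"{preset.name}-{rng.integers(1 << 31)}",
        group=preset.group,
        age=max(preset.age.draw(rng), 10.0),
        stature=stature,
        body_mass=bm,
        ffm=ffm,
        bmr=bmr,
        hr_peak=hrpeak,
        true_mfo=mfo,
        true_fatmax=fatmax,
        true_crossover=crossover,
        true_vo2peak=vo2peak,
        session_fat_gain=preset.session_fat_gain,
    )


def _apply_gas_noise(
    rng: np.random.Generator, noise: NoiseModel, vo2: np.ndarray, vco2: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    if noise.gas_cv > 0:
        vo2 = vo2 * (1.0 + noise.gas_cv * rng.standard_normal(vo2.size))
        vco2 = vco2 * (1.0 + noise.gas_cv * rng.standard_normal(vco2.size))
    vo2 = np.clip(vo2, 0.0, None)
    vco2 = np.clip(vco2, 0.0, RER_CEILING * vo2)
    return vo2, vco2


def simulate_bmr_recording(
    subject: SyntheticSubject,
    noise: Optional[NoiseModel] = None,
    duration_min: int = 45,
    seed=None,
) -> GasSeries:
    """45-min ventilated-canopy recording at 1-min averaging.

    Steady-state gas exchange is chosen so that Weir inversion returns the
    subject's BMR exactly (RER 0.85); the first 8 min carry a decaying
    adaptation transient (identically zero afterwards), so an analyzer
    discarding the first 10 min recovers the truth and one discarding
    nothing is biased high.
    """
    noise = noise or DEFAULT_NOISE
    rng = _rng(seed, noise)
    t = np.arange(duration_min, dtype=float) * 60.0
    vo2_ss = subject.vo2_rest
    vco2_ss = REST_RER * vo2_ss
    adapt = np.where(
        t < ADAPT_DURATION_S,
        1.0 + ADAPT_AMPLITUDE * (1.0 - t / ADAPT_DURATION_S) ** 2,
        1.0,
    )
    vo2, vco2 = _apply_gas_noise(rng, noise, vo2_ss * adapt, vco2_ss * adapt)
    return GasSeries(t=t, vo2=vo2, vco2=vco2, dt_nominal=60.0, phase=Phase.REST)


def _kinetic_trace(
    t: np.ndarray, seg_starts: np.ndarray, seg_targets: np.ndarray, v0: float, tau: float
) -> np.ndarray:
    """Piecewise mono-exponential approach to each segment's target."""
    out = np.empty_like(t)
    current = v0
    for i, start in enumerate(seg_starts):
        end = seg_starts[i + 1] if i + 1 < len(seg_starts) else np.inf
        mask = (t >= start) & (t < end)
        if tau <= 0:
            out[mask] = seg_targets[i]
        else:
            out[mask] = seg_targets[i] + (current - seg_targets[i]) * np.exp(
                -(t[mask] - start) / tau
            )
        if tau <= 0:
            current = seg_targets[i]
        else:
            current = seg_targets[i] + (current - seg_targets[i]) * np.exp(-(end - start) / tau) \
                if np.isfinite(end) else seg_targets[i]
    return out


def _hr_from_vo2(subject: SyntheticSubject, vo2: np.ndarray) -> np.ndarray:
    span = subject.true_vo2peak - subject.vo2_rest
    frac = np.clip((vo2 - subject.vo2_rest) / span, 0.0, None)
    return subject.hr_rest + (subject.hr_peak - subject.hr_rest) * frac


def simulate_graded_test(
    subject: SyntheticSubject,
    noise: Optional[NoiseModel] = None,
    protocol: Optional[GradedProtocol] = None,
    seed=None,
    dt: float = 5.0,
    stage_fractions: Tuple[float, ...] = STAGE_INTENSITY_FRACTIONS,
) -> GasSeries:
    """One graded treadmill test at 5-s breath averaging.

    Stage steady-states climb to the subject's true V'O2peak at the final
    workload; V'CO2 encodes the subject's fat-oxidation truth curve at the
    subject's resting Pox.  The recording is truncated at the first sample
    whose 30-s smoothed heart rate reaches the protocol's stop criterion.
    """
    noise = noise or DEFAULT_NOISE
    rng = _rng(seed, noise)
    protocol = protocol or default_grad_protocol()
    n_stages = len(protocol.stages)
    if len(stage_fractions) != n_stages:
        raise ConfigurationError(
            f"stage_fractions has {len(stage_fractions)} entries for {n_stages} stages"
        )
    pox = subject.resting_pox

    seg_starts = [0.0]
    vo2_targets = [subject.vo2_rest]
    vco2_targets = [REST_RER * subject.vo2_rest]
    speeds = [0.0]
    inclines = [0.0]
    for i, stage in enumerate(protocol.stages):
        start, _ = protocol.stage_window(i)
        vo2_s = stage_fractions[i] * subject.true_vo2peak
        fat_s = fat_curve(
            100.0 * stage_fractions[i], subject.true_mfo,
            subject.true_fatmax, subject.true_crossover,
        )
        seg_starts.append(start)
        vo2_targets.append(vo2_s)
        vco2_targets.append(vo2_s - (fat_s + abs(cal.FAT_POX) * pox) / cal.FAT_O2)
        speeds.append(stage.speed)
        inclines.append(stage.incline)

    t_total = protocol.rest_duration + protocol.exercise_duration
    t = np.arange(0.0, t_total, dt)
    seg_starts = np.array(seg_starts)
    vo2_nl = _kinetic_trace(t, seg_starts, np.array(vo2_targets), subject.vo2_rest, noise.onset_tau)
    vco2_nl = _kinetic_trace(
        t, seg_starts, np.array(vco2_targets), REST_RER * subject.vo2_rest, noise.onset_tau
    )
    hr = _hr_from_vo2(subject, vo2_nl)
    if noise.hr_sd > 0:
        hr = hr + noise.hr_sd * rng.standard_normal(hr.size)
    hr = np.clip(hr, 30.0, 230.0)
    vo2, vco2 = _apply_gas_noise(rng, noise, vo2_nl, vco2_nl)

    # clinician watches a smoothed HR trend; stop at the first crossing
    win = max(int(round(30.0 / dt)), 1)
    kernel = np.ones(win) / win
    smoothed = np.convolve(hr, kernel, mode="full")[: hr.size]
    smoothed[: win - 1] = hr[: win - 1]  # warm-up of the running mean
    over = (smoothed >= protocol.hr_stop) & (t >= protocol.rest_duration)
    cut = int(np.argmax(over)) + 1 if np.any(over) else t.size

    seg_idx = np.searchsorted(seg_starts, t, side="right") - 1
    speed_arr = np.array(speeds)[seg_idx]
    incline_arr = np.array(inclines)[seg_idx]
    return GasSeries(
        t=t[:cut],
        vo2=vo2[:cut],
        vco2=vco2[:cut],
        hr=hr[:cut],
        speed=speed_arr[:cut],
        incline=incline_arr[:cut],
        dt_nominal=dt,
        phase=Phase.MIXED,
        exercise_start_s=protocol.rest_duration,
    )


def _segment_steady_gas(
    subject: SyntheticSubject,
    intensity: float,
    kj_per_l_o2: float = KJ_PER_L_O2,
) -> Tuple[float, float]:
    """Steady (V'O2, V'CO2) of a session segment at planned ``intensity``.

    The substrate truth is the subject's fat curve (times the preset's
    session fat gain) and a protein rate at 12% of the segment's Weir EE;
    V'O2 is solved by fixed point so the substrate-sum energy per minute
    equals the planned segment energy (intensity x V'O2peak x kJ/L), which
    keeps simulated sessions on their designed energy budget.
    """
    per_min_target = intensity / 100.0 * subject.true_vo2peak * kj_per_l_o2
    fat = subject.session_fat_gain * fat_curve(
        intensity, subject.true_mfo, subject.true_fatmax, subject.true_crossover
    )
    fat = min(fat, 0.9 * per_min_target / cal.DEFAULT_FACTORS.kj_per_g_fat)
    vo2 = per_min_target / 20.4
    vco2 = REST_RER * vo2
    for _ in range(60):
        ee_w = cal.resting_ee_weir(vo2, vco2)
        pox = cal.protein_oxidation_rate(ee_w)
        vco2 = vo2 - (fat + abs(cal.FAT_POX) * pox) / cal.FAT_O2
        cho = max(cal.cho_oxidation_rate(vo2, max(vco2, 0.0), pox), 0.0)
        ee_sum = (
            cal.DEFAULT_FACTORS.kj_per_g_fat * fat
            + cal.DEFAULT_FACTORS.kj_per_g_cho * cho
            + cal.DEFAULT_FACTORS.kj_per_g_protein * pox
        )
        ratio = per_min_target / ee_sum
        if abs(ratio - 1.0) < 1e-12:
            break
        vo2 *= ratio
    return float(vo2), float(vco2)


def simulate_submax_session(
    subject: SyntheticSubject,
    plan: SessionPlan,
    noise: Optional[NoiseModel] = None,
    seed=None,
    dt: float = 5.0,
) -> GasSeries:
    """Gas-exchange recording of one planned training session (exercise only)."""
    noise = noise or DEFAULT_NOISE
    rng = _rng(seed, noise)
    seg_starts, vo2_targets, vco2_targets = [], [], []
    t_cursor = 0.0
    for seg in plan.segments:
        vo2_s, vco2_s = _segment_steady_gas(subject, seg.intensity)
        seg_starts.append(t_cursor)
        vo2_targets.append(vo2_s)
        vco2_targets.append(vco2_s)
        t_cursor += seg.duration
    t = np.arange(0.0, t_cursor, dt)
    seg_starts = np.array(seg_starts)
    vo2_nl = _kinetic_trace(t, seg_starts, np.array(vo2_targets), subject.vo2_rest, noise.onset_tau)
    vco2_nl = _kinetic_trace(
        t, seg_starts, np.array(vco2_targets), REST_RER * subject.vo2_rest, noise.onset_tau
    )
    hr = _hr_from_vo2(subject, vo2_nl)
    if noise.hr_sd > 0:
        hr = hr + noise.hr_sd * rng.standard_normal(hr.size)
    hr = np.clip(hr, 30.0, 230.0)
    vo2, vco2 = _apply_gas_noise(rng, noise, vo2_nl, vco2_nl)
    return GasSeries(
        t=t, vo2=vo2, vco2=vco2, hr=hr, dt_nominal=dt,
        phase=Phase.EXERCISE, exercise_start_s=0.0,
    )


@dataclass
class CohortBundle:
    """Everything simulate_cohort produces."""

    table: TrialTable
    subjects: dict  # (subject_id, timepoint) -> SyntheticSubject
    series: dict = field(default_factory=dict)  # (subject_id, timepoint, kind) -> GasSeries


_UNITS = {
    "BM": "kg",
    "BMI": "kg m-2",
    "FFM": "kg",
    "FM": "kg",
    "FM_pct": "%",
    "BMR": "MJ day-1",
    "VO2peak": "L min-1",
    "VO2peak_rel_FFM": "mL min-1 kg FFM-1",
    "HRpeak": "bpm",
    "O2pulse": "mL beat-1",
    "MFO": "g min-1",
    "Fatmax": "%VO2peak",
}

_PAIRED_FIELDS = (
    "age", "stature", "body_mass", "ffm", "bmr",
    "vo2peak", "hrpeak", "mfo", "fatmax", "crossover",
)


def _paired_draw(rng, c0: Gauss, c3: Gauss, rho: float) -> Tuple[float, float]:
    x0 = c0.draw(rng)
    if c0.sd == 0 or c3.sd == 0:
        return x0, c3.draw(rng)
    z = rng.standard_normal()
    x3 = c3.mean + rho * c3.sd / c0.sd * (x0 - c0.mean) + np.sqrt(1 - rho**2) * c3.sd * z
    return x0, float(x3)


def simulate_cohort(
    n_per_group,
    presets: Optional[Dict[str, GroupPreset]] = None,
    noise: Optional[NoiseModel] = None,
    seed=None,
    rho: float = 0.8,
    include_series: bool = False,
) -> CohortBundle:
    """Paired W0/W3 cohort with correlated within-subject changes.

    ``n_per_group`` is an int or a ``{group: n}`` mapping.  Outcome columns
    derived from the draws (BMI, FM, O2 pulse, relative V'O2peak) are
    computed, not drawn, so their group summaries are mean-of-ratios over
    subjects exactly as a real cohort table would report them.  With
    ``include_series`` the bundle also carries per-subject canopy and
    graded-test recordings.
    """
    import pandas as pd

    presets = presets or PRESETS
    noise = noise or DEFAULT_NOISE
    rng = _rng(seed, noise)
    if isinstance(n_per_group, int):
        n_per_group = {"COMB": n_per_group, "MICT": n_per_group}
    rows = []
    subjects = {}
    series = {}
    for group, n in n_per_group.items():
        p0 = presets[f"{group}_W0"]
        p3 = presets[f"{group}_W3"]
        if min(n, 0) < 0 or n < 2:
            raise DomainError(f"need n >= 2 per group, got {n} for {group}")
        for i in range(n):
            sid = f"{group}{i:03d}"
            draws = {f: _paired_draw(rng, getattr(p0, f), getattr(p3, f), rho)
                     for f in _PAIRED_FIELDS}
            for tp_idx, (preset, tp) in enumerate(((p0, "W0"), (p3, "W3"))):
                d = {f: draws[f][tp_idx] for f in _PAIRED_FIELDS}
                bm = max(d["body_mass"], 40.0)
                ffm = min(max(d["ffm"], 25.0), 0.95 * bm)
                fatmax = float(np.clip(d["fatmax"], 25.0, 70.0))
                subj = SyntheticSubject(
                    subject_id=sid,
                    group=preset.group,
                    age=max(d["age"], 10.0),
                    stature=max(d["stature"], 1.2),
                    body_mass=bm,
                    ffm=ffm,
                    bmr=max(d["bmr"], 3.0),
                    hr_peak=float(np.clip(d["hrpeak"], 140.0, 210.0)),
                    true_mfo=max(d["mfo"], 0.05),
                    true_fatmax=fatmax,
                    true_crossover=float(np.clip(d["crossover"], fatmax + 4.0, 100.0)),
                    true_vo2peak=max(d["vo2peak"], 1.0),
                    session_fat_gain=preset.session_fat_gain,
                )
                subjects[(sid, tp)] = subj
                fm_kg, fm_pct = fat_mass(subj.body_mass, subj.ffm)
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "timepoint": tp,
                        "BM": subj.body_mass,
                        "BMI": bmi(subj.body_mass, subj.stature),
                        "FFM": subj.ffm,
                        "FM": fm_kg,
                        "FM_pct": fm_pct,
                        "BMR": subj.bmr,
                        "VO2peak": subj.true_vo2peak,
                        "VO2peak_rel_FFM": 1000.0 * subj.true_vo2peak / subj.ffm,
                        "HRpeak": subj.hr_peak,
                        "O2pulse": o2_pulse(subj.true_vo2peak, subj.hr_peak),
                        "MFO": subj.true_mfo,
                        "Fatmax": subj.true_fatmax,
                    }
                )
                if include_series:
                    sub_seed = int(rng.integers(1 << 31))
                    series[(sid, tp, "bmr")] = simulate_bmr_recording(
                        subj, noise, seed=sub_seed
                    )
                    series[(sid, tp, "graded")] = simulate_graded_test(
                        subj, noise, seed=sub_seed + 1
                    )
    table = TrialTable(data=pd.DataFrame(rows), units=dict(_UNITS))
    return CohortBundle(table=table, subjects=subjects, series=series)
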