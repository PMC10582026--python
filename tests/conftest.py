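import numpy as np
import pytest

from ergocal.calorimetry import SubstrateRates
from ergocal.graded import GradedResult, StageMeasurement
from ergocal.synthetic import PRESETS, NoiseModel, make_subject
from ergocal.types import GasSeries, Phase


@pytest.fixture(scope="session")
def noiseless() -> NoiseModel:
    return NoiseModel(gas_cv=0.0, hr_sd=0.0)


@pytest.fixture(scope="session")
def comb_subject():
    """The mean baseline combined-training subject (zero-SD preset)."""
    return make_subject(PRESETS["COMB_W0"].zero_noise(), seed=0)


@pytest.fixture(scope="session")
def mict_subject():
    return make_subject(PRESETS["MICT_W0"].zero_noise(), seed=0)


def constant_series(
    vo2: float,
    vco2: float,
    duration_s: float,
    dt: float = 5.0,
    hr: float | None = None,
    phase: Phase = Phase.EXERCISE,
) -> GasSeries:
    t = np.arange(0.0, duration_s, dt)
    n = t.size
    return GasSeries(
        t=t,
        vo2=np.full(n, vo2),
        vco2=np.full(n, vco2),
        hr=None if hr is None else np.full(n, float(hr)),
        dt_nominal=dt,
        phase=phase,
    )


def make_stage(
    index: int,
    intensity: float,
    fat: float,
    cho: float = 0.5,
    hr: float | None = None,
    vo2: float = 1.0,
    vco2: float = 0.85,
) -> StageMeasurement:
    return StageMeasurement(
        stage_index=index,
        intensity=intensity,
        vo2=vo2,
        vco2=vco2,
        hr=hr,
        rates=SubstrateRates(fat=fat, cho=cho, protein=0.04),
    )


def result_from_stages(stages, vo2peak=2.52, hrpeak=176.0) -> GradedResult:
    return GradedResult(vo2peak=vo2peak, hrpeak=hrpeak, o2pulse=None, stages=list(stages))
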