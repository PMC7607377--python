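import numpy as np
import pytest

from jointrisk.filters import PatientRecord
from jointrisk.splines import KnotSet
from jointrisk.survival import FlexPHModel, SurvivalDataset
from jointrisk.synthetic import default_config, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def simple_knots():
    """Boundary knots at 0 and 2, one internal knot at 1 (log-time axis)."""
    return KnotSet(0.0, 2.0, (1.0,))


@pytest.fixture
def unit_exp_model():
    """Unit-rate exponential baseline: log Lambda0 = log t, no covariates."""
    return FlexPHModel(
        beta=np.array([]), gamma=np.array([0.0, 1.0]), knots=KnotSet(-3.0, 3.0)
    )


def make_exponential_dataset(rate: float, n: int, seed: int,
                             censor: float | None = None) -> SurvivalDataset:
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / rate, n)
    d = np.ones(n, dtype=int)
    if censor is not None:
        d = (t <= censor).astype(int)
        t = np.minimum(t, censor)
    return SurvivalDataset(X=np.empty((n, 0)), time=t, event=d, names=())


@pytest.fixture(scope="session")
def small_cohort():
    """2000-record synthetic cohort under the default study conditions."""
    return simulate_cohort(default_config(n=2000, seed=11))


def make_record(**overrides) -> PatientRecord:
    base = dict(age=68.0, sex="female", bmi=29.0, asa=2,
                surgery_group="hip", prom_pre=18)
    base.update(overrides)
    return PatientRecord(**base)
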