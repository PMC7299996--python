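import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from srstream import CQParams, SampleRecord, SyntheticConfig, TrendParams, generate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trend_params() -> TrendParams:
    """The fitted long-term decline parameters used throughout the examples."""
    return TrendParams(alpha=9357.0, beta=2500.0, k1=0.254, k2=0.002, lam=0.024)


@pytest.fixture(scope="session")
def cq_params() -> CQParams:
    """Best-fit concentration-formation parameters."""
    return CQParams(a=0.28, b=1.37, d=2117.0)


@pytest.fixture(scope="session")
def noisefree_dataset(trend_params, cq_params):
    """Biweekly 1990-2016 series with exact model concentrations (no measurement noise)."""
    cfg = SyntheticConfig(trend=trend_params, cq=cq_params, noise_cv=0.0, err_pct=None, seed=11)
    records, sidecar = generate_dataset(cfg)
    return records, sidecar


@pytest.fixture(scope="session")
def noisy_dataset(trend_params, cq_params):
    """Default study-condition series: biweekly 1990-2016 with 10.9% lognormal noise."""
    cfg = SyntheticConfig(trend=trend_params, cq=cq_params, seed=42)
    records, sidecar = generate_dataset(cfg)
    return records, sidecar


def make_record(date: dt.date, q: float, c: float, err_pct: float | None = None) -> SampleRecord:
    return SampleRecord(date=date, q=q, c=c, err_pct=err_pct)
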