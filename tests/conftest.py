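import numpy as np
import pytest

from grangernet import TimeSeriesTable


@pytest.fixture
def small_table() -> TimeSeriesTable:
    """3 variables x 12 time points, deterministic, no missing values."""
    rng = np.random.default_rng(99)
    return TimeSeriesTable(
        values=rng.normal(size=(3, 12)),
        var_ids=["A", "B", "C"],
        var_class=["OTU", "OTU", "environmental"],
        time_labels=[str(t) for t in range(12)],
    )


def ar1(coef: float, T: int, seed: int, sd: float = 1.0) -> np.ndarray:
    """Independent AR(1) draw used as a simple oracle-side generator."""
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, sd, size=T + 100)
    x = np.zeros(T + 100)
    for t in range(1, T + 100):
        x[t] = coef * x[t - 1] + e[t]
    return x[100:]
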