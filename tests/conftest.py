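import numpy as np
import pytest

from mfl import DimensionSummary, FactorModel, InstrumentSummary, LoadingSet


@pytest.fixture
def tau_model():
    """Essentially tau-equivalent two-factor model (equal 0.70 loadings)."""
    ls = LoadingSet(np.array([0.70, 0.70, 0.70]))
    return FactorModel(ls, ls, 0.6)


@pytest.fixture
def congeneric_model():
    """Congeneric model with the 0.60/0.70/0.80 loading pattern."""
    ls = LoadingSet(np.array([0.60, 0.70, 0.80]))
    return FactorModel(ls, ls, 0.6)


def constant_corr(k: int, r: float) -> np.ndarray:
    """K x K correlation matrix with constant off-diagonal r."""
    m = np.full((k, k), r, dtype=float)
    np.fill_diagonal(m, 1.0)
    return m


@pytest.fixture
def tau_instrument():
    """Two-dimension instrument at the tau-equivalent population values
    (alpha = 1.47/1.98, composite correlation = 0.6 * alpha)."""
    alpha = 3 * 0.49 / (1 + 2 * 0.49)
    r = 0.6 * alpha
    return InstrumentSummary(
        dimensions=(
            DimensionSummary("X", alpha, 3),
            DimensionSummary("Y", alpha, 3),
        ),
        composite_corr=constant_corr(2, r),
    )
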