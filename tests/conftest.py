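import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tmescore import synthetic
from tmescore.containers import ExpressionMatrix, Unit

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def signature22():
    return synthetic.bundled_signature()


@pytest.fixture(scope="session")
def default_cohort(signature22):
    """Default 4-subtype cohort, n = 200."""
    cfg = synthetic.SimConfig(seed=0)
    return synthetic.simulate_cohort(cfg, signature22)


@pytest.fixture(scope="session")
def small_cohort(signature22):
    """Small cohort for fast pipeline smoke tests."""
    cfg = synthetic.SimConfig(seed=5, n_samples=80, n_genes=700,
                              missing_frac=0.02)
    return synthetic.simulate_cohort(cfg, signature22)


def make_expression(values: np.ndarray, unit=Unit.TPM, mask=None,
                    prefix="G") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"S{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    m = None
    if mask is not None:
        m = pd.DataFrame(np.asarray(mask, dtype=bool), index=genes,
                         columns=samples)
    return ExpressionMatrix(df, unit, m)
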