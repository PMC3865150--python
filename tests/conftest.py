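import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from refrank.ct_data import CtMatrix, QuantityMatrix, SampleAnnotation

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_annotations(n, group="g", treatment="ctrl", tech=0):
    return [SampleAnnotation(f"s{i}", group, treatment, i + 1, tech) for i in range(n)]


def make_ct(values, genes=None, samples=None):
    """CtMatrix from a 2-D array with autogenerated single-group annotations."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or make_annotations(values.shape[1])
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                      columns=[s.sample_id for s in samples])
    return CtMatrix(df, samples)


def make_quantity(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or make_annotations(values.shape[1])
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                      columns=[s.sample_id for s in samples])
    return QuantityMatrix(df, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
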