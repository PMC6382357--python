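import numpy as np
import pandas as pd
import pytest

from evintegra.tables_io import ExpressionMatrix, SampleMeta


def make_matrix(values, feature_ids=None, samples=None, unit="FPKM"):
    """Build a small ExpressionMatrix from a 2D array.

    Default design: one cell line, columns alternating 2D/3D cell samples.
    """
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    if samples is None:
        samples = []
        for j in range(n_samp):
            cond = "2D" if j < n_samp // 2 else "3D"
            rep = j % (n_samp // 2) + 1 if n_samp >= 2 else 1
            samples.append(
                SampleMeta(f"s{j + 1}", "MKN45", cond, "cell", rep)
            )
    data = pd.DataFrame(
        values, index=pd.Index(feature_ids, name="feature_id"),
        columns=[s.sample_id for s in samples],
    )
    return ExpressionMatrix(data, samples, unit)


def full_design_matrix(values, feature_ids=None):
    """4-group design (2D/3D x cell/EV), 2 replicates each, one cell line."""
    values = np.asarray(values, dtype=float)
    samples = []
    for cond in ("2D", "3D"):
        for ent in ("cell", "EV"):
            for rep in (1, 2):
                samples.append(
                    SampleMeta(f"{cond}_{ent}_r{rep}", "MKN45", cond, ent, rep)
                )
    assert values.shape[1] == len(samples)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(values.shape[0])]
    data = pd.DataFrame(
        values, index=pd.Index(feature_ids, name="feature_id"),
        columns=[s.sample_id for s in samples],
    )
    return ExpressionMatrix(data, samples)


@pytest.fixture(scope="session")
def synthetic_default():
    """One default synthetic dataset shared across tests (seed 7)."""
    from evintegra.synthetic_data import SyntheticConfig, generate_dataset

    return generate_dataset(SyntheticConfig(seed=7))
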