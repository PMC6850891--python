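import numpy as np
import pandas as pd
import pytest

from refstab.core import CtMatrix


def make_matrix(genes, samples, ct, meta=None) -> CtMatrix:
    return CtMatrix(genes=list(genes), samples=list(samples),
                    ct=np.asarray(ct, float), meta=meta)


@pytest.fixture
def t1_matrix() -> CtMatrix:
    """Toy matrix T1: 3 genes x 4 samples, hand-picked values."""
    return make_matrix(
        genes=["gA", "gB", "gC"],
        samples=["s1", "s2", "s3", "s4"],
        ct=[[20.0, 21.0, 19.5, 22.0],
            [25.0, 25.8, 24.6, 26.9],
            [30.0, 30.1, 29.9, 31.5]],
    )


@pytest.fixture
def t2_matrix() -> CtMatrix:
    """Toy matrix T2: 3 genes x 2 groups x 3 samples, fixed values."""
    meta = pd.DataFrame({
        "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
        "set": "toy", "group": ["A", "A", "A", "B", "B", "B"],
    }).set_index("sample_id")
    return make_matrix(
        genes=["gA", "gB", "gC"],
        samples=["a1", "a2", "a3", "b1", "b2", "b3"],
        ct=[[20.0, 20.3, 19.8, 20.1, 20.4, 19.9],
            [25.0, 25.5, 24.8, 26.9, 27.3, 27.1],
            [30.0, 29.7, 30.2, 30.1, 29.8, 30.3]],
        meta=meta,
    )


@pytest.fixture
def grouped_meta():
    def build(samples, groups, set_name="set"):
        return pd.DataFrame(
            {"sample_id": samples, "set": set_name, "group": groups}
        ).set_index("sample_id")
    return build
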