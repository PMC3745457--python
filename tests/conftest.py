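import numpy as np
import pytest

from stromasig import ExpressionMatrix, SampleAnnotation, SurvivalTable


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(30)]
    samples = [f"s{j}" for j in range(10)]
    return ExpressionMatrix(genes, samples, rng.normal(7, 1, size=(30, 10)))


@pytest.fixture
def two_group_annot() -> SampleAnnotation:
    return SampleAnnotation(
        {f"s{j}": ("tumor" if j < 5 else "normal") for j in range(10)}
    )


@pytest.fixture
def six_patient_surv() -> SurvivalTable:
    # mixed events and censoring, with one tie at t=4
    return SurvivalTable(
        ["p1", "p2", "p3", "p4", "p5", "p6"],
        np.array([1.0, 2.0, 2.5, 4.0, 4.0, 5.0]),
        np.array([1, 0, 1, 1, 1, 0]),
    )
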