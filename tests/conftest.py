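import numpy as np
import pandas as pd
import pytest

from slidecorr.synthetic import ConfounderSpec, PiecewiseCouplingModel, generate


@pytest.fixture(scope="session")
def piecewise_table():
    """Seeded piecewise dataset with two confounders (n=2000) + ground truth."""
    model = PiecewiseCouplingModel(
        n=2000,
        breakpoints=(40.0, 60.0),
        slopes=(1.0, 0.0, -1.0),
        noise_sd=4.0,
        confounders=(ConfounderSpec(1.0, 1.0), ConfounderSpec(-0.5, 0.8)),
        seed=2024,
    )
    return generate(model)


@pytest.fixture()
def simple_csv(tmp_path):
    """A three-row CSV with a label column and two numeric columns."""
    path = tmp_path / "obs.csv"
    path.write_text("prov,fert,yield\nA,1.0,2.0\nB,2.0,4.0\nC,3.0,6.0\n")
    return path


def precision_matrix_partial_r(x, y, Z=None):
    """Independent partial-correlation oracle: -P01/sqrt(P00*P11) from the
    inverse of the correlation matrix of [x, y, controls...]."""
    cols = [np.asarray(x, float), np.asarray(y, float)]
    if Z is not None:
        Z = np.atleast_2d(np.asarray(Z, float).T).T
        cols.extend(Z[:, j] for j in range(Z.shape[1]))
    C = np.corrcoef(np.column_stack(cols), rowvar=False)
    P = np.linalg.inv(C)
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
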