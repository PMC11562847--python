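import numpy as np
import pandas as pd
import pytest

from gexdist.distributions import Family, ParamVector
from gexdist.matrixio import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, gene_ids=None, sample_ids=None, labels=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    lab = pd.Series(labels, index=sample_ids) if labels is not None else None
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), labels=lab
    )


@pytest.fixture
def small_matrix(rng):
    return make_matrix(rng.lognormal(0.0, 1.0, size=(5, 40)))


#: Representative valid parameter sets, one per family.
REFERENCE_PARAMS = {
    Family.NORMAL: ParamVector(Family.NORMAL, (5.0, 2.0)),
    Family.T: ParamVector(Family.T, (5.0, 0.0, 1.0)),
    Family.PARETO: ParamVector(Family.PARETO, (3.0, 2.0)),
    Family.DWEIBULL: ParamVector(Family.DWEIBULL, (2.0, 1.5, 2.0)),
    Family.GENEXTREME: ParamVector(Family.GENEXTREME, (0.0, 1.0, 0.2)),
    Family.LAPLACE: ParamVector(Family.LAPLACE, (0.0, 1.0)),
    Family.CAUCHY: ParamVector(Family.CAUCHY, (1.0, 3.0)),
    Family.CHI2: ParamVector(Family.CHI2, (4.0,)),
    Family.EXPON: ParamVector(Family.EXPON, (1.5,)),
    Family.EXPONPOW: ParamVector(Family.EXPONPOW, (1.5, 1.0, 0.0)),
    Family.GAMMA: ParamVector(Family.GAMMA, (2.0, 1.0)),
    Family.BETA: ParamVector(Family.BETA, (2.0, 5.0)),
    Family.LOGNORM: ParamVector(Family.LOGNORM, (1.0, 0.5)),
    Family.LOGGAMMA: ParamVector(Family.LOGGAMMA, (3.0, 2.0)),
    Family.UNIFORM: ParamVector(Family.UNIFORM, (0.0, 1.0)),
    Family.GAUSSIAN_MIXTURE: ParamVector(
        Family.GAUSSIAN_MIXTURE, (-2.0, 2.0, 1.0, 1.0, 0.5)
    ),
}
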