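import numpy as np
import pytest

import ssinfer as si


@pytest.fixture(scope="session")
def s1():
    return si.make_s1()


@pytest.fixture(scope="session")
def s2():
    return si.make_s2()


@pytest.fixture(scope="session")
def s1_data(s1):
    """Noise-free S1 dataset (4 conditions, 15 points, five-point slopes)."""
    return si.generate_dataset(s1, 4, 15, (0.0, 0.5), (0.5, 1.5), seed=11)


@pytest.fixture(scope="session")
def s1_data_analytic(s1):
    """Noise-free S1 dataset with exact-RHS slopes (zero error at the truth)."""
    return si.generate_dataset(s1, 4, 15, (0.0, 0.5), (0.5, 1.5), seed=11,
                               slope_method="analytic")


def true_solution(model, i, ds=None):
    """MixedSolution encoding the true parameters of equation i."""
    n = model.n_dep
    g, h = model.G[i, :n], model.H[i, :n]
    bx = np.concatenate([(g != 0), (h != 0)]).astype(np.uint8)
    rx = np.concatenate([g, h, [model.alpha[i], model.beta[i]]])
    return si.MixedSolution(bx=bx, rx=rx, eq_index=i)
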