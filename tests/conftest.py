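import numpy as np
import pytest

from netdisrupt import synthdata as sd
from netdisrupt.pipeline import atlas_raster_masks


@pytest.fixture(scope="session")
def atlas():
    return sd.make_phantom_atlas((24, 24, 16), seed=0)


@pytest.fixture(scope="session")
def masks(atlas):
    return atlas_raster_masks(atlas)


@pytest.fixture(scope="session")
def rest_design():
    return sd.make_design("rest", tr=3.0, n_volumes=65)


def fista_lasso(X, D, lam, n_iter=20000):
    """Independent slow LASSO oracle: accelerated projected (proximal)
    gradient on min_a 1/2||x_j - D a||^2 + lam ||a||_1 for every row of X."""
    V, _T = X.shape
    n = D.shape[1]
    L = np.linalg.norm(D, 2) ** 2
    A = np.zeros((V, n))
    Y = A.copy()
    t = 1.0
    for _ in range(n_iter):
        G = (Y @ D.T - X) @ D
        Z = Y - G / L
        A_new = np.sign(Z) * np.maximum(np.abs(Z) - lam / L, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        Y = A_new + ((t - 1) / t_new) * (A_new - A)
        A, t = A_new, t_new
    return A


def lasso_objective(X, D, A, lam):
    resid = X - A @ D.T
    return 0.5 * np.sum(resid ** 2) + lam * np.abs(A).sum()
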