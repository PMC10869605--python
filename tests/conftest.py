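"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize


@pytest.fixture(scope="session")
def activity_table():
    from mkqsar.datasets import load_activity_table

    return load_activity_table()


def dense_qp_svr(K: np.ndarray, y: np.ndarray, eps: float, box: float):
    """Brute-force dense convex-QP solution of the epsilon-SVR dual.

    Solves over the 2l split multipliers (alpha, alpha*) with SLSQP at tight
    tolerance; independent of the package's SMO path.  Returns
    (beta, minimized objective).
    """
    l = len(y)

    def obj(z):
        beta = z[:l] - z[l:]
        return 0.5 * beta @ K @ beta + eps * z.sum() - y @ beta

    def grad(z):
        g = K @ (z[:l] - z[l:])
        return np.concatenate([g + eps - y, -g + eps + y])

    cons = [{
        "type": "eq",
        "fun": lambda z: z[:l].sum() - z[l:].sum(),
        "jac": lambda z: np.concatenate([np.ones(l), -np.ones(l)]),
    }]
    res = minimize(
        obj, np.zeros(2 * l), jac=grad, bounds=[(0.0, box)] * (2 * l),
        constraints=cons, method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x[:l] - res.x[l:], float(res.fun)


@pytest.fixture(scope="session")
def qp_oracle():
    return dense_qp_svr


def random_kernel_spec(rng: np.random.Generator):
    """A random valid KernelSpec drawn uniformly over the three families."""
    from mkqsar.kernels import KernelSpec

    family = ("single", "double", "triple")[int(rng.integers(3))]
    sigma = float(rng.uniform(0.3, 3.0))
    q = int(rng.integers(1, 4))
    if family == "single":
        return KernelSpec("single", sigma=sigma)
    if family == "double":
        a = float(rng.uniform(0, 1))
        return KernelSpec("double", sigma=sigma, q=q, a=a, b=1 - a)
    a = float(rng.uniform(0, 1))
    b = float(rng.uniform(0, 1 - a))
    return KernelSpec("triple", sigma=sigma, q=q, a=a, b=b)


@pytest.fixture(scope="session")
def spec_sampler():
    return random_kernel_spec
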