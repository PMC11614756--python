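"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: polynomial
coefficients come from an explicit normal-equations Vandermonde solve (on
a rescaled time axis for conditioning, with exact coefficient rescaling
back), and the t-test is cross-checked against an exhaustive permutation
test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from qdtherm import RunConfig, SyntheticConfig, generate_study


def ols_vandermonde_oracle(t, y, degree, weights=None):
    """Brute-force least squares via the normal equations.

    Solves (V'WV) c = V'Wy on u = t/t_max and rescales the coefficients
    back to the power basis over t, exactly.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tmax = t.max() if t.max() > 0 else 1.0
    u = t / tmax
    V = np.vander(u, degree + 1, increasing=True)
    if weights is None:
        A, b = V.T @ V, V.T @ y
    else:
        w2 = np.asarray(weights, dtype=float) ** 2
        A, b = V.T @ (w2[:, None] * V), V.T @ (w2 * y)
    c_scaled = np.linalg.solve(A, b)
    return c_scaled / tmax ** np.arange(degree + 1)


def permutation_t_test_oracle(a, b):
    """Exhaustive two-sided permutation p-value for the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = abs(a.mean() - b.mean())
    count = total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += diff >= observed - 1e-12
        total += 1
    return count / total


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def default_dataset():
    """One paper-matched synthetic study, shared across read-only tests."""
    return generate_study(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 2-vs-2-animal study for I/O round trips."""
    return generate_study(SyntheticConfig(seed=7, n_animals_per_group=2))
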