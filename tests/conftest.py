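"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's sparse/operator code paths:
graph functionals are evaluated with dense double loops, and the proximal /
constrained problems are solved with generic scipy optimizers on a smoothed
total variation with hand-derived double-loop gradients.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize

from npgtv.patch_graph import WeightedGraph

# smoothing of the Euclidean norm inside the oracle objective; the induced
# objective bias is at most n * gamma * sqrt(DELTA), far below test tolerances
DELTA = 1e-14


def random_weighted_graph(n: int, rng: np.random.Generator, density: float = 0.6) -> WeightedGraph:
    """Random connected symmetric weighted graph on n nodes (path backbone)."""
    A = np.triu((rng.random((n, n)) < density) * rng.random((n, n)), 1)
    for i in range(n - 1):  # guarantee connectivity
        if A[i, i + 1] == 0:
            A[i, i + 1] = rng.uniform(0.1, 1.0)
    A = A + A.T
    return WeightedGraph(sp.csr_matrix(A))


def double_loop_local_variations(f: np.ndarray, graph: WeightedGraph) -> np.ndarray:
    """Per-node local variation via an O(n^2) dense double loop."""
    W = graph.W.toarray()
    n = len(f)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if W[i, j] != 0:
                acc += W[i, j] * (f[i] - f[j]) ** 2
        out[i] = np.sqrt(acc)
    return out


def double_loop_tv(f: np.ndarray, graph: WeightedGraph) -> float:
    return float(double_loop_local_variations(f, graph).sum())


def _smoothed_tv_and_grad(f: np.ndarray, W: np.ndarray):
    """Smoothed TV sum_i sqrt(s_i + delta) and its gradient, double loop."""
    n = len(f)
    s = np.zeros(n)
    for i in range(n):
        for j in range(n):
            s[i] += W[i, j] * (f[i] - f[j]) ** 2
    val = float(np.sum(np.sqrt(s + DELTA)))
    grad = np.zeros(n)
    for k in range(n):
        acc = 0.0
        for j in range(n):
            acc += W[k, j] * (f[k] - f[j]) / np.sqrt(s[k] + DELTA)
            acc += W[j, k] * (f[k] - f[j]) / np.sqrt(s[j] + DELTA)
        grad[k] = acc
    return val, grad


def prox_tv_oracle(y: np.ndarray, gamma: float, graph: WeightedGraph) -> float:
    """Minimum of 1/2||u - y||^2 + gamma TV(u) by a generic smooth minimizer."""
    W = graph.W.toarray()

    def obj(v):
        tv, g = _smoothed_tv_and_grad(v, W)
        return 0.5 * float(np.sum((v - y) ** 2)) + gamma * tv, (v - y) + gamma * g

    best = np.inf
    for start in (y, np.full_like(y, y.mean())):
        res = minimize(obj, start, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=20000, ftol=1e-16, gtol=1e-12))
        best = min(best, float(res.fun))
    return best


def constrained_tv_oracle(u0: np.ndarray, eps: float, graph: WeightedGraph,
                          rng: np.random.Generator) -> float:
    """Minimum TV inside the fidelity ball by SLSQP (convex problem)."""
    W = graph.W.toarray()

    def obj(v):
        return _smoothed_tv_and_grad(v, W)

    cons = [{
        "type": "ineq",
        "fun": lambda v: eps**2 - float(np.sum((v - u0) ** 2)),
        "jac": lambda v: -2.0 * (v - u0),
    }]
    best = np.inf
    starts = [u0, np.full_like(u0, u0.mean()), u0 + 0.01 * rng.standard_normal(len(u0))]
    for start in starts:
        res = minimize(obj, start, jac=True, method="SLSQP", constraints=cons,
                       options=dict(maxiter=2000, ftol=1e-14))
        if res.success:
            best = min(best, float(res.fun))
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def pair_graph():
    """Two nodes joined by a unit-weight edge."""
    return WeightedGraph(sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])))
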