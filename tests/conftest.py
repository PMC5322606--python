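"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own fast paths: the
likelihood oracle enumerates every ancestral state assignment, the
matrix-exponential oracle is scipy's Pade ``expm`` (not the package's
eigendecomposition), and the endpoint-conditioned oracles integrate the
defining integrals with adaptive quadrature.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

import statemap as sm
from statemap.model import _edge_transition_matrices


# ---------------------------------------------------------------------------
# Oracles


def enumeration_log_likelihood(tree, data, model) -> float:
    """Brute-force likelihood: sum over all ancestral state assignments."""
    decomp = sm.spectral_decompose(model)
    P = _edge_transition_matrices(tree, decomp)
    tipmat = data.tip_likelihood_matrix([tree.labels[v] for v in tree.tip_ids])
    tip_pos = {int(v): i for i, v in enumerate(tree.tip_ids)}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    s = model.n_states
    total = 0.0
    for assign in itertools.product(range(s), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        prob = model.pi[amap[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            a = amap[tree.parent[v]]
            if tree.children[v]:
                prob *= P[v][a, amap[v]]
            else:
                prob *= float(P[v][a] @ tipmat[tip_pos[v]])
        total += prob
    return float(np.log(total))


def enumeration_node_marginals(tree, data, model) -> np.ndarray:
    """Posterior state marginals per node by exhaustive enumeration,
    summing over ambiguous tip states as well."""
    decomp = sm.spectral_decompose(model)
    P = _edge_transition_matrices(tree, decomp)
    tipmat = data.tip_likelihood_matrix([tree.labels[v] for v in tree.tip_ids])
    tip_pos = {int(v): i for i, v in enumerate(tree.tip_ids)}
    s = model.n_states
    m = tree.n_nodes
    marg = np.zeros((m, s))
    nodes = list(range(m))
    for assign in itertools.product(range(s), repeat=m):
        prob = model.pi[assign[tree.root]]
        for v in nodes:
            if v == tree.root:
                continue
            prob *= P[v][assign[tree.parent[v]], assign[v]]
            if not tree.children[v]:
                prob *= tipmat[tip_pos[v], assign[v]]
        for v in nodes:
            marg[v, assign[v]] += prob
    return marg / marg.sum(axis=1, keepdims=True)


def quadrature_dwell(Q: np.ndarray, T: float, i: int, a: int, b: int) -> float:
    """E[time in state i | X_0=a, X_T=b] by adaptive quadrature on expm."""
    Pab = expm(Q * T)[a, b]
    val, _ = quad(
        lambda tau: expm(Q * tau)[a, i] * expm(Q * (T - tau))[i, b],
        0.0, T, epsabs=1e-13, epsrel=1e-11, limit=200,
    )
    return val / Pab


def quadrature_transitions(Q: np.ndarray, T: float, i: int, j: int, a: int, b: int) -> float:
    """E[# i->j jumps | X_0=a, X_T=b] by adaptive quadrature on expm."""
    Pab = expm(Q * T)[a, b]
    val, _ = quad(
        lambda tau: expm(Q * tau)[a, i] * expm(Q * (T - tau))[j, b],
        0.0, T, epsabs=1e-13, epsrel=1e-11, limit=200,
    )
    return Q[i, j] * val / Pab


def series_expm(Q: np.ndarray, t: float, terms: int = 60) -> np.ndarray:
    """Taylor-series matrix exponential with scaling-and-squaring, as an
    oracle independent of both eigendecomposition and scipy."""
    norm = np.abs(Q * t).sum(axis=1).max()
    k = max(0, int(np.ceil(np.log2(max(norm, 1e-300)))) + 1)
    A = Q * (t / 2**k)
    s = Q.shape[0]
    out = np.eye(s)
    term = np.eye(s)
    for n in range(1, terms):
        term = term @ A / n
        out = out + term
    for _ in range(k):
        out = out @ out
    return out


def observed_character(history: sm.TrueHistory) -> sm.CharacterData:
    return history.tip_states()


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def er2_model() -> sm.RateModel:
    return sm.build_rate_matrix([1.0], "ER", 2)


@pytest.fixture(scope="session")
def yule16(er2_model):
    """A 16-tip pure-birth tree with a simulated binary character."""
    tree = sm.simulate_pure_birth_tree(16, 1.0, seed=7)
    history = sm.simulate_history(tree, er2_model, seed=3)
    return tree, history.tip_states(), history


@pytest.fixture(scope="session")
def cherry() -> sm.Tree:
    return sm.Tree(parent=[-1, 0, 0], edge_length=[0.0, 1.0, 1.0], labels=[None, "A", "B"])


def random_reversible_model(s: int, rng: np.random.Generator) -> sm.RateModel:
    k = s * (s - 1) // 2
    return sm.build_rate_matrix(rng.uniform(0.3, 2.0, size=k), "SYM", s)


def random_ard_model(s: int, rng: np.random.Generator) -> sm.RateModel:
    k = s * (s - 1)
    return sm.build_rate_matrix(rng.uniform(0.3, 2.0, size=k), "ARD", s)
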