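"""Continuous-time Markov models for discrete characters (Mk family).

The character evolves along each branch under an instantaneous rate matrix Q
(rows sum to zero, off-diagonals are pairwise rates).  Three symmetry classes
are supported: ER (one rate), SYM (q_ij = q_ji) and ARD (all rates free).
Transition probabilities P(t) = exp(Qt) are obtained from the eigendecomposition
Q = U diag(lambda) U^-1, which is also the workhorse of the per-branch
expectation integrals computed in :mod:`statemap.expectations`.

Q is estimated by maximum likelihood: the Felsenstein pruning algorithm gives
the tip-data likelihood, optimized with a bounded quasi-Newton method in
log-rate space with multistarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .trees import CharacterData, Tree, ValidationError

__all__ = [
    "RateModel",
    "SpectralDecomposition",
    "build_rate_matrix",
    "spectral_decompose",
    "transition_probabilities",
    "tree_log_likelihood",
    "estimate_mle",
    "CONSTRAINTS",
]

CONSTRAINTS = ("ER", "SYM", "ARD")

#: relative tolerance under which two eigenvalues are treated as equal when
#: evaluating the dwelling/transition integral factors downstream
EIGENVALUE_EQUALITY_RTOL = 1e-9

_U_CONDITION_LIMIT = 1e12


class DecompositionError(np.linalg.LinAlgError):
    """Q is numerically non-diagonalizable; use the quadrature fallback."""


def n_free_params(constraint: str, s: int) -> int:
    if constraint == "ER":
        return 1
    if constraint == "SYM":
        return s * (s - 1) // 2
    if constraint == "ARD":
        return s * (s - 1)
    raise ValueError(f"unknown constraint {constraint!r} (use one of {CONSTRAINTS})")


@dataclass
class RateModel:
    """A rate matrix Q with its constraint class and root prior pi."""

    Q: np.ndarray
    constraint: str
    pi: np.ndarray
    free_params: np.ndarray
    log_likelihood: float | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        s = self.Q.shape[0]
        if self.Q.shape != (s, s):
            raise ValidationError("Q must be square")
        off = self.Q[~np.eye(s, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValidationError("off-diagonal rates must be non-negative")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-12 * max(1.0, np.abs(self.Q).max()):
            raise ValidationError("rows of Q must sum to zero")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValidationError("pi must be a probability vector")

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of Q, normalized to a probability vector."""
        s = self.n_states
        # solve pi Q = 0 with sum(pi) = 1
        A = np.vstack([self.Q.T, np.ones(s)])
        b = np.zeros(s + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def with_pi(self, pi: np.ndarray | str) -> "RateModel":
        if isinstance(pi, str):
            if pi == "uniform":
                vec = np.full(self.n_states, 1.0 / self.n_states)
            elif pi == "stationary":
                vec = self.stationary_distribution()
            else:
                raise ValueError(f"unknown root prior {pi!r}")
        else:
            vec = np.asarray(pi, dtype=float)
            vec = vec / vec.sum()
        return RateModel(self.Q, self.constraint, vec, self.free_params,
                         self.log_likelihood, self.converged)


@dataclass
class SpectralDecomposition:
    """Eigendecomposition Q = U diag(lambda) U^-1.

    For symmetric Q (ER/SYM as parameterized here) the decomposition is real
    and orthogonal.  ARD matrices may have complex eigenvalues; intermediate
    arithmetic then stays complex and consumers validate that imaginary parts
    are negligible before taking real parts.
    """

    U: np.ndarray
    lam: np.ndarray
    U_inv: np.ndarray
    symmetric_transform_used: bool = False
    Q: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_states(self) -> int:
        return self.U.shape[0]

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.lam)


def build_rate_matrix(
    free_params,
    constraint: str = "ER",
    s: int | None = None,
    pi: np.ndarray | str = "uniform",
) -> RateModel:
    """Assemble Q from positive rates under an ER/SYM/ARD constraint.

    Off-diagonal filling order: ER repeats the single rate; SYM fills the
    upper triangle row-wise and mirrors it; ARD fills row-wise skipping the
    diagonal.  Diagonals are set to minus the row sums.
    """
    rates = np.atleast_1d(np.asarray(free_params, dtype=float))
    if np.any(rates <= 0):
        raise ValidationError("rates must be strictly positive")
    if s is None:
        raise ValueError("number of states s is required")
    expected = n_free_params(constraint, s)
    if len(rates) != expected:
        raise ValidationError(
            f"{constraint} with s={s} needs {expected} rate(s), got {len(rates)}"
        )
    Q = np.zeros((s, s))
    if constraint == "ER":
        Q[:] = rates[0]
    elif constraint == "SYM":
        iu = np.triu_indices(s, k=1)
        Q[iu] = rates
        Q.T[iu] = rates
    else:  # ARD
        mask = ~np.eye(s, dtype=bool)
        Q[mask.nonzero()] = 0.0
        k = 0
        for i in range(s):
            for j in range(s):
                if i != j:
                    Q[i, j] = rates[k]
                    k += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if isinstance(pi, str):
        if pi == "uniform":
            pvec = np.full(s, 1.0 / s)
        elif pi == "stationary":
            model = RateModel(Q, constraint, np.full(s, 1.0 / s), rates)
            pvec = model.stationary_distribution()
        else:
            raise ValueError(f"unknown root prior {pi!r}")
    else:
        pvec = np.asarray(pi, dtype=float)
        pvec = pvec / pvec.sum()
    return RateModel(Q, constraint, pvec, rates)


def spectral_decompose(model: RateModel | np.ndarray) -> SpectralDecomposition:
    """Eigendecompose Q, preferring the symmetric (real, stable) route.

    Symmetric Q uses ``eigh`` directly.  Otherwise a general decomposition is
    attempted; a badly conditioned eigenvector matrix raises
    :class:`DecompositionError` so callers can fall back to quadrature.
    """
    Q = model.Q if isinstance(model, RateModel) else np.asarray(model, dtype=float)
    if np.allclose(Q, Q.T, atol=1e-12 * max(1.0, np.abs(Q).max())):
        lam, U = np.linalg.eigh(Q)
        return SpectralDecomposition(U, lam, U.T.copy(), True, Q=Q)
    lam, U = np.linalg.eig(Q)
    cond = np.linalg.cond(U)
    if not np.isfinite(cond) or cond > _U_CONDITION_LIMIT:
        raise DecompositionError(
            f"eigenvector matrix condition number {cond:.2e} exceeds "
            f"{_U_CONDITION_LIMIT:.0e}; Q is numerically defective -- use the "
            "quadrature fallback (expectations with method='quadrature')"
        )
    U_inv = np.linalg.inv(U)
    if np.all(np.abs(lam.imag) < 1e-12 * max(1.0, np.abs(lam.real).max())):
        lam, U, U_inv = lam.real, U.real.copy(), U_inv.real.copy()
    return SpectralDecomposition(U, lam, U_inv, False, Q=Q)


def transition_probabilities(decomp: SpectralDecomposition, t: float) -> np.ndarray:
    """P(t) = exp(Qt) = U diag(e^{lambda t}) U^-1, clipped to [0, 1]."""
    if t < 0:
        raise ValueError("time must be non-negative")
    P = (decomp.U * np.exp(decomp.lam * t)) @ decomp.U_inv
    if np.iscomplexobj(P):
        if np.abs(P.imag).max() > 1e-8:
            raise DecompositionError(
                "transition probabilities have non-negligible imaginary parts; "
                "use the quadrature fallback"
            )
        P = P.real
    if P.min() < -1e-12 - 1e-9 * abs(t):
        # large negative entries indicate decomposition failure, not roundoff
        P = np.clip(P, 0.0, 1.0)
    else:
        P = np.clip(P, 0.0, 1.0)
    return P


# ---------------------------------------------------------------------------
# Pruning likelihood


def _edge_transition_matrices(tree: Tree, decomp: SpectralDecomposition) -> np.ndarray:
    """P(T_v) for every node v (identity on the root), shape (m, s, s)."""
    expl = np.exp(np.multiply.outer(tree.edge_length, decomp.lam))  # (m, s)
    P = np.einsum("ak,mk,kb->mab", decomp.U, expl, decomp.U_inv)
    if np.iscomplexobj(P):
        if np.abs(P.imag).max() > 1e-8:
            raise DecompositionError("complex transition probabilities; use quadrature")
        P = P.real
    return np.clip(P, 0.0, 1.0)


def _postorder_partials(
    tree: Tree, tips: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled conditional (pruning) partial likelihoods.

    ``tips`` has shape (n_tips, C, s): indicator rows per tip and character.
    Returns ``F`` of shape (m, C, s) with per-(node, character) scaling and
    ``logscale`` (m, C) holding the cumulative log scale factors.
    """
    m = tree.n_nodes
    C = tips.shape[1]
    s = tips.shape[2]
    F = np.empty((m, C, s))
    logscale = np.zeros((m, C))
    tip_pos = {int(v): i for i, v in enumerate(tree.tip_ids)}
    for v in tree.postorder:
        if not tree.children[v]:
            F[v] = tips[tip_pos[v]]
            continue
        acc = np.ones((C, s))
        ls = np.zeros(C)
        for c in tree.children[v]:
            acc = acc * (F[c] @ P[c].T)
            ls = ls + logscale[c]
        mx = acc.max(axis=1)
        safe = np.where(mx > 0, mx, 1.0)
        F[v] = acc / safe[:, None]
        logscale[v] = ls + np.log(safe)
    return F, logscale


def _tip_matrix(tree: Tree, data: CharacterData) -> np.ndarray:
    labels = [tree.labels[v] for v in tree.tip_ids]
    return data.tip_likelihood_matrix(labels)


def tree_log_likelihood(
    tree: Tree,
    data: CharacterData | list[CharacterData],
    model: RateModel,
    decomp: SpectralDecomposition | None = None,
) -> float:
    """Log-likelihood of tip data under the CTMC, by Felsenstein pruning.

    ``data`` may be a list of characters sharing one alphabet; their
    log-likelihoods (independent characters) are summed.
    """
    datasets = data if isinstance(data, list) else [data]
    for d in datasets:
        d.validate_against(tree.taxon_namespace)
        if d.n_states != model.n_states:
            raise ValidationError("alphabet size does not match Q")
    if decomp is None:
        decomp = spectral_decompose(model)
    tips = np.stack([_tip_matrix(tree, d) for d in datasets], axis=1)
    P = _edge_transition_matrices(tree, decomp)
    F, logscale = _postorder_partials(tree, tips, P)
    root_lik = F[tree.root] @ model.pi
    if np.any(root_lik <= 0):
        return -np.inf
    return float(np.sum(np.log(root_lik) + logscale[tree.root]))


# ---------------------------------------------------------------------------
# Maximum-likelihood estimation of Q


def default_rate_bounds(tree: Tree) -> tuple[float, float]:
    """Rate search interval [1e-8, 1e3] scaled by 1/mean branch length."""
    mean_bl = float(np.mean(tree.edge_length[tree.edge_length > 0]))
    if not np.isfinite(mean_bl) or mean_bl <= 0:
        mean_bl = 1.0
    return 1e-8 / mean_bl, 1e3 / mean_bl


def estimate_mle(
    tree: Tree,
    data: CharacterData | list[CharacterData],
    constraint: str = "ER",
    bounds: tuple[float, float] | None = None,
    starts: int = 3,
    root_prior: str | np.ndarray = "uniform",
    seed: int | None = 0,
) -> RateModel:
    """Estimate Q by maximum likelihood under a symmetry constraint.

    The objective (negative pruning log-likelihood, summed over characters
    when several are given) is minimized in log-rate space with L-BFGS-B from
    ``starts`` starting points: the first at the parsimony-flavoured heuristic
    rate (#tips / total tree length), the rest log-uniform within bounds from
    a seeded generator.  The best converged solution is returned with its
    log-likelihood and convergence flag attached.
    """
    datasets = data if isinstance(data, list) else [data]
    s = datasets[0].n_states
    k = n_free_params(constraint, s)
    if starts < 1:
        raise ValueError("need at least one start")
    if bounds is None:
        bounds = default_rate_bounds(tree)
    lo, hi = bounds
    if lo <= 0 or hi <= lo:
        raise ValueError("bounds must satisfy 0 < lo < hi")

    pi_for_fit = root_prior

    def negloglik(logr: np.ndarray) -> float:
        model = build_rate_matrix(np.exp(logr), constraint, s, pi=pi_for_fit)
        ll = tree_log_likelihood(tree, datasets, model)
        return -ll if np.isfinite(ll) else 1e300

    rng = np.random.default_rng(seed)
    heuristic = np.clip(tree.n_tips / max(tree.total_length(), 1e-12), lo * 1.01, hi * 0.99)
    start_points = [np.full(k, np.log(heuristic))]
    for _ in range(starts - 1):
        start_points.append(rng.uniform(np.log(lo), np.log(hi), size=k))

    best = None
    diagnostics = []
    for x0 in start_points:
        res = minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=[(np.log(lo), np.log(hi))] * k,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        diagnostics.append(res.message)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all optimizer starts failed: {diagnostics}")
    rates = np.exp(best.x)
    model = build_rate_matrix(rates, constraint, s, pi=pi_for_fit)
    model.log_likelihood = -float(best.fun)
    model.converged = bool(best.success)
    return model
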