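"""Analytic per-branch expectations for stochastic mapping.

Given tip data, a rate matrix Q and a branch of length T with endpoint states
(a at the parent, b at the child), the conditional expectations of (i) the
time the character dwells in state i on the branch, and (ii) the number of
i -> j transitions on the branch, have closed forms built from the
eigendecomposition Q = U diag(lambda) U^-1 and the integral factors

    J_kl = int_0^T e^{lambda_k tau} e^{lambda_l (T - tau)} d tau
         = (e^{lambda_k T} - e^{lambda_l T}) / (lambda_k - lambda_l),

with the limit T e^{lambda_k T} when the eigenvalues coincide.  Averaging the
endpoint-conditioned values over the joint posterior of branch endpoints
(from pruning partials and their preorder complements) yields the per-branch
expectations without any path simulation.

The per-branch kernel is O(s^3) (matrix products of size s), so a whole-tree
mapping costs O(n s^3) and a posterior sample of t trees O(t n s^3).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.linalg import expm

from .model import (
    EIGENVALUE_EQUALITY_RTOL,
    DecompositionError,
    RateModel,
    SpectralDecomposition,
    _edge_transition_matrices,
    _postorder_partials,
    _tip_matrix,
    estimate_mle,
    spectral_decompose,
    transition_probabilities,
)
from .trees import CharacterData, Tree, TreeSet, ValidationError, clade_index

__all__ = [
    "IntegralFactors",
    "BranchPosterior",
    "MappingResult",
    "integral_factor_matrix",
    "endpoint_conditioned_dwell",
    "endpoint_conditioned_transitions",
    "branch_posteriors",
    "map_tree",
    "map_treeset",
]


@dataclass
class IntegralFactors:
    """The symmetric matrix J of pairwise eigenvalue convolution integrals."""

    J: np.ndarray
    T: float
    lam: np.ndarray


@dataclass
class BranchPosterior:
    """Joint posterior W_ab of (parent state a, child state b) on one branch."""

    W: np.ndarray
    child: int

    @property
    def parent_marginal(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def child_marginal(self) -> np.ndarray:
        return self.W.sum(axis=0)


def integral_factor_matrix(lam: np.ndarray, T: float) -> IntegralFactors:
    """Compute J_kl for a branch of length T (zero matrix when T = 0).

    Eigenvalue pairs equal within ``EIGENVALUE_EQUALITY_RTOL`` use the
    analytic limit T e^{lambda T}; the result is symmetric by construction.
    """
    lam = np.asarray(lam)
    if T < 0:
        raise ValueError("branch length must be non-negative")
    s = len(lam)
    if T == 0:
        return IntegralFactors(np.zeros((s, s), dtype=lam.dtype), 0.0, lam)
    e = np.exp(lam * T)
    diff = lam[:, None] - lam[None, :]
    scale = np.maximum(1.0, np.maximum(np.abs(lam)[:, None], np.abs(lam)[None, :]))
    equal = np.abs(diff) < EIGENVALUE_EQUALITY_RTOL * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        J = (e[:, None] - e[None, :]) / diff
    limit = T * np.broadcast_to(e[:, None], (s, s))
    J = np.where(equal, limit, J)
    return IntegralFactors(J, float(T), lam)


def _endpoint_numerators(
    decomp: SpectralDecomposition, J: np.ndarray, i: int, j: int
) -> np.ndarray:
    """Matrix over endpoints (a, b) of sum_kl U_ak Uinv_ki U_jl Uinv_lb J_kl."""
    U, Ui = decomp.U, decomp.U_inv
    X = U * Ui[:, i][None, :]          # X_ak = U_ak Uinv_ki
    Y = U[j, :][:, None] * Ui          # Y_lb = U_jl Uinv_lb
    M = X @ J @ Y
    if np.iscomplexobj(M):
        if np.abs(M.imag).max() > 1e-8 * max(1.0, np.abs(M.real).max()):
            raise DecompositionError("complex endpoint numerators; use quadrature")
        M = M.real
    return M


def endpoint_conditioned_dwell(
    decomp: SpectralDecomposition, T: float, i: int
) -> np.ndarray:
    """D_i(a, b): expected time in state i on a branch of length T given the
    branch starts in a and ends in b.

    Endpoint pairs with P_ab(T) = 0 are impossible and reported as NaN; they
    carry zero posterior weight so the NaN never propagates into mappings.
    """
    J = integral_factor_matrix(decomp.lam, T).J
    num = _endpoint_numerators(decomp, J, i, i)
    P = transition_probabilities(decomp, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(P > 0, num / np.where(P > 0, P, 1.0), np.nan)
    return np.clip(D, 0.0, T, out=D, where=~np.isnan(D))


def endpoint_conditioned_transitions(
    decomp: SpectralDecomposition, Q: np.ndarray, T: float, i: int, j: int
) -> np.ndarray:
    """N_ij(a, b): expected number of i -> j jumps given branch endpoints."""
    if i == j:
        raise ValueError("transition counts are defined for i != j only")
    J = integral_factor_matrix(decomp.lam, T).J
    num = Q[i, j] * _endpoint_numerators(decomp, J, i, j)
    P = transition_probabilities(decomp, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        N = np.where(P > 0, num / np.where(P > 0, P, 1.0), np.nan)
    return np.clip(N, 0.0, None, out=N, where=~np.isnan(N))


# ---------------------------------------------------------------------------
# Tree-wide machinery


def _outside_partials(
    tree: Tree, model: RateModel, F: np.ndarray, P: np.ndarray
) -> np.ndarray:
    """Preorder "outside" vectors G per node (single character, shape (m, s)).

    G_v(a) is proportional to the joint probability of state a at node v and
    all tip data outside the subtree of v (root prior included).  Each vector
    is renormalized to sum 1; per-branch quantities only ever use ratios so
    the scale drops out.
    """
    m = tree.n_nodes
    s = model.n_states
    G = np.zeros((m, s))
    G[tree.root] = model.pi
    for v in tree.postorder[::-1]:  # preorder
        kids = tree.children[v]
        if not kids:
            continue
        # down messages m_c(a) = sum_b P_ab(T_c) F_c(b)
        msgs = [P[c] @ F[c] for c in kids]
        # leave-one-out products (avoids dividing by possible zeros)
        k = len(kids)
        prefix = [np.ones(s)]
        for t in range(k):
            prefix.append(prefix[-1] * msgs[t])
        suffix = [np.ones(s)] * (k + 1)
        for t in range(k - 1, -1, -1):
            suffix[t] = suffix[t + 1] * msgs[t]
        for t, c in enumerate(kids):
            excl = G[v] * prefix[t] * suffix[t + 1]
            g = excl @ P[c]  # G_c(b) = sum_a excl(a) P_ab
            tot = g.sum()
            G[c] = g / tot if tot > 0 else g
    return G


def branch_posteriors(
    tree: Tree,
    data: CharacterData,
    model: RateModel,
    decomp: SpectralDecomposition | None = None,
) -> dict[int, BranchPosterior]:
    """Joint endpoint posteriors W for every branch (keyed by child node).

    W_ab is proportional to G_parent-excluding-this-subtree(a) * P_ab(T) *
    F_child(b); each W is normalized to total mass 1.
    """
    data.validate_against(tree.taxon_namespace)
    if decomp is None:
        decomp = spectral_decompose(model)
    tips = _tip_matrix(tree, data)[:, None, :]
    P = _edge_transition_matrices(tree, decomp)
    F3, _ = _postorder_partials(tree, tips, P)
    F = F3[:, 0, :]
    G = _outside_partials(tree, model, F, P)
    out: dict[int, BranchPosterior] = {}
    # mirror _outside_partials to recover each branch's parent-side
    # exclusion vector (outside evidence with the sibling subtrees only)
    for v in tree.postorder[::-1]:
        kids = tree.children[v]
        if not kids:
            continue
        msgs = [P[c] @ F[c] for c in kids]
        k = len(kids)
        prefix = [np.ones(model.n_states)]
        for t in range(k):
            prefix.append(prefix[-1] * msgs[t])
        suffix = [np.ones(model.n_states)] * (k + 1)
        for t in range(k - 1, -1, -1):
            suffix[t] = suffix[t + 1] * msgs[t]
        for t, c in enumerate(kids):
            excl = G[v] * prefix[t] * suffix[t + 1]
            W = excl[:, None] * P[c] * F[c][None, :]
            tot = W.sum()
            if tot <= 0:
                raise ValidationError(
                    "tip data have zero likelihood under the model on this tree"
                )
            out[c] = BranchPosterior(W / tot, child=int(c))
    return out


@dataclass
class MappingResult:
    """Per-branch mapping expectations for one tree.

    Branch arrays are indexed in the order of ``branch_children`` (child-node
    ids).  ``dwell`` holds expected dwelling times in branch-length units;
    ``pairwise`` the expected i -> j transition counts; ``away`` is always
    derived as the row sums of ``pairwise``.
    """

    tree: Tree
    state_alphabet: tuple[str, ...]
    branch_children: np.ndarray
    branch_lengths: np.ndarray
    dwell: np.ndarray          # (n_branches, s)
    pairwise: np.ndarray       # (n_branches, s, s), zero diagonal
    model: RateModel
    clades: dict[int, frozenset[str]] = field(default_factory=dict)

    @property
    def away(self) -> np.ndarray:
        return self.pairwise.sum(axis=2)

    @property
    def dwell_fraction(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = self.dwell / self.branch_lengths[:, None]
        frac[self.branch_lengths == 0] = 0.0
        return frac

    @property
    def transition_rate(self) -> np.ndarray:
        """Expected transitions away per unit branch length."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.away / self.branch_lengths[:, None]
        r[self.branch_lengths == 0] = 0.0
        return r

    # tree-level totals -------------------------------------------------

    @property
    def total_dwell(self) -> np.ndarray:
        return self.dwell.sum(axis=0)

    @property
    def total_away(self) -> np.ndarray:
        return self.away.sum(axis=0)

    @property
    def total_pairwise(self) -> np.ndarray:
        return self.pairwise.sum(axis=0)

    def branch_index(self) -> dict[int, int]:
        return {int(c): i for i, c in enumerate(self.branch_children)}

    def to_dataframe(self) -> pd.DataFrame:
        s = len(self.state_alphabet)
        cols: dict[str, np.ndarray | list] = {
            "branch_clade": [
                "|".join(sorted(self.clades[int(c)])) for c in self.branch_children
            ],
            "branch_length": self.branch_lengths,
        }
        frac = self.dwell_fraction
        for k, st in enumerate(self.state_alphabet):
            cols[f"dwell_{st}"] = self.dwell[:, k]
        for k, st in enumerate(self.state_alphabet):
            cols[f"dwell_frac_{st}"] = frac[:, k]
        for k, st in enumerate(self.state_alphabet):
            cols[f"away_{st}"] = self.away[:, k]
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _branch_expectations_spectral(
    decomp: SpectralDecomposition,
    Q: np.ndarray,
    T: float,
    g: np.ndarray,
    f: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Dwell vector and pairwise matrix for one branch.

    ``g`` is the parent-side exclusion vector, ``f`` the child's pruning
    partial.  With alpha = g U and beta = U^-1 f, the endpoint-summed
    numerators for every (i, j) collapse to B = U^-T (alpha J beta^T) U^T,
    normalized by g' P(T) f.  This is the O(s^3) kernel.
    """
    s = Q.shape[0]
    if T == 0:
        return np.zeros(s), np.zeros((s, s))
    J = integral_factor_matrix(decomp.lam, T).J
    alpha = g @ decomp.U
    beta = decomp.U_inv @ f
    norm = float(np.real(alpha @ (np.exp(decomp.lam * T) * beta)))
    if norm <= 0:
        raise ValidationError("zero-probability branch configuration")
    K = alpha[:, None] * J * beta[None, :]
    B = decomp.U_inv.T @ K @ decomp.U.T
    if np.iscomplexobj(B):
        if np.abs(B.imag).max() > 1e-8 * max(1.0, np.abs(B.real).max()):
            raise DecompositionError("complex branch expectations; use quadrature")
        B = B.real
    B = B / norm
    dwell = np.clip(np.diag(B).copy(), 0.0, T)
    pairwise = Q * B
    np.fill_diagonal(pairwise, 0.0)
    return dwell, np.clip(pairwise, 0.0, None)


def _branch_expectations_quadrature(
    Q: np.ndarray, T: float, g: np.ndarray, f: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive-quadrature fallback for defective Q (no eigendecomposition).

    Integrates int_0^T g' e^{Q tau} E e^{Q (T-tau)} f d tau elementwise,
    where E selects the dwell state or the i->j jump.
    """
    s = Q.shape[0]
    if T == 0:
        return np.zeros(s), np.zeros((s, s))
    norm = float(g @ expm(Q * T) @ f)
    if norm <= 0:
        raise ValidationError("zero-probability branch configuration")

    def kernel(tau: float) -> np.ndarray:
        left = g @ expm(Q * tau)          # (s,)
        right = expm(Q * (T - tau)) @ f   # (s,)
        return np.outer(left, right)

    # integrate each entry of the outer product; modest s keeps this cheap
    B = np.empty((s, s))
    for i in range(s):
        for j in range(s):
            B[i, j] = quad(
                lambda tau, i=i, j=j: (g @ expm(Q * tau))[i]
                * (expm(Q * (T - tau)) @ f)[j],
                0.0,
                T,
                epsabs=1e-12,
                epsrel=1e-10,
                limit=200,
            )[0]
    B = B / norm
    dwell = np.clip(np.diag(B).copy(), 0.0, T)
    pairwise = Q * B
    np.fill_diagonal(pairwise, 0.0)
    return dwell, np.clip(pairwise, 0.0, None)


def map_tree(
    tree: Tree,
    data: CharacterData,
    model: RateModel,
    method: str = "spectral",
) -> MappingResult:
    """Analytic stochastic mapping of one character on one tree.

    For every branch, the expected dwelling time per state and the expected
    number of each pairwise transition, conditional on all tip data.  The
    reported away-from-state counts are the row sums of the pairwise matrix.
    ``method`` is ``spectral`` (default) or ``quadrature`` (slow fallback for
    numerically defective rate matrices).
    """
    data.validate_against(tree.taxon_namespace)
    if data.n_states != model.n_states:
        raise ValidationError("alphabet size does not match Q")
    if method not in ("spectral", "quadrature"):
        raise ValueError(f"unknown method {method!r}")
    decomp = spectral_decompose(model) if method == "spectral" else None
    if decomp is not None:
        P = _edge_transition_matrices(tree, decomp)
    else:
        P = np.stack([expm(model.Q * t) for t in tree.edge_length])
        P[tree.root] = np.eye(model.n_states)
    tips = _tip_matrix(tree, data)[:, None, :]
    F3, _ = _postorder_partials(tree, tips, P)
    F = F3[:, 0, :]
    G = _outside_partials(tree, model, F, P)

    s = model.n_states
    children = tree.branch_nodes()
    nb = len(children)
    dwell = np.zeros((nb, s))
    pairwise = np.zeros((nb, s, s))
    lengths = tree.edge_length[children]
    pos = {int(c): i for i, c in enumerate(children)}

    for v in tree.postorder[::-1]:
        kids = tree.children[v]
        if not kids:
            continue
        msgs = [P[c] @ F[c] for c in kids]
        k = len(kids)
        prefix = [np.ones(s)]
        for t in range(k):
            prefix.append(prefix[-1] * msgs[t])
        suffix = [np.ones(s)] * (k + 1)
        for t in range(k - 1, -1, -1):
            suffix[t] = suffix[t + 1] * msgs[t]
        for t, c in enumerate(kids):
            excl = G[v] * prefix[t] * suffix[t + 1]
            tot = excl.sum()
            if tot > 0:
                excl = excl / tot
            i = pos[int(c)]
            if decomp is not None:
                d, pw = _branch_expectations_spectral(
                    decomp, model.Q, float(tree.edge_length[c]), excl, F[c]
                )
            else:
                d, pw = _branch_expectations_quadrature(
                    model.Q, float(tree.edge_length[c]), excl, F[c]
                )
            dwell[i] = d
            pairwise[i] = pw

    return MappingResult(
        tree=tree,
        state_alphabet=data.state_alphabet,
        branch_children=children,
        branch_lengths=lengths,
        dwell=dwell,
        pairwise=pairwise,
        model=model,
        clades=clade_index(tree),
    )


def map_treeset(
    trees: TreeSet,
    data: CharacterData,
    q_mode: str = "per-tree",
    constraint: str = "ER",
    rate_matrix: RateModel | None = None,
    root_prior: str | np.ndarray = "uniform",
    starts: int = 3,
    seed: int | None = 0,
    on_error: str = "raise",
    method: str = "spectral",
) -> list[MappingResult]:
    """Map one character over every tree of a posterior sample.

    ``q_mode`` controls Q estimation granularity: ``per-tree`` fits Q on each
    tree independently; ``pooled`` fits once on the first tree and reuses it
    (the "empirical" convention); ``user`` takes ``rate_matrix`` as given and
    skips optimization.  Results preserve tree order.  ``on_error`` is
    ``raise`` (fail fast, default) or ``skip`` (drop the failing tree and
    substitute None, flagged to the caller).
    """
    data.validate_against(trees.taxon_namespace)
    if q_mode not in ("per-tree", "pooled", "user"):
        raise ValueError(f"unknown q_mode {q_mode!r}")
    if q_mode == "user":
        if rate_matrix is None:
            raise ValueError("q_mode='user' requires rate_matrix")
        shared: RateModel | None = rate_matrix
    elif q_mode == "pooled":
        shared = estimate_mle(
            trees[0], data, constraint, starts=starts, root_prior=root_prior, seed=seed
        )
    else:
        shared = None

    results: list[MappingResult | None] = []
    for idx, tree in enumerate(trees):
        try:
            model = shared
            if model is None:
                model = estimate_mle(
                    tree, data, constraint, starts=starts,
                    root_prior=root_prior, seed=seed,
                )
            results.append(map_tree(tree, data, model, method=method))
        except Exception as exc:
            if on_error == "raise":
                raise RuntimeError(f"mapping failed on tree {idx}: {exc}") from exc
            results.append(None)
    return results  # type: ignore[return-value]


def time_treeset_mapping(
    tree: Tree,
    data: CharacterData,
    model: RateModel,
    sizes: tuple[int, ...] = (2, 4, 8, 16),
    repeats: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Wall-clock time of mapping tree sets of increasing size (same tree
    repeated), for scaling diagnostics.  Returns (sizes, best-of-repeat
    seconds)."""
    times = []
    for t in sizes:
        ts = TreeSet([tree] * t)
        best = np.inf
        for _ in range(repeats):
            t0 = time.perf_counter()
            map_treeset(ts, data, q_mode="user", rate_matrix=model)
            best = min(best, time.perf_counter() - t0)
        times.append(best)
    return np.asarray(sizes, dtype=float), np.asarray(times)
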