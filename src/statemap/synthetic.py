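"""Simulators: pure-birth trees, character histories, and simulation-based
stochastic mapping used as the Monte-Carlo cross-check of the analytic maps.

All operations take an explicit seed and derive any sub-streams from it with
``numpy``'s SeedSequence spawning, so every fixture is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    RateModel,
    SpectralDecomposition,
    _edge_transition_matrices,
    _postorder_partials,
    _tip_matrix,
    spectral_decompose,
    transition_probabilities,
)
from .trees import CharacterData, Tree

__all__ = [
    "TrueHistory",
    "simulate_pure_birth_tree",
    "simulate_history",
    "sample_endpoint_conditioned_path",
    "simulate_mappings",
    "simulate_mapping_totals",
]

#: above this expected number of auxiliary (uniformized) events per branch the
#: dominating-process construction is abandoned in favour of rejection sampling
UNIFORMIZATION_EVENT_LIMIT = 1e4


@dataclass
class TrueHistory:
    """A realized character history on a tree: per-branch (state, duration)
    segments plus the realized dwelling times and transition counts they
    imply.  Segment durations sum exactly to the branch length and adjacent
    segments always differ in state; the first state on a branch equals the
    last state on its parent branch.
    """

    tree: Tree
    state_alphabet: tuple[str, ...]
    segments: dict[int, list[tuple[int, float]]]  # child node -> [(state, dur)]
    node_states: np.ndarray                       # state index per node
    seed: int | None = None

    @property
    def n_states(self) -> int:
        return len(self.state_alphabet)

    def branch_dwell(self) -> dict[int, np.ndarray]:
        out = {}
        for v, segs in self.segments.items():
            d = np.zeros(self.n_states)
            for st, dur in segs:
                d[st] += dur
            out[v] = d
        return out

    def branch_pairwise(self) -> dict[int, np.ndarray]:
        out = {}
        for v, segs in self.segments.items():
            c = np.zeros((self.n_states, self.n_states))
            for (a, _), (b, _) in zip(segs[:-1], segs[1:]):
                c[a, b] += 1
            out[v] = c
        return out

    @property
    def total_dwell(self) -> np.ndarray:
        d = np.zeros(self.n_states)
        for vec in self.branch_dwell().values():
            d += vec
        return d

    @property
    def total_pairwise(self) -> np.ndarray:
        c = np.zeros((self.n_states, self.n_states))
        for mat in self.branch_pairwise().values():
            c += mat
        return c

    @property
    def total_away(self) -> np.ndarray:
        return self.total_pairwise.sum(axis=1)

    @property
    def n_transitions(self) -> float:
        return float(self.total_pairwise.sum())

    def tip_states(self) -> CharacterData:
        assignments = {
            self.tree.labels[v]: {self.state_alphabet[self.node_states[v]]}
            for v in self.tree.tip_ids
        }
        return CharacterData.from_dict(assignments, alphabet=self.state_alphabet)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for v in self.tree.branch_nodes():
            for k, (st, dur) in enumerate(self.segments[int(v)]):
                rows.append((int(v), k, self.state_alphabet[st], dur))
        return pd.DataFrame(rows, columns=["branch_child", "segment", "state", "duration"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Pure-birth (Yule) trees


def simulate_pure_birth_tree(
    n: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    label_prefix: str = "t",
) -> Tree:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n`` tips.

    The process starts from the root split (two lineages).  While j lineages
    are extant the waiting time to the next speciation is Exp(j * birth_rate)
    and a uniformly chosen lineage splits.  After the n-th lineage appears a
    final Exp(n * birth_rate) interval separates the last split from the
    present, so the expected root-to-tip depth is sum_{j=2..n} 1/(j * rate).
    """
    if n < 2:
        raise ValueError("need at least two tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    parent = [-1, 0, 0]
    birth_time = [0.0, 0.0, 0.0]  # time the node (as a lineage) came into being
    active = [1, 2]
    t = 0.0
    while len(active) < n:
        j = len(active)
        t += rng.exponential(1.0 / (j * birth_rate))
        k = int(rng.integers(j))
        node = active[k]
        left = len(parent)
        parent.extend([node, node])
        birth_time.extend([t, t])
        active[k] = left
        active.append(left + 1)
    t += rng.exponential(1.0 / (n * birth_rate))

    edge_length = np.zeros(len(parent))
    is_tip = np.ones(len(parent), dtype=bool)
    for v, p in enumerate(parent):
        if p >= 0:
            is_tip[p] = False
    # a lineage v spans [birth_time[v], time of its own split or the present]
    end_time = np.full(len(parent), t)
    for v, p in enumerate(parent):
        if p >= 0:
            end_time[p] = birth_time[v]  # all children share the split time
    for v, p in enumerate(parent):
        if p >= 0:
            edge_length[v] = end_time[v] - birth_time[v]

    labels: list[str | None] = [None] * len(parent)
    counter = 1
    for v in range(len(parent)):
        if is_tip[v]:
            labels[v] = f"{label_prefix}{counter}"
            counter += 1
    return Tree(parent, edge_length, labels)


# ---------------------------------------------------------------------------
# Forward CTMC simulation


def _simulate_branch_path(
    Q: np.ndarray, T: float, start: int, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Exact forward Gillespie path on one branch: exponential holds, jump
    probabilities proportional to off-diagonal rates."""
    segs: list[tuple[int, float]] = []
    state = start
    remaining = T
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            segs.append((state, remaining))
            return segs
        hold = rng.exponential(1.0 / rate)
        if hold >= remaining:
            segs.append((state, remaining))
            return segs
        segs.append((state, hold))
        remaining -= hold
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = int(rng.choice(len(probs), p=probs))


def simulate_history(
    tree: Tree, model: RateModel, seed: int | None = None
) -> TrueHistory:
    """Simulate one full character history: root state from the root prior,
    then an exact CTMC realization down every branch."""
    rng = np.random.default_rng(seed)
    s = model.n_states
    node_states = np.full(tree.n_nodes, -1, dtype=int)
    node_states[tree.root] = int(rng.choice(s, p=model.pi))
    segments: dict[int, list[tuple[int, float]]] = {}
    for v in tree.postorder[::-1]:
        if v == tree.root:
            continue
        start = node_states[tree.parent[v]]
        segs = _simulate_branch_path(model.Q, float(tree.edge_length[v]), start, rng)
        segments[int(v)] = segs
        node_states[v] = segs[-1][0]
    alphabet = tuple(str(i) for i in range(s))
    return TrueHistory(tree, alphabet, segments, node_states, seed=seed)


# ---------------------------------------------------------------------------
# Endpoint-conditioned path sampling (uniformization)


def _uniformization_setup(Q: np.ndarray, T: float):
    """Dominating rate, uniformized jump chain R and its powers up to a
    truncation point covering the conditioned Poisson tail."""
    s = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        return 0.0, None, None
    R = np.eye(s) + Q / mu
    lam = mu * T
    nmax = int(max(16, np.ceil(lam + 12 * np.sqrt(lam) + 25)))
    Rpow = np.empty((nmax + 1, s, s))
    Rpow[0] = np.eye(s)
    for k in range(1, nmax + 1):
        Rpow[k] = Rpow[k - 1] @ R
    return mu, R, Rpow


def _sample_jump_counts(
    Rpow: np.ndarray, lam: float, a: int, b: int, P_ab: float,
    size: int, rng: np.random.Generator,
) -> np.ndarray:
    """Sample numbers of uniformized events: P(N=n | a,b) ~ Pois(n; lam) R^n_ab."""
    nmax = Rpow.shape[0] - 1
    n = np.arange(nmax + 1)
    logw = n * np.log(lam) - lam - np.cumsum(np.log(np.maximum(n, 1)))
    w = np.exp(logw) * Rpow[:, a, b]
    tot = w.sum()
    if tot <= 0:
        raise ValueError("impossible endpoint pair (P_ab(T) = 0)")
    w = w / tot
    return rng.choice(nmax + 1, size=size, p=w)


def _sample_uniformized_chains(
    R: np.ndarray, Rpow: np.ndarray, a: int, b: int, N: int,
    count: int, rng: np.random.Generator,
) -> np.ndarray:
    """States S_0..S_N of the uniformized chain given S_0=a, S_N=b, for
    ``count`` independent chains of the same length (vectorized forward
    filtering / direct sampling: P(S_t=c | S_{t-1}, S_N=b) ~ R[prev,c] R^{N-t}[c,b])."""
    s = R.shape[0]
    states = np.empty((count, N + 1), dtype=np.int64)
    states[:, 0] = a
    for t in range(1, N + 1):
        back = Rpow[N - t][:, b]                     # (s,)
        probs = R[states[:, t - 1], :] * back[None, :]
        probs = probs / probs.sum(axis=1, keepdims=True)
        u = rng.random(count)
        cdf = np.cumsum(probs, axis=1)
        states[:, t] = (u[:, None] > cdf).sum(axis=1).clip(0, s - 1)
    return states


def _chains_to_stats(
    states: np.ndarray, T: float, s: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Realized dwell (per state) and pairwise jump counts for uniformized
    chains; event times are uniform order statistics on (0, T)."""
    count, n1 = states.shape
    N = n1 - 1
    dwell = np.zeros((count, s))
    pairwise = np.zeros((count, s, s))
    if N == 0:
        dwell[np.arange(count), states[:, 0]] = T
        return dwell, pairwise
    times = np.sort(rng.random((count, N)), axis=1) * T
    bounds = np.concatenate(
        [np.zeros((count, 1)), times, np.full((count, 1), T)], axis=1
    )
    durations = np.diff(bounds, axis=1)  # (count, N+1)
    for i in range(s):
        dwell[:, i] = np.where(states == i, durations, 0.0).sum(axis=1)
    prev, nxt = states[:, :-1], states[:, 1:]
    real = prev != nxt
    np.add.at(pairwise, (np.repeat(np.arange(count), N)[real.ravel()],
                         prev.ravel()[real.ravel()], nxt.ravel()[real.ravel()]), 1.0)
    return dwell, pairwise


def _segments_from_chain(
    states: np.ndarray, times: np.ndarray, T: float
) -> list[tuple[int, float]]:
    """Collapse a uniformized chain (virtual jumps included) to segments."""
    segs: list[tuple[int, float]] = []
    bounds = np.concatenate([[0.0], times, [T]])
    for st, t0, t1 in zip(states, bounds[:-1], bounds[1:]):
        dur = float(t1 - t0)
        if segs and segs[-1][0] == int(st):
            segs[-1] = (segs[-1][0], segs[-1][1] + dur)
        else:
            segs.append((int(st), dur))
    # exact conservation of the branch length
    total = sum(d for _, d in segs)
    if segs and total != T:
        st, d = segs[-1]
        segs[-1] = (st, d + (T - total))
    return segs


def sample_endpoint_conditioned_path(
    Q: np.ndarray,
    T: float,
    a: int,
    b: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, float]]:
    """Draw one CTMC path on [0, T] conditioned to start in ``a`` and end in
    ``b``, by uniformization (dominating Poisson process + conditioned jump
    chain).  When the dominating process would generate more than
    ``UNIFORMIZATION_EVENT_LIMIT`` expected events, rejection sampling of
    forward paths is used instead."""
    Q = np.asarray(Q, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    s = Q.shape[0]
    if T == 0:
        if a != b:
            raise ValueError("zero-length branch cannot change state")
        return [(int(a), 0.0)]
    mu = float(np.max(-np.diag(Q)))
    if mu * T > UNIFORMIZATION_EVENT_LIMIT:
        return _rejection_path(Q, T, a, b, rng)
    decomp = spectral_decompose(Q)
    P = transition_probabilities(decomp, T)
    if P[a, b] <= 0:
        raise ValueError("impossible endpoint pair (P_ab(T) = 0)")
    mu, R, Rpow = _uniformization_setup(Q, T)
    if R is None:  # absorbing-everywhere matrix: no jumps possible
        if a != b:
            raise ValueError("impossible endpoint pair")
        return [(int(a), float(T))]
    N = int(_sample_jump_counts(Rpow, mu * T, a, b, P[a, b], 1, rng)[0])
    states = _sample_uniformized_chains(R, Rpow, a, b, N, 1, rng)[0]
    times = np.sort(rng.random(N)) * T
    return _segments_from_chain(states, times, T)


def _rejection_path(
    Q: np.ndarray, T: float, a: int, b: int, rng: np.random.Generator
) -> list[tuple[int, float]]:
    for _ in range(1_000_000):
        segs = _simulate_branch_path(Q, T, a, rng)
        if segs[-1][0] == b:
            return segs
    raise RuntimeError("rejection sampling failed to hit the required endpoint")


# ---------------------------------------------------------------------------
# Simulation-based stochastic mapping (the Monte-Carlo comparator)


def _sample_node_states(
    tree: Tree,
    data: CharacterData,
    model: RateModel,
    decomp: SpectralDecomposition,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint draws of all node states from their conditional posterior:
    root from pi * F_root, then each child given its parent from
    P_ab(T) * F_child(b).  Returns (states (n_reps, m), P per edge)."""
    tips = _tip_matrix(tree, data)[:, None, :]
    P = _edge_transition_matrices(tree, decomp)
    F3, _ = _postorder_partials(tree, tips, P)
    F = F3[:, 0, :]
    m = tree.n_nodes
    s = model.n_states
    states = np.empty((n_reps, m), dtype=np.int64)
    root_w = model.pi * F[tree.root]
    if root_w.sum() <= 0:
        raise ValueError("tip data have zero likelihood under the model")
    root_w = root_w / root_w.sum()
    states[:, tree.root] = rng.choice(s, size=n_reps, p=root_w)
    for v in tree.postorder[::-1]:
        if v == tree.root:
            continue
        M = P[v] * F[v][None, :]  # rows: parent state a -> weight over child b
        rowsum = M.sum(axis=1, keepdims=True)
        M = np.divide(M, rowsum, out=np.zeros_like(M), where=rowsum > 0)
        cdf = np.cumsum(M, axis=1)
        u = rng.random(n_reps)
        pa = states[:, tree.parent[v]]
        states[:, v] = (u[:, None] > cdf[pa]).sum(axis=1).clip(0, s - 1)
    return states, P


def simulate_mapping_totals(
    tree: Tree,
    data: CharacterData,
    model: RateModel,
    n_reps: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tree-level dwelling times and pairwise transition counts per replicate
    of simulation-based stochastic mapping.

    Returns ``(dwell, pairwise)`` with shapes (n_reps, s) and (n_reps, s, s).
    Identical in law to :func:`simulate_mappings` but vectorized across
    replicates (endpoint-conditioned branch paths are grouped by branch and
    endpoint pair), so large replicate counts are affordable.
    """
    rng = np.random.default_rng(seed)
    decomp = spectral_decompose(model)
    s = model.n_states
    states, P = _sample_node_states(tree, data, model, decomp, n_reps, rng)
    dwell = np.zeros((n_reps, s))
    pairwise = np.zeros((n_reps, s, s))
    for v in tree.branch_nodes():
        T = float(tree.edge_length[v])
        pa = states[:, tree.parent[v]]
        ch = states[:, v]
        if T == 0:
            continue
        mu, R, Rpow = _uniformization_setup(model.Q, T)
        if R is None:
            dwell[np.arange(n_reps), pa] += T
            continue
        for a in range(s):
            for b in range(s):
                idx = np.flatnonzero((pa == a) & (ch == b))
                if len(idx) == 0:
                    continue
                Ns = _sample_jump_counts(Rpow, mu * T, a, b, P[v][a, b], len(idx), rng)
                for N in np.unique(Ns):
                    sub = idx[Ns == N]
                    chains = _sample_uniformized_chains(
                        R, Rpow, a, b, int(N), len(sub), rng
                    )
                    d, pw = _chains_to_stats(chains, T, s, rng)
                    dwell[sub] += d
                    pairwise[sub] += pw
    return dwell, pairwise


def simulate_mappings(
    tree: Tree,
    data: CharacterData,
    model: RateModel,
    n_reps: int,
    seed: int | None = None,
) -> list[TrueHistory]:
    """Simulation-based stochastic mapping: joint node-state draws followed by
    endpoint-conditioned path filling on every branch.  Returns one full
    :class:`TrueHistory` per replicate, each consistent with the tip data."""
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    decomp = spectral_decompose(model)
    states, _ = _sample_node_states(tree, data, model, decomp, n_reps, rng)
    out: list[TrueHistory] = []
    for r in range(n_reps):
        segments: dict[int, list[tuple[int, float]]] = {}
        for v in tree.branch_nodes():
            a = int(states[r, tree.parent[v]])
            b = int(states[r, v])
            segments[int(v)] = sample_endpoint_conditioned_path(
                model.Q, float(tree.edge_length[v]), a, b, rng=rng
            )
        out.append(
            TrueHistory(tree, data.state_alphabet, segments, states[r].copy(), seed=seed)
        )
    return out
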