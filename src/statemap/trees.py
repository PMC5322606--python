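"""Trees, tree sets and tip-state tables.

Phylogenies are read through :mod:`dendropy` (Newick and NEXUS, including
TRANSLATE tables) and converted to a light array-backed :class:`Tree` used by
the numerical code.  Trees are taken as rooted exactly as written: clade
identity -- the set of tip labels descended from a branch -- is the key used
to match "the same branch" across the trees of a posterior sample, and that
key is root-dependent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "TreeSet",
    "CharacterData",
    "read_trees",
    "write_trees",
    "read_tip_states",
    "write_tip_states",
    "clade_index",
]


class TreeFormatError(ValueError):
    """Raised when a tree file cannot be parsed in the requested dialect."""


class ValidationError(ValueError):
    """Raised when inputs are structurally inconsistent (taxa, states...)."""


class Tree:
    """A rooted phylogeny with branch lengths, stored as flat node arrays.

    Nodes are integers ``0 .. m-1``.  ``parent[v]`` is the parent of ``v``
    (``-1`` for the root) and ``edge_length[v]`` is the length of the branch
    above ``v`` (0.0 for the root).  ``postorder`` lists every node after all
    of its children, so a single pass in that order implements the pruning
    recursion; the reverse is a valid preorder.

    Polytomies are allowed.  Edge lengths must be non-negative; a missing
    length in the input is treated as an error except on the root edge.
    """

    def __init__(
        self,
        parent: Sequence[int],
        edge_length: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.labels = list(labels)
        m = len(self.parent)
        if not (len(self.edge_length) == len(self.labels) == m):
            raise ValidationError("parent/edge_length/labels length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if np.any(self.edge_length < 0):
            raise ValidationError("negative edge length")
        self.children: list[list[int]] = [[] for _ in range(m)]
        for v in range(m):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        self.tip_ids = np.array(
            [v for v in range(m) if not self.children[v]], dtype=np.int64
        )
        tip_labels = [self.labels[v] for v in self.tip_ids]
        if any(lab is None for lab in tip_labels):
            raise ValidationError("every tip must carry a label")
        if len(set(tip_labels)) != len(tip_labels):
            raise ValidationError("tip labels must be unique within a tree")
        self.postorder = self._compute_postorder()

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        """Number of terminals (the quantity runtime scales linearly in)."""
        return len(self.tip_ids)

    @property
    def taxon_namespace(self) -> frozenset[str]:
        return frozenset(self.labels[v] for v in self.tip_ids)

    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()  # parents now follow all descendants
        return np.array(order, dtype=np.int64)

    def branch_nodes(self) -> np.ndarray:
        """Non-root nodes, i.e. one id per branch (the branch above the node)."""
        return np.array([v for v in self.postorder if v != self.root], dtype=np.int64)

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node, in branch-length units."""
        depth = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.edge_length[v]
        return depth

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = self.node_depths()[self.tip_ids]
        return bool(np.ptp(d) <= tol * max(1.0, float(np.max(d))))

    def total_length(self) -> float:
        return float(self.edge_length.sum())

    # -- conversion -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        for i, nd in enumerate(nodes):
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            el = nd.edge.length
            if el is None:
                if nd.parent_node is not None:
                    raise TreeFormatError(
                        f"missing branch length above node {nd.taxon or nd.label}"
                    )
                el = 0.0
            lengths.append(float(el))
            if nd.taxon is not None:
                labels.append(str(nd.taxon.label))
            else:
                labels.append(str(nd.label) if nd.label is not None else None)
        return cls(parent, lengths, labels)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                body = _quote_label(self.labels[v])
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if v == self.root:
                return body
            return f"{body}:{self.edge_length[v]:.12g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"<Tree n_tips={self.n_tips} n_nodes={self.n_nodes}>"


def _quote_label(label: str) -> str:
    if any(c in label for c in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


class TreeSet:
    """An ordered collection of trees over a shared taxon namespace.

    Typically a thinned posterior sample from a Bayesian analysis; order is
    preserved so results can be aligned with the source file.
    """

    def __init__(self, trees: Iterable[Tree]) -> None:
        self.trees = list(trees)
        if not self.trees:
            raise ValidationError("TreeSet requires at least one tree")
        ns = self.trees[0].taxon_namespace
        for i, t in enumerate(self.trees[1:], start=1):
            if t.taxon_namespace != ns:
                missing = sorted(ns ^ t.taxon_namespace)
                raise ValidationError(
                    f"tree {i} has a different taxon set (symmetric difference: "
                    f"{missing[:5]}{'...' if len(missing) > 5 else ''})"
                )
        self.taxon_namespace = ns

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Tree:
        return self.trees[i]


@dataclass
class CharacterData:
    """One discrete character scored for every taxon.

    ``state_alphabet`` is the ordered list of the character's *s* states.
    Each taxon maps to a non-empty subset of states: a singleton is an
    observed state, the full alphabet encodes missing data ("?"), and a
    proper subset encodes ambiguity ("a/b" in the TSV convention).
    """

    state_alphabet: tuple[str, ...]
    assignments: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state_alphabet = tuple(str(s) for s in self.state_alphabet)
        if len(self.state_alphabet) < 2:
            raise ValidationError("a character needs at least 2 states")
        if len(set(self.state_alphabet)) != len(self.state_alphabet):
            raise ValidationError("duplicate states in alphabet")
        alpha = set(self.state_alphabet)
        clean: dict[str, frozenset[str]] = {}
        for taxon, states in self.assignments.items():
            ss = frozenset(str(x) for x in states)
            if not ss:
                raise ValidationError(f"empty state set for taxon {taxon!r}")
            extra = ss - alpha
            if extra:
                raise ValidationError(
                    f"taxon {taxon!r} carries states {sorted(extra)} not in alphabet"
                )
            clean[str(taxon)] = ss
        self.assignments = clean

    @property
    def n_states(self) -> int:
        return len(self.state_alphabet)

    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.state_alphabet)}

    def validate_against(self, namespace: frozenset[str]) -> None:
        missing = sorted(namespace - set(self.assignments))
        if missing:
            raise ValidationError(f"taxa without state assignment: {missing}")

    def tip_likelihood_matrix(self, tip_labels: Sequence[str]) -> np.ndarray:
        """Indicator matrix (len(tip_labels) x s): 1 for each allowed state."""
        idx = self.state_index()
        out = np.zeros((len(tip_labels), self.n_states))
        for r, taxon in enumerate(tip_labels):
            try:
                states = self.assignments[taxon]
            except KeyError:
                raise ValidationError(f"no state assignment for taxon {taxon!r}")
            for s in states:
                out[r, idx[s]] = 1.0
        return out

    @classmethod
    def from_dict(
        cls,
        assignments: Mapping[str, str | Iterable[str]],
        alphabet: Sequence[str] | None = None,
    ) -> "CharacterData":
        parsed: dict[str, frozenset[str]] = {}
        observed: set[str] = set()
        for taxon, raw in assignments.items():
            if isinstance(raw, str):
                states = _parse_state_cell(raw)
            else:
                states = frozenset(str(x) for x in raw)
            parsed[str(taxon)] = states
        for states in parsed.values():
            if states:  # "?" placeholders resolved below
                observed |= states
        if alphabet is None:
            alphabet = sorted(observed)
        alphabet = tuple(str(s) for s in alphabet)
        full = frozenset(alphabet)
        final = {t: (ss if ss else full) for t, ss in parsed.items()}
        return cls(alphabet, final)


def _parse_state_cell(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if cell == "":
        raise ValidationError("empty state cell")
    if cell == "?":
        return frozenset()  # resolved to the full alphabet later
    return frozenset(part.strip() for part in cell.split("/"))


# ---------------------------------------------------------------------------
# I/O


def read_trees(path: str | Path, format: str = "auto") -> TreeSet:
    """Read one or more rooted trees from a Newick or NEXUS file.

    ``format`` is one of ``newick``, ``nexus`` or ``auto`` (sniffed from the
    leading ``#NEXUS`` token).  Input order is preserved.  NEXUS TRANSLATE
    tables are resolved to taxon names before any clade indexing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if format == "auto":
        format = "nexus" if text.lstrip()[:6].upper() == "#NEXUS" else "newick"
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        dtrees = dendropy.TreeList.get(
            data=text,
            schema=format,
            preserve_underscores=True,
            rooting="default-rooted",
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeFormatError(f"could not parse {path} as {format}: {exc}") from exc
    if not dtrees:
        raise TreeFormatError(f"no trees found in {path}")
    return TreeSet(Tree.from_dendropy(t) for t in dtrees)


def write_trees(trees: TreeSet | Tree | Sequence[Tree], path: str | Path) -> None:
    """Write trees as one Newick string per line."""
    if isinstance(trees, Tree):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


def read_tip_states(
    path: str | Path, alphabet: Sequence[str] | None = None
) -> CharacterData:
    """Read a tab-separated tip-state table with columns ``taxon`` and ``state``.

    ``?`` marks missing data (taxon may be in any state); ``a/b`` marks an
    ambiguity set.  Unless ``alphabet`` is supplied, the alphabet is the
    sorted set of states seen in unambiguous and ambiguous cells.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"taxon", "state"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"tip-state table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["taxon"].duplicated().any():
        dups = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
        raise ValidationError(f"duplicate taxa in tip-state table: {dups}")
    assignments = dict(zip(df["taxon"], df["state"]))
    for taxon, cell in assignments.items():
        if str(cell).strip() == "":
            raise ValidationError(f"empty state cell for taxon {taxon!r}")
    return CharacterData.from_dict(assignments, alphabet=alphabet)


def write_tip_states(data: CharacterData, path: str | Path) -> None:
    rows = []
    full = frozenset(data.state_alphabet)
    for taxon in sorted(data.assignments):
        states = data.assignments[taxon]
        if states == full:
            cell = "?"
        else:
            cell = "/".join(sorted(states))
        rows.append((taxon, cell))
    pd.DataFrame(rows, columns=["taxon", "state"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clade identity


def clade_index(tree: Tree) -> dict[int, frozenset[str]]:
    """Map every non-root node to the set of tip labels descended from it.

    This is the cross-tree branch-matching key: two branches in different
    rooted trees are "the same branch" when their descendant tip sets match.
    """
    clades: dict[int, frozenset[str]] = {}
    below: list[frozenset[str] | None] = [None] * tree.n_nodes
    for v in tree.postorder:
        if not tree.children[v]:
            below[v] = frozenset([tree.labels[v]])
        else:
            acc: set[str] = set()
            for c in tree.children[v]:
                acc |= below[c]  # type: ignore[arg-type]
            below[v] = frozenset(acc)
        if v != tree.root:
            clades[v] = below[v]  # type: ignore[assignment]
    return clades
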