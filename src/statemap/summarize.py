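"""Posterior summarization of mapping results onto a target topology.

Per-branch quantities (dwelling fractions or transition counts) computed on
every tree of a posterior sample are matched onto a user-supplied target tree
(e.g. a MAP or consensus tree) by clade identity, then discretized into 21
bins -- 5% tonality steps for dwelling fractions, an adaptive 0-to-max scale
for transition counts -- so each target branch carries a posterior
distribution over tones ready for painting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expectations import MappingResult
from .trees import Tree, TreeSet, ValidationError, clade_index

__all__ = ["TargetSummary", "bin_dwelling_fraction", "summarize_on_target", "N_BINS"]

N_BINS = 21  # tones 0%, 5%, ..., 100%


def bin_dwelling_fraction(fraction: float) -> int:
    """Nearest-multiple-of-5% bin: bin k covers ((k-0.5)*5%, (k+0.5)*5%].

    Bin 0 is [0, 2.5%], bin 20 is (97.5%, 100%] (the pure-red tone).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    x = fraction * 20.0
    k = int(np.ceil(x - 0.5 - 1e-9))
    return min(max(k, 0), N_BINS - 1)


def _bin_on_scale(value: float, vmax: float) -> int:
    """Same nearest-step rule on an adaptive [0, vmax] scale."""
    if vmax <= 0:
        return 0
    x = np.clip(value / vmax, 0.0, 1.0) * 20.0
    k = int(np.ceil(x - 0.5 - 1e-9))
    return min(max(k, 0), N_BINS - 1)


@dataclass
class TargetSummary:
    """Binned posterior distributions for every branch of the target tree.

    ``distributions[i]`` is the 21-bin mass for target branch i (indexed as
    in ``branch_children``); it sums to ``matched_fraction[i]`` -- the
    posterior probability that the branch's clade exists in a posterior tree
    -- unless ``renormalized`` is set, in which case partially matched
    branches are rescaled to total mass 1.  A branch found in no posterior
    tree is flagged gray.
    """

    target: Tree
    branch_children: np.ndarray
    clades: dict[int, frozenset[str]]
    matched_fraction: np.ndarray
    distributions: np.ndarray  # (n_branches, N_BINS)
    gray: np.ndarray           # bool
    quantity: str
    state: str
    scale_max: float           # 1.0 for dwelling fractions; max count otherwise
    renormalized: bool = False
    n_trees: int = 0

    def branch_row(self, child: int) -> int:
        return int(np.flatnonzero(self.branch_children == child)[0])

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "branch_clade": [
                "|".join(sorted(self.clades[int(c)])) for c in self.branch_children
            ],
            "matched_fraction": self.matched_fraction,
            "gray": self.gray.astype(int),
        }
        for k in range(N_BINS):
            cols[f"bin_{k}"] = self.distributions[:, k]
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def summarize_on_target(
    target: Tree,
    trees: TreeSet,
    mappings: list[MappingResult],
    state: str,
    quantity: str = "dwelling_fraction",
    renormalize: bool = False,
) -> TargetSummary:
    """Accumulate per-branch binned posteriors onto the target topology.

    For each target branch the same-clade branch is looked up in every
    posterior tree; each match contributes weight 1/t to the bin of its
    quantity (dwelling fraction of ``state``, or transitions away from
    ``state``).  Trees lacking the clade contribute to 1 - matched_fraction.
    Transition counts are binned on a shared scale from 0 to the maximum
    observed across all matched target branches.
    """
    if len(mappings) != len(trees):
        raise ValidationError("need exactly one mapping per posterior tree")
    if target.taxon_namespace != trees.taxon_namespace:
        raise ValidationError("target tree and posterior share no common taxon set")
    if quantity not in ("dwelling_fraction", "transitions"):
        raise ValueError(f"unknown quantity {quantity!r}")
    alphabet = mappings[0].state_alphabet
    if state not in alphabet:
        raise ValueError(f"state {state!r} not in alphabet {alphabet}")
    k_state = alphabet.index(state)

    target_children = target.branch_nodes()
    target_clades = clade_index(target)

    # per posterior tree: clade -> quantity value
    per_tree: list[dict[frozenset[str], float]] = []
    for mp in mappings:
        values = (
            mp.dwell_fraction[:, k_state]
            if quantity == "dwelling_fraction"
            else mp.away[:, k_state]
        )
        lookup = {
            mp.clades[int(c)]: float(values[i])
            for i, c in enumerate(mp.branch_children)
        }
        per_tree.append(lookup)

    t = len(trees)
    nb = len(target_children)
    matched_values: list[list[float]] = [[] for _ in range(nb)]
    for lookup in per_tree:
        for i, c in enumerate(target_children):
            clade = target_clades[int(c)]
            if clade in lookup:
                matched_values[i].append(lookup[clade])

    scale_max = 1.0
    if quantity == "transitions":
        allvals = [v for vals in matched_values for v in vals]
        scale_max = max(allvals) if allvals else 0.0

    dist = np.zeros((nb, N_BINS))
    matched = np.zeros(nb)
    for i, vals in enumerate(matched_values):
        for v in vals:
            if quantity == "dwelling_fraction":
                b = bin_dwelling_fraction(min(max(v, 0.0), 1.0))
            else:
                b = _bin_on_scale(v, scale_max)
            dist[i, b] += 1.0 / t
        matched[i] = len(vals) / t
    gray = matched == 0.0
    if renormalize:
        nz = matched > 0
        dist[nz] = dist[nz] / matched[nz, None]
    return TargetSummary(
        target=target,
        branch_children=target_children,
        clades=target_clades,
        matched_fraction=matched,
        distributions=dist,
        gray=gray,
        quantity=quantity,
        state=state,
        scale_max=scale_max,
        renormalized=renormalize,
        n_trees=t,
    )
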