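"""High-level Model/Results interface for analytic stochastic mapping.

:class:`StochasticMap` bundles a posterior tree sample with a tip-state
table and a model specification; :meth:`StochasticMap.fit` estimates the
rate matrix (unless supplied) and computes the per-branch expectations for
every tree, returning a :class:`StochasticMapResults` that carries the
estimates, diagnostics, a text summary, and the posterior summarization /
painting entry points.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import plotting, summarize as _summarize
from .expectations import MappingResult, map_treeset
from .model import RateModel
from .trees import CharacterData, Tree, TreeSet, read_tip_states, read_trees

__all__ = ["StochasticMap", "StochasticMapResults"]


class StochasticMap:
    """Analytic stochastic mapping of one discrete character on a tree set.

    Parameters
    ----------
    trees
        A :class:`TreeSet`, a single :class:`Tree`, or a sequence of trees.
    data
        The character's tip states (:class:`CharacterData`).
    constraint
        Rate-matrix symmetry class: ``ER``, ``SYM`` or ``ARD``.
    q_mode
        ``per-tree`` (fit Q on every tree), ``pooled`` (fit once on the
        first tree and reuse), or ``user`` (take ``rate_matrix`` as given).
    root_prior
        ``uniform`` (default), ``stationary``, or an explicit vector.
    """

    def __init__(
        self,
        trees: TreeSet | Tree | Sequence[Tree],
        data: CharacterData,
        constraint: str = "ER",
        q_mode: str = "per-tree",
        rate_matrix: RateModel | None = None,
        root_prior="uniform",
    ) -> None:
        if isinstance(trees, Tree):
            trees = TreeSet([trees])
        elif not isinstance(trees, TreeSet):
            trees = TreeSet(trees)
        data.validate_against(trees.taxon_namespace)
        self.trees = trees
        self.data = data
        self.constraint = constraint
        self.q_mode = "user" if rate_matrix is not None else q_mode
        self.rate_matrix = rate_matrix
        self.root_prior = root_prior

    @classmethod
    def from_files(
        cls,
        trees_path: str | Path,
        states_path: str | Path,
        tree_format: str = "auto",
        **kwargs,
    ) -> "StochasticMap":
        """Build the model from a Newick/NEXUS tree file and a tip-state TSV."""
        trees = read_trees(trees_path, format=tree_format)
        data = read_tip_states(states_path)
        return cls(trees, data, **kwargs)

    def fit(
        self, starts: int = 3, seed: int | None = 0, method: str = "spectral"
    ) -> "StochasticMapResults":
        """Estimate Q (per ``q_mode``) and map every tree analytically."""
        mappings = map_treeset(
            self.trees,
            self.data,
            q_mode=self.q_mode,
            constraint=self.constraint,
            rate_matrix=self.rate_matrix,
            root_prior=self.root_prior,
            starts=starts,
            seed=seed,
            method=method,
        )
        return StochasticMapResults(self, mappings)


class StochasticMapResults:
    """Fitted mapping results over a posterior tree sample."""

    def __init__(self, model: StochasticMap, mappings: list[MappingResult]) -> None:
        self.model = model
        self.mappings = mappings
        self.state_alphabet = model.data.state_alphabet

    @property
    def rate_models(self) -> list[RateModel]:
        return [m.model for m in self.mappings]

    @property
    def total_dwell(self) -> np.ndarray:
        """Tree-level dwelling-time totals, one row per tree."""
        return np.stack([m.total_dwell for m in self.mappings])

    @property
    def total_away(self) -> np.ndarray:
        return np.stack([m.total_away for m in self.mappings])

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for i, m in enumerate(self.mappings):
            df = m.to_dataframe()
            df.insert(0, "tree", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def tree_summary_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.mappings):
            row: dict[str, object] = {
                "tree": i,
                "tree_length": float(m.branch_lengths.sum()),
                "logL": m.model.log_likelihood,
            }
            for k, st in enumerate(self.state_alphabet):
                row[f"total_dwell_{st}"] = m.total_dwell[k]
            for k, st in enumerate(self.state_alphabet):
                row[f"total_away_{st}"] = m.total_away[k]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report: model, rates, and tree-level expectations."""
        md = self.model
        lines = [
            "Analytic stochastic mapping results",
            "===================================",
            f"trees: {len(md.trees)}   taxa: {md.trees[0].n_tips}   "
            f"states: {len(self.state_alphabet)} {self.state_alphabet}",
            f"constraint: {md.constraint}   q_mode: {md.q_mode}   "
            f"root prior: {md.root_prior}",
            "",
        ]
        rates = np.stack([rm.free_params for rm in self.rate_models])
        if len(self.mappings) > 1:
            lines.append(
                "rates (mean over trees): "
                + np.array2string(rates.mean(axis=0), precision=5)
            )
        else:
            lines.append("rates: " + np.array2string(rates[0], precision=5))
        lls = [rm.log_likelihood for rm in self.rate_models]
        if all(ll is not None for ll in lls):
            lines.append(f"log-likelihood (mean): {np.mean(lls):.5f}")
        lines.append("")
        lines.append("tree-level expectations (mean over trees):")
        td = self.total_dwell.mean(axis=0)
        ta = self.total_away.mean(axis=0)
        tl = np.mean([m.branch_lengths.sum() for m in self.mappings])
        for k, st in enumerate(self.state_alphabet):
            lines.append(
                f"  state {st}: dwell {td[k]:.5f} ({100 * td[k] / tl:.2f}% of "
                f"tree length), transitions away {ta[k]:.5f}"
            )
        return "\n".join(lines)

    def summarize_on(
        self,
        target: Tree,
        state: str,
        quantity: str = "dwelling_fraction",
        renormalize: bool = False,
    ) -> _summarize.TargetSummary:
        return _summarize.summarize_on_target(
            target, self.model.trees, self.mappings, state, quantity, renormalize
        )

    def plot_on(
        self,
        target: Tree,
        state: str,
        out: str | Path,
        quantity: str = "dwelling_fraction",
        spec: plotting.PaintSpec | None = None,
        format: str | None = None,
        renormalize: bool = False,
    ) -> Path:
        summ = self.summarize_on(target, state, quantity, renormalize)
        return plotting.paint_tree(target, summ, spec=spec, out=out, format=format)
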