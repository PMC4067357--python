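"""Model-style front end: fit a maximum-parsimony tree estimate to a matrix.

`MaximumParsimony` wraps the heuristic search the way regression packages
wrap an estimator: the model is constructed from data, ``fit()`` runs the
optimisation and returns a results object carrying the estimates (the best
trees and their length), fit diagnostics (homoplasy indices) and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import dendropy

from .matrix import CharacterMatrix, Constraint
from .parsimony import FitIndices, fit_indices
from .report import ensemble_statistics_table, fit_indices_table
from .search import (
    SearchConfig,
    SearchResult,
    heuristic_search,
    majority_rule_consensus,
    strict_consensus,
)


class MaximumParsimony:
    """Maximum-parsimony tree estimation for a discrete character matrix."""

    def __init__(self, matrix: CharacterMatrix, multistate_mode: str = "uncertainty"):
        self.matrix = matrix
        self.multistate_mode = multistate_mode

    @classmethod
    def from_file(cls, source, multistate_mode: str = "uncertainty") -> "MaximumParsimony":
        from .io import read_matrix

        return cls(read_matrix(source), multistate_mode=multistate_mode)

    def fit(
        self,
        n_random_additions: int = 10,
        swap: str = "TBR",
        max_trees: int = 100,
        rearrangement_limit: Optional[int] = None,
        seed: int = 0,
        constraint: Optional[Constraint] = None,
    ) -> "ParsimonyResults":
        config = SearchConfig(
            n_random_additions=n_random_additions,
            swap=swap,
            max_trees=max_trees,
            rearrangement_limit=rearrangement_limit,
            seed=seed,
            constraint=constraint,
            multistate_mode=self.multistate_mode,
        )
        result = heuristic_search(self.matrix, config)
        return ParsimonyResults(model=self, config=config, search=result)


@dataclass
class ParsimonyResults:
    model: MaximumParsimony
    config: SearchConfig
    search: SearchResult

    @property
    def best_length(self) -> int:
        return self.search.best_length

    @property
    def trees(self) -> List[dendropy.Tree]:
        return self.search.trees

    @property
    def n_trees(self) -> int:
        return len(self.search.trees)

    def indices(self, tree_index: int = 0) -> FitIndices:
        return fit_indices(
            self.trees[tree_index], self.model.matrix, self.model.multistate_mode
        )

    def strict_consensus(self) -> dendropy.Tree:
        return strict_consensus(self.trees)

    def majority_rule_consensus(self, threshold: float = 0.5) -> dendropy.Tree:
        return majority_rule_consensus(self.trees, threshold=threshold)

    def summary(self) -> str:
        fi = self.indices()
        s = self.model.matrix.summary()

        def fmt(x):
            return "undefined" if x is None else f"{x:.3f}"

        lines = [
            "Maximum parsimony fit",
            "=" * 52,
            f"Taxa:                         {s.n_taxa}",
            f"Characters:                   {s.n_characters}",
            f"Missing cells:                {s.missing_fraction:.1%}",
            f"Polymorphic cells:            {s.polymorphic_fraction:.1%}",
            f"Multistate mode:              {self.model.multistate_mode}",
            f"Random-addition replicates:   {self.config.n_random_additions}",
            f"Branch swapping:              {self.config.swap}",
            f"Rearrangements evaluated:     {self.search.n_evaluated}",
            "-" * 52,
            f"Best tree length:             {self.best_length}",
            f"Most parsimonious trees:      {self.n_trees}"
            + (" (capped)" if self.n_trees >= self.config.max_trees else ""),
            f"Ensemble consistency index:   {fmt(fi.ensemble_ci)}",
            f"Ensemble retention index:     {fmt(fi.ensemble_ri)}",
            f"Rescaled consistency index:   {fmt(fi.ensemble_rc)}",
            "=" * 52,
        ]
        return "\n".join(lines)

    def indices_table(self):
        labels = [c.label for c in self.model.matrix.characters]
        return fit_indices_table(self.indices(), labels)

    def statistics_table(self):
        return ensemble_statistics_table(self.model.matrix, self.indices())
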