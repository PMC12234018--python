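"""End-to-end convenience: raw cohort -> tree, forest importance, scheme comparison."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import compare as compare_mod
from .preprocess import build_analysis_table, indicator_matrix
from .schemes import assignment_table
from .semforest import Forest, ForestConfig, ImportanceTable, grow_forest, variable_importance
from .semtree import SemTree, TreeConfig, grow_tree

TREE_COVARIATES = ("overvaluation", "comp_freq_28d")


@dataclass
class PipelineResult:
    analysis: pd.DataFrame
    exclusion_log: list
    tree: SemTree
    importance: ImportanceTable | None
    comparisons: list
    summary: compare_mod.VarianceSummary


def run_pipeline(
    records: pd.DataFrame,
    tree_config: TreeConfig | None = None,
    forest_config: ForestConfig | None = None,
    run_forest: bool = True,
) -> PipelineResult:
    """Preprocess, grow the severity tree (and forest), compare all schemes."""
    analysis, log = build_analysis_table(records)
    y = indicator_matrix(analysis)
    covariates = analysis[list(TREE_COVARIATES)].reset_index(drop=True)

    tree_config = tree_config or TreeConfig()
    tree = grow_tree(y, covariates, tree_config)

    importance = None
    if run_forest:
        forest_config = forest_config or ForestConfig(tree_config=tree_config)
        forest = grow_forest(y, covariates, forest_config)
        importance = variable_importance(forest, y, covariates)

    assignments = assignment_table(analysis, tree=tree)
    results, summary = compare_mod.compare_schemes(analysis, assignments)
    return PipelineResult(
        analysis=analysis,
        exclusion_log=log,
        tree=tree,
        importance=importance,
        comparisons=results,
        summary=summary,
    )
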