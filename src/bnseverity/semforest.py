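"""SEM Forests: bootstrapped SEM Trees with permutation variable importance.

Each tree is grown on a bootstrap resample (size n, with replacement) with a
random subset of covariates offered at every node (one per split by default,
so the two covariates compete head-to-head across the forest).  Importance of
a covariate is measured on each tree's out-of-bag (OOB) rows in -2
log-likelihood units: permute the covariate's OOB values, re-route the rows
through the tree, and take the increase of the summed leaf-model -2LL over
the intact routing.  Covariates never used by a tree contribute exactly 0
for that tree.  The table reports the summed contribution across trees
(equivalently, the mean per tree scaled by the number of trees).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .semcore import rowwise_loglik
from .semtree import SemTree, TreeConfig, grow_tree

__all__ = ["ForestConfig", "Forest", "ImportanceTable", "grow_forest", "variable_importance"]


@dataclass
class ForestConfig:
    n_trees: int = 100
    resample: bool = True  # bootstrap with out-of-bag tracking
    vars_per_split: int = 1
    tree_config: TreeConfig = field(default_factory=TreeConfig)
    n_permutations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if self.vars_per_split < 1:
            raise ValueError("vars_per_split must be at least 1")


@dataclass
class Forest:
    trees: list[SemTree]
    oob_indices: list[np.ndarray]
    covariates: tuple[str, ...]
    config: ForestConfig

    def to_json_dict(self) -> dict:
        return {
            "config": {
                "n_trees": self.config.n_trees,
                "resample": self.config.resample,
                "vars_per_split": self.config.vars_per_split,
                "seed": self.config.seed,
            },
            "covariates": list(self.covariates),
            "trees": [t.root.to_dict() for t in self.trees],
            "oob": [idx.tolist() for idx in self.oob_indices],
        }


@dataclass
class ImportanceTable:
    importance: dict[str, float]  # summed -2LL units across the forest
    per_tree: dict[str, list[float]]
    rank: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "covariate": list(self.importance),
                "importance": list(self.importance.values()),
                "rank": [self.rank[c] for c in self.importance],
            }
        )
        return df.sort_values("rank").reset_index(drop=True)


def grow_forest(
    y: np.ndarray, covariates: pd.DataFrame, config: ForestConfig | None = None
) -> Forest:
    """Grow ``n_trees`` bootstrap SEM Trees; deterministic given ``config.seed``."""
    config = config or ForestConfig()
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    names = tuple(covariates.columns)
    if config.vars_per_split > len(names):
        raise ValueError("covariate set smaller than vars_per_split")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_trees)
    trees: list[SemTree] = []
    oob: list[np.ndarray] = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        if config.resample:
            boot = np.sort(rng.integers(0, n, size=n))
            out = np.setdiff1d(np.arange(n), np.unique(boot))
        else:
            boot = np.arange(n)
            out = np.arange(n)  # degenerate forest: evaluate in-sample
            rng = None  # grow_tree then seeds from tree_config, matching standalone use
        vps = config.vars_per_split if config.vars_per_split < len(names) else None
        tree = grow_tree(
            y[boot],
            covariates.iloc[boot].reset_index(drop=True),
            config.tree_config,
            vars_per_split=vps,
            rng=rng,
        )
        trees.append(tree)
        oob.append(out)
    return Forest(trees=trees, oob_indices=oob, covariates=names, config=config)


def _tree_covariates(tree: SemTree) -> set[str]:
    return {s.covariate for s in tree.splits()}


def _routed_neg2ll(
    tree: SemTree, y: np.ndarray, cov: pd.DataFrame, idx: np.ndarray
) -> float:
    """Summed -2LL of rows ``idx`` under the leaf models they route to.

    Rows that cannot be routed (missing covariate on their path) are skipped.
    """
    total = 0.0

    def rec(node, rows: np.ndarray) -> None:
        nonlocal total
        if rows.size == 0:
            return
        if node.is_leaf:
            total += -2.0 * float(rowwise_loglik(node.fit, y[rows]).sum())
            return
        x = cov[node.split.covariate].to_numpy(dtype=float)[rows]
        ok = ~np.isnan(x)
        rec(node.left, rows[ok & (x < node.split.value)])
        rec(node.right, rows[ok & (x >= node.split.value)])

    rec(tree.root, np.asarray(idx))
    return total


def variable_importance(forest: Forest, y: np.ndarray, covariates: pd.DataFrame) -> ImportanceTable:
    """OOB permutation importance in -2LL units.

    For each tree and covariate used by that tree: permute the covariate's
    values among the tree's OOB rows (seeded), re-route, and record
    (permuted -2LL) - (intact -2LL), averaged over ``n_permutations``.
    """
    y = np.asarray(y, dtype=float)
    config = forest.config
    per_tree: dict[str, list[float]] = {c: [] for c in forest.covariates}
    perm_seeds = np.random.SeedSequence(config.seed + 1).spawn(config.n_trees)

    for tree, oob, ss in zip(forest.trees, forest.oob_indices, perm_seeds):
        rng = np.random.default_rng(ss)
        used = _tree_covariates(tree)
        intact = _routed_neg2ll(tree, y, covariates, oob) if used else 0.0
        for name in forest.covariates:
            if name not in used:
                per_tree[name].append(0.0)
                continue
            deltas = []
            for _ in range(config.n_permutations):
                perm = rng.permutation(len(oob))
                shuffled = covariates.iloc[oob].reset_index(drop=True).copy()
                shuffled[name] = shuffled[name].to_numpy()[perm]
                permuted = _routed_neg2ll(tree, y[oob], shuffled, np.arange(len(oob)))
                deltas.append(permuted - intact)
            per_tree[name].append(float(np.mean(deltas)))

    totals = {c: float(np.sum(v)) for c, v in per_tree.items()}
    order = sorted(totals, key=lambda c: -totals[c])
    rank = {c: i + 1 for i, c in enumerate(order)}
    return ImportanceTable(importance=totals, per_tree=per_tree, rank=rank)
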