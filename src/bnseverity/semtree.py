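"""SEM Trees: model-based recursive partitioning of the latent severity model.

At each node the one-factor FIML model is refit; a candidate split of the
node's rows on a covariate threshold is scored by the likelihood-ratio
improvement

    LR = 2 * (LL_left + LL_right - LL_parent)

where all three log-likelihoods come from models refit on the respective row
sets (7 free parameters each, so the LR is referred to a chi-square with 7
degrees of freedom).

Split selection uses the *fair* criterion: the node's rows are randomly
halved; every candidate threshold of every offered covariate is scored on the
first half and each covariate keeps its best threshold; those selected
thresholds are then scored on the held-out second half, and the covariate
with the largest held-out improvement wins.  Retention is decided on the
held-out (confirmation) p-value — which is exactly chi-square distributed
under the null because the threshold was chosen on independent data — with a
Bonferroni correction over the covariates offered at the node.  The reported
LR and p of a retained split are then recomputed on the full node sample.

Split convention: left child takes covariate < threshold; the threshold
itself routes right (so "group >= 5.75"-style definitions read directly off
the tree).  Rows missing the split covariate are used for the node's model
fit but not for split evaluation, and are unassigned at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .semcore import FactorFit, FitConfig, N_FREE_PARAMS, fit_factor_model

__all__ = [
    "TreeConfig",
    "SplitCandidate",
    "TreeNode",
    "SemTree",
    "evaluate_split",
    "fair_split_search",
    "grow_tree",
    "assign_leaf",
]


@dataclass
class TreeConfig:
    min_node_size: int = 30
    alpha: float = 0.05
    bonferroni: bool = True
    max_depth: int | None = None
    max_candidates: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_node_size < N_FREE_PARAMS + 1:
            raise ValueError(
                f"min_node_size must be at least {N_FREE_PARAMS + 1} (free parameters + 1)"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SplitCandidate:
    covariate: str
    value: float
    lr: float  # -2*delta-LL improvement on the full node sample
    p_value: float
    n_left: int
    n_right: int
    feasible: bool = True
    lr_select: float = float("nan")  # best LR on the selection half
    lr_confirm: float = float("nan")  # LR of that threshold on the held-out half
    p_confirm: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TreeNode:
    fit: FactorFit
    n: int
    depth: int
    split: SplitCandidate | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    leaf_label: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "depth": self.depth, "fit": self.fit.to_dict() if self.fit else None}
        if self.is_leaf:
            d["label"] = self.leaf_label
        else:
            d["split"] = self.split.to_dict()
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        fit = FactorFit.from_dict(d["fit"]) if d.get("fit") else None
        node = cls(fit=fit, n=d.get("n", 0), depth=d.get("depth", 0))
        if "split" in d:
            node.split = SplitCandidate(**d["split"])
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        else:
            node.leaf_label = d.get("label")
        return node


@dataclass
class SemTree:
    root: TreeNode
    covariates: tuple[str, ...]
    config: TreeConfig | None = None

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def splits(self) -> list[SplitCandidate]:
        out = []

        def rec(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node.split)
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    def assign(self, covariate_values) -> int | None:
        return assign_leaf(self, covariate_values)

    def assign_frame(self, df: pd.DataFrame) -> pd.Series:
        """Leaf label per row; <NA> where a path covariate is missing."""
        labels = [assign_leaf(self, row) for _, row in df.iterrows()]
        return pd.Series(labels, index=df.index, dtype="Int64")

    def to_json(self, path=None) -> str:
        payload = {
            "covariates": list(self.covariates),
            "config": asdict(self.config) if self.config else None,
            "root": self.root.to_dict(),
        }
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SemTree":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        cfg = TreeConfig(**payload["config"]) if payload.get("config") else None
        tree = cls(
            root=TreeNode.from_dict(payload["root"]),
            covariates=tuple(payload["covariates"]),
            config=cfg,
        )
        _label_leaves(tree.root)
        return tree

    def render(self) -> str:
        """Plain-text rendering of the tree, one node per line."""
        lines: list[str] = []

        def rec(node: TreeNode, prefix: str) -> None:
            if node.is_leaf:
                lines.append(f"{prefix}leaf group {node.leaf_label} (n={node.n})")
            else:
                s = node.split
                lines.append(
                    f"{prefix}{s.covariate} < {s.value:g} "
                    f"(LR={s.lr:.1f}, p={s.p_value:.3g}, n={node.n})"
                )
                rec(node.left, prefix + "  ")
                rec(node.right, prefix + "  ")

        rec(self.root, "")
        return "\n".join(lines)


def _fit(y: np.ndarray, idx: np.ndarray, start: np.ndarray | None = None) -> FactorFit:
    cfg = FitConfig(start=start) if start is not None else FitConfig()
    return fit_factor_model(y[idx], cfg)


def _start_from(fit: FactorFit) -> np.ndarray:
    return np.concatenate(
        ([fit.loading], fit.means, np.log(fit.residual_variances))
    )


def evaluate_split(
    y: np.ndarray,
    cov_values: np.ndarray,
    value: float,
    covariate: str = "",
    min_node_size: int = 30,
    parent_fit: FactorFit | None = None,
    parent_loglik: float | None = None,
    idx: np.ndarray | None = None,
) -> SplitCandidate:
    """Score one (covariate, threshold) candidate on the rows ``idx``.

    ``y`` is the full (n, 3) indicator matrix; ``cov_values`` the aligned
    covariate column.  Rows with a missing covariate value are dropped.  The
    parent log-likelihood is refit on the same (nonmissing) row set unless
    supplied.  Children smaller than ``min_node_size`` mark the candidate
    infeasible.
    """
    if idx is None:
        idx = np.arange(y.shape[0])
    x = cov_values[idx]
    ok = ~np.isnan(x)
    idx = idx[ok]
    x = x[ok]
    left = idx[x < value]
    right = idx[x >= value]
    if len(left) < min_node_size or len(right) < min_node_size:
        return SplitCandidate(
            covariate, float(value), 0.0, 1.0, len(left), len(right), feasible=False
        )
    start = _start_from(parent_fit) if parent_fit is not None else None
    if parent_loglik is None:
        parent_loglik = _fit(y, idx, start).loglik
    ll_left = _fit(y, left, start).loglik
    ll_right = _fit(y, right, start).loglik
    lr = max(0.0, 2.0 * (ll_left + ll_right - parent_loglik))
    p = float(stats.chi2.sf(lr, df=N_FREE_PARAMS))
    return SplitCandidate(covariate, float(value), lr, p, len(left), len(right))


def _candidate_thresholds(x: np.ndarray, max_candidates: int) -> np.ndarray:
    """Midpoints between consecutive unique values; quantile grid when the
    covariate is near-continuous (more than ``max_candidates`` candidates)."""
    vals = np.unique(x[~np.isnan(x)])
    if len(vals) < 2:
        return np.empty(0)
    mids = (vals[:-1] + vals[1:]) / 2.0
    if len(mids) <= max_candidates:
        return mids
    qs = np.quantile(x[~np.isnan(x)], np.linspace(0, 1, max_candidates + 2)[1:-1])
    qs = np.unique(qs)
    return qs[(qs > vals[0]) & (qs <= vals[-1])]


def fair_split_search(
    y: np.ndarray,
    covariates: pd.DataFrame,
    config: TreeConfig,
    rng: np.random.Generator,
    idx: np.ndarray | None = None,
    offered: list[str] | None = None,
    node_fit: FactorFit | None = None,
) -> SplitCandidate | None:
    """Fair-criterion split selection at one node; None when nothing survives.

    Steps: (1) randomly halve the node rows; (2) per covariate, pick the
    threshold with the best LR on half 1; (3) score each covariate's chosen
    threshold on half 2; (4) keep the covariate with the largest half-2 LR,
    requiring its half-2 p to clear alpha (Bonferroni over offered
    covariates); (5) recompute LR/p and child sizes on the full node sample.
    """
    if idx is None:
        idx = np.arange(y.shape[0])
    if offered is None:
        offered = list(covariates.columns)
    if len(idx) < 2 * config.min_node_size:
        return None

    perm = rng.permutation(len(idx))
    half = len(idx) // 2
    idx1 = np.sort(idx[perm[:half]])
    idx2 = np.sort(idx[perm[half:]])

    if node_fit is None:
        node_fit = _fit(y, idx)
    start = _start_from(node_fit)

    # selection on half 1
    chosen: dict[str, SplitCandidate] = {}
    for name in offered:
        col = covariates[name].to_numpy(dtype=float)
        x1 = col[idx1]
        thresholds = _candidate_thresholds(x1, config.max_candidates)
        if thresholds.size == 0:
            continue
        ll_parent1 = None
        best: SplitCandidate | None = None
        for t in thresholds:
            if ll_parent1 is None:
                ok = ~np.isnan(x1)
                if ok.sum() < 2 * config.min_node_size:
                    break
                ll_parent1 = _fit(y, idx1[ok], start).loglik
            cand = evaluate_split(
                y, col, t, name, config.min_node_size, node_fit, ll_parent1, idx1
            )
            if cand.feasible and (best is None or cand.lr > best.lr):
                best = cand
        if best is not None:
            chosen[name] = best

    if not chosen:
        return None

    # confirmation on half 2
    n_tests = max(1, len(offered))
    level = config.alpha / n_tests if config.bonferroni else config.alpha
    winner: tuple[str, SplitCandidate, SplitCandidate] | None = None
    for name, sel in chosen.items():
        col = covariates[name].to_numpy(dtype=float)
        conf = evaluate_split(
            y, col, sel.value, name, config.min_node_size, node_fit, None, idx2
        )
        if not conf.feasible:
            continue
        if winner is None or conf.lr > winner[2].lr:
            winner = (name, sel, conf)

    if winner is None:
        return None
    name, sel, conf = winner
    if conf.p_value > level:
        return None

    # final statistics on the full node sample
    col = covariates[name].to_numpy(dtype=float)
    full = evaluate_split(y, col, sel.value, name, config.min_node_size, node_fit, None, idx)
    if not full.feasible:
        return None
    full.lr_select = sel.lr
    full.lr_confirm = conf.lr
    full.p_confirm = conf.p_value
    return full


def _label_leaves(root: TreeNode) -> None:
    label = 0

    def rec(node: TreeNode) -> None:
        nonlocal label
        if node.is_leaf:
            label += 1
            node.leaf_label = label
        else:
            rec(node.left)
            rec(node.right)

    rec(root)


def grow_tree(
    y: np.ndarray,
    covariates: pd.DataFrame,
    config: TreeConfig | None = None,
    vars_per_split: int | None = None,
    rng: np.random.Generator | None = None,
) -> SemTree:
    """Grow a fair-criterion SEM Tree; deterministic given ``config.seed``.

    ``vars_per_split`` (used by the forest) draws that many candidate
    covariates uniformly at random at each node; by default all covariates
    are offered everywhere.  Leaf labels 1..K are assigned in left-to-right
    (ascending threshold) order.
    """
    config = config or TreeConfig()
    y = np.asarray(y, dtype=float)
    if y.shape[0] == 0:
        raise ValueError("empty input")
    if y.shape[0] != len(covariates):
        raise ValueError("indicators and covariates must align")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = list(covariates.columns)
    if vars_per_split is not None and vars_per_split > len(names):
        raise ValueError("vars_per_split exceeds the number of covariates")

    node_log: list[dict] = []

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        fit = _fit(y, idx)
        node = TreeNode(fit=fit, n=len(idx), depth=depth)
        if config.max_depth is not None and depth >= config.max_depth:
            return node
        if len(idx) < 2 * config.min_node_size:
            return node
        if vars_per_split is not None and vars_per_split < len(names):
            offered = sorted(rng.choice(names, size=vars_per_split, replace=False).tolist())
        else:
            offered = names
        node_log.append({"depth": depth, "n": len(idx), "offered": list(offered)})
        split = fair_split_search(y, covariates, config, rng, idx, offered, fit)
        if split is None:
            return node
        col = covariates[split.covariate].to_numpy(dtype=float)[idx]
        ok = ~np.isnan(col)
        node.split = split
        node.left = build(idx[ok & (col < split.value)], depth + 1)
        node.right = build(idx[ok & (col >= split.value)], depth + 1)
        return node

    root = build(np.arange(y.shape[0]), 0)
    _label_leaves(root)
    tree = SemTree(root=root, covariates=tuple(names), config=config)
    tree.node_log = node_log
    return tree


def assign_leaf(tree: SemTree, covariate_values) -> int | None:
    """Route one record to its leaf label; None when a path covariate is missing.

    ``covariate_values`` is a mapping (dict / Series / namedtuple row) from
    covariate name to value.  Left means strictly less than the threshold.
    """
    node = tree.root
    while not node.is_leaf:
        v = covariate_values[node.split.covariate]
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            return None
        node = node.left if float(v) < node.split.value else node.right
    return node.leaf_label
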