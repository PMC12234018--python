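"""Fair-criterion SEM Tree: split scoring, recovery, determinism, conventions."""

import numpy as np
import pandas as pd
import pytest

from bnseverity.semtree import (
    SemTree,
    TreeConfig,
    assign_leaf,
    evaluate_split,
    fair_split_search,
    grow_tree,
)
from conftest import make_analysis, null_spec, one_cut_spec


def _null_node(seed, n=800, miss=0.35):
    rng = np.random.default_rng(seed)
    y = 0.8 * rng.standard_normal((n, 1)) + 0.6 * rng.standard_normal((n, 3))
    y[rng.random(n) < miss, 2] = np.nan
    x = rng.random(n)
    return y, x


def test_null_split_lr_centered_at_df():
    """Children drawn from one distribution: LR at a fixed threshold is
    central chi-square with df = 7 (mean 7)."""
    lrs = [evaluate_split(*_null_node(s), value=0.5, covariate="x").lr for s in range(50)]
    assert 5.5 <= np.mean(lrs) <= 8.5
    assert min(lrs) >= 0.0


def test_separated_groups_give_large_lr(one_cut_cohort):
    _, y, cov, _ = one_cut_cohort
    c = evaluate_split(
        y[:500], cov["overvaluation"].to_numpy()[:500], 3.75, "overvaluation"
    )
    assert c.lr > 50 and c.p_value < 1e-6
    assert c.n_left + c.n_right == 500


def test_small_child_marked_infeasible():
    y, x = _null_node(0, n=200)
    c = evaluate_split(y, x, float(np.sort(x)[5]), "x", min_node_size=30)
    assert not c.feasible


def test_fair_search_recovers_planted_cutpoint(one_cut_cohort):
    _, y, cov, _ = one_cut_cohort
    hits = 0
    for seed in range(10):
        s = fair_split_search(y, cov, TreeConfig(seed=seed), np.random.default_rng(seed))
        if s is not None and s.covariate == "overvaluation" and abs(s.value - 4.0) <= 0.25:
            hits += 1
    assert hits >= 9


def test_fair_search_null_rarely_splits():
    hits = 0
    for seed in range(40):
        _, y, cov, _ = make_analysis(null_spec(500, seed=500 + seed))
        s = fair_split_search(y, cov, TreeConfig(seed=seed), np.random.default_rng(seed))
        hits += s is not None
    assert hits / 40 <= 0.125  # nominal 5% plus Monte Carlo slack


def test_single_candidate_seed_invariant(one_cut_cohort):
    """A binary covariate admits one threshold; the returned full-sample
    statistics cannot depend on the halving seed."""
    _, y, cov, _ = one_cut_cohort
    binary = pd.DataFrame({"flag": (cov["overvaluation"] >= 4.0).astype(float)})
    results = [
        fair_split_search(y, binary, TreeConfig(seed=s), np.random.default_rng(s))
        for s in range(5)
    ]
    assert all(r is not None for r in results)
    assert len({(r.covariate, r.value, round(r.lr, 6)) for r in results}) == 1


def test_tree_recovers_two_cutpoints():
    from bnseverity import CohortSpec

    _, y, cov, _ = make_analysis(
        CohortSpec(
            n_patients=2000, true_cutpoints=(3.0, 5.0),
            group_latent_means=(-1.2, 0.0, 1.2), comp_latent_slope=0.0, seed=77,
        )
    )
    tree = grow_tree(y, cov, TreeConfig(seed=4))
    values = sorted(s.value for s in tree.splits())
    assert tree.n_leaves == 3
    assert abs(values[0] - 3.0) <= 0.25 and abs(values[1] - 5.0) <= 0.25


def test_degenerate_covariates_single_leaf():
    rng = np.random.default_rng(1)
    y = rng.standard_normal((300, 3))
    cov = pd.DataFrame({"c": np.ones(300)})
    tree = grow_tree(y, cov, TreeConfig(seed=0))
    assert tree.n_leaves == 1


def test_empty_input_errors():
    with pytest.raises(ValueError, match="empty"):
        grow_tree(np.empty((0, 3)), pd.DataFrame({"c": []}))


def test_leaf_logliks_dominate_root(one_cut_cohort):
    _, y, cov, _ = one_cut_cohort
    tree = grow_tree(y, cov, TreeConfig(seed=2))
    assert tree.n_leaves >= 2
    leaf_sum = sum(l.fit.loglik for l in tree.leaves())
    assert leaf_sum > tree.root.fit.loglik


def test_leaf_counts_partition_rows(one_cut_cohort):
    _, y, cov, _ = one_cut_cohort
    tree = grow_tree(y, cov, TreeConfig(seed=2))
    assert sum(l.n for l in tree.leaves()) == len(cov)
    labels = tree.assign_frame(cov)
    assert labels.notna().all()
    assert sorted(labels.unique()) == [l.leaf_label for l in sorted(tree.leaves(), key=lambda l: l.leaf_label)]


def test_tree_serialization_roundtrip_and_determinism(one_cut_cohort):
    _, y, cov, _ = one_cut_cohort
    t1 = grow_tree(y, cov, TreeConfig(seed=6))
    t2 = grow_tree(y, cov, TreeConfig(seed=6))
    assert t1.to_json() == t2.to_json()
    back = SemTree.from_json(t1.to_json())
    assert back.assign({"overvaluation": 2.0, "comp_freq_28d": 10.0}) == t1.assign(
        {"overvaluation": 2.0, "comp_freq_28d": 10.0}
    )


def test_nested_threshold_consistency(one_cut_cohort):
    """Thresholds on the same covariate along any root-to-leaf path define
    nested intervals."""
    _, y, cov, _ = make_analysis(
        one_cut_spec(1500, seed=55, cut=3.0)
    )
    tree = grow_tree(y, cov, TreeConfig(seed=3))

    def walk(node, bounds):
        if node.is_leaf:
            return
        lo, hi = bounds.get(node.split.covariate, (-np.inf, np.inf))
        assert lo < node.split.value < hi
        left = dict(bounds)
        left[node.split.covariate] = (lo, node.split.value)
        right = dict(bounds)
        right[node.split.covariate] = (node.split.value, hi)
        walk(node.left, left)
        walk(node.right, right)

    walk(tree.root, {})


def test_assignment_conventions():
    tree = SemTree.from_json(
        '{"covariates": ["overvaluation"], "config": null, "root": {"n": 0, "depth": 0, "fit": null,'
        ' "split": {"covariate": "overvaluation", "value": 4.0, "lr": 0, "p_value": 0,'
        ' "n_left": 0, "n_right": 0, "feasible": true},'
        ' "left": {"n": 0, "depth": 1, "fit": null, "label": 1},'
        ' "right": {"n": 0, "depth": 1, "fit": null, "label": 2}}}'
    )
    assert assign_leaf(tree, {"overvaluation": 3.5}) == 1
    assert assign_leaf(tree, {"overvaluation": 4.0}) == 2  # boundary routes right
    assert assign_leaf(tree, {"overvaluation": np.nan}) is None
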