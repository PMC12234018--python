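"""Competing severity classification schemes for bulimia nervosa.

Four schemes label each patient with an ordered severity group:

* ``semtree`` — leaves of a (grown or published) SEM Tree, ordered by
  ascending covariate interval;
* ``dsm5`` — DSM-5 compensatory-frequency bands per week: mild 1-3,
  moderate 4-7, severe 8-13, extreme >= 14; below 1/week is flagged
  subthreshold rather than forced into "mild";
* ``clinical_overvaluation`` — clinically significant shape/weight
  overvaluation: either item rated >= 4;
* ``purging_count`` — single versus multiple purging methods (a method
  counts when its 28-day frequency is >= 1); patients with no purging are
  labelled ``none`` and excluded from this scheme's comparisons.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .semtree import SemTree, assign_leaf

__all__ = [
    "DSM5_BANDS",
    "assign_dsm5",
    "assign_clinical_overvaluation",
    "assign_purging_count",
    "assign_semtree",
    "published_severity_tree",
    "assignment_table",
]

#: weekly-episode bands, half-open [lo, hi)
DSM5_BANDS = (
    ("subthreshold", 0.0, 1.0),
    ("mild", 1.0, 4.0),
    ("moderate", 4.0, 8.0),
    ("severe", 8.0, 14.0),
    ("extreme", 14.0, float("inf")),
)

DSM5_ORDER = ("subthreshold", "mild", "moderate", "severe", "extreme")

#: methods counted as purging; the questionnaire merges laxative and
#: diuretic use into one frequency item, exercise is not purging
DEFAULT_PURGING_ITEMS = ("vomiting_28d", "laxative_diuretic_28d")


def assign_dsm5(comp_freq_weekly) -> str | None:
    """DSM-5 severity band for a weekly compensatory-behaviour frequency."""
    if pd.isna(comp_freq_weekly):
        return None
    f = float(comp_freq_weekly)
    if f < 0:
        raise ValueError(f"weekly frequency must be nonnegative, got {f}")
    for name, lo, hi in DSM5_BANDS:
        if lo <= f < hi:
            return name
    raise AssertionError("unreachable")


def assign_clinical_overvaluation(item_weight, item_shape) -> str | None:
    """``clinical`` iff either overvaluation item is rated >= 4."""
    if pd.isna(item_weight) or pd.isna(item_shape):
        return None
    return "clinical" if max(float(item_weight), float(item_shape)) >= 4.0 else "nonclinical"


def assign_purging_count(freqs, purging_items: tuple[str, ...] = DEFAULT_PURGING_ITEMS) -> str:
    """``single`` / ``multiple`` / ``none`` by the number of purging methods used."""
    k = 0
    for item in purging_items:
        v = freqs[item] if not isinstance(freqs, (list, tuple)) else freqs[purging_items.index(item)]
        if not pd.isna(v) and float(v) >= 1:
            k += 1
    if k == 0:
        return "none"
    return "single" if k == 1 else "multiple"


def assign_semtree(tree: SemTree, covariate_values) -> int | None:
    """Ordered leaf label (1..K) under the tree scheme; None if unroutable."""
    return assign_leaf(tree, covariate_values)


def published_severity_tree() -> SemTree:
    """The five-group overvaluation tree with the published cutpoints
    (1.25 / 3.75 / 4.75 / 5.75), shipped as a JSON fixture."""
    text = resources.files("bnseverity").joinpath("data/published_tree.json").read_text()
    return SemTree.from_json(text)


def assignment_table(
    analysis: pd.DataFrame,
    tree: SemTree | None = None,
    purging_items: tuple[str, ...] = DEFAULT_PURGING_ITEMS,
) -> pd.DataFrame:
    """id x scheme label table for all four schemes.

    ``analysis`` is the preprocessed table (needs overvaluation items,
    ``comp_freq_weekly``, purging frequency items, and the tree covariates).
    """
    if tree is None:
        tree = published_severity_tree()
    out = pd.DataFrame({"id": analysis["id"]})
    out["semtree"] = pd.array(
        [assign_semtree(tree, row) for row in analysis.to_dict("records")], dtype="Int64"
    )
    out["dsm5"] = [assign_dsm5(v) for v in analysis["comp_freq_weekly"]]
    out["clinical_overvaluation"] = [
        assign_clinical_overvaluation(w, s)
        for w, s in zip(analysis["ov_weight"], analysis["ov_shape"])
    ]
    out["purging_count"] = [
        assign_purging_count(row, purging_items) for row in analysis.to_dict("records")
    ]
    return out
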