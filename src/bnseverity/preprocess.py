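"""Composites, exclusion rules, and within-stratum standardization.

The analysis table carries, per patient:

* ``overvaluation`` — mean of the two shape/weight overvaluation items
  (0-6 scale, 0.5 increments); missing if either item is missing;
* ``comp_freq_28d`` — 28-day compensatory behaviour frequency, each item
  capped at 56 (two episodes per day) before summing; ``comp_freq_weekly``
  is the 28-day total divided by 4;
* ``z_cognitive``, ``z_depression``, ``z_anxiety`` — indicators z-scored
  within level-of-care stratum (different instruments are used per setting,
  so standardization must be stratified).

Exclusion rules, applied as pure predicates: (1) missing data on all
measures; (2) cognitive global score < 0.5 in residential or PHP care
(invalid-responding indicator at those levels of care); (3) no core
diagnostic indicators of bulimia nervosa, or all such items missing.
"""

from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import COMP_ITEMS

__all__ = [
    "ExclusionConfig",
    "overvaluation_composite",
    "compensatory_frequency",
    "edeq_global_without_overvaluation",
    "apply_exclusions",
    "zscore_within_stratum",
    "build_analysis_table",
]

logger = logging.getLogger(__name__)

ITEM_CAP = 56  # two episodes per day over 28 days


def _check_item(x, name: str) -> float:
    if x is None or (isinstance(x, numbers.Real) and np.isnan(x)):
        return np.nan
    x = float(x)
    if not (0.0 <= x <= 6.0):
        raise ValueError(f"{name}: item score {x} outside the 0-6 scale")
    return x


def overvaluation_composite(item_weight, item_shape) -> float:
    """Mean of the two overvaluation items; NaN if either is missing.

    Accepts scalars or aligned arrays.
    """
    if np.ndim(item_weight) > 0 or np.ndim(item_shape) > 0:
        w = np.asarray(item_weight, dtype=float)
        s = np.asarray(item_shape, dtype=float)
        for arr, name in ((w, "item_weight"), (s, "item_shape")):
            bad = (arr < 0) | (arr > 6)
            if np.any(bad[~np.isnan(arr)]):
                raise ValueError(f"{name}: item scores outside the 0-6 scale")
        return (w + s) / 2.0
    w = _check_item(item_weight, "item_weight")
    s = _check_item(item_shape, "item_shape")
    return (w + s) / 2.0


def compensatory_frequency(counts, cap: int = ITEM_CAP) -> float:
    """Sum of per-behaviour 28-day counts, each capped at ``cap``."""
    arr = np.asarray(counts, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("compensatory counts must be nonnegative")
    return float(np.minimum(arr, cap).sum())


def edeq_global_without_overvaluation(
    items,
    overvaluation_indices: tuple[int, ...] = (21, 20),
    min_present_fraction: float = 0.8,
) -> float:
    """Cognitive global score: mean of the retained (non-overvaluation) items.

    Returns NaN (with a logged reason) when fewer than
    ``min_present_fraction`` of the retained items are present.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 1:
        raise ValueError("items must be a 1-D array of item scores")
    present = ~np.isnan(arr)
    if np.any((arr[present] < 0) | (arr[present] > 6)):
        raise ValueError("item scores outside the 0-6 scale")
    keep = np.ones(arr.shape[0], dtype=bool)
    keep[list(overvaluation_indices)] = False
    retained = arr[keep]
    n_present = int(np.sum(~np.isnan(retained)))
    if n_present < min_present_fraction * retained.size:
        logger.info(
            "global score not computed: %d/%d retained items present",
            n_present,
            retained.size,
        )
        return float("nan")
    return float(np.nanmean(retained))


@dataclass
class ExclusionConfig:
    """Which columns the exclusion predicates look at (kept configurable
    because the core-diagnostic-indicator item set is instrument-specific)."""

    measure_columns: tuple[str, ...] = (
        "ov_weight",
        "ov_shape",
        "cognitive_ed",
        "depression_total",
        "anxiety_total",
        "binge_28d",
        *COMP_ITEMS,
    )
    global_column: str = "cognitive_ed"
    global_floor: float = 0.5
    floor_strata: tuple[str, ...] = ("residential", "php")
    core_indicator_columns: tuple[str, ...] = ("binge_28d", *COMP_ITEMS)


def apply_exclusions(
    records: pd.DataFrame, config: ExclusionConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the three exclusion rules; returns (retained, exclusion log).

    Each rule is a pure predicate on the raw record, so the retained set does
    not depend on evaluation order; a record failing several rules is logged
    under the first.
    """
    config = config or ExclusionConfig()
    measures = [c for c in config.measure_columns if c in records.columns]
    core = [c for c in config.core_indicator_columns if c in records.columns]

    all_missing = records[measures].isna().all(axis=1)
    low_global = (
        (records[config.global_column] < config.global_floor)
        & records["stratum"].isin(config.floor_strata)
    ).fillna(False)
    core_vals = records[core]
    no_core = (core_vals.isna() | (core_vals == 0)).all(axis=1)

    log: list[dict] = []
    for rule, mask, reason in (
        (1, all_missing, "missing data on all measures"),
        (2, low_global & ~all_missing, "global score below floor in residential/PHP care"),
        (3, no_core & ~all_missing & ~low_global, "no core diagnostic indicators"),
    ):
        for rid in records.loc[mask, "id"]:
            log.append({"rule": rule, "id": rid, "reason": reason})

    excluded = all_missing | low_global | no_core
    retained = records.loc[~excluded].reset_index(drop=True)
    if retained.empty:
        logger.warning("all %d records excluded", len(records))
    return retained, log


def zscore_within_stratum(values, strata) -> pd.Series:
    """Standardize ``values`` to mean 0, sd 1 (ddof=1) within each stratum.

    Missing values stay missing; a stratum with fewer than 2 nonmissing
    values or zero variance raises, naming the stratum.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    strata = pd.Series(np.asarray(strata, dtype=object))
    if len(values) != len(strata):
        raise ValueError("values and strata must align")
    out = pd.Series(np.nan, index=values.index)
    for s in strata.dropna().unique():
        mask = (strata == s).to_numpy()
        x = values[mask]
        n = x.notna().sum()
        if n < 2:
            raise ValueError(f"stratum {s!r}: fewer than 2 nonmissing values")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"stratum {s!r}: zero variance")
        out[mask] = (x - x.mean()) / sd
    return out


def build_analysis_table(
    records: pd.DataFrame,
    exclusion_config: ExclusionConfig | None = None,
    apply_exclusion_rules: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """Raw records -> analysis table with composites and z-scored indicators."""
    log: list[dict] = []
    if apply_exclusion_rules:
        records, log = apply_exclusions(records, exclusion_config)
    if records.empty:
        raise ValueError("no records left after exclusions")

    df = records.copy()
    df["overvaluation"] = overvaluation_composite(
        df["ov_weight"].to_numpy(), df["ov_shape"].to_numpy()
    )
    comp = df[list(COMP_ITEMS)].to_numpy(dtype=float)
    df["comp_freq_28d"] = np.minimum(comp, ITEM_CAP).sum(axis=1)
    df["comp_freq_weekly"] = df["comp_freq_28d"] / 4.0
    df["binge_weekly"] = df["binge_28d"] / 4.0
    for src, dst in (
        ("cognitive_ed", "z_cognitive"),
        ("depression_total", "z_depression"),
        ("anxiety_total", "z_anxiety"),
    ):
        df[dst] = zscore_within_stratum(df[src], df["stratum"]).to_numpy()
    return df, log


def indicator_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n, 3) array of z-scored indicators in the canonical order."""
    return df[["z_cognitive", "z_depression", "z_anxiety"]].to_numpy(dtype=float)
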