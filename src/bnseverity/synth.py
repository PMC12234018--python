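"""Synthetic treatment-seeking bulimia nervosa cohorts with planted severity structure.

The generator emulates the statistical structure the downstream analysis
assumes, with known ground truth:

* a single latent severity factor ``eta`` with unit within-group variance,
  driving three indicators ``y_k = loading * eta + eps_k``;
* two shape/weight overvaluation items on the 0-6 integer grid, drawn as a
  thresholded bivariate normal with a target correlation (default 0.80), whose
  mean is the 0.5-increment overvaluation composite;
* planted severity groups: the composite is binned at ``true_cutpoints`` and
  each bin shifts the latent mean by ``group_latent_means``;
* negative-binomial 28-day compensatory behaviour counts (vomiting,
  laxative/diuretic use, excessive exercise) with an optionally weak
  log-linear dependence on ``eta``;
* anxiety missing completely at random at a configurable rate (default 35%);
* three levels of care (residential / PHP / outpatient) with
  instrument-specific affine scales for depression and anxiety totals, so
  within-stratum z-scoring is a genuine preprocessing step.

Ground truth (group label, eta) is written to a JSON sidecar, never to the
analysis CSV, so the pipeline cannot accidentally consume it.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "write_cohort", "read_cohort"]

STRATA = ("residential", "php", "outpatient")

#: per-stratum affine maps (intercept, slope) from the latent-model indicator
#: scale to instrument-like totals.  Affine, so stratified z-scoring recovers
#: the generated indicator exactly (up to sampling noise).
_SCALE = {
    "cognitive": {"residential": (3.2, 1.1), "php": (3.2, 1.1), "outpatient": (3.0, 1.1)},
    "depression": {"residential": (28.0, 11.0), "php": (28.0, 11.0), "outpatient": (13.0, 6.0)},
    "anxiety": {"residential": (10.0, 4.0), "php": (10.0, 4.0), "outpatient": (9.0, 5.0)},
}

COMP_ITEMS = ("vomiting_28d", "laxative_diuretic_28d", "exercise_28d")


def _default_comp_dispersion() -> dict[str, tuple[float, float]]:
    # (mean 28-day count, negative-binomial size r) per compensatory item
    return {
        "vomiting_28d": (20.0, 0.8),
        "laxative_diuretic_28d": (6.0, 0.5),
        "exercise_28d": (10.0, 0.7),
    }


def _default_strata() -> dict[str, float]:
    # roughly the study's level-of-care mix (residential-heavy)
    return {"residential": 0.757, "php": 0.189, "outpatient": 0.054}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``true_cutpoints`` are overvaluation-composite values in (0, 6); records
    with composite >= cutpoint fall in the higher group (boundary goes right,
    matching the tree's split convention).  ``group_latent_means`` has one
    entry per group (len(cutpoints) + 1).
    """

    n_patients: int
    true_cutpoints: tuple[float, ...] = (1.25, 3.75, 4.75, 5.75)
    group_latent_means: tuple[float, ...] = (-1.5, -0.8, -0.2, 0.3, 0.8)
    loading: float = 0.8
    residual_variances: tuple[float, float, float] = (0.36, 0.36, 0.36)
    item_correlation: float = 0.80
    anxiety_missing_rate: float = 0.35
    comp_behavior_dispersion: dict[str, tuple[float, float]] = field(
        default_factory=_default_comp_dispersion
    )
    comp_latent_slope: float = 0.15
    binge_mean: float = 8.0
    binge_size: float = 1.0
    binge_latent_slope: float = 0.05
    strata_proportions: dict[str, float] = field(default_factory=_default_strata)
    noise_covariates: int = 0
    ov_item_mean: float = 4.3
    ov_item_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients: must be a positive integer")
        cuts = tuple(float(c) for c in self.true_cutpoints)
        if any(not (0.0 < c < 6.0) for c in cuts):
            raise ValueError("true_cutpoints: values must lie in (0, 6)")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("true_cutpoints: must be strictly increasing")
        self.true_cutpoints = cuts
        self.group_latent_means = tuple(float(m) for m in self.group_latent_means)
        if len(self.group_latent_means) != len(cuts) + 1:
            raise ValueError(
                "group_latent_means: length must equal len(true_cutpoints) + 1"
            )
        if self.loading <= 0:
            raise ValueError("loading: must be positive")
        self.residual_variances = tuple(float(v) for v in self.residual_variances)
        if len(self.residual_variances) != 3 or any(v <= 0 for v in self.residual_variances):
            raise ValueError("residual_variances: three positive values required")
        if not (0.0 <= self.item_correlation < 1.0):
            raise ValueError("item_correlation: must lie in [0, 1)")
        if not (0.0 <= self.anxiety_missing_rate < 1.0):
            raise ValueError("anxiety_missing_rate: must lie in [0, 1)")
        for name, (mean, size) in self.comp_behavior_dispersion.items():
            if mean < 0 or size <= 0:
                raise ValueError(f"comp_behavior_dispersion[{name}]: mean >= 0 and size > 0 required")
        props = self.strata_proportions
        if set(props) - set(STRATA):
            raise ValueError(f"strata_proportions: unknown strata {set(props) - set(STRATA)}")
        if abs(sum(props.values()) - 1.0) > 1e-8:
            raise ValueError("strata_proportions: must sum to 1")
        if self.noise_covariates < 0:
            raise ValueError("noise_covariates: must be nonnegative")

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("comp_behavior_dispersion",):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Generated records plus the planted ground truth, kept separate."""

    records: pd.DataFrame
    truth: pd.DataFrame  # columns: id, group, eta
    spec: CohortSpec

    def __post_init__(self) -> None:
        if len(self.records) != len(self.truth):
            raise ValueError("records and truth must align row-for-row")


def _draw_overvaluation_items(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    rho = spec.item_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=spec.n_patients, method="cholesky")
    items = np.clip(np.rint(spec.ov_item_mean + spec.ov_item_sd * z), 0, 6)
    return items


def _nb(rng: np.random.Generator, mean: np.ndarray | float, size_r: float, n: int) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (n,))
    p = size_r / (size_r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size_r, p)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    items = _draw_overvaluation_items(spec, rng)
    composite = items.mean(axis=1)
    group = np.searchsorted(np.asarray(spec.true_cutpoints), composite, side="right")
    eta = np.asarray(spec.group_latent_means)[group] + rng.standard_normal(n)

    resid = np.asarray(spec.residual_variances)
    indicators = spec.loading * eta[:, None] + rng.standard_normal((n, 3)) * np.sqrt(resid)

    strata_names = [s for s in STRATA if s in spec.strata_proportions]
    probs = np.array([spec.strata_proportions[s] for s in strata_names])
    stratum = rng.choice(strata_names, size=n, p=probs / probs.sum())

    def scale(kind: str, col: int) -> np.ndarray:
        out = np.empty(n)
        for s in strata_names:
            a, b = _SCALE[kind][s]
            mask = stratum == s
            out[mask] = a + b * indicators[mask, col]
        return out

    cognitive = scale("cognitive", 0)
    depression = scale("depression", 1)
    anxiety = scale("anxiety", 2)
    anxiety[rng.random(n) < spec.anxiety_missing_rate] = np.nan

    comp = {
        name: _nb(rng, mean * np.exp(spec.comp_latent_slope * eta), size_r, n)
        for name, (mean, size_r) in spec.comp_behavior_dispersion.items()
    }
    binge = _nb(rng, spec.binge_mean * np.exp(spec.binge_latent_slope * eta), spec.binge_size, n)

    records = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "stratum": stratum,
            "ov_weight": items[:, 0],
            "ov_shape": items[:, 1],
            "cognitive_ed": cognitive,
            "depression_total": depression,
            "anxiety_total": anxiety,
            "binge_28d": binge,
            **comp,
        }
    )
    for j in range(spec.noise_covariates):
        records[f"noise_{j}"] = rng.standard_normal(n)

    truth = pd.DataFrame({"id": records["id"], "group": group + 1, "eta": eta})
    return SyntheticCohort(records=records, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# CSV round trip

_EXPECTED_COLUMNS = (
    "id",
    "stratum",
    "ov_weight",
    "ov_shape",
    "cognitive_ed",
    "depression_total",
    "anxiety_total",
    "binge_28d",
    *COMP_ITEMS,
)


def write_cohort(cohort: SyntheticCohort, path) -> None:
    """Write the analysis CSV plus a ``<stem>.truth.json`` sidecar.

    Missing values are encoded as empty fields.  Byte-identical for identical
    cohorts (floats via repr round trip).
    """
    path = Path(path)
    csv = cohort.records.to_csv(index=False, na_rep="", lineterminator="\n")
    path.write_text(csv)
    sidecar = path.with_suffix(".truth.json")
    truth = {
        "cutpoints": list(cohort.spec.true_cutpoints),
        "seed": cohort.spec.seed,
        "id": cohort.truth["id"].tolist(),
        "group": cohort.truth["group"].tolist(),
        "eta": cohort.truth["eta"].tolist(),
    }
    sidecar.write_text(json.dumps(truth, sort_keys=True))


def read_cohort(path) -> SyntheticCohort | pd.DataFrame:
    """Read a cohort CSV (and, when present, its truth sidecar).

    Unknown columns are dropped with a warning; an empty file is an error.
    Returns a SyntheticCohort when the sidecar exists, else the records frame.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: file is empty")
    try:
        df = pd.read_csv(io.StringIO(text))
    except pd.errors.ParserError as exc:  # pandas reports the offending row
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc

    known = [c for c in df.columns if c in _EXPECTED_COLUMNS or c.startswith("noise_")]
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
        df = df[known]
    missing = [c for c in _EXPECTED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: required columns absent: {missing}")

    sidecar = path.with_suffix(".truth.json")
    if not sidecar.exists():
        return df
    t = json.loads(sidecar.read_text())
    truth = pd.DataFrame({"id": t["id"], "group": t["group"], "eta": t["eta"]})
    spec = CohortSpec(
        n_patients=len(df),
        true_cutpoints=tuple(t["cutpoints"]),
        group_latent_means=tuple([0.0] * (len(t["cutpoints"]) + 1)),
        seed=t.get("seed", 0),
    )
    return SyntheticCohort(records=df, truth=truth, spec=spec)
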