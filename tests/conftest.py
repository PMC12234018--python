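import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from bnseverity import CohortSpec, generate_cohort, build_analysis_table, indicator_matrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

TREE_COVARIATES = ["overvaluation", "comp_freq_28d"]


def make_analysis(spec: CohortSpec):
    """Generate a cohort and run it through preprocessing; returns
    (analysis table, indicator matrix, covariate frame, truth)."""
    cohort = generate_cohort(spec)
    analysis, _ = build_analysis_table(cohort.records)
    y = indicator_matrix(analysis)
    cov = analysis[TREE_COVARIATES].reset_index(drop=True)
    truth = cohort.truth.merge(analysis[["id"]], on="id")
    return analysis, y, cov, truth


def null_spec(n: int, seed: int, **kw) -> CohortSpec:
    """Cohort with no covariate effect at all (flat latent mean, no
    latent-count coupling)."""
    return CohortSpec(
        n_patients=n,
        true_cutpoints=(),
        group_latent_means=(0.0,),
        comp_latent_slope=0.0,
        binge_latent_slope=0.0,
        seed=seed,
        **kw,
    )


def one_cut_spec(n: int, seed: int, cut: float = 4.0, **kw) -> CohortSpec:
    return CohortSpec(
        n_patients=n,
        true_cutpoints=(cut,),
        group_latent_means=(-1.0, 1.0),
        comp_latent_slope=0.0,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def small_null_cohort():
    return make_analysis(null_spec(400, seed=123))


@pytest.fixture(scope="session")
def one_cut_cohort():
    return make_analysis(one_cut_spec(1000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
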