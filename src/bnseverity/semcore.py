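"""One-factor latent severity model estimated by full-information maximum likelihood.

The outcome model holds three standardized indicators (cognitive eating-disorder
symptoms, depression, anxiety) to a single latent severity factor with one
*shared* loading:

    y_k = m_k + lambda * eta + eps_k,    eta ~ N(0, 1),  eps_k ~ N(0, resid_k)

so the model-implied moments are mu = (m1, m2, m3) and
Sigma = lambda^2 * 11' + diag(resid1, resid2, resid3).  The latent variance is
fixed at 1 for identification, giving 7 free parameters (lambda, three means,
three residual variances).  Missing indicator values (anxiety in particular)
are handled by FIML: each row contributes the log-density of its observed
sub-vector under the corresponding marginal normal.

Rows are grouped by missingness pattern and reduced to sufficient statistics
(count, mean, scatter), so one objective evaluation costs O(#patterns) 3x3
linear algebra regardless of n.  Gradients are analytic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize

__all__ = [
    "FactorFit",
    "FitConfig",
    "implied_moments",
    "fiml_loglik",
    "rowwise_loglik",
    "fit_factor_model",
]

_LOG_2PI = math.log(2.0 * math.pi)
N_FREE_PARAMS = 7


@dataclass
class FactorFit:
    """Estimated one-factor model for one node's data."""

    loading: float
    means: tuple[float, float, float]
    residual_variances: tuple[float, float, float]
    loglik: float = float("nan")
    n: int = 0
    converged: bool = False
    n_free_params: int = N_FREE_PARAMS

    def __post_init__(self) -> None:
        self.means = tuple(float(m) for m in self.means)
        self.residual_variances = tuple(float(v) for v in self.residual_variances)
        if len(self.means) != 3 or len(self.residual_variances) != 3:
            raise ValueError("FactorFit requires exactly three means and residual variances")
        if any(v <= 0 for v in self.residual_variances):
            raise ValueError(f"residual variances must be positive, got {self.residual_variances}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["means"] = list(self.means)
        d["residual_variances"] = list(self.residual_variances)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FactorFit":
        return cls(
            loading=d["loading"],
            means=tuple(d["means"]),
            residual_variances=tuple(d["residual_variances"]),
            loglik=d.get("loglik", float("nan")),
            n=d.get("n", 0),
            converged=d.get("converged", False),
            n_free_params=d.get("n_free_params", N_FREE_PARAMS),
        )


@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit_factor_model`.

    start_loading / start override the deterministic default starting values
    (lambda=0.5, means=sample means, residuals=half sample variances); internal
    callers warm-start child-node fits from the parent's estimate.
    """

    min_rows: int = N_FREE_PARAMS + 1
    tol: float = 1e-8
    max_iter: int = 500
    start: np.ndarray | None = None  # full 7-vector (lambda, m1..3, log r1..3)
    retries: tuple[float, ...] = (0.2, 0.9)  # alternative starting loadings


def implied_moments(fit: FactorFit) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix.

    Sigma = lambda^2 * J + diag(residual_variances) with J the 3x3 all-ones
    matrix (unit latent variance).
    """
    mu = np.asarray(fit.means, dtype=float)
    lam = float(fit.loading)
    sigma = lam * lam * np.ones((3, 3)) + np.diag(fit.residual_variances)
    return mu, sigma


def _as_triplets(triplets) -> np.ndarray:
    y = np.asarray(triplets, dtype=float)
    if y.ndim != 2 or y.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) indicator array, got shape {y.shape}")
    return y


def _pattern_stats(y: np.ndarray) -> list[tuple[np.ndarray, int, np.ndarray, np.ndarray]]:
    """Sufficient statistics per missingness pattern.

    Returns a list of (observed_indices, n, mean, scatter) where scatter is the
    centered cross-product matrix sum_i (x_i - xbar)(x_i - xbar)'.
    """
    obs_mask = ~np.isnan(y)
    if np.any(~obs_mask.any(axis=1)):
        raise ValueError("rows with all three indicators missing are not allowed")
    code = obs_mask @ np.array([1, 2, 4])
    out = []
    for c in np.unique(code):
        rows = y[code == c]
        obs = np.flatnonzero(obs_mask[np.argmax(code == c)])
        x = rows[:, obs]
        n = x.shape[0]
        xbar = x.mean(axis=0)
        centered = x - xbar
        scatter = centered.T @ centered
        out.append((obs, n, xbar, scatter))
    return out


def _loglik_from_stats(mu: np.ndarray, sigma: np.ndarray, stats) -> float:
    total = 0.0
    for obs, n, xbar, scatter in stats:
        so = sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(so)
        if sign <= 0:
            return -np.inf
        si = np.linalg.inv(so)
        delta = xbar - mu[obs]
        d = len(obs)
        total += -0.5 * (
            n * (d * _LOG_2PI + logdet)
            + float(np.sum(si * scatter))
            + n * float(delta @ si @ delta)
        )
    return total


def fiml_loglik(fit: FactorFit, triplets) -> float:
    """FIML log-likelihood of the data under ``fit``.

    Each row contributes the log-density of its observed sub-vector under the
    marginal of (mu, Sigma) obtained by selecting the observed rows/columns.
    """
    y = _as_triplets(triplets)
    mu, sigma = implied_moments(fit)
    return _loglik_from_stats(mu, sigma, _pattern_stats(y))


def rowwise_loglik(fit: FactorFit, triplets) -> np.ndarray:
    """Per-row FIML log-density (used for out-of-bag forest evaluation)."""
    y = _as_triplets(triplets)
    mu, sigma = implied_moments(fit)
    obs_mask = ~np.isnan(y)
    if np.any(~obs_mask.any(axis=1)):
        raise ValueError("rows with all three indicators missing are not allowed")
    out = np.empty(y.shape[0])
    code = obs_mask @ np.array([1, 2, 4])
    for c in np.unique(code):
        sel = code == c
        obs = np.flatnonzero(obs_mask[np.argmax(sel)])
        so = sigma[np.ix_(obs, obs)]
        si = np.linalg.inv(so)
        _, logdet = np.linalg.slogdet(so)
        d = len(obs)
        delta = y[np.ix_(sel, obs)] - mu[obs]
        quad = np.einsum("ij,jk,ik->i", delta, si, delta)
        out[sel] = -0.5 * (d * _LOG_2PI + logdet + quad)
    return out


def _neg_loglik_and_grad(theta: np.ndarray, stats) -> tuple[float, np.ndarray]:
    lam = theta[0]
    mu = theta[1:4]
    resid = np.exp(theta[4:7])
    sigma = lam * lam * np.ones((3, 3)) + np.diag(resid)

    ll = 0.0
    g_mu = np.zeros(3)
    g_sigma = np.zeros((3, 3))
    for obs, n, xbar, scatter in stats:
        so = sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(so)
        if sign <= 0:
            return np.inf, np.zeros(7)
        si = np.linalg.inv(so)
        delta = xbar - mu[obs]
        sid = si @ delta
        d = len(obs)
        ll += -0.5 * (
            n * (d * _LOG_2PI + logdet)
            + float(np.sum(si * scatter))
            + n * float(delta @ sid)
        )
        g_mu[obs] += n * sid
        # d ll / d Sigma_o = 0.5 * Si (S + n dd' - n Sigma_o) Si
        inner = scatter + n * np.outer(delta, delta) - n * so
        g_sigma[np.ix_(obs, obs)] += 0.5 * (si @ inner @ si)

    g = np.empty(7)
    g[0] = 2.0 * lam * g_sigma.sum()
    g[1:4] = g_mu
    g[4:7] = np.diag(g_sigma) * resid
    return -ll, -g


def fit_factor_model(triplets, config: FitConfig | None = None) -> FactorFit:
    """Maximize the FIML log-likelihood over (lambda, means, residual variances).

    The latent variance is fixed at 1; the shared loading is constrained to
    lambda >= 0 to resolve the sign indeterminacy.  Residual variances are
    optimized on the log scale.  Deterministic given data and config.
    """
    config = config or FitConfig()
    y = _as_triplets(triplets)
    n = y.shape[0]
    if n < config.min_rows:
        raise ValueError(f"need at least {config.min_rows} rows, got {n}")
    n_obs_per_ind = (~np.isnan(y)).sum(axis=0)
    if np.any(n_obs_per_ind < 2):
        raise ValueError("each indicator needs at least 2 observed values")
    sample_var = np.nanvar(y, axis=0, ddof=1)
    if np.any(sample_var <= 0):
        bad = int(np.argmin(sample_var))
        raise ValueError(f"indicator {bad} has zero variance; model is degenerate")

    stats = _pattern_stats(y)

    if config.start is not None:
        starts = [np.asarray(config.start, dtype=float)]
    else:
        base = np.concatenate(
            ([0.5], np.nanmean(y, axis=0), np.log(0.5 * sample_var))
        )
        starts = [base]
        for lam0 in config.retries:
            alt = base.copy()
            alt[0] = lam0
            starts.append(alt)

    bounds = [(0.0, None)] + [(None, None)] * 6
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_loglik_and_grad,
            x0,
            args=(stats,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break

    theta = best.x
    fit = FactorFit(
        loading=float(theta[0]),
        means=tuple(theta[1:4]),
        residual_variances=tuple(np.exp(theta[4:7])),
        loglik=-float(best.fun),
        n=n,
        converged=bool(best.success),
    )
    return fit
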