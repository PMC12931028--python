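"""Monte-Carlo uncertainty for standardized estimands, and the median
hazard ratio.

Standard errors and confidence intervals for any standardized survival
probability or contrast psi are obtained by parametric simulation:

1. draw model parameters from the multivariate normal approximation of the
   MLE on the transformed (log) scale, using the Hessian-based covariance;
2. draw random-effect values for each cluster from the normal approximation
   of its posterior, N(EB mean, posterior SD^2), independently across
   clusters;
3. recompute psi with the drawn parameters and effects;
4. repeat B times; the SE is the standard deviation across repetitions and
   the default 95% interval the empirical 2.5th/97.5th percentiles.

The point estimate stays the plug-in value, not the mean of the draws.
Effects that an estimand fixes at zero (theoretical-average clusters) have
no posterior uncertainty, so step 2 is skipped for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .likelihood import ModelParams


@dataclass
class MCInterval:
    """Result of the B-draw variance procedure for one estimand."""

    point: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    B: int
    n_excluded: int
    method: str
    draws: np.ndarray | None = None


def draw_parameters(fit, B: int, seed: int) -> list[ModelParams]:
    """B multivariate-normal parameter draws on the transformed scale,
    back-transformed to the natural scale.

    Positive parameters (shape, scale, variances) are log-mapped inside the
    sampling space, so every draw respects positivity by construction.
    """
    if fit.vcov is None or not fit.vcov_ok:
        raise ValueError(
            "parameter covariance unavailable (singular or missing Hessian); "
            "cannot draw parameters"
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    mean = np.asarray(fit.transformed, float)
    draws = rng.multivariate_normal(mean, fit.vcov, size=B,
                                    method="cholesky" if _is_pd(fit.vcov)
                                    else "svd")
    par = fit.parametrization
    return [par.unpack(v) for v in draws]


def _is_pd(m):
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


def draw_random_effects(eb: pd.DataFrame, B: int, seed: int) -> pd.DataFrame:
    """B independent normal draws per cluster, N(EB mean, posterior SD^2).

    Returns a DataFrame with one row per cluster and a ``draws`` column
    holding a length-B array; draws are independent across clusters.
    """
    if eb["sd"].isna().any():
        raise ValueError("EB predictions lack posterior SDs; cannot draw")
    rng = np.random.default_rng(seed)
    out = eb[["level", "cluster_id", "center_id", "prediction", "sd"]].copy()
    out["draws"] = [
        rng.normal(row.prediction, row.sd, B) for row in eb.itertuples()
    ]
    return out


def mc_interval(estimand_fn, fit, eb: pd.DataFrame | None, B: int = 1000,
                seed: int = 0, method: str = "percentile",
                alpha: float = 0.05, keep_draws: bool = False) -> MCInterval:
    """Monte-Carlo SE and CI for an estimand.

    Parameters
    ----------
    estimand_fn : callable(params, effects) -> float or ndarray
        Pure function evaluating the estimand at given model parameters and
        a mapping ``(level, cluster_id) -> effect value``.  The plug-in
        point estimate is ``estimand_fn(fit.params, eb_means)``.
    eb : DataFrame or None
        EB prediction table (from ``predict_random_effects``); None when the
        estimand uses no cluster effects.
    method : {"percentile", "normal"}
        Empirical-quantile or Wald-style interval.

    Non-finite repetitions are dropped with a warning; more than 5% of them
    is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if method not in ("percentile", "normal"):
        raise ValueError("method must be 'percentile' or 'normal'")
    param_draws = draw_parameters(fit, B, seed)
    if eb is not None and len(eb):
        eff_draws = draw_random_effects(eb, B, seed + 1)
        keys = [(r.level, r.cluster_id) for r in eff_draws.itertuples()]
        draw_mat = np.stack([r for r in eff_draws["draws"]])
        point_effects = dict(zip(keys, eff_draws["prediction"]))
    else:
        keys, draw_mat, point_effects = [], None, {}

    point = np.asarray(estimand_fn(fit.params, point_effects), float)
    vals = []
    for b in range(B):
        effects = (dict(zip(keys, draw_mat[:, b])) if keys else {})
        vals.append(np.asarray(estimand_fn(param_draws[b], effects), float))
    vals = np.stack(vals)
    finite = np.all(np.isfinite(vals.reshape(len(vals), -1)), axis=1)
    n_excl = int(B - finite.sum())
    if n_excl > 0.05 * B:
        raise FloatingPointError(
            f"{n_excl}/{B} Monte-Carlo repetitions were non-finite"
        )
    vals = vals[finite]
    se = vals.std(axis=0)  # 1/B normalization, matching the SE definition
    if method == "percentile":
        lower = np.percentile(vals, 100 * alpha / 2, axis=0)
        upper = np.percentile(vals, 100 * (1 - alpha / 2), axis=0)
    else:
        z = norm.ppf(1 - alpha / 2)
        lower, upper = point - z * se, point + z * se
    return MCInterval(point=point, se=se, lower=lower, upper=upper, B=B,
                      n_excluded=n_excl, method=method,
                      draws=vals if keep_draws else None)


def median_hazard_ratio(variance: float) -> float:
    """Median hazard ratio implied by a random-intercept variance.

    The median of the hazard ratio between the higher- and lower-risk
    member of randomly drawn cluster pairs with intercepts ~ N(0, variance):

        MHR = exp( sqrt(2 * variance) * Phi^{-1}(0.75) )

    Always >= 1; equals 1 when the variance is 0.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    return float(np.exp(np.sqrt(2.0 * variance) * norm.ppf(0.75)))
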