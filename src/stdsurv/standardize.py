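"""Directly standardized survival probabilities and contrasts.

A cluster's performance is summarized by imposing its predicted random
effect(s) on every subject of a fixed reference population (by default the
whole study cohort) and averaging the resulting conditional survival
probabilities:

    S_fixed(t)   = (1/m) sum_i  S0(t)^exp(x_i @ beta + alpha* + gamma*)
    S_marginal(t)= (1/m) sum_i Int S0(t)^exp(x_i @ beta + alpha* + g)
                                 phi(g; var) dg

with ``S0(t) = exp(-lam * t**p)`` the baseline survival.  Fixing both
effects compares (surgeon, center) combinations; marginalizing one level
over its estimated normal distribution isolates the other level; setting an
effect to 0 gives the "theoretical average" cluster.  Because every
comparison standardizes over the same case-mix, differences between the
resulting curves are directly interpretable as adjusted risk differences.

The marginal integral is a prior (exactly Gaussian) expectation and is
evaluated with non-adaptive Gauss-Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss

from .data import SurvivalDataset
from .likelihood import ModelParams


@dataclass
class StandardizedEstimate:
    """A standardized survival curve S(t) on a time grid.

    ``estimand`` is one of ``fixed_both``, ``fixed_surgeon_marginal_center``,
    ``fixed_center_marginal_surgeon`` or ``theoretical_average``.
    ``population`` describes the standardization population;
    ``extrapolation_fraction`` is the share of that population drawn from
    clusters other than the one being profiled (an extrapolation warning
    signal, not a correction).
    """

    estimand: str
    times: np.ndarray
    values: np.ndarray
    surgeon_id: object = None
    center_id: object = None
    population: str = "all"
    population_size: int = 0
    extrapolation_fraction: float = float("nan")
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.times, "estimate": self.values})
        if self.lower is not None:
            out["lower"] = self.lower
            out["upper"] = self.upper
        return out

    def metadata(self) -> dict:
        return {
            "estimand": self.estimand,
            "surgeon_id": None if self.surgeon_id is None else str(self.surgeon_id),
            "center_id": None if self.center_id is None else str(self.center_id),
            "population": self.population,
            "population_size": self.population_size,
            "extrapolation_fraction": self.extrapolation_fraction,
        }


@dataclass
class ContrastEstimate:
    """Pointwise difference of two standardized survival curves."""

    minuend: dict
    subtrahend: dict
    times: np.ndarray
    differences: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.times, "difference": self.differences})
        if self.lower is not None:
            out["lower"] = self.lower
            out["upper"] = self.upper
        return out


def conditional_survival(params: ModelParams, X, alpha: float, gamma: float,
                         t) -> np.ndarray:
    """Fully conditional survival S0(t)^exp(X @ beta + alpha + gamma)."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    X = np.atleast_2d(np.asarray(X, float))
    lp = X @ params.beta if X.shape[1] else np.zeros(X.shape[0])
    logS0 = -params.scale * t ** params.shape
    out = np.exp(np.outer(logS0, np.exp(lp + alpha + gamma)))
    return out.squeeze()


def default_time_grid(dataset: SurvivalDataset, n_points: int = 100
                      ) -> np.ndarray:
    """Equally spaced grid from 0 to the 99th follow-up percentile."""
    return np.linspace(0.0, float(np.quantile(dataset.time, 0.99)), n_points)


def _resolve_population(dataset: SurvivalDataset, population):
    """Population selector: None (all rows), a boolean mask, an index array,
    or a center id whose subjects form the reference case-mix."""
    if population is None:
        return np.arange(dataset.n), "all"
    if isinstance(population, str):
        k = dataset.center_code(population)
        return np.flatnonzero(dataset.center_idx == k), f"center:{population}"
    idx = np.asarray(population)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    return idx.astype(np.intp), "subset"


def _effects_from_eb(eb: pd.DataFrame, level: str, cluster_id, center_id=None):
    sub = eb[(eb.level == level) & (eb.cluster_id == cluster_id)]
    if center_id is not None:
        sub = sub[sub.center_id == center_id]
    if len(sub) == 0:
        raise KeyError(f"no EB prediction for {level} {cluster_id!r}")
    if len(sub) > 1:
        raise KeyError(f"{level} id {cluster_id!r} is ambiguous; pass center_id")
    return float(sub.prediction.iloc[0])


def _core_standardize(params: ModelParams, X_pop, alpha_term, gamma_term,
                      times, marginal_var=None, nodes=30):
    """Shared kernel.  One of ``alpha_term``/``gamma_term`` may be the
    string ``"marginal"``, in which case it is integrated over
    N(0, marginal_var) by Gauss-Hermite quadrature."""
    times = np.asarray(times, float)
    lp = X_pop @ params.beta if X_pop.shape[1] else np.zeros(X_pop.shape[0])
    logS0 = -params.scale * times ** params.shape  # (T,)
    fixed = 0.0
    marg = None
    for term in (alpha_term, gamma_term):
        if term == "marginal":
            marg = marginal_var
        else:
            fixed += float(term)
    if marg is None or marg == 0.0:
        # (T, m) matrix of conditional survivals, averaged over subjects
        expo = np.exp(lp + fixed)
        vals = np.exp(np.outer(logS0, expo)).mean(axis=1)
        return vals
    x, w = hermgauss(nodes)
    v = w / np.sqrt(np.pi)
    g = np.sqrt(2.0 * marg) * x  # (Q,)
    expo = np.exp(lp[:, None] + fixed + g)  # (m, Q)
    # average over quadrature then subjects
    vals = np.einsum("tmq,q->tm",
                     np.exp(logS0[:, None, None] * expo[None, :, :]), v
                     ).mean(axis=1)
    return vals


def _extrapolation_fraction(dataset, idx, center_id):
    if center_id is None:
        return float("nan")
    k = dataset.center_code(center_id)
    return float(np.mean(dataset.center_idx[idx] != k))


def standardize_fixed(fit, eb: pd.DataFrame | None = None, surgeon=None,
                      center=None, times=None, population=None,
                      dataset: SurvivalDataset | None = None
                      ) -> StandardizedEstimate:
    """Standardized survival with both random effects fixed.

    ``surgeon``/``center`` are cluster ids looked up in the EB prediction
    table ``eb``; passing ``None`` for a level fixes its effect at 0 (the
    theoretical average).  The expectation runs over the case-mix of
    ``population`` (default: every subject in the dataset).
    """
    ds = dataset if dataset is not None else fit.dataset
    params = fit.params if hasattr(fit, "params") else fit
    idx, pop_name = _resolve_population(ds, population)
    if len(idx) == 0:
        raise ValueError("empty standardization population")
    if times is None:
        times = default_time_grid(ds)
    alpha = 0.0 if surgeon is None else _effects_from_eb(eb, "surgeon", surgeon, center)
    gamma = 0.0 if center is None else _effects_from_eb(eb, "center", center)
    vals = _core_standardize(params, ds.X[idx], alpha, gamma, times)
    estimand = "theoretical_average" if surgeon is None and center is None \
        else "fixed_both"
    return StandardizedEstimate(
        estimand=estimand, times=np.asarray(times, float), values=vals,
        surgeon_id=surgeon, center_id=center, population=pop_name,
        population_size=len(idx),
        extrapolation_fraction=_extrapolation_fraction(ds, idx, center),
    )


def standardize_marginal(fit, eb: pd.DataFrame | None = None, surgeon=None,
                         center=None, times=None, population=None,
                         nodes: int = 30,
                         dataset: SurvivalDataset | None = None
                         ) -> StandardizedEstimate:
    """Standardized survival fixing one level and marginalizing the other.

    Fix a surgeon (pass ``surgeon=...``) and integrate the center effect
    over N(0, var_center), or fix a center (pass ``center=...``) and
    integrate the surgeon effect over N(0, var_surgeon).  The
    marginalization uses the estimated prior variance, not the empirical
    set of EB predictions.
    """
    ds = dataset if dataset is not None else fit.dataset
    params = fit.params if hasattr(fit, "params") else fit
    if (surgeon is None) == (center is None):
        raise ValueError("fix exactly one of surgeon= or center=")
    idx, pop_name = _resolve_population(ds, population)
    if len(idx) == 0:
        raise ValueError("empty standardization population")
    if times is None:
        times = default_time_grid(ds)
    if surgeon is not None:
        alpha = _effects_from_eb(eb, "surgeon", surgeon)
        vals = _core_standardize(params, ds.X[idx], alpha, "marginal", times,
                                 marginal_var=params.var_center, nodes=nodes)
        estimand = "fixed_surgeon_marginal_center"
    else:
        gamma = _effects_from_eb(eb, "center", center)
        vals = _core_standardize(params, ds.X[idx], "marginal", gamma, times,
                                 marginal_var=params.var_surgeon, nodes=nodes)
        estimand = "fixed_center_marginal_surgeon"
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("non-finite marginal standardized survival")
    return StandardizedEstimate(
        estimand=estimand, times=np.asarray(times, float), values=vals,
        surgeon_id=surgeon, center_id=center, population=pop_name,
        population_size=len(idx),
        extrapolation_fraction=_extrapolation_fraction(ds, idx, center),
    )


def survival_estimand(dataset: SurvivalDataset, times, surgeon=None,
                      center=None, marginalize: str | None = None,
                      population=None):
    """Build a pure ``(params, effects) -> S(t)`` function for the
    Monte-Carlo variance machinery.

    ``effects`` maps ``(level, cluster_id)`` to a random-effect value;
    levels set to None are fixed at zero (theoretical average) and levels
    named in ``marginalize`` are integrated over their estimated prior.
    """
    idx, _ = _resolve_population(dataset, population)
    X = dataset.X[idx]
    times = np.asarray(times, float)
    if marginalize not in (None, "surgeon", "center"):
        raise ValueError("marginalize must be None, 'surgeon' or 'center'")

    def fn(params: ModelParams, effects):
        if marginalize == "surgeon":
            alpha_term, mvar = "marginal", params.var_surgeon
        else:
            alpha_term = (effects[("surgeon", surgeon)]
                          if surgeon is not None else 0.0)
            mvar = None
        if marginalize == "center":
            gamma_term, mvar = "marginal", params.var_center
        else:
            gamma_term = (effects[("center", center)]
                          if center is not None else 0.0)
        return _core_standardize(params, X, alpha_term, gamma_term, times,
                                 marginal_var=mvar)

    return fn


def difference_estimand(fn_a, fn_b):
    """Estimand computing ``fn_a - fn_b`` under shared draws (a contrast)."""

    def fn(params, effects):
        return np.asarray(fn_a(params, effects)) - np.asarray(fn_b(params, effects))

    return fn


def contrast(a: StandardizedEstimate, b: StandardizedEstimate
             ) -> ContrastEstimate:
    """Pointwise difference a - b of two standardized curves.

    Requires identical time grids and identical standardization
    populations, so the comparison is over a common case-mix.
    """
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("time grids differ; contrasts need a shared grid")
    if a.population != b.population or a.population_size != b.population_size:
        raise ValueError(
            "standardization populations differ; contrasts must share the "
            "same case-mix"
        )
    return ContrastEstimate(
        minuend=a.metadata(), subtrahend=b.metadata(), times=a.times.copy(),
        differences=a.values - b.values,
    )


def rank_clusters(estimates: dict, reference: float | None = None,
                  bands: dict | None = None, policy: str = "ci_overlap"
                  ) -> pd.DataFrame:
    """Rank clusters by a standardized survival at a reference time.

    Parameters
    ----------
    estimates : mapping cluster id -> point estimate (survival probability).
    reference : float, optional
        Target value, typically the theoretical-average cluster's estimate.
    bands : mapping cluster id -> (lower, upper), optional
        CI at the same time point.
    policy : str
        ``"ci_overlap"`` (default): a cluster is medium-risk if its CI
        covers the reference, low-risk if the CI lies entirely above it
        (better survival), high-risk if entirely below.  ``"tercile"``
        splits the point estimates into thirds and needs no CIs.

    Returns a DataFrame sorted by decreasing estimate (best first) with a
    ``category`` column; the policy used is recorded in ``attrs``.
    """
    ids = sorted(estimates, key=str)
    rows = []
    for cid in ids:
        est = float(estimates[cid])
        lo, hi = (bands.get(cid, (np.nan, np.nan)) if bands else (np.nan, np.nan))
        rows.append((cid, est, lo, hi))
    out = pd.DataFrame(rows, columns=["cluster_id", "estimate", "lower", "upper"])
    out = out.sort_values(["estimate", "cluster_id"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)

    if policy == "tercile":
        terc = np.ceil(3 * out["rank"] / len(out)).astype(int)
        out["category"] = terc.map({1: "low", 2: "medium", 3: "high"})
    elif policy == "ci_overlap":
        if bands is None or out[["lower", "upper"]].isna().any().any():
            out["category"] = "uncategorized"
        elif reference is None:
            raise ValueError("ci_overlap policy needs a reference value")
        else:
            cat = np.where(out.lower > reference, "low",
                           np.where(out.upper < reference, "high", "medium"))
            out["category"] = cat
    else:
        raise ValueError(f"unknown policy {policy!r}")
    out.attrs["policy"] = policy
    out.attrs["reference"] = reference
    return out
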