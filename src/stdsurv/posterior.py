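"""Empirical-Bayes prediction of surgeon- and center-level random intercepts.

With model parameters fixed at their maximum-likelihood estimates, the joint
posterior of a center's intercept gamma and its surgeons' intercepts
alpha_1..alpha_J is

    omega(gamma, alpha | data) ∝ phi(gamma; var_center)
        * Prod_j [ phi(alpha_j; var_surgeon) * Prod_i f_ij(alpha_j, gamma) ]

Surgeons are conditionally independent given gamma, so every posterior
summary reduces to nested one-dimensional quadratures: an outer adaptive
Gauss-Hermite rule over gamma (recentered at the posterior mode of gamma)
and, at each outer node, inner adaptive rules over one alpha at a time.
Posterior means minimize mean-squared prediction error and are the default;
posterior modes are also provided, with standard deviations from the
curvature of the joint log-posterior at the mode.

Clusters with little data are shrunk toward zero (the population mean); a
cluster with no data has posterior equal to its prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .likelihood import ModelParams, WeibullPHEngine, _logphi


@dataclass
class EBPrediction:
    """Posterior summary of one cluster's random intercept."""

    level: str  # "surgeon" or "center"
    cluster_id: object
    center_id: object
    mean: float
    mode: float
    sd: float


def log_posterior_density(fit, dataset: SurvivalDataset, center_id,
                          gamma: float, alphas) -> float:
    """Log of the unnormalized joint posterior of one center's effects.

    Sums the conditional log-likelihood of the center's subjects with the
    prior log-densities of gamma and each surgeon's alpha.  The normalizing
    constant (the center's marginal likelihood) is omitted.
    """
    params = fit.params if hasattr(fit, "params") else fit
    engine = WeibullPHEngine(dataset, nodes=5)
    k = dataset.center_code(center_id)
    surgeons = np.flatnonzero(dataset.surgeon_center == k)
    alphas = np.atleast_1d(np.asarray(alphas, float))
    if len(alphas) != len(surgeons):
        raise ValueError(
            f"center {center_id!r} has {len(surgeons)} surgeons, got "
            f"{len(alphas)} alpha values"
        )
    B, D, C = engine.suffstats(params)
    va, vg = params.var_surgeon, params.var_center
    out = _logphi(gamma, vg) if vg > 0 else 0.0
    for a, s in zip(alphas, surgeons):
        u = a + gamma
        out += C[s] + D[s] * u - B[s] * np.exp(u)
        out += _logphi(a, va) if va > 0 else 0.0
    return float(out)


def _require_converged(fit):
    if not getattr(fit, "converged", True):
        raise ValueError(
            "fit did not converge; refusing to compute posterior predictions"
        )


def _posterior_engine(fit, dataset, nodes):
    _require_converged(fit)
    engine = WeibullPHEngine(dataset, nodes=nodes)
    params = fit.params
    suff = engine.suffstats(params)
    gnodes, logint, logwts = engine.center_gamma_quadrature(params, suff)
    # normalized gamma-posterior weights per center
    mx = logwts.max(axis=1, keepdims=True)
    w = np.exp(logwts - mx)
    w /= w.sum(axis=1, keepdims=True)
    return engine, params, suff, gnodes, w


def _center_moments(gnodes, w):
    mean = (w * gnodes).sum(axis=1)
    second = (w * gnodes ** 2).sum(axis=1)
    var = np.maximum(second - mean ** 2, 0.0)
    return mean, np.sqrt(var)


def _surgeon_moments(engine, params, suff, gnodes, w):
    """Posterior mean/sd of every surgeon's alpha, marginal over gamma and
    sibling surgeons (which integrate out by conditional independence)."""
    B, D, _ = suff
    va = params.var_surgeon
    g = gnodes[engine.surgeon_center]  # (S, Q)
    _, m1, m2 = engine._log_inner(B[:, None], D[:, None], va, g,
                                  with_moments=True)
    ws = w[engine.surgeon_center]
    mean = (ws * m1).sum(axis=1)
    second = (ws * m2).sum(axis=1)
    var = np.maximum(second - mean ** 2, 0.0)
    return mean, np.sqrt(var)


def eb_mean(fit, dataset: SurvivalDataset, cluster_id, level: str,
            center_id=None, nodes: int = 30) -> EBPrediction:
    """Empirical-Bayes (posterior) mean and SD of one cluster's intercept.

    For a surgeon, the center effect and sibling surgeons are integrated
    out; for a center, all its surgeons are integrated out.
    """
    engine, params, suff, gnodes, w = _posterior_engine(fit, dataset, nodes)
    if level == "center":
        k = dataset.center_code(cluster_id)
        mean, sd = _center_moments(gnodes, w)
        if not np.isfinite(mean[k]):
            raise FloatingPointError(f"non-finite posterior for center {cluster_id!r}")
        return EBPrediction("center", cluster_id, cluster_id,
                            float(mean[k]), np.nan, float(sd[k]))
    if level != "surgeon":
        raise ValueError("level must be 'surgeon' or 'center'")
    s = dataset.surgeon_code(cluster_id, center_id)
    mean, sd = _surgeon_moments(engine, params, suff, gnodes, w)
    if not np.isfinite(mean[s]):
        raise FloatingPointError(f"non-finite posterior for surgeon {cluster_id!r}")
    return EBPrediction("surgeon", cluster_id,
                        dataset.surgeon_pairs[s][0],
                        float(mean[s]), np.nan, float(sd[s]))


def _joint_modes(engine, params, suff):
    """Joint posterior mode per center: maximize over gamma the profile
    with every alpha at its conditional mode, then read the curvature of
    the joint log-posterior (an arrow-structured Hessian) at the optimum.

    Returns (gamma_mode (K,), alpha_mode (S,), gamma_sd (K,), alpha_sd (S,)).
    """
    B, D, _ = suff
    va, vg = params.var_surgeon, params.var_center
    K, S = engine.K, engine.S

    def profile(gv):
        g = gv[engine.surgeon_center]
        if va == 0.0:
            val = D * g - B * np.exp(g)
        else:
            m = engine._inner_mode(B, D, va, g)
            u = m + g
            val = D * u - B * np.exp(u) + _logphi(m, va)
        out = engine._center_sum(val)
        return out + (_logphi(gv, vg) if vg > 0 else 0.0)

    if vg == 0.0:
        gmode = np.zeros(K)
    else:
        gmode = np.zeros(K)
        h = 1e-5
        for _ in range(80):
            f0 = profile(gmode)
            fp = (profile(gmode + h) - profile(gmode - h)) / (2 * h)
            fpp = (profile(gmode + h) - 2 * f0 + profile(gmode - h)) / (h * h)
            fpp = np.minimum(fpp, -1e-10)
            step = np.clip(-fp / fpp, -1.5, 1.5)
            gmode = gmode + step
            if np.max(np.abs(step)) < 1e-10:
                break

    g = gmode[engine.surgeon_center]
    amode = (engine._inner_mode(B, D, va, g) if va > 0
             else np.zeros(S))

    # curvature: -d2/da2 = E + 1/va, -d2/dadg = E, -d2/dg2 = sum E + 1/vg
    E = B * np.exp(np.clip(amode + g, -700, 700))
    if va > 0:
        A = E + 1.0 / va
        asd_cond = 1.0 / A
        b = E
    else:
        A = np.full(S, np.inf)
        asd_cond = np.zeros(S)
        b = np.zeros(S)
    if vg > 0:
        c = engine._center_sum(E) + 1.0 / vg
        schur = c - engine._center_sum(np.where(np.isfinite(A), b * b / A, 0.0))
        gvar = 1.0 / np.maximum(schur, 1e-300)
    else:
        gvar = np.zeros(K)
    avar = asd_cond + (b * asd_cond) ** 2 * gvar[engine.surgeon_center] \
        if va > 0 else np.zeros(S)
    return gmode, amode, np.sqrt(gvar), np.sqrt(avar)


def eb_mode(fit, dataset: SurvivalDataset, cluster_id, level: str,
            center_id=None, nodes: int = 30) -> EBPrediction:
    """Empirical-Bayes (posterior) mode of one cluster's intercept, with SD
    from the inverse curvature of the joint log-posterior at the mode."""
    _require_converged(fit)
    engine = WeibullPHEngine(dataset, nodes=nodes)
    params = fit.params
    suff = engine.suffstats(params)
    gmode, amode, gsd, asd = _joint_modes(engine, params, suff)
    if level == "center":
        k = dataset.center_code(cluster_id)
        return EBPrediction("center", cluster_id, cluster_id, np.nan,
                            float(gmode[k]), float(gsd[k]))
    s = dataset.surgeon_code(cluster_id, center_id)
    return EBPrediction("surgeon", cluster_id, dataset.surgeon_pairs[s][0],
                        np.nan, float(amode[s]), float(asd[s]))


def predict_all(fit, dataset: SurvivalDataset, method: str = "mean",
                nodes: int = 30) -> pd.DataFrame:
    """Empirical-Bayes predictions for every surgeon and center.

    Returns a DataFrame with columns ``level``, ``cluster_id``,
    ``center_id``, ``prediction``, ``sd`` and ``rank`` (rank 1 = smallest
    prediction = lowest hazard = best cluster; ties broken by cluster id).
    The attrs carry the best/worst cluster per level.
    """
    if method not in ("mean", "mode"):
        raise ValueError("method must be 'mean' or 'mode'")
    if method == "mean":
        engine, params, suff, gnodes, w = _posterior_engine(fit, dataset, nodes)
        cmean, csd = _center_moments(gnodes, w)
        smean, ssd = _surgeon_moments(engine, params, suff, gnodes, w)
    else:
        _require_converged(fit)
        engine = WeibullPHEngine(dataset, nodes=nodes)
        suff = engine.suffstats(fit.params)
        gmode, amode, gsd, asd = _joint_modes(engine, fit.params, suff)
        cmean, csd, smean, ssd = gmode, gsd, amode, asd
    if not (np.all(np.isfinite(cmean)) and np.all(np.isfinite(smean))):
        raise FloatingPointError("non-finite posterior prediction")

    rows = []
    for k, cid in enumerate(dataset.center_ids):
        rows.append(("center", cid, cid, cmean[k], csd[k]))
    for s, (cid, sid) in enumerate(dataset.surgeon_pairs):
        rows.append(("surgeon", sid, cid, smean[s], ssd[s]))
    out = pd.DataFrame(rows, columns=["level", "cluster_id", "center_id",
                                      "prediction", "sd"])
    # rank 1 = best (smallest effect); ties broken by cluster id
    out = out.sort_values(["level", "prediction", "cluster_id"],
                          kind="stable").reset_index(drop=True)
    out["rank"] = out.groupby("level").cumcount() + 1
    extremes = {}
    for level in ("center", "surgeon"):
        sub = out[out.level == level].sort_values(
            ["prediction", "cluster_id"], kind="stable")
        extremes[level] = {"best": sub.iloc[0].cluster_id,
                           "worst": sub.iloc[-1].cluster_id}
    out.attrs["extremes"] = extremes
    out.attrs["method"] = method
    return out
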