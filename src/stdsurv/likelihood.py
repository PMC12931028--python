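"""Marginal likelihood of the three-level Weibull PH random-intercept model.

The hazard for subject i treated by surgeon j at center k is

    h_ijk(t) = p * lam * t**(p-1) * exp(X_ijk @ beta + alpha_jk + gamma_k)

with alpha_jk ~ N(0, var_surgeon) and gamma_k ~ N(0, var_center) independent.
The marginal likelihood of a center integrates its surgeons' intercepts and
its own intercept out:

    L_k = Int phi(g; var_center) Prod_j [ Int phi(a; var_surgeon)
              Prod_i f_ijk(a, g) da ] dg

Both integrals are one-dimensional and are evaluated by adaptive
Gauss-Hermite quadrature: nodes are recentered at the conditional mode and
rescaled by the curvature there.  The Weibull likelihood makes the inner
(surgeon) problem analytically tractable: given the total frailty
u = alpha + gamma, a surgeon's conditional log-likelihood collapses to
``C + D*u - B*exp(u)`` with per-surgeon sufficient statistics (D events,
B cumulated baseline hazard, C a constant), so the inner mode solves a
scalar concave equation by Newton iteration, vectorized across surgeons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss

from .data import SurvivalDataset

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class ModelParams:
    """Parameters of the three-level Weibull PH model.

    ``shape`` (p) and ``scale`` (lam) are the Weibull baseline parameters,
    ``beta`` the fixed-effect coefficients, and ``var_surgeon`` /
    ``var_center`` the random-intercept variances.
    """

    shape: float
    scale: float
    beta: np.ndarray
    var_surgeon: float = 0.0
    var_center: float = 0.0

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.var_surgeon < 0 or self.var_center < 0:
            raise ValueError("variances must be >= 0")

    def copy(self) -> "ModelParams":
        return ModelParams(self.shape, self.scale, self.beta.copy(),
                           self.var_surgeon, self.var_center)


def subject_loglik_conditional(params: ModelParams, record, alpha: float,
                               gamma: float) -> float:
    """Conditional log-likelihood of one subject given its random effects.

    Returns ``d*log h(t) - H(t)`` with ``h`` and ``H`` the conditional hazard
    and cumulative hazard, i.e. the log of f(t)^d * S(t)^(1-d).

    ``record`` needs attributes ``time``, ``event`` and ``covariates``
    (a :class:`~stdsurv.data.SubjectRecord` or any row-like object).
    """
    t = float(record.time)
    d = int(record.event)
    x = np.asarray(record.covariates, float)
    p, lam = params.shape, params.scale
    eta = float(x @ params.beta) + alpha + gamma if x.size else alpha + gamma
    if t == 0.0:
        if d == 1:
            raise ValueError("event at time 0: hazard undefined at the origin")
        return 0.0
    H = lam * t ** p * np.exp(eta)
    if d == 0:
        return -H
    return np.log(p * lam) + (p - 1.0) * np.log(t) + eta - H


def _logphi(x, var):
    return -0.5 * (_LOG_2PI + np.log(var)) - 0.5 * x * x / var


class WeibullPHEngine:
    """Vectorized likelihood/posterior machinery for one dataset.

    Holds per-surgeon sufficient statistics as functions of the parameters
    and the Gauss-Hermite rule; warm-starts the center-level mode search
    across successive calls (the optimizer changes parameters smoothly).
    """

    def __init__(self, dataset: SurvivalDataset, nodes: int = 15):
        if nodes < 3:
            raise ValueError("quadrature needs at least 3 nodes")
        self.dataset = dataset
        self.nodes = int(nodes)
        x, w = hermgauss(self.nodes)
        self._gh_x = x
        self._gh_logw = np.log(w)

        ds = dataset
        self.t = ds.time
        self.d = ds.event.astype(float)
        self.X = ds.X
        self.surg_idx = ds.surgeon_idx
        self.S = ds.n_surgeons
        self.K = ds.n_centers
        self.surgeon_center = ds.surgeon_center
        # reduceat boundaries require surgeons sorted by center
        order = np.argsort(ds.surgeon_center, kind="stable")
        self._surgeon_order = order
        sc_sorted = ds.surgeon_center[order]
        self._seg_starts = np.searchsorted(sc_sorted, np.arange(self.K))
        self._logt = np.log(self.t)
        self._gamma_warm = np.zeros(self.K)

    # -- sufficient statistics -------------------------------------------

    def suffstats(self, params: ModelParams):
        """Per-surgeon (B, D, C): cumulated baseline hazard at the observed
        times, event count, and the frailty-free part of the event terms."""
        p, lam = params.shape, params.scale
        lp = self.X @ params.beta if self.X.shape[1] else np.zeros(len(self.t))
        logw = np.log(lam) + p * self._logt + lp
        B = np.bincount(self.surg_idx, np.exp(np.clip(logw, -700, 700)),
                        minlength=self.S)
        D = np.bincount(self.surg_idx, self.d, minlength=self.S)
        logh = np.log(p) + np.log(lam) + (p - 1.0) * self._logt + lp
        C = np.bincount(self.surg_idx, self.d * logh, minlength=self.S)
        return B, D, C

    # -- inner (surgeon-level) integral ----------------------------------

    @staticmethod
    def _inner_mode(B, D, va, g, tol=1e-11, max_iter=100):
        """Mode of a(alpha) = D*(alpha+g) - B*exp(alpha+g) - alpha^2/(2 va),
        solved by damped Newton, vectorized over any broadcastable shape."""
        m = np.zeros(np.broadcast(B, g).shape)
        for _ in range(max_iter):
            E = B * np.exp(np.clip(m + g, -700, 700))
            f = D - E - m / va
            fp = -E - 1.0 / va
            step = -f / fp
            np.clip(step, -4.0, 4.0, out=step)
            m += step
            if np.max(np.abs(step)) < tol:
                break
        return m

    def _log_inner(self, B, D, va, g, with_moments: bool = False):
        """log of the inner integral  Int exp(D*(a+g) - B*exp(a+g))
        phi(a; va) da  for per-surgeon statistics B, D and center effect g
        (broadcastable).  With ``with_moments`` also returns the conditional
        posterior mean and second moment of alpha given g.
        """
        if va == 0.0:
            val = D * g - B * np.exp(g)
            if with_moments:
                z = np.zeros(np.broadcast(B, g).shape)
                return val, z, z
            return val
        m = self._inner_mode(B, D, va, g)
        h = B * np.exp(np.clip(m + g, -700, 700)) + 1.0 / va
        sig = np.sqrt(2.0 / h)
        # nodes along a trailing axis
        a = m[..., None] + sig[..., None] * self._gh_x
        ga = (
            D[..., None] * (a + g[..., None])
            - B[..., None] * np.exp(np.clip(a + g[..., None], -700, 700))
            + _logphi(a, va)
        )
        logsum = self._gh_logw + self._gh_x ** 2 + ga
        mx = logsum.max(axis=-1)
        wts = np.exp(logsum - mx[..., None])
        s0 = wts.sum(axis=-1)
        val = np.log(sig) + mx + np.log(s0)
        if with_moments:
            mean = (wts * a).sum(axis=-1) / s0
            second = (wts * a * a).sum(axis=-1) / s0
            return val, mean, second
        return val

    # -- outer (center-level) integral -----------------------------------

    def _center_sum(self, per_surgeon):
        """Sum a per-surgeon array into per-center totals (leading axis S)."""
        ordered = per_surgeon[self._surgeon_order]
        return np.add.reduceat(ordered, self._seg_starts, axis=0)

    def _F(self, B, D, va, gamma_per_center):
        """Sum over surgeons of log inner integrals, per center.
        ``gamma_per_center`` has shape (K,) or (K, Q)."""
        g = gamma_per_center[self.surgeon_center]
        Bs = B if g.ndim == 1 else B[:, None]
        Ds = D if g.ndim == 1 else D[:, None]
        return self._center_sum(self._log_inner(Bs, Ds, va, g))

    def _outer_mode(self, B, D, va, vg, warm=None, tol=1e-9, max_iter=60,
                    fd_step=1e-5):
        """Mode and curvature of F_pen(gamma) = F(gamma) + log phi(gamma; vg)
        per center, by finite-difference Newton with damping."""
        g = np.zeros(self.K) if warm is None else warm.copy()

        def fpen(gv):
            return self._F(B, D, va, gv) + _logphi(gv, vg)

        h = fd_step
        for _ in range(max_iter):
            f0 = fpen(g)
            fp = (fpen(g + h) - fpen(g - h)) / (2 * h)
            fpp = (fpen(g + h) - 2 * f0 + fpen(g - h)) / (h * h)
            fpp = np.minimum(fpp, -1e-10)
            step = np.clip(-fp / fpp, -1.5, 1.5)
            g = g + step
            if np.max(np.abs(step)) < tol:
                break
        f0 = fpen(g)
        fpp = (fpen(g + h) - 2 * f0 + fpen(g - h)) / (h * h)
        H = np.maximum(-fpp, 1e-10)
        return g, H

    def center_gamma_quadrature(self, params: ModelParams, suff=None):
        """Adaptive quadrature rule for the center-level posteriors.

        Returns ``(gnodes, logint, logwts)`` where ``gnodes`` has shape
        (K, Q) with the recentered gamma nodes per center, ``logint`` the
        per-center log marginal likelihood contribution excluding the
        event-term constant, and ``logwts`` (K, Q) the log of unnormalized
        quadrature weights of the gamma posterior at the nodes.
        """
        B, D, C = self.suffstats(params) if suff is None else suff
        va, vg = params.var_surgeon, params.var_center
        if vg == 0.0:
            g0 = np.zeros((self.K, 1))
            logF = self._F(B, D, va, np.zeros(self.K))[:, None]
            return g0, logF[:, 0], logF
        mode, H = self._outer_mode(B, D, va, vg, warm=self._gamma_warm)
        self._gamma_warm = mode
        sig = np.sqrt(2.0 / H)
        gnodes = mode[:, None] + sig[:, None] * self._gh_x
        fvals = self._F(B, D, va, gnodes) + _logphi(gnodes, vg)
        logwts = self._gh_logw + self._gh_x ** 2 + fvals
        mx = logwts.max(axis=1)
        logint = np.log(sig) + mx + np.log(
            np.exp(logwts - mx[:, None]).sum(axis=1)
        )
        return gnodes, logint, logwts

    def center_logliks(self, params: ModelParams) -> np.ndarray:
        """Marginal log-likelihood contribution of each center."""
        suff = self.suffstats(params)
        _, logint, _ = self.center_gamma_quadrature(params, suff)
        C = suff[2]
        return logint + self._center_sum(C)

    def loglik(self, params: ModelParams) -> float:
        """Total marginal log-likelihood."""
        return float(self.center_logliks(params).sum())


def cluster_log_likelihood(params: ModelParams, dataset: SurvivalDataset,
                           center_id, nodes: int = 15) -> float:
    """Marginal log-likelihood contribution of one center.

    Integrates the center's intercept and its surgeons' intercepts out of the
    conditional likelihood by nested adaptive Gauss-Hermite quadrature; zero
    variance components collapse the corresponding integral to a point mass
    at zero.
    """
    engine = WeibullPHEngine(dataset, nodes=nodes)
    k = dataset.center_code(center_id)
    return float(engine.center_logliks(params)[k])


def total_log_likelihood(params: ModelParams, dataset: SurvivalDataset,
                         nodes: int = 15) -> float:
    """Marginal log-likelihood of the whole dataset (sum over centers)."""
    return WeibullPHEngine(dataset, nodes=nodes).loglik(params)
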