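"""Model and results classes for the three-level Weibull PH mixed model.

Follows the model/results split common in statistical packages: build a
:class:`MultilevelWeibullPH` from data, call :meth:`~MultilevelWeibullPH.fit`,
and work with the returned :class:`MultilevelWeibullPHResults` (estimates,
covariance, summary table, posterior predictions, standardization).
"""

from __future__ import annotations

import json
import time as _time

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import Schema, SurvivalDataset, read_dataset
from .likelihood import ModelParams, WeibullPHEngine


class Parametrization:
    """Maps between :class:`ModelParams` and the internal optimization
    vector.  Positive parameters (shape, scale, variances) are
    log-transformed; variance components may be fixed (excluded from the
    vector), typically at zero."""

    def __init__(self, covariate_names, fix_var_surgeon=None, fix_var_center=None):
        self.covariate_names = list(covariate_names)
        self.fix_var_surgeon = fix_var_surgeon
        self.fix_var_center = fix_var_center
        self.names = ["log(shape)", "log(scale)"] + list(self.covariate_names)
        self.transform = ["log", "log"] + ["identity"] * len(self.covariate_names)
        if fix_var_surgeon is None:
            self.names.append("log(var_surgeon)")
            self.transform.append("log")
        if fix_var_center is None:
            self.names.append("log(var_center)")
            self.transform.append("log")

    @property
    def k(self) -> int:
        return len(self.names)

    def pack(self, params: ModelParams) -> np.ndarray:
        v = [np.log(params.shape), np.log(params.scale), *params.beta]
        if self.fix_var_surgeon is None:
            v.append(np.log(max(params.var_surgeon, 1e-12)))
        if self.fix_var_center is None:
            v.append(np.log(max(params.var_center, 1e-12)))
        return np.asarray(v, float)

    def unpack(self, vector: np.ndarray) -> ModelParams:
        q = len(self.covariate_names)
        i = 2 + q
        # clip so extreme MVN draws on the log scale stay representable
        va = self.fix_var_surgeon
        if va is None:
            va = float(np.exp(np.clip(vector[i], -700.0, 50.0)))
            i += 1
        vg = self.fix_var_center
        if vg is None:
            vg = float(np.exp(np.clip(vector[i], -700.0, 50.0)))
            i += 1
        return ModelParams(
            shape=float(np.exp(np.clip(vector[0], -50, 50))),
            scale=float(np.exp(np.clip(vector[1], -50, 50))),
            beta=np.asarray(vector[2:2 + q], float),
            var_surgeon=va,
            var_center=vg,
        )

    def bounds(self):
        b = [(-3.0, 3.0), (-20.0, 8.0)] + [(-30.0, 30.0)] * len(self.covariate_names)
        n_var = (self.fix_var_surgeon is None) + (self.fix_var_center is None)
        b += [(-12.0, 5.0)] * n_var
        return b


class MultilevelWeibullPH:
    """Three-level Weibull proportional-hazards model with nested normal
    random intercepts at the surgeon and center levels.

    Parameters
    ----------
    dataset : SurvivalDataset
        Hierarchical survival data (see :mod:`stdsurv.data`).

    Examples
    --------
    >>> model = MultilevelWeibullPH.from_dataframe(df, covariates=["age"])
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, dataset: SurvivalDataset):
        if dataset.n_events < 1:
            raise ValueError("dataset has no events; likelihood is degenerate")
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, covariates,
                       time="time", event="event", surgeon="surgeon",
                       center="center") -> "MultilevelWeibullPH":
        out = frame.rename(columns={time: "time", event: "event",
                                    surgeon: "surgeon", center: "center"})
        return cls(SurvivalDataset(out, covariates))

    @classmethod
    def from_csv(cls, path, schema: Schema | None = None) -> "MultilevelWeibullPH":
        return cls(read_dataset(path, schema))

    # -- likelihood -------------------------------------------------------

    def loglike(self, params: ModelParams, nodes: int = 15) -> float:
        """Marginal log-likelihood at ``params``."""
        return WeibullPHEngine(self.dataset, nodes=nodes).loglik(params)

    # -- estimation -------------------------------------------------------

    def _start_values(self, nodes: int) -> ModelParams:
        """Cheap single-level Weibull PH fit (variances fixed at zero)."""
        ds = self.dataset
        lam0 = ds.n_events / max(ds.time.sum(), 1e-12)
        start = ModelParams(1.0, lam0, np.zeros(ds.n_covariates), 0.0, 0.0)
        par = Parametrization(ds.covariate_names, fix_var_surgeon=0.0,
                              fix_var_center=0.0)
        engine = WeibullPHEngine(ds, nodes=nodes)

        nll = _robust_nll(engine, par)
        res = minimize(nll, par.pack(start), method="L-BFGS-B",
                       bounds=par.bounds(), options={"maxiter": 200})
        return par.unpack(res.x)

    def fit(self, start: ModelParams | None = None, nodes: int = 15,
            fix_var_surgeon: float | None = None,
            fix_var_center: float | None = None,
            start_variance: float = 0.05, maxiter: int = 500,
            gtol: float = 1e-6, compute_vcov: bool = True
            ) -> "MultilevelWeibullPHResults":
        """Maximize the marginal likelihood by quasi-Newton iteration on the
        log-transformed parameter space.

        Parameters
        ----------
        start : ModelParams, optional
            Starting values; defaults to a single-level Weibull PH fit for
            the baseline and covariate effects with both variances started
            at ``start_variance``.
        nodes : int
            Gauss-Hermite nodes per integration level.
        fix_var_surgeon, fix_var_center : float, optional
            Fix a variance component (commonly at 0.0) instead of
            estimating it.
        compute_vcov : bool
            Compute the covariance of the transformed parameters from a
            finite-difference Hessian at the optimum (needed for Monte-Carlo
            confidence intervals).
        """
        ds = self.dataset
        t0 = _time.perf_counter()
        if start is None:
            base = self._start_values(nodes)
            start = ModelParams(
                base.shape, base.scale, base.beta,
                fix_var_surgeon if fix_var_surgeon is not None else start_variance,
                fix_var_center if fix_var_center is not None else start_variance,
            )
        par = Parametrization(ds.covariate_names, fix_var_surgeon, fix_var_center)
        engine = WeibullPHEngine(ds, nodes=nodes)
        nll = _robust_nll(engine, par)
        opt = minimize(nll, par.pack(start), method="L-BFGS-B",
                       bounds=par.bounds(),
                       options={"maxiter": maxiter, "gtol": gtol,
                                "ftol": 1e-11})
        params = par.unpack(opt.x)
        vcov = None
        vcov_ok = False
        if compute_vcov:
            vcov, vcov_ok = _fd_vcov(nll, opt.x)
        return MultilevelWeibullPHResults(
            model=self, params=params, loglik=-float(opt.fun),
            transformed=np.asarray(opt.x, float), parametrization=par,
            vcov=vcov, vcov_ok=vcov_ok, converged=bool(opt.success),
            niter=int(opt.nit), message=str(opt.message), nodes=nodes,
            fit_seconds=_time.perf_counter() - t0,
        )


def _robust_nll(engine, par):
    """Negative log-likelihood that stays finite so line searches can
    backtrack out of numerically hostile regions."""

    def nll(v):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            try:
                val = -engine.loglik(par.unpack(v))
            except (FloatingPointError, ValueError):
                return 1e12
        return val if np.isfinite(val) else 1e12

    return nll


def _fd_vcov(nll, x):
    """Covariance from a central finite-difference Hessian of the negative
    log-likelihood; returns (vcov, ok)."""
    k = len(x)
    H = np.empty((k, k))
    h = np.maximum(1e-4, 1e-4 * np.abs(x))
    f0 = nll(x)

    def at(dx):
        return nll(x + dx)

    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (at(ei) - 2 * f0 + at(-ei)) / (h[i] ** 2)
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                at(ei + ej) - at(ei - ej) - at(-ei + ej) + at(-ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        evals = np.linalg.eigvalsh(H)
        if evals.min() <= 0:
            return None, False
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, False
    return vcov, True


class MultilevelWeibullPHResults:
    """Fitted three-level Weibull PH mixed model.

    Attributes
    ----------
    params : ModelParams
        Estimates on the natural scale.
    loglik : float
        Maximized marginal log-likelihood.
    vcov : ndarray or None
        Covariance of the *transformed* parameters (log scale for positive
        parameters); ``parametrization.transform`` records the map.
    converged : bool
        Optimizer convergence status; failures are reported, not hidden.
    """

    def __init__(self, model, params, loglik, transformed, parametrization,
                 vcov, vcov_ok, converged, niter, message, nodes,
                 fit_seconds=float("nan")):
        self.model = model
        self.params = params
        self.loglik = loglik
        self.transformed = transformed
        self.parametrization = parametrization
        self.vcov = vcov
        self.vcov_ok = vcov_ok
        self.converged = converged
        self.niter = niter
        self.message = message
        self.nodes = nodes
        self.fit_seconds = fit_seconds

    @property
    def dataset(self) -> SurvivalDataset:
        return self.model.dataset

    @property
    def param_names(self):
        return list(self.parametrization.names)

    @property
    def bse(self):
        """Standard errors of the transformed parameters (NaN when the
        Hessian was singular)."""
        if self.vcov is None:
            return np.full(len(self.transformed), np.nan)
        return np.sqrt(np.diag(self.vcov))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald intervals on the transformed scale, back-transformed to the
        natural scale for log-mapped parameters."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        lo = self.transformed - z * se
        hi = self.transformed + z * se
        natural = [
            (np.exp(a), np.exp(b)) if tr == "log" else (a, b)
            for a, b, tr in zip(lo, hi, self.parametrization.transform)
        ]
        return pd.DataFrame(natural, index=self.param_names,
                            columns=["lower", "upper"])

    def natural_estimates(self) -> pd.Series:
        vals = [
            np.exp(v) if tr == "log" else v
            for v, tr in zip(self.transformed, self.parametrization.transform)
        ]
        names = [n.replace("log(", "").replace(")", "") for n in self.param_names]
        return pd.Series(vals, index=names)

    def summary(self) -> str:
        """Plain-text estimation summary."""
        p = self.params
        lines = [
            "Three-level Weibull PH mixed model",
            "=" * 58,
            f"subjects: {self.dataset.n}   surgeons: {self.dataset.n_surgeons}"
            f"   centers: {self.dataset.n_centers}",
            f"events: {self.dataset.n_events}"
            f"   log-likelihood: {self.loglik:.4f}",
            f"converged: {self.converged} ({self.niter} iterations)",
            "-" * 58,
            f"{'parameter':<22}{'estimate':>12}{'std.err.':>12}",
        ]
        se = self.bse
        natural = self.natural_estimates()
        for name, t_est, s in zip(self.param_names, self.transformed, se):
            lines.append(f"{name:<22}{t_est:>12.4f}{s:>12.4f}")
        lines.append("-" * 58)
        lines.append("natural scale:")
        for name, v in natural.items():
            lines.append(f"  {name:<20}{v:>12.4f}")
        fixed = []
        if self.parametrization.fix_var_surgeon is not None:
            fixed.append(f"var_surgeon={p.var_surgeon:g}")
        if self.parametrization.fix_var_center is not None:
            fixed.append(f"var_center={p.var_center:g}")
        if fixed:
            lines.append("fixed: " + ", ".join(fixed))
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- downstream conveniences -----------------------------------------

    def predict_random_effects(self, method: str = "mean",
                               nodes: int = 30) -> pd.DataFrame:
        """Empirical-Bayes predictions for every surgeon and center."""
        from .posterior import predict_all

        return predict_all(self, self.dataset, method=method, nodes=nodes)

    def standardized_survival(self, *args, **kwargs):
        """See :func:`stdsurv.standardize.standardize_fixed`."""
        from .standardize import standardize_fixed

        return standardize_fixed(self, *args, **kwargs)

    def median_hazard_ratio(self, level: str = "center") -> float:
        """Median hazard ratio implied by a variance component."""
        from .uncertainty import median_hazard_ratio

        var = (self.params.var_center if level == "center"
               else self.params.var_surgeon)
        return median_hazard_ratio(var)

    # -- serialization (fit.json interchange) ----------------------------

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {
                "shape": p.shape, "scale": p.scale,
                "beta": {n: float(b) for n, b in
                         zip(self.dataset.covariate_names, p.beta)},
                "var_surgeon": p.var_surgeon, "var_center": p.var_center,
            },
            "param_names": self.param_names,
            "transform": self.parametrization.transform,
            "transformed": [float(v) for v in self.transformed],
            "fixed": {"var_surgeon": self.parametrization.fix_var_surgeon,
                      "var_center": self.parametrization.fix_var_center},
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "vcov_ok": self.vcov_ok,
            "loglik": self.loglik,
            "converged": self.converged,
            "niter": self.niter,
            "message": self.message,
            "nodes": self.nodes,
            "covariate_names": self.dataset.covariate_names,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path, dataset: SurvivalDataset
                  ) -> "MultilevelWeibullPHResults":
        with open(path) as fh:
            d = json.load(fh)
        if d["covariate_names"] != dataset.covariate_names:
            raise ValueError(
                "fit covariates do not match the dataset: "
                f"{d['covariate_names']} vs {dataset.covariate_names}"
            )
        par = Parametrization(d["covariate_names"],
                              d["fixed"]["var_surgeon"],
                              d["fixed"]["var_center"])
        pd_ = d["params"]
        params = ModelParams(pd_["shape"], pd_["scale"],
                             np.array(list(pd_["beta"].values())),
                             pd_["var_surgeon"], pd_["var_center"])
        return cls(
            model=MultilevelWeibullPH(dataset), params=params,
            loglik=d["loglik"], transformed=np.array(d["transformed"]),
            parametrization=par,
            vcov=None if d["vcov"] is None else np.array(d["vcov"]),
            vcov_ok=d["vcov_ok"], converged=d["converged"],
            niter=d["niter"], message=d["message"], nodes=d["nodes"],
        )
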