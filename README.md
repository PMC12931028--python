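# stdsurv

Standardized survival probabilities and contrasts between hierarchical
units in multilevel parametric survival models.

## The problem

Survival data in medicine is often hierarchical: patients are treated by
surgeons, who operate within centers. Mixed-effects survival models absorb
the resulting within-cluster correlation with random intercepts, but the
usual outputs (variance components, hazard ratios) say little about *which*
center or surgeon performs well, on an interpretable scale. `stdsurv`
answers that question for provider-profiling and risk-adjustment analyses:
it fits a three-level Weibull proportional-hazards model with nested normal
random intercepts, predicts each cluster's effect by empirical Bayes, and
converts those effects into **directly standardized survival curves** —
"how would the whole study population have fared under this surgeon /
center?" — together with contrasts (adjusted risk differences), Monte-Carlo
confidence intervals, median-hazard-ratio summaries and cluster rankings.

## The model

For patient $i$ of surgeon $j$ in center $k$, with case-mix covariates
$X_{ijk}$, the hazard is

$$\lambda_{ijk}(t) = p\,\lambda\,t^{p-1}
  \exp(X_{ijk}\beta + \alpha_{jk} + \gamma_k),\qquad
  \alpha_{jk}\sim N(0,\sigma^2_\alpha),\ \ \gamma_k\sim N(0,\sigma^2_\gamma),$$

with a Weibull baseline (shape $p$, scale $\lambda$) and independent nested
random intercepts. The marginal likelihood integrates the intercepts out by
nested adaptive Gauss–Hermite quadrature, and the parameter covariance
comes from the numerically differentiated Hessian at the optimum.

Cluster performance is summarized by standardized survival probabilities

$$\hat S^{(j^*,k^*)}(t) = \frac1n\sum_{i,j,k}
  S_0(t)^{\exp(X_{ijk}\hat\beta + \tilde\alpha_{j^*k^*} + \tilde\gamma_{k^*})},$$

where $\tilde\alpha,\tilde\gamma$ are empirical-Bayes posterior means and
$S_0(t)=\exp(-\lambda t^p)$; one level can instead be marginalized over its
estimated $N(0,\hat\sigma^2)$ distribution, and setting an effect to zero
gives the *theoretical average* cluster. Differences between such curves
are case-mix-adjusted risk differences. Confidence intervals re-evaluate
any such quantity under $B$ joint draws of the parameters (multivariate
normal on the transformed scale) and the random effects (normal posterior
approximations), and take empirical percentiles.

## Worked example

```python
import numpy as np
from stdsurv import (MultilevelWeibullPH, studylike_config, predict_all,
                     simulate_dataset, standardize_fixed, median_hazard_ratio)

ds, truth = simulate_dataset(studylike_config(), seed=1)   # 1,260 patients,
model = MultilevelWeibullPH(ds)                            # 63 surgeons, 21 centers
res = model.fit()
print(f"var_surgeon={res.params.var_surgeon:.4f}  "
      f"var_center={res.params.var_center:.4f}  "
      f"MHR(center)={median_hazard_ratio(res.params.var_center):.3f}")

eb = predict_all(res, ds)                     # empirical-Bayes predictions
best = eb.attrs["extremes"]["center"]["best"]
worst = eb.attrs["extremes"]["center"]["worst"]
t10 = np.array([10.0])
s_best = standardize_fixed(res, eb, center=best, times=t10).values[0]
s_worst = standardize_fixed(res, eb, center=worst, times=t10).values[0]
print(f"S(10 | best center)={s_best:.3f}  S(10 | worst center)={s_worst:.3f}  "
      f"difference={s_best - s_worst:.3f}")
```

prints

```
var_surgeon=0.0535  var_center=0.0224  MHR(center)=1.153
S(10 | best center)=0.163  S(10 | worst center)=0.070  difference=0.093
```

Read: the fitted center-level heterogeneity (0.022) implies that in a
random pair of centers the higher-risk one has a ~15% higher hazard at the
median; more tangibly, if the entire cohort were treated at the best
center (with an average surgeon) 16.3% would survive 10 years versus 7.0%
at the worst center — an adjusted risk difference of 9.3 percentage
points, since both numbers standardize over the same case-mix.

The same workflow is available from the shell:

```sh
stdsurv simulate --seed 1 --out data.csv
stdsurv fit --data data.csv --out fit.json
stdsurv predict-eb --fit fit.json --data data.csv --out eb.csv
stdsurv standardize --fit fit.json --eb eb.csv --data data.csv \
    --estimand fixed_center_marginal_surgeon --center c04 \
    --times 0:12:0.25 --ci-b 1000 --out std.csv
stdsurv rank --fit fit.json --eb eb.csv --data data.csv --time 10 --out rank.csv
```

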