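"""Standardized survival estimators: row-wise and Monte-Carlo oracles,
curve shape invariants, contrasts and ranking."""

import numpy as np
import pandas as pd
import pytest

from stdsurv import (
    ModelParams,
    MultilevelWeibullPH,
    conditional_survival,
    contrast,
    difference_estimand,
    rank_clusters,
    simulate_dataset,
    standardize_fixed,
    standardize_marginal,
    survival_estimand,
)
from stdsurv.simulate import CovariateSpec, SimulationConfig


def test_conditional_survival_basics():
    params = ModelParams(1.3, 0.2, [0.4])
    assert conditional_survival(params, [[1.0]], 0.3, -0.1, 0.0) == 1.0
    t = 2.5
    base = conditional_survival(params, [[0.0]], 0.0, 0.0, t)
    assert base == pytest.approx(np.exp(-0.2 * t ** 1.3), rel=1e-14)


def test_conditional_survival_ph_structure():
    """log(-log S) is linear in the linear predictor with slope one."""
    params = ModelParams(1.2, 0.15, [1.0])
    t = 3.0
    etas = np.array([-1.0, 0.0, 0.5, 2.0])
    vals = np.array([
        float(conditional_survival(params, [[e]], 0.0, 0.0, t)) for e in etas
    ])
    y = np.log(-np.log(vals))
    slope = np.polyfit(etas, y, 1)[0]
    assert slope == pytest.approx(1.0, rel=1e-10)


def test_standardize_fixed_is_rowwise_mean(small_fit, small_eb, small_dataset):
    ds = small_dataset
    eb = small_eb
    cid = ds.center_ids[0]
    sid = [s for c, s in ds.surgeon_pairs if c == cid][0]
    times = np.array([0.0, 1.0, 3.0, 6.0])
    est = standardize_fixed(small_fit, eb, surgeon=sid, center=cid,
                            times=times)
    alpha = float(eb[(eb.level == "surgeon") & (eb.cluster_id == sid)]
                  .prediction.iloc[0])
    gamma = float(eb[(eb.level == "center") & (eb.cluster_id == cid)]
                  .prediction.iloc[0])
    for j, t in enumerate(times):
        rows = [
            float(conditional_survival(small_fit.params, [ds.X[i]],
                                       alpha, gamma, t))
            for i in range(ds.n)
        ]
        assert est.values[j] == pytest.approx(np.mean(rows), rel=1e-12)
    assert est.values[0] == 1.0
    assert np.all(np.diff(est.values) <= 0)


def test_single_subject_population(small_fit, small_eb, small_dataset):
    ds = small_dataset
    times = np.array([2.0])
    est = standardize_fixed(small_fit, small_eb, times=times,
                            population=np.array([3]))
    expect = conditional_survival(small_fit.params, [ds.X[3]], 0.0, 0.0, 2.0)
    assert est.values[0] == pytest.approx(float(expect), rel=1e-14)
    assert est.population_size == 1


def test_empty_population_rejected(small_fit, small_eb):
    with pytest.raises(ValueError, match="empty"):
        standardize_fixed(small_fit, small_eb, times=[1.0],
                          population=np.array([], dtype=int))


def test_marginal_with_zero_variance_equals_fixed_at_zero(small_dataset,
                                                          small_eb,
                                                          plug_in_fit):
    params = ModelParams(1.2, 0.1, [0.5, -0.3], var_surgeon=0.0,
                         var_center=0.1)
    fit = plug_in_fit(params)
    cid = small_dataset.center_ids[1]
    times = np.linspace(0, 8, 17)
    marg = standardize_marginal(fit, small_eb, center=cid, times=times,
                                dataset=small_dataset)
    fixed = standardize_fixed(fit, small_eb, surgeon=None, center=cid,
                              times=times, dataset=small_dataset)
    np.testing.assert_allclose(marg.values, fixed.values, rtol=0, atol=1e-14)


def test_marginal_matches_monte_carlo(small_fit, small_eb, small_dataset):
    ds = small_dataset
    cid = ds.center_ids[0]
    times = np.array([1.0, 5.0])
    est = standardize_marginal(small_fit, small_eb, center=cid, times=times)
    gamma = float(small_eb[(small_eb.level == "center")
                           & (small_eb.cluster_id == cid)].prediction.iloc[0])
    rng = np.random.default_rng(123)
    n_mc = 100_000
    a = rng.normal(0, np.sqrt(small_fit.params.var_surgeon), n_mc)
    lp = ds.X @ small_fit.params.beta
    for j, t in enumerate(times):
        logS0 = -small_fit.params.scale * t ** small_fit.params.shape
        per_draw = np.concatenate([
            np.exp(logS0 * np.exp(lp[None, :] + gamma + chunk[:, None])
                   ).mean(axis=1)
            for chunk in np.array_split(a, 20)
        ])
        mc = per_draw.mean()
        se = per_draw.std(ddof=1) / np.sqrt(len(per_draw))
        assert abs(est.values[j] - mc) < 3 * se + 1e-6


def test_jensen_direction_follows_curvature(small_fit, small_eb,
                                            small_dataset):
    """g -> S0(t)^exp(lp + g) is convex in g exactly where the conditional
    survival is below 1/e (cumulative hazard > 1) and concave above it, so
    marginalizing a positive-variance effect lifts the curve below the
    1/e line and depresses it above."""
    from stdsurv import conditional_survival

    ds = small_dataset
    cid = ds.center_ids[2]
    gamma = float(small_eb[(small_eb.level == "center")
                           & (small_eb.cluster_id == cid)].prediction.iloc[0])

    def rowwise(t):
        return np.array([
            float(conditional_survival(small_fit.params, [ds.X[i]], 0.0,
                                       gamma, t))
            for i in range(ds.n)
        ])

    # pick one early time where every subject survives above 1/e and one
    # late time where every subject is below it
    t_lo = 1.0
    while not np.all(rowwise(t_lo) > np.exp(-1) + 0.02):
        t_lo /= 2
    t_hi = 8.0
    while not np.all(rowwise(t_hi) < np.exp(-1) - 0.02):
        t_hi *= 1.5
    times = np.array([t_lo, t_hi])
    marg = standardize_marginal(small_fit, small_eb, center=cid, times=times)
    fixed = standardize_fixed(small_fit, small_eb, surgeon=None, center=cid,
                              times=times)
    assert small_fit.params.var_surgeon > 0
    assert marg.values[0] < fixed.values[0]  # concave region
    assert marg.values[1] > fixed.values[1]  # convex region


def test_standardized_curve_bounded_by_constituents(small_fit, small_eb,
                                                    small_dataset):
    ds = small_dataset
    times = np.array([4.0])
    est = standardize_fixed(small_fit, small_eb, times=times)
    rows = np.array([
        float(conditional_survival(small_fit.params, [ds.X[i]], 0.0, 0.0, 4.0))
        for i in range(ds.n)
    ])
    assert rows.min() <= est.values[0] <= rows.max()


def test_contrast_properties(small_fit, small_eb, small_dataset):
    ds = small_dataset
    times = np.linspace(0, 8, 33)
    a = standardize_fixed(small_fit, small_eb, center=ds.center_ids[0],
                          times=times)
    b = standardize_fixed(small_fit, small_eb, center=ds.center_ids[1],
                          times=times)
    d_ab = contrast(a, b)
    d_ba = contrast(b, a)
    np.testing.assert_allclose(d_ab.differences, -d_ba.differences, atol=1e-15)
    np.testing.assert_allclose(contrast(a, a).differences, 0.0, atol=1e-15)
    assert np.all(np.abs(d_ab.differences) <= 1.0)

    mismatched = standardize_fixed(small_fit, small_eb,
                                   center=ds.center_ids[1],
                                   times=times[:-1])
    with pytest.raises(ValueError, match="grid"):
        contrast(a, mismatched)
    other_pop = standardize_fixed(small_fit, small_eb,
                                  center=ds.center_ids[1], times=times,
                                  population=np.arange(10))
    with pytest.raises(ValueError, match="population"):
        contrast(a, other_pop)


def test_unknown_cluster_rejected(small_fit, small_eb):
    with pytest.raises(KeyError):
        standardize_fixed(small_fit, small_eb, center="nope", times=[1.0])


def test_extrapolation_fraction_reported(small_fit, small_eb, small_dataset):
    ds = small_dataset
    cid = ds.center_ids[0]
    est = standardize_fixed(small_fit, small_eb, center=cid, times=[1.0])
    own = (ds.center_idx == 0).mean()
    assert est.extrapolation_fraction == pytest.approx(1 - own)
    own_pop = standardize_fixed(small_fit, small_eb, center=cid, times=[1.0],
                                population=cid)
    assert own_pop.extrapolation_fraction == 0.0


def test_marginal_center_curve_near_average_of_its_surgeons(
        small_fit, small_eb, small_dataset):
    """A center's marginal-over-surgeons curve lies inside the envelope of
    the fixed (center, surgeon) curves and near their average."""
    ds = small_dataset
    cid = ds.center_ids[0]
    times = np.linspace(0.5, 8, 16)
    marg = standardize_marginal(small_fit, small_eb, center=cid, times=times)
    fixed_curves = np.array([
        standardize_fixed(small_fit, small_eb, surgeon=sid, center=cid,
                          times=times).values
        for c, sid in ds.surgeon_pairs if c == cid
    ])
    lo = fixed_curves.min(axis=0) - 0.02
    hi = fixed_curves.max(axis=0) + 0.02
    assert np.all(marg.values >= lo) and np.all(marg.values <= hi)
    assert np.max(np.abs(marg.values - fixed_curves.mean(axis=0))) < 0.03


def test_two_level_model_gives_similar_center_curves(small_dataset, small_eb):
    """Centers-only (two-level) fit produces center-standardized curves
    close to the three-level marginal-over-surgeon curves."""
    three = MultilevelWeibullPH(small_dataset).fit(nodes=9)
    two = MultilevelWeibullPH(small_dataset).fit(nodes=9, fix_var_surgeon=0.0)
    from stdsurv import predict_all

    eb3 = predict_all(three, small_dataset)
    eb2 = predict_all(two, small_dataset)
    times = np.linspace(0, 8, 17)
    gap = 0.0
    for cid in small_dataset.center_ids:
        c3 = standardize_marginal(three, eb3, center=cid, times=times)
        c2 = standardize_fixed(two, eb2, surgeon=None, center=cid,
                               times=times)
        gap = max(gap, np.max(np.abs(c3.values - c2.values)))
    assert gap < 0.03


def test_rank_clusters_policies():
    est = {f"c{i}": 0.5 for i in range(4)}
    bands = {f"c{i}": (0.4, 0.6) for i in range(4)}
    table = rank_clusters(est, reference=0.5, bands=bands)
    assert (table.category == "medium").all()

    est2 = {"good": 0.8, "mid": 0.5, "bad": 0.1}
    bands2 = {"good": (0.7, 0.9), "mid": (0.4, 0.6), "bad": (0.05, 0.2)}
    table2 = rank_clusters(est2, reference=0.5, bands=bands2)
    cat = dict(zip(table2.cluster_id, table2.category))
    assert cat == {"good": "low", "mid": "medium", "bad": "high"}
    assert list(table2.cluster_id) == ["good", "mid", "bad"]

    # ranking invariant to input order
    reordered = rank_clusters(dict(reversed(list(est2.items()))),
                              reference=0.5, bands=bands2)
    pd.testing.assert_frame_equal(table2, reordered)

    # no CIs: uncategorized unless terciles requested
    t3 = rank_clusters(est2, reference=0.5)
    assert (t3.category == "uncategorized").all()
    t4 = rank_clusters({f"c{i}": i / 8 for i in range(9)}, policy="tercile")
    assert list(t4.category.value_counts()) == [3, 3, 3]


def test_planted_outlier_flagged_high_risk(plug_in_fit):
    """A center simulated with a large harmful effect lands in the
    high-risk category of the CI-overlap rule."""
    cfg = SimulationConfig(
        n_centers=6, surgeons_per_center=2, patients_per_surgeon=40,
        shape=1.2, scale=0.1, beta=[0.5],
        covariates=[CovariateSpec("x", "normal")],
        var_surgeon=0.01, var_center=0.01, admin_censoring=8.0, seed=31,
    )
    ds, _ = simulate_dataset(cfg)
    # plant the outlier: rescale the last center's times sharply downward
    frame = ds.frame.copy()
    bad = ds.center_ids[-1]
    sel = frame.center == bad
    frame.loc[sel, "time"] = frame.loc[sel, "time"] / 6.0
    from stdsurv import SurvivalDataset, predict_all

    ds2 = SurvivalDataset(frame, ds.covariate_names)
    res = MultilevelWeibullPH(ds2).fit(nodes=9)
    eb = predict_all(res, ds2)
    times = np.array([5.0])
    ref = standardize_fixed(res, eb, times=times).values[0]
    estimates, bands = {}, {}
    from stdsurv import mc_interval

    for cid in ds2.center_ids:
        est = standardize_fixed(res, eb, surgeon=None, center=cid,
                                times=times)
        fn = survival_estimand(ds2, times, center=cid)
        mc = mc_interval(fn, res,
                         eb[(eb.level == "center") & (eb.cluster_id == cid)],
                         B=300, seed=11)
        estimates[cid] = est.values[0]
        bands[cid] = (mc.lower[0], mc.upper[0])
    table = rank_clusters(estimates, reference=ref, bands=bands)
    assert table.set_index("cluster_id").loc[bad, "category"] == "high"


def test_difference_estimand_composes(small_fit, small_eb, small_dataset):
    times = np.array([3.0])
    fn_a = survival_estimand(small_dataset, times,
                             center=small_dataset.center_ids[0])
    fn_b = survival_estimand(small_dataset, times, marginalize="surgeon",
                             center=small_dataset.center_ids[0])
    gamma = float(small_eb[(small_eb.level == "center")
                           & (small_eb.cluster_id == small_dataset.center_ids[0])]
                  .prediction.iloc[0])
    effects = {("center", small_dataset.center_ids[0]): gamma}
    d = difference_estimand(fn_a, fn_b)(small_fit.params, effects)
    a = fn_a(small_fit.params, effects)
    b = fn_b(small_fit.params, effects)
    np.testing.assert_allclose(d, np.asarray(a) - np.asarray(b))
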