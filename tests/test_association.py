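"""GEE association machinery: estimates, robust errors, helper statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from iggfc.association import (AssociationResult, ModelSpec, association_grid,
                               bonferroni_threshold, friedewald_ldlc, gee_fit,
                               paired_subclass_test, replicate_correlation,
                               r_squared, residualize)


def _clustered(seed, n=900, fam=300, rho=0.3, beta1=0.5, binary_x=False):
    rng = np.random.default_rng(seed)
    family = np.sort(np.arange(n) % fam)
    x = rng.integers(0, 2, n).astype(float) if binary_x else rng.normal(size=n)
    age = rng.normal(59.1, 6.7, n)
    sex = rng.integers(0, 2, n)
    u = rng.normal(0, np.sqrt(rho), fam)[family]
    y = (beta1 * x + 0.05 * age + 0.3 * sex + u
         + rng.normal(0, np.sqrt(1 - rho), n))
    return pd.DataFrame({"y": y, "x": x, "age": age, "sex": sex,
                         "family_id": family})


def test_bonferroni_threshold_values():
    assert bonferroni_threshold(14, 5) == pytest.approx(7.14e-4, abs=5e-7)
    assert bonferroni_threshold(1, 1) == 0.05
    assert bonferroni_threshold(2, 5) == 0.005
    with pytest.raises(ValueError):
        bonferroni_threshold(0, 5)


def test_association_grid_has_70_cells():
    grid = association_grid()
    assert len(grid) == 70
    assert len({v for v, _ in grid}) == 14
    assert len({f for _, f in grid}) == 5


def test_friedewald():
    assert friedewald_ldlc(5.55, 1.42, 1.82) == pytest.approx(3.766)
    assert np.isnan(friedewald_ldlc(5.0, 1.0, 4.53))
    assert friedewald_ldlc(5.0, 1.0, 0.0) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        friedewald_ldlc(-1.0, 1.0, 1.0)


def test_gee_singleton_clusters_equal_ols():
    df = _clustered(seed=1, n=400, fam=400, rho=0.0)
    spec = ModelSpec(outcome="y", exposure="x")
    res = gee_fit(spec, df)
    X = np.column_stack([np.ones(len(df)), df.x, df.age, df.sex,
                         df.age * df.sex])
    ols = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)[0]
    assert res.beta1 == pytest.approx(ols[1], abs=1e-6)


def test_gee_recovers_true_effect():
    df = _clustered(seed=2, n=1000, fam=400, rho=0.3, beta1=0.5)
    res = gee_fit(ModelSpec(outcome="y", exposure="x"), df)
    assert abs(res.beta1 - 0.5) < 3 * res.se
    assert res.t == pytest.approx(res.beta1 / res.se)
    # exchangeable correlation estimate near the generating value
    assert abs(res.rho - 0.3) < 0.05


def test_gee_constant_exposure_rejected():
    df = _clustered(seed=3, n=200, fam=100)
    df["x"] = 1.0
    with pytest.raises(ValueError):
        gee_fit(ModelSpec(outcome="y", exposure="x"), df)


def test_gee_binomial_independence():
    rng = np.random.default_rng(4)
    n, fam = 600, 200
    family = np.repeat(np.arange(fam), n // fam)
    trait = rng.normal(size=n)
    age = rng.normal(59, 7, n)
    sex = rng.integers(0, 2, n)
    logit = -0.2 + 0.8 * trait
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    df = pd.DataFrame({"longevity": y, "trait": trait, "age": age,
                       "sex": sex, "family_id": family})
    spec = ModelSpec(outcome="longevity", exposure="trait", family="binomial",
                     working_correlation="independence")
    res = gee_fit(spec, df)
    assert abs(res.beta1 - 0.8) < 3 * res.se


def test_robust_and_naive_se_agree_without_clustering():
    df = _clustered(seed=5, n=2000, fam=2000, rho=0.0)
    res = gee_fit(ModelSpec(outcome="y", exposure="x"), df)
    # with independent observations the sandwich SE matches the model-based
    # OLS SE within 10%
    X = np.column_stack([np.ones(len(df)), df.x, df.age, df.sex,
                         df.age * df.sex])
    resid = df.y.to_numpy() - X @ np.linalg.lstsq(X, df.y, rcond=None)[0]
    s2 = resid @ resid / (len(df) - X.shape[1])
    se_ols = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    assert res.se == pytest.approx(se_ols, rel=0.10)


def test_tiers():
    assert AssociationResult.tier_for(1e-5, 7.14e-4) == "bonferroni"
    assert AssociationResult.tier_for(0.01, 7.14e-4) == "nominal"
    assert AssociationResult.tier_for(0.5, 7.14e-4) == "none"


def test_paired_t_recovers_shift():
    rng = np.random.default_rng(6)
    a = rng.normal(50, 5, 400)
    b = a + 2.0 + rng.normal(0, 1, 400)
    t, p = paired_subclass_test(a, b)
    assert np.mean(b - a) == pytest.approx(2.0, abs=0.2)
    assert t < 0 or t > 0  # finite
    assert p < 1e-10


def test_paired_t_null_p_uniform():
    rng = np.random.default_rng(7)
    reps = 300
    A = rng.normal(size=(200, reps))
    B = rng.normal(size=(200, reps))
    _, ps = st.ttest_rel(A, B, axis=0)
    assert st.kstest(ps, "uniform").pvalue > 0.01


def test_paired_t_errors():
    with pytest.raises(ValueError):
        paired_subclass_test([1.0], [2.0])
    with pytest.raises(ValueError):
        paired_subclass_test([1.0, 2.0], [2.0, 3.0])  # constant difference


def test_replicate_correlation_limits():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert replicate_correlation(x, x) == pytest.approx(1.0)
    assert replicate_correlation(x, -x) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        replicate_correlation(x[:2], x[:2])
    with pytest.raises(ValueError):
        replicate_correlation(np.ones(4), x)


def test_replicate_correlation_noise_share():
    # measurement-noise share 5% of total variance -> r ~ 0.95
    rng = np.random.default_rng(8)
    n = 600
    signal = rng.normal(0, 1, n)
    noise_var = 0.05 / 0.95
    x = signal + rng.normal(0, np.sqrt(noise_var), n)
    y = signal + rng.normal(0, np.sqrt(noise_var), n)
    assert replicate_correlation(x, y) == pytest.approx(0.95, abs=0.02)


def test_residualize_removes_age_trend():
    df = _clustered(seed=9, n=600, fam=200)
    df["trait"] = 2.0 * df.age
    resid = residualize(df, "trait", covariates=("age",))
    assert np.allclose(resid, 0.0, atol=1e-6)
    df["trait2"] = df.y
    resid2 = residualize(df, "trait2", covariates=("age", "sex"))
    assert abs(np.corrcoef(resid2, df.age.loc[resid2.index])[0, 1]) < 0.02
    assert abs(resid2.mean()) < 0.05


def test_r_squared():
    x = np.linspace(0, 1, 100)
    assert r_squared(2 * x + 1, x) == pytest.approx(1.0)
    rng = np.random.default_rng(10)
    assert r_squared(rng.normal(size=5000), rng.normal(size=5000)) < 0.01
    # constructed explained-variance share 0.0569
    n = 1800
    xs = rng.normal(size=n)
    y = np.sqrt(0.0569) * xs + np.sqrt(1 - 0.0569) * rng.normal(size=n)
    assert r_squared(y, xs) == pytest.approx(0.0569, abs=0.02)


def test_heatmap_marker_consistency(tmp_path):
    from iggfc.report import heatmap_report
    rows = []
    rng = np.random.default_rng(11)
    for f in ("fucosylation", "bisection"):
        for v in ("crp", "tg", "age"):
            p = float(rng.uniform(0, 1)) if v != "crp" else 1e-5
            rows.append({"feature": f, "variable": v,
                         "t": float(rng.normal()), "p": p})
    res = pd.DataFrame(rows)
    alpha = 7.14e-4
    fig, twin = heatmap_report(res, alpha, out_prefix=tmp_path / "hm")
    assert (twin.marker == "X").sum() == (res.p < alpha).sum()
    assert (twin.marker == "point").sum() == \
        ((res.p >= alpha) & (res.p < 0.05)).sum()
    assert (tmp_path / "hm.png").exists() and (tmp_path / "hm.tsv").exists()


def test_heatmap_zero_grid_has_no_markers(tmp_path):
    res = pd.DataFrame([{"feature": "f", "variable": v, "t": 0.0, "p": 0.9}
                        for v in "abc"])
    from iggfc.report import heatmap_report
    _, twin = heatmap_report(res, 7.14e-4)
    assert (twin.marker == "").all()
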