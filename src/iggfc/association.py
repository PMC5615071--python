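"""Association analysis of glycosylation traits with metabolic-health markers.

Linear models ``trait ~ b1*X + b2*age + b3*sex + b4*(age*sex)`` are fitted by
generalized estimating equations with family as the clustering unit and an
exchangeable working correlation; standard errors come from the robust
sandwich estimator and the Wald statistic t = b1/SE(b1) is referred to the
normal distribution.  The familial-metabolic-health contrast (long-lived
family membership 1 vs partner controls 0) uses a binomial GEE with an
independence working correlation, with the glycosylation feature as the
exposure.  Multiple testing uses a Bonferroni threshold of 0.05 over the
(variables x features) grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

#: metabolic parameters entering the association grid (with age and sex this
#: makes 14 variables; times 5 features = 70 analyses)
METABOLIC_VARIABLES = ["crp", "il6", "glucose", "insulin", "tc", "ldlc",
                       "hdlc", "tg", "free_t3", "smoking", "cmv", "longevity"]
GRID_FEATURES = ["fucosylation", "bisection", "galactosylation",
                 "sialylation", "sa_per_gal"]


@dataclass
class ModelSpec:
    outcome: str
    exposure: str
    covariates: tuple = ("age", "sex", "age_sex")
    cluster: str = "family_id"
    family: str = "gaussian"          # or "binomial"
    working_correlation: str = "exchangeable"  # or "independence"


@dataclass
class AssociationResult:
    outcome: str
    exposure: str
    beta1: float
    se: float
    t: float
    p: float
    tier: str   # none | nominal | bonferroni
    n: int
    rho: float = float("nan")  # estimated exchangeable correlation

    @staticmethod
    def tier_for(p: float, alpha: float) -> str:
        if p < alpha:
            return "bonferroni"
        if p < 0.05:
            return "nominal"
        return "none"


def bonferroni_threshold(n_variables: int, n_features: int) -> float:
    """alpha = 0.05 / (n_variables * n_features)."""
    if n_variables < 1 or n_features < 1:
        raise ValueError("counts must be >= 1")
    return 0.05 / (n_variables * n_features)


def friedewald_ldlc(tc: float, hdlc: float, tg: float) -> float:
    """LDL cholesterol (mmol/L): TC - HDLC - TG/5; missing when TG > 4.52."""
    if min(tc, hdlc, tg) < 0:
        raise ValueError("lipid concentrations must be non-negative")
    if tg > 4.52:
        return math.nan
    return tc - hdlc - tg / 5.0


def _design(data: pd.DataFrame, exposure: str, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X[exposure] = data[exposure].astype(float)
    for c in covariates:
        if c == "age_sex":
            X[c] = data["age"].astype(float) * data["sex"].astype(float)
        else:
            X[c] = data[c].astype(float)
    return X


def gee_fit(spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05 / 70
            ) -> AssociationResult:
    """Fit one GEE model and report the exposure coefficient.

    Complete cases on outcome, exposure and covariates are used.  Robust
    (sandwich) standard errors; p-values from the normal reference.
    """
    needed = [spec.outcome, spec.exposure, spec.cluster]
    needed += [c for c in spec.covariates if c != "age_sex"]
    if "age_sex" in spec.covariates:
        needed += ["age", "sex"]
    df = data[sorted(set(needed))].dropna()
    if df[spec.cluster].nunique() < 2:
        raise ValueError("need at least 2 clusters")
    y = df[spec.outcome].astype(float).to_numpy()
    X = _design(df, spec.exposure, spec.covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"collinear design for exposure {spec.exposure!r}")

    family = sm.families.Binomial() if spec.family == "binomial" \
        else sm.families.Gaussian()
    cov = sm.cov_struct.Independence() \
        if spec.working_correlation == "independence" \
        else sm.cov_struct.Exchangeable()
    model = sm.GEE(y, X, groups=df[spec.cluster].to_numpy(),
                   family=family, cov_struct=cov)
    res = model.fit(maxiter=200, ctol=1e-8)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("GEE fit did not converge to finite coefficients")
    j = list(X.columns).index(spec.exposure)
    beta1, se = float(res.params.iloc[j]), float(res.bse.iloc[j])
    t = beta1 / se
    p = float(res.pvalues.iloc[j])
    rho = float(cov.dep_params) if spec.working_correlation == "exchangeable" \
        else math.nan
    return AssociationResult(spec.outcome, spec.exposure, beta1, se, t, p,
                             AssociationResult.tier_for(p, alpha), len(df), rho)


def association_grid(variables=None, features=None) -> list:
    """Enumerate the (variable, feature) analyses of the association grid."""
    variables = list(METABOLIC_VARIABLES) + ["age", "sex"] \
        if variables is None else list(variables)
    features = GRID_FEATURES if features is None else list(features)
    return [(v, f) for v in variables for f in features]


def run_association_grid(data: pd.DataFrame, trait_columns: dict,
                         alpha: float | None = None) -> pd.DataFrame:
    """Fit the full association grid for one subclass.

    ``trait_columns`` maps feature name -> column in ``data`` holding the
    (transformed) trait.  Variables age/sex drop themselves from the
    covariate set; the familial-health variable is fitted as a binomial GEE
    with independence working correlation and the trait as exposure.
    """
    pairs = association_grid()
    if alpha is None:
        n_vars = len({v for v, _ in pairs})
        n_feats = len({f for _, f in pairs})
        alpha = bonferroni_threshold(n_vars, n_feats)
    rows = []
    for variable, feature in pairs:
        # a feature may be unavailable (IgG4 fucosylation): skip its cells
        trait_col = trait_columns.get(feature)
        if trait_col is None or trait_col not in data.columns:
            continue
        if variable == "longevity":
            spec = ModelSpec(outcome="longevity", exposure=trait_col,
                             family="binomial",
                             working_correlation="independence")
        elif variable == "age":
            spec = ModelSpec(outcome=trait_col, exposure="age",
                             covariates=("sex", "age_sex"))
        elif variable == "sex":
            spec = ModelSpec(outcome=trait_col, exposure="sex",
                             covariates=("age", "age_sex"))
        else:
            spec = ModelSpec(outcome=trait_col, exposure=variable)
        res = gee_fit(spec, data, alpha=alpha)
        rows.append({"feature": feature, "variable": variable,
                     "beta1": res.beta1, "se": res.se, "t": res.t,
                     "p": res.p, "tier": res.tier, "n": res.n})
    return pd.DataFrame(rows)


def residualize(data: pd.DataFrame, trait: str, covariates=("age",),
                cluster: str = "family_id") -> pd.Series:
    """GEE residuals of a trait on age (or age + sex) for plotting."""
    df = data[[trait, cluster] + list(covariates)].dropna()
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    for c in covariates:
        X[c] = df[c].astype(float)
    model = sm.GEE(df[trait].astype(float).to_numpy(), X,
                   groups=df[cluster].to_numpy(),
                   cov_struct=sm.cov_struct.Exchangeable())
    res = model.fit(maxiter=200, ctol=1e-8)
    fitted = X.to_numpy() @ res.params
    return pd.Series(df[trait].to_numpy(dtype=float) - fitted, index=df.index,
                     name=f"{trait}_resid")


def paired_subclass_test(a, b) -> tuple[float, float]:
    """Paired t-test of one glycosylation feature between two subclasses."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.ptp(a - b) == 0:
        raise ValueError("paired differences have zero variance")
    t, p = st.ttest_rel(a, b)
    return float(t), float(p)


def replicate_correlation(x, y) -> float:
    """Pearson correlation of a feature between replicate plate runs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in replicate values")
    return float(st.pearsonr(x, y).statistic)


def r_squared(y, x) -> float:
    """Ordinary linear-model coefficient of determination of y on x."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if np.ptp(y) == 0:
        raise ValueError("outcome has zero variance")
    return float(st.linregress(x, y).rvalue ** 2)
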