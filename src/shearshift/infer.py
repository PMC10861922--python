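"""Statistical layer: destination classification and effect decomposition.

Implements the inference machinery for separating phenotypic flexibility from
individual turnover in a repeatedly tracked population:

* a yearly climate covariate (box-mean July/August SST proxy);
* two-component Gaussian mixture classification of migration median
  latitudes into the northern and southern destination areas, fitted per
  multi-year batch by EM;
* van de Pol & Wright subject-centering of predictors into a
  between-individual component (each individual's mean) and a
  within-individual component (yearly deviations from that mean);
* random-intercept mixed models (Gaussian via statsmodels MixedLM with ML;
  binomial logit via in-package adaptive Gauss-Hermite maximum likelihood);
* likelihood-ratio tests on nested ML fits, AICc comparison for non-nested
  models, and parametric-bootstrap confidence intervals on effects and on
  the between-minus-within effect difference.

The within-individual slope measures reversible flexibility (one bird
changing its behaviour between years); an excess of the between-individual
slope over it indicates turnover of individuals with fixed behaviours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "mean_sst_proxy",
    "MixtureFit",
    "fit_mixture",
    "batch_and_classify",
    "CenteredPredictor",
    "subject_center",
    "add_centered",
    "ModelSpec",
    "FittedModel",
    "fit_mixed_model",
    "lrt",
    "aicc",
    "aicc_from_aic",
    "compare_aicc",
    "bootstrap_effects",
    "EffectDecomposition",
    "decompose_effect",
    "first_track_trend",
    "PAPER_MODELS",
]

DEFAULT_SST_BOX = (-12.0, -1.0, 38.0, 51.0)
DEFAULT_BATCHES = ((2010, 2012), (2013, 2015), (2016, 2018))


def mean_sst_proxy(
    data,
    year: int,
    box=DEFAULT_SST_BOX,
    months=(7, 8),
    latitude_weighted: bool = False,
) -> float:
    """Mean July/August SST over a fixed box for one year, in degC.

    `data` is either a gridded field (xarray Dataset/DataArray with lat, lon
    and time coordinates) or a scalar per-year table (DataFrame with columns
    year and sst_c). The box mean is unweighted by default; pass
    ``latitude_weighted=True`` for a cos-latitude area weighting.
    """
    if isinstance(data, pd.DataFrame):
        hit = data.loc[data["year"] == year, "sst_c"]
        if hit.empty:
            raise ValueError(f"year {year} missing from SST table")
        return float(hit.iloc[0])
    da = data["sst"] if hasattr(data, "data_vars") else data
    west, east, south, north = box
    sel = da.sel(lon=slice(west, east), lat=slice(south, north))
    tsel = sel.time.dt.year.isin([year]) & sel.time.dt.month.isin(list(months))
    got_months = set(sel.time.dt.month.values[tsel.values])
    if got_months != set(months):
        raise ValueError(f"months {sorted(set(months) - got_months)} missing for {year}")
    sub = sel.isel(time=np.flatnonzero(tsel.values))
    if latitude_weighted:
        w = np.cos(np.radians(sub.lat))
        return float(sub.weighted(w).mean(("time", "lat", "lon")).values)
    return float(sub.mean(("time", "lat", "lon")).values)


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture (EM)
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray  # (n, 2), column 1 = higher-mean component
    log_likelihood: float
    ll_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def labels(self) -> np.ndarray:
        """north/south by responsibility (larger-mean component is north)."""
        north = self.responsibilities[:, 1] > 0.5
        return np.where(north, "north", "south")


def _em(x, mu, max_iter, tol):
    n = x.size
    sd = np.array([np.std(x) or 1.0, np.std(x) or 1.0]) * 0.5 + 1e-3
    w = np.array([0.5, 0.5])
    mu = np.array(mu, float)
    trace = []
    prev = -np.inf
    for it in range(1, max_iter + 1):
        logp = np.stack(
            [np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)], axis=1
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        r = np.exp(logp - lse[:, None])
        nk = r.sum(axis=0)
        if nk.min() < 1e-8:
            return None  # a component collapsed to zero weight
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        if var.min() < 1e-10:
            return None  # degenerate zero-variance component
        sd = np.sqrt(var)
        if abs(ll - prev) < tol:
            return mu, sd, w, r, ll, np.array(trace), it, True
        prev = ll
    return mu, sd, w, r, ll, np.array(trace), max_iter, False


def fit_mixture(
    x,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 10,
    seed: int = 0,
) -> MixtureFit:
    """Two-component univariate Gaussian mixture by EM.

    Initialized k-means-style at the 25th/75th percentiles, plus
    `n_restarts` random restarts (pairs of observed values as starting
    means); the best log-likelihood is kept. The EM log-likelihood is
    non-decreasing by construction and is asserted so. Degenerate
    (zero-variance) components trigger a restart and, if every start
    degenerates, an error.
    """
    x = np.asarray(x, float)
    if x.size < 4:
        raise ValueError("need at least 4 observations for a 2-component mixture")
    rng = np.random.default_rng(seed)
    starts = [np.percentile(x, [25, 75])]
    for _ in range(n_restarts):
        starts.append(rng.choice(x, size=2, replace=False))
    best = None
    for mu0 in starts:
        if abs(mu0[0] - mu0[1]) < 1e-12:
            continue
        out = _em(x, np.sort(mu0), max_iter, tol)
        if out is None:
            continue
        if best is None or out[4] > best[4]:
            best = out
    if best is None:
        raise ValueError("mixture fit degenerate from every start (zero-variance component)")
    mu, sd, w, r, ll, trace, n_iter, conv = best
    assert np.all(np.diff(trace) >= -1e-9), "EM log-likelihood decreased"
    order = np.argsort(mu)  # component 1 = larger mean (north)
    return MixtureFit(
        means=mu[order],
        sds=sd[order],
        weights=w[order],
        responsibilities=r[:, order],
        log_likelihood=ll,
        ll_trace=trace,
        n_iter=n_iter,
        converged=conv,
    )


def batch_and_classify(
    summaries: pd.DataFrame,
    batches=DEFAULT_BATCHES,
    lat_col: str = "median_lat",
    seed: int = 0,
) -> pd.Series:
    """north/south area labels from per-batch mixture fits on median latitudes.

    Tracks are grouped into multi-year batches (three consecutive years by
    default) so the mixture tracks the moving destination distribution; each
    track is assigned to the component with the higher responsibility, and
    the larger-mean component is labelled north.
    """
    years = summaries["year"].to_numpy(int)
    labels = pd.Series(index=summaries.index, dtype=object)
    covered = np.zeros(len(summaries), dtype=int)
    for lo, hi in batches:
        covered += (years >= lo) & (years <= hi)
    if (covered != 1).any():
        bad = sorted(set(years[covered != 1]))
        raise ValueError(f"years {bad} not covered by exactly one batch")
    for lo, hi in batches:
        sel = (years >= lo) & (years <= hi)
        if sel.sum() == 0:
            continue
        if sel.sum() < 4:
            raise ValueError(f"batch {lo}-{hi} has {sel.sum()} tracks (< 4)")
        fit = fit_mixture(summaries.loc[sel, lat_col].to_numpy(), seed=seed)
        labels.loc[sel] = fit.labels
    return labels


# ---------------------------------------------------------------------------
# Subject-centering
# ---------------------------------------------------------------------------


@dataclass
class CenteredPredictor:
    """Between/within decomposition of a predictor keyed by individual."""

    between: pd.Series  # each observation's individual mean
    within: pd.Series  # deviation from that mean (0 for singletons)

    def reconstruct(self) -> pd.Series:
        return self.between + self.within


def subject_center(values: pd.Series, individuals: pd.Series) -> CenteredPredictor:
    """Exact mean/deviation decomposition of a predictor by individual.

    between + within reconstructs the raw predictor exactly; the within
    component sums to zero inside every individual, and individuals with a
    single observation get deviation 0.
    """
    v = pd.Series(np.asarray(values, float), index=pd.RangeIndex(len(values)))
    g = pd.Series(np.asarray(individuals), index=v.index)
    means = v.groupby(g).transform("mean")
    return CenteredPredictor(between=means, within=v - means)


def add_centered(
    df: pd.DataFrame, col: str, id_col: str = "individual_id"
) -> pd.DataFrame:
    """Return a copy with `{col}_between` and `{col}_within` columns added."""
    cp = subject_center(df[col], df[id_col])
    out = df.copy()
    out[f"{col}_between"] = cp.between.to_numpy()
    out[f"{col}_within"] = cp.within.to_numpy()
    return out


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One model structure: response, fixed effects, grouping and family."""

    response: str
    fixed_effects: tuple
    random_intercept: str | None = "individual_id"
    family: str = "gaussian"  # or "binomial"
    method: str = "ML"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_effects) if self.fixed_effects else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class FittedModel:
    spec: ModelSpec
    params: pd.Series  # fixed effects
    cov_params: pd.DataFrame  # fixed-effect sampling covariance
    llf: float
    nobs: int
    k_fixed: int
    k_total: int  # fixed + variance parameters, for AICc
    singular: bool = False
    approximation: str | None = None  # e.g. "gauss-hermite(31)" for binomial

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_total


def _gh_binomial_loglik(beta, log_sigma, y, X, group_idx, nodes, wts):
    eta = X @ beta
    sigma = np.exp(log_sigma)
    # per-observation log Bernoulli at each quadrature node
    u = np.sqrt(2.0) * sigma * nodes  # (q,)
    lin = eta[:, None] + u[None, :]
    logp_obs = np.where(y[:, None] == 1, -np.logaddexp(0, -lin), -np.logaddexp(0, lin))
    df = pd.DataFrame(logp_obs)
    grouped = df.groupby(group_idx).sum().to_numpy()  # (n_groups, q)
    m = grouped.max(axis=1, keepdims=True)
    ll_g = m[:, 0] + np.log(np.exp(grouped - m) @ (wts / np.sqrt(np.pi)))
    return float(ll_g.sum())


def _fit_binomial_glmm(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    import patsy
    import statsmodels.api as sm
    from statsmodels.tools.numdiff import approx_hess

    y_mat, X_mat = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    y = y_mat.to_numpy().ravel()
    X = X_mat.to_numpy()
    names = list(X_mat.columns)
    groups = pd.Categorical(data.loc[X_mat.index, spec.random_intercept]).codes
    nodes, wts = np.polynomial.hermite.hermgauss(31)

    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    x0 = np.concatenate([glm.params, [np.log(0.5)]])

    def negll(theta):
        return -_gh_binomial_loglik(theta[:-1], theta[-1], y, X, groups, nodes, wts)

    res = minimize(negll, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    theta = res.x
    H = approx_hess(theta, negll)
    singular = False
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
        singular = True
    k_fe = X.shape[1]
    cov_fe = cov_all[:k_fe, :k_fe]
    if np.any(np.diag(cov_fe) <= 0):
        singular = True
        cov_fe = np.abs(np.diag(np.diag(cov_fe))) + 1e-8 * np.eye(k_fe)
        warnings.warn("binomial GLMM Hessian not positive definite; covariance regularized")
    return FittedModel(
        spec=spec,
        params=pd.Series(theta[:k_fe], index=names),
        cov_params=pd.DataFrame(cov_fe, index=names, columns=names),
        llf=-res.fun,
        nobs=len(y),
        k_fixed=k_fe,
        k_total=k_fe + 1,
        singular=singular,
        approximation="gauss-hermite(31)",
    )


def _fit_gaussian(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    import statsmodels.formula.api as smf

    if spec.random_intercept is None:
        fit = smf.ols(spec.formula, data=data).fit()
        names = list(fit.params.index)
        return FittedModel(
            spec=spec,
            params=fit.params,
            cov_params=fit.cov_params(),
            llf=float(fit.llf),
            nobs=int(fit.nobs),
            k_fixed=len(names),
            k_total=len(names) + 1,  # + residual variance
        )
    model = smf.mixedlm(spec.formula, data=data, groups=data[spec.random_intercept])
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                fit = model.fit(reml=(spec.method.upper() == "REML"), method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if fit is None:
        raise np.linalg.LinAlgError(
            f"mixed-model fit failed for '{spec.formula}' with every optimizer"
        )
    singular = bool(getattr(fit, "converged", True) is False)
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    if re_var < 1e-10:
        singular = True
        warnings.warn("random-intercept variance estimated at the boundary (~0)")
    names = list(fit.fe_params.index)
    cov = fit.cov_params().loc[names, names]
    return FittedModel(
        spec=spec,
        params=fit.fe_params,
        cov_params=cov,
        llf=float(fit.llf),
        nobs=int(fit.nobs),
        k_fixed=len(names),
        k_total=len(names) + 2,  # + residual and random-intercept variances
        singular=singular,
    )


def fit_mixed_model(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """Fit one model structure by maximum likelihood.

    Gaussian responses use a linear mixed model with a single random
    intercept per individual (plain OLS when `random_intercept` is None);
    binomial responses use a logit-link random-intercept model maximized by
    Gauss-Hermite quadrature. ML (not REML) is the default so fits can enter
    likelihood-ratio tests and AICc comparisons.
    """
    if spec.random_intercept is not None:
        if data[spec.random_intercept].nunique() < 2:
            raise ValueError("need at least 2 individuals for a random intercept")
    if spec.family == "binomial":
        return _fit_binomial_glmm(spec, data)
    return _fit_gaussian(spec, data)


# ---------------------------------------------------------------------------
# Tests and comparisons
# ---------------------------------------------------------------------------


def lrt(full: FittedModel, null: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (chi2, df, p)."""
    if not set(null.spec.fixed_effects) <= set(full.spec.fixed_effects):
        raise ValueError("null model's fixed effects are not nested in the full model's")
    if full.nobs != null.nobs:
        raise ValueError("models fitted to different data")
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    df = full.k_fixed - null.k_fixed
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def aicc_from_aic(aic: float, n: int, k: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def aicc(model: FittedModel, n: int | None = None, k: int | None = None) -> float:
    n = model.nobs if n is None else n
    k = model.k_total if k is None else k
    return aicc_from_aic(-2.0 * model.llf + 2.0 * k, n, k)


def compare_aicc(model_a: FittedModel, model_b: FittedModel) -> float:
    """Delta AICc = AICc(A) - AICc(B); negative favours A."""
    return aicc(model_a) - aicc(model_b)


def bootstrap_effects(
    fit: FittedModel,
    n_draws: int = 1000,
    seed: int = 0,
    difference: tuple | None = None,
) -> dict:
    """Parametric bootstrap of the fixed effects.

    Draws the coefficient vector from its estimated multivariate normal
    sampling distribution and reports percentile 2.5/97.5 CIs; when
    `difference` names a (between, within) pair, the CI of their difference
    is computed on the paired draws. Deterministic given `seed`.
    """
    rng = np.random.default_rng(seed)
    cov = fit.cov_params.to_numpy()
    if not np.all(np.isfinite(cov)):
        raise ValueError("singular/non-finite coefficient covariance")
    if not np.allclose(cov, cov.T):
        raise ValueError("coefficient covariance is not symmetric")
    # SVD sampling tolerates a degenerate (zero) covariance: the CI then
    # collapses to the point estimate
    draws = rng.multivariate_normal(
        fit.params.to_numpy(), cov, size=n_draws, method="svd"
    )
    draws = pd.DataFrame(draws, columns=fit.params.index)
    ci = draws.quantile([0.025, 0.975])
    out = {"draws": draws, "ci": ci, "n_draws": n_draws, "seed": seed}
    if difference is not None:
        b, w = difference
        d = draws[b] - draws[w]
        out["difference_ci"] = (float(d.quantile(0.025)), float(d.quantile(0.975)))
        out["difference"] = float(fit.params[b] - fit.params[w])
    return out


@dataclass
class EffectDecomposition:
    """Between/within slope estimates with bootstrap CIs and their difference."""

    predictor: str
    between_slope: float
    between_ci: tuple
    within_slope: float
    within_ci: tuple
    difference: float
    difference_ci: tuple
    lrt_between: tuple  # (chi2, df, p)
    lrt_within: tuple
    full: FittedModel = field(repr=False)
    n_boot: int = 1000
    seed: int = 0


def decompose_effect(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    extra_terms: tuple = (),
    id_col: str = "individual_id",
    family: str = "gaussian",
    n_boot: int = 1000,
    seed: int = 0,
) -> EffectDecomposition:
    """Subject-center `predictor` and decompose its effect on `response`.

    Fits the full random-intercept model with both centered components plus
    `extra_terms`, likelihood-ratio tests each component against its nested
    null, and bootstraps the CIs of both slopes and of their difference
    (between minus within). The headline question: is the population-level
    change carried by within-individual flexibility (within slope), by
    turnover of fixed individuals (between exceeding within), or both?
    """
    d = add_centered(data, predictor, id_col)
    b, w = f"{predictor}_between", f"{predictor}_within"
    terms = (b, w) + tuple(extra_terms)
    full_spec = ModelSpec(response, terms, random_intercept=id_col, family=family)
    full = fit_mixed_model(full_spec, d)
    drop_b = fit_mixed_model(
        ModelSpec(response, (w,) + tuple(extra_terms), random_intercept=id_col, family=family), d
    )
    drop_w = fit_mixed_model(
        ModelSpec(response, (b,) + tuple(extra_terms), random_intercept=id_col, family=family), d
    )
    boot = bootstrap_effects(full, n_draws=n_boot, seed=seed, difference=(b, w))
    ci = boot["ci"]
    return EffectDecomposition(
        predictor=predictor,
        between_slope=float(full.params[b]),
        between_ci=(float(ci.loc[0.025, b]), float(ci.loc[0.975, b])),
        within_slope=float(full.params[w]),
        within_ci=(float(ci.loc[0.025, w]), float(ci.loc[0.975, w])),
        difference=boot["difference"],
        difference_ci=boot["difference_ci"],
        lrt_between=lrt(full, drop_b),
        lrt_within=lrt(full, drop_w),
        full=full,
        n_boot=n_boot,
        seed=seed,
    )


# Full model structures used in paper mode (response, fixed effects, family).
PAPER_MODELS = {
    "first_track_latitude": ModelSpec(
        "median_lat", ("year", "C(area)", "C(sex)", "C(island)"), random_intercept=None
    ),
    "median_latitude": ModelSpec(
        "median_lat", ("sst_between", "sst_within", "C(area)", "C(sex)")
    ),
    "area_choice": ModelSpec(
        "north", ("sst_between", "sst_within", "C(island)", "C(sex)"), family="binomial"
    ),
    "return_speed": ModelSpec(
        "return_speed",
        ("max_lat_between", "max_lat_within", "outbound_speed", "C(area)", "C(sex)"),
    ),
    "departure_date": ModelSpec(
        "departure_doy", ("max_lat_between", "max_lat_within", "C(area)", "C(island)")
    ),
    "return_date": ModelSpec(
        "return_doy", ("max_lat_between", "max_lat_within", "C(area)", "C(island)")
    ),
}


def first_track_trend(
    summaries: pd.DataFrame, sst: pd.DataFrame | None = None
) -> dict:
    """Range-shift trend from each individual's first recorded migration.

    OLS of median latitude on year (plus area, sex and island), one row per
    individual to avoid pseudoreplication. When an SST table is supplied the
    rival non-nested model replacing year with SST is fitted too and both
    AICc values (and their difference, year-model minus SST-model) returned.
    """
    first = summaries.sort_values("year").groupby("individual_id", as_index=False).first()
    if first["individual_id"].duplicated().any():
        raise ValueError("duplicated individuals in first-track table")
    import statsmodels.formula.api as smf

    year_fit = smf.ols(
        "median_lat ~ year + C(area) + C(sex) + C(island)", data=first
    ).fit()
    if year_fit.condition_number > 1e8:
        warnings.warn("near-collinear design in first-track regression")
    out = {
        "n": int(year_fit.nobs),
        "slope_per_year": float(year_fit.params["year"]),
        "slope_se": float(year_fit.bse["year"]),
        "f_statistic": float(year_fit.fvalue),
        "f_df": (int(year_fit.df_model), int(year_fit.df_resid)),
        "p_value": float(year_fit.f_pvalue),
        "per_term_p": year_fit.pvalues.to_dict(),
        "fit": year_fit,
    }
    if sst is not None:
        first = first.merge(sst, on="year", how="left")
        if first["sst_c"].isna().any():
            raise ValueError("SST table missing years present in the data")
        sst_fit = smf.ols(
            "median_lat ~ sst_c + C(area) + C(sex) + C(island)", data=first
        ).fit()
        k = int(year_fit.df_model) + 2  # + intercept + residual variance
        n = int(year_fit.nobs)
        out["aicc_year"] = aicc_from_aic(float(year_fit.aic), n, k)
        out["aicc_sst"] = aicc_from_aic(float(sst_fit.aic), n, k)
        out["delta_aicc"] = out["aicc_year"] - out["aicc_sst"]
        out["sst_fit"] = sst_fit
    return out
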