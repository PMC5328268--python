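"""Statistical inference layer.

Three analyses sit on top of the rarefied CVs and the overlap summaries:

* a linear mixed model of per-species ITV (rarefied CV, log scale by
  default) against community species richness with mean annual temperature
  and annual precipitation as covariates and a random intercept per forest
  type, reported with Nakagawa–Schielzeth marginal/conditional R^2;
* ordinary least squares of each square-root-transformed overlap summary
  (median, share < 0.25, share > 0.75) against species richness across
  forests;
* a paired Wilcoxon signed-rank comparison of the per-forest median overlap
  under the normal vs the kernel estimator, with the tie-corrected normal
  approximation for Z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.special import ndtr

from .errors import DegenerateDesignError, InsufficientDataError, UndefinedTestError

FIXED_EFFECTS = ("species_richness", "mat_c", "ap_mm")


@dataclass
class ItvModelFit:
    trait: str
    n_obs: int
    coefficients: pd.DataFrame  # term, estimate, se, t, p
    r2_marginal: float
    r2_conditional: float
    random_intercept_variance: float
    residual_variance: float
    family: str
    fixed_effects_only: bool = False

    @property
    def sr_slope(self) -> float:
        return float(
            self.coefficients.set_index("term").loc["species_richness", "estimate"]
        )


@dataclass
class SummaryRegressionFit:
    response: str
    method: str
    trait: str
    transform: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


@dataclass
class PairedComparison:
    n: int
    z: float  # signed; positive when the first input tends larger
    p_value: float
    n_nonzero: int = field(default=0)

    @property
    def abs_z(self) -> float:
        return abs(self.z)


def fit_itv_model(
    stats: pd.DataFrame,
    meta: pd.DataFrame,
    family_config: str = "log_gaussian",
    trait: str | None = None,
) -> ItvModelFit:
    """Mixed model of ITV on richness and climate with a forest-type intercept.

    ``family_config`` selects the response scale: ``log_gaussian`` (default)
    fits a Gaussian mixed model to log(CV); ``gaussian`` fits the CV on the
    identity scale.  Fixed-effect p-values use the t statistic with
    n - p residual degrees of freedom.  A singular random-intercept fit
    (variance estimated at zero) triggers a warning and a fixed-effects-only
    refit with conditional R^2 equal to marginal R^2.
    """
    if family_config not in ("log_gaussian", "gaussian"):
        raise ValueError(f"unknown family_config {family_config!r}")
    meta_cols = ["forest_type", "mat_c", "ap_mm", "species_richness"]
    df = stats.drop(columns=[c for c in meta_cols if c in stats.columns]).merge(
        meta[["forest_id", *meta_cols]],
        on="forest_id",
        how="inner",
    ).dropna(subset=["cv_r", "mat_c", "ap_mm", "species_richness", "forest_type"])
    if trait is None:
        trait = str(df["trait"].iloc[0]) if "trait" in df and len(df) else "?"
    if df["forest_type"].nunique() < 2:
        raise InsufficientDataError("need >= 2 forest types for the random intercept")
    if len(df) < 10:
        raise InsufficientDataError(f"need >= 10 observations, got {len(df)}")
    if family_config == "log_gaussian":
        df = df[df["cv_r"] > 0]
        endog = np.log(df["cv_r"].to_numpy())
    else:
        endog = df["cv_r"].to_numpy()
    exog = sm.add_constant(df[list(FIXED_EFFECTS)].astype(float))

    fe_only = False
    re_var = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(endog, exog, groups=df["forest_type"])
            res = model.fit(reml=True)
            re_var = float(np.asarray(res.cov_re)[0, 0])
            singular = not res.converged or re_var <= 1e-8 * max(np.var(endog), 1e-12)
        except (np.linalg.LinAlgError, ValueError):
            singular = True
    if singular:
        warnings.warn(
            "singular random-intercept structure; falling back to a "
            "fixed-effects-only fit",
            stacklevel=2,
        )
        fe_only = True
        ols = sm.OLS(endog, exog).fit()
        params = ols.params
        bse = ols.bse
        resid_var = float(ols.mse_resid)
        re_var = 0.0
        fitted_fixed = ols.fittedvalues
    else:
        params = res.fe_params
        bse = res.bse_fe
        resid_var = float(res.scale)
        fitted_fixed = exog.to_numpy() @ np.asarray(params)

    n, p = len(df), exog.shape[1]
    tvals = np.asarray(params) / np.asarray(bse)
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tvals), df=n - p)
    coef = pd.DataFrame(
        {
            "term": ["intercept", *FIXED_EFFECTS],
            "estimate": np.asarray(params, dtype=float),
            "se": np.asarray(bse, dtype=float),
            "t": tvals,
            "p": pvals,
        }
    )
    var_fixed = float(np.var(np.asarray(fitted_fixed)))
    denom = var_fixed + re_var + resid_var
    r2m = var_fixed / denom
    r2c = (var_fixed + re_var) / denom
    return ItvModelFit(
        trait=trait,
        n_obs=n,
        coefficients=coef,
        r2_marginal=r2m,
        r2_conditional=r2c,
        random_intercept_variance=re_var,
        residual_variance=resid_var,
        family=family_config,
        fixed_effects_only=fe_only,
    )


def regress_summary(
    summaries: pd.DataFrame,
    meta: pd.DataFrame,
    response: str = "median_overlap",
    transform: str = "sqrt",
) -> SummaryRegressionFit:
    """OLS of a (sqrt-transformed) overlap summary on species richness.

    One observation per forest.  The summaries frame should already be
    restricted to one trait and one method (columns ``trait`` and ``method``
    are carried through to the fit record when present).
    """
    df = summaries.merge(meta[["forest_id", "species_richness"]], on="forest_id")
    df = df.dropna(subset=[response, "species_richness"])
    if len(df) < 3:
        raise InsufficientDataError(f"need >= 3 forests, got {len(df)}")
    x = df["species_richness"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("species richness has zero variance")
    y = df[response].to_numpy(dtype=float)
    if transform == "sqrt":
        y = np.sqrt(y)
    elif transform not in (None, "none", "identity"):
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(y) == 0:
        # constant response: zero slope explains nothing, by convention r2 = 0
        return SummaryRegressionFit(
            response=response,
            method=str(df["method"].iloc[0]) if "method" in df else "?",
            trait=str(df["trait"].iloc[0]) if "trait" in df else "?",
            transform=transform if transform else "none",
            slope=0.0,
            intercept=float(y[0]),
            r2=0.0,
            p_value=1.0,
            n=len(df),
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SummaryRegressionFit(
        response=response,
        method=str(df["method"].iloc[0]) if "method" in df else "?",
        trait=str(df["trait"].iloc[0]) if "trait" in df else "?",
        transform=transform if transform else "none",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=len(df),
    )


def signed_rank_z(diffs) -> tuple[float, float, int]:
    """Tie-corrected normal-approximation signed-rank statistic.

    Zero differences are dropped; absolute differences are midranked.
    Returns (signed z, two-sided p, number of nonzero differences); z > 0
    when positive differences dominate.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    n = d.size
    ranks = scipy.stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if var <= 0:
        raise UndefinedTestError("zero variance in signed ranks")
    z = (w_pos - mu) / np.sqrt(var)
    p = 2.0 * ndtr(-abs(z))
    return float(z), float(p), int(n)


def compare_methods(medians_a: pd.Series, medians_b: pd.Series) -> PairedComparison:
    """Paired Wilcoxon signed-rank comparison of two per-forest median series.

    The inputs are indexed by forest id; only forests present in both enter.
    ``z`` is signed (positive when the first series tends larger); the
    conventional report uses ``abs_z``.
    """
    a, b = medians_a.align(medians_b, join="inner")
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if len(a) < 6:
        raise InsufficientDataError(f"need >= 6 paired forests, got {len(a)}")
    z, p, n_nonzero = signed_rank_z(a.to_numpy() - b.to_numpy())
    return PairedComparison(n=len(a), z=z, p_value=p, n_nonzero=n_nonzero)
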