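"""Population-level statistics for the nAb / killing-assay cohort.

The cohort table carries one row per animal: population (range), sex, mean
nAb ELISA signal, optional total IgM, and the log time-to-threshold killing
score. The analyses mirror a standard ecoimmunology design: pairwise
linear regressions between assays at the individual level, and a linear
mixed model on the log response with population as the fixed effect and a
random intercept for sex (sex enters as a random effect because the
populations are not sex-balanced).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .bka import KillingClass

logger = logging.getLogger(__name__)

#: Canonical cohort-table columns (superset; optional ones may be absent).
COHORT_COLUMNS = (
    "sample_id",
    "population",
    "sex",
    "nab_a450",
    "total_igm",
    "bka_ln_t",
    "killing_class",
)


def validate_cohort(cohort: pd.DataFrame, censor_time_h: float | None = None) -> None:
    """Sanity-check a cohort table: unique ids, known columns, censor bound."""
    if "sample_id" not in cohort.columns:
        raise ValueError("cohort table needs a sample_id column")
    if cohort["sample_id"].duplicated().any():
        dupes = cohort.loc[cohort["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if censor_time_h is not None and "bka_ln_t" in cohort.columns:
        ln_cap = np.log(censor_time_h)
        bad = cohort["bka_ln_t"].dropna() > ln_cap + 1e-9
        if bad.any():
            raise ValueError("bka_ln_t exceeds the log censor value")


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS regression of y on x with the usual single-slope summaries."""

    slope: float
    intercept: float
    r2: float
    p_slope: float
    n: int
    conf_band: pd.DataFrame  # columns x, fit, lo, hi (pointwise 95% CI of the mean)


@dataclass(frozen=True)
class MixedModelResult:
    """Population contrast from the log-response linear mixed model."""

    population_effect: float  # difference on the ln scale (second level - first)
    se: float
    p_population: float
    random_effect_sd: float  # sd of the sex random intercept
    converged: bool
    method: str  # "reml" or "ols_fallback"


def simple_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with r², slope t-test and a pointwise 95% mean CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 complete (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    band = pd.DataFrame(
        {
            "x": grid,
            "fit": pred["mean"].to_numpy(),
            "lo": pred["mean_ci_lower"].to_numpy(),
            "hi": pred["mean_ci_upper"].to_numpy(),
        }
    )
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p_slope=float(fit.pvalues[1]),
        n=int(x.size),
        conf_band=band,
    )


def population_mixed_model(
    cohort: pd.DataFrame,
    response: str,
    log_response: bool = True,
    use_lrt: bool = False,
) -> MixedModelResult:
    """Population comparison with sex as a random intercept.

    Fits, by REML, ``ln(response) ~ population + (1 | sex)`` (the response
    is used as-is when ``log_response`` is false, e.g. when it is already a
    log time-to-threshold). The fixed effect is the difference between the
    second and first population label in sorted order; its p-value is a
    Wald z-test by default, or a likelihood-ratio test against the
    population-free model when ``use_lrt`` is set. When the sex variance
    estimate collapses to the boundary (sd -> 0) the model reduces to OLS,
    which is then reported explicitly.
    """
    df = cohort.dropna(subset=[response, "population", "sex"]).copy()
    pops = sorted(df["population"].unique())
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be represented")
    if log_response:
        if (df[response] <= 0).any():
            raise ValueError(f"{response} must be positive to take logs")
        df["_y"] = np.log(df[response].astype(float))
    else:
        df["_y"] = df[response].astype(float)
    df["_pop"] = (df["population"] == pops[1]).astype(float)

    fit, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("_y ~ _pop", df, groups=df["sex"])
        for method in (None, "powell", "cg"):
            try:
                fit = model.fit(reml=True) if method is None else model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if fit.converged:
                converged = True
                break

    if fit is not None and converged:
        re_var = float(np.asarray(fit.cov_re)[0, 0])
        effect = float(fit.params["_pop"])
        se = float(fit.bse["_pop"])
        p = float(fit.pvalues["_pop"])
        method = "reml"
        if use_lrt:
            p = _lrt_population(df)
        if re_var < 1e-10:
            logger.info("sex random-intercept variance at boundary (sd -> 0)")
        return MixedModelResult(
            population_effect=effect,
            se=se,
            p_population=p,
            random_effect_sd=float(np.sqrt(max(re_var, 0.0))),
            converged=True,
            method=method,
        )

    # boundary/convergence fallback: sex variance profiled out at 0
    logger.warning("mixed model did not converge; falling back to OLS with sex sd = 0")
    ols = smf.ols("_y ~ _pop", df).fit()
    p = _lrt_population(df) if use_lrt else float(ols.pvalues["_pop"])
    return MixedModelResult(
        population_effect=float(ols.params["_pop"]),
        se=float(ols.bse["_pop"]),
        p_population=p,
        random_effect_sd=0.0,
        converged=False,
        method="ols_fallback",
    )


def _lrt_population(df: pd.DataFrame) -> float:
    """Likelihood-ratio p-value for the population fixed effect (ML fits)."""
    from scipy import stats as _sps

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm("_y ~ _pop", df, groups=df["sex"]).fit(reml=False)
        null = smf.mixedlm("_y ~ 1", df, groups=df["sex"]).fit(reml=False)
    stat = 2.0 * (full.llf - null.llf)
    return float(_sps.chi2.sf(max(stat, 0.0), df=1))


def killing_class_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of the three killing classes per population.

    Returns one row per (population, class) with columns ``count`` and
    ``fraction``; fractions sum to one within each population.
    """
    if "killing_class" not in cohort.columns:
        raise ValueError("cohort table has no killing_class column")
    df = cohort.dropna(subset=["killing_class"])
    classes = [k.value for k in KillingClass]
    rows = []
    for pop, grp in df.groupby("population", sort=True):
        total = len(grp)
        for cls in classes:
            n = int((grp["killing_class"] == cls).sum())
            rows.append(
                {
                    "population": pop,
                    "killing_class": cls,
                    "count": n,
                    "fraction": n / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def cross_assay_regression(cohort: pd.DataFrame) -> dict[str, RegressionResult]:
    """The study's named between-assay regressions.

    ``nab_vs_total_igm``: reactive-nAb signal against total IgM;
    ``bka_vs_nab``: log killing time against nAb signal; and, when both
    columns are present, ``ecoli_vs_vibrio_bka``: the killing scores of the
    two bacterial targets against each other. Regressions whose columns
    are absent are omitted from the result.
    """
    pairs = {
        "nab_vs_total_igm": ("total_igm", "nab_a450"),
        "bka_vs_nab": ("nab_a450", "bka_ln_t"),
        "ecoli_vs_vibrio_bka": ("bka_ln_t_vibrio", "bka_ln_t"),
    }
    out: dict[str, RegressionResult] = {}
    for name, (xcol, ycol) in pairs.items():
        if xcol not in cohort.columns or ycol not in cohort.columns:
            continue
        sub = cohort.dropna(subset=[xcol, ycol])
        if len(sub) < 3 or np.ptp(sub[xcol].to_numpy(dtype=float)) == 0:
            continue
        out[name] = simple_regression(
            sub[xcol].to_numpy(dtype=float), sub[ycol].to_numpy(dtype=float)
        )
    return out
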