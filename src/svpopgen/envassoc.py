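"""Binomial GLMs linking site-level SV haplotype frequencies to
environmental covariates, against a geographic null model.

The response is the haplotype-B count out of 2n chromosomes per site
(logit link); the null design is intercept + lon + lat + lon:lat, and each
covariate is tested in a separate model nested over the null, compared by a
likelihood-ratio (analysis-of-deviance) chi-square test with 1 df.  No
multiple-testing correction is applied across covariates (each is reported
as its own test); the AIC column is on the deviance scale
(residual deviance + 2 * number of parameters), so only differences
between rows are meaningful.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simdata import ENV_COVARIATES

__all__ = ["fit_binomial_glm", "env_screen", "GlmFit"]

NULL_TERMS = ("lon", "lat", "lon:lat")


@dataclasses.dataclass
class GlmFit:
    """One fitted binomial GLM with its test against the nested null."""

    terms: list[str]
    coefficients: dict[str, float]
    deviance: float
    aic: float
    llf: float
    lrt_stat: float | None
    lrt_p: float | None
    converged: bool
    separation_flag: bool
    pearson_dispersion: float


def _design(
    df: pd.DataFrame, extra: str | None, geo_terms: tuple[str, ...] = NULL_TERMS
) -> tuple[np.ndarray, list[str]]:
    cols = {"const": np.ones(len(df))}
    names = ["const"]
    for term in geo_terms:
        if term == "lon:lat":
            cols[term] = df["lon"].to_numpy(float) * df["lat"].to_numpy(float)
        else:
            cols[term] = df[term].to_numpy(float)
        names.append(term)
    if extra is not None:
        cols[extra] = df[extra].to_numpy(float)
        names.append(extra)
    return np.column_stack([cols[n] for n in names]), names


def fit_binomial_glm(
    successes: np.ndarray,
    totals: np.ndarray,
    data: pd.DataFrame,
    covariate: str | None = None,
    null_fit: "GlmFit | None" = None,
    geo_terms: tuple[str, ...] = NULL_TERMS,
) -> GlmFit:
    """Fit the logit-link binomial GLM (IRLS) for one covariate (or the null).

    ``successes``/``totals`` are haplotype-B counts and chromosome counts per
    site; ``data`` supplies lon/lat and covariate columns.  When ``null_fit``
    is given, reports the likelihood-ratio test of the covariate (1 df).
    ``geo_terms`` sets the geographic base design (empty for intercept-only).
    Perfect separation is flagged, not raised.
    """
    successes = np.asarray(successes, float)
    totals = np.asarray(totals, float)
    if np.any(successes < 0) or np.any(totals < successes):
        raise ValueError("need 0 <= successes <= totals")
    x, names = _design(data, covariate, geo_terms)
    if len(successes) <= x.shape[1] - 1:
        raise ValueError("need at least one more site than parameters")
    endog = np.column_stack([successes, totals - successes])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, x, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-10)
    mu = res.predict(x)
    separation = bool(np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10) or np.any(np.abs(res.params) > 1e2))
    k = x.shape[1]
    dof = max(len(successes) - k, 1)
    dispersion = float(res.pearson_chi2 / dof)
    lrt_stat = lrt_p = None
    if null_fit is not None:
        lrt_stat = max(float(null_fit.deviance - res.deviance), 0.0)
        lrt_p = float(stats.chi2.sf(lrt_stat, 1))
    return GlmFit(
        terms=names,
        coefficients=dict(zip(names, map(float, res.params))),
        deviance=float(res.deviance),
        aic=float(res.deviance + 2 * k),
        llf=float(res.llf),
        lrt_stat=lrt_stat,
        lrt_p=lrt_p,
        converged=bool(res.converged),
        separation_flag=separation,
        pearson_dispersion=dispersion,
    )


def env_screen(
    karyo_freqs: pd.DataFrame,
    env: pd.DataFrame,
    covariates: Sequence[str] = ENV_COVARIATES,
) -> pd.DataFrame:
    """One-model-per-covariate screen over the environmental table.

    ``karyo_freqs`` needs columns ``collection`` (or ``site``), ``q_hat`` and
    ``n``; ``env`` one row per site with lon/lat and the covariates.  Returns
    a table with the null row first, then one row per covariate with its
    deviance-scale AIC and likelihood-ratio p-value.
    """
    kf = karyo_freqs.copy()
    if "site" not in kf.columns:
        for cand in ("collection", "area"):
            if cand in kf.columns:
                kf = kf.rename(columns={cand: "site"})
                break
        else:
            raise ValueError("karyotype frequency table needs a site/collection column")
    merged = kf.merge(env, on="site", how="inner", validate="one_to_one")
    if len(merged) < len(kf) or len(merged) < len(env):
        dropped = sorted(set(kf["site"]).symmetric_difference(env["site"]))
        warnings.warn(f"sites without both tables dropped: {dropped}")
    if merged.empty:
        raise ValueError("no shared sites between frequency and environment tables")
    successes = np.rint(merged["q_hat"].to_numpy(float) * 2 * merged["n"].to_numpy(float))
    totals = 2 * merged["n"].to_numpy(float)

    null = fit_binomial_glm(successes, totals, merged, covariate=None)
    rows = [("Null (lon*lat)", null.aic, np.nan, null)]
    for cov in covariates:
        if cov not in merged.columns:
            raise ValueError(f"covariate {cov} absent from environment table")
        fit = fit_binomial_glm(successes, totals, merged, covariate=cov, null_fit=null)
        rows.append((f"lon*lat + {cov}", fit.aic, fit.lrt_p, fit))
    out = pd.DataFrame(
        {
            "model": [r[0] for r in rows],
            "AIC": [r[1] for r in rows],
            "lrt_p": [r[2] for r in rows],
        }
    )
    out.attrs["fits"] = {r[0]: r[3] for r in rows}
    return out
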