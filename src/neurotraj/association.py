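"""Covariance analysis of individual trajectory parameters.

For every region, the estimated onset age tau and log-pace xi are regressed
by ordinary least squares on female sex (0/1), APOE-e4 allele count (0/1/2)
and education (years).  Each coefficient gets a two-sided t-test against 0;
p-values are corrected across regions by Benjamini-Hochberg FDR, and the
surviving associations are rendered as signed -log10(q) maps (positive =
risk: earlier onset or faster pace; negative = protective).

Because xi is a log-pace, a coefficient beta on xi corresponds to a
multiplicative (e^beta - 1) * 100 percent change in progression pace, which
is reported alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

COVARIATES = ("sex_female", "apoe4_count", "education_years")
PARAMETERS = ("onset", "log_pace")
_PARAM_COL = {"onset": "tau", "log_pace": "xi"}


def ols_covariance(individual: pd.DataFrame,
                   covariates: pd.DataFrame,
                   disattenuate: bool | None = None) -> pd.DataFrame:
    """Per-region OLS of each individual parameter on the covariates.

    ``individual`` has columns subject_id, region, tau, xi (one row per
    subject per region); ``covariates`` has subject_id plus the three
    covariate columns.  Subjects missing covariates are dropped (counted in
    ``n``); a zero-variance covariate yields NA rows with a warning.

    Estimated individual parameters are posterior means, which shrink
    toward the population mode and therefore attenuate regression
    coefficients (classical measurement-error bias).  When the individual
    table carries posterior variances (``tau_var``/``xi_var``), the
    coefficients and standard errors are rescaled by the regression-
    calibration factor lambda = var(estimates) / (var(estimates) + mean
    posterior variance); t statistics and p-values are unaffected.  Set
    ``disattenuate=False`` to report the raw attenuated coefficients;
    the default applies the correction exactly when the variance columns
    are present.

    Returns the pre-FDR association table: region, parameter, covariate,
    beta, se, t, p, n, attenuation_lambda, percent_pace.
    """
    merged = individual.merge(covariates, on="subject_id", how="left")
    n_missing = int(merged[list(COVARIATES)].isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(f"dropping {n_missing} rows with missing covariates",
                      stacklevel=2)
        merged = merged.dropna(subset=list(COVARIATES))

    rows = []
    for region, sub in merged.groupby("region", sort=True):
        sub = sub.dropna(subset=["tau", "xi"])
        n = len(sub)
        if n < 10:
            raise ValueError(
                f"region {region!r}: only {n} subjects; need >= 10 for OLS")
        X = sm.add_constant(sub[list(COVARIATES)].to_numpy(dtype=float),
                            has_constant="add")
        degenerate = [
            cov for j, cov in enumerate(COVARIATES)
            if np.ptp(X[:, j + 1]) == 0
        ]
        if degenerate:
            warnings.warn(
                f"region {region!r}: constant covariate(s) {degenerate}; "
                "their coefficients are reported as NA", stacklevel=2)
        for parameter in PARAMETERS:
            col = _PARAM_COL[parameter]
            y = sub[col].to_numpy(dtype=float)
            var_col = f"{col}_var"
            lam = 1.0
            apply_corr = (disattenuate is not False) and var_col in sub.columns
            if disattenuate and var_col not in sub.columns:
                raise ValueError(
                    f"disattenuation requested but {var_col!r} column absent")
            if apply_corr and np.ptp(y) > 0:
                ev = float(sub[var_col].mean())
                lam = float(np.var(y) / (np.var(y) + ev))
            if np.ptp(y) == 0:
                for cov in COVARIATES:
                    rows.append(_row(region, parameter, cov, 0.0, np.nan,
                                     np.nan, np.nan, n, lam))
                continue
            fit = sm.OLS(y, X).fit()
            for j, cov in enumerate(COVARIATES):
                if cov in degenerate:
                    rows.append(_row(region, parameter, cov, np.nan, np.nan,
                                     np.nan, np.nan, n, lam))
                else:
                    rows.append(_row(region, parameter, cov,
                                     fit.params[j + 1] / lam,
                                     fit.bse[j + 1] / lam,
                                     fit.tvalues[j + 1], fit.pvalues[j + 1],
                                     n, lam))
    return pd.DataFrame(rows)


def _row(region, parameter, covariate, beta, se, t, p, n, lam=1.0):
    return {
        "region": region,
        "parameter": parameter,
        "covariate": covariate,
        "beta": beta,
        "se": se,
        "t": t,
        "p": p,
        "n": n,
        "attenuation_lambda": lam,
        "percent_pace": (np.expm1(beta) * 100.0
                         if parameter == "log_pace" and np.isfinite(beta)
                         else np.nan),
    }


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def add_fdr(results: pd.DataFrame, family: str = "per-map") -> pd.DataFrame:
    """Attach BH-FDR q-values to an association table.

    family="per-map": one correction family per (parameter, covariate) pair,
    across regions (matching one brain map per covariate and parameter).
    family="pooled": onset and pace tests pooled within each covariate.
    """
    if family not in ("per-map", "pooled"):
        raise ValueError(f"unknown FDR family mode {family!r}")
    out = results.copy()
    out["q"] = np.nan
    keys = (["parameter", "covariate"] if family == "per-map"
            else ["covariate"])
    for _, idx in out.groupby(keys).groups.items():
        block = out.loc[idx]
        ok = block["p"].notna()
        if ok.any():
            out.loc[block.index[ok], "q"] = fdr_adjust(block.loc[ok, "p"])
    return out


def significance_map(results: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Signed -log10(q) per region for associations surviving FDR.

    Regions with q > alpha are masked (absent from the output).  The sign
    encodes direction of risk: positive when the covariate brings an earlier
    onset (beta_tau < 0) or a faster pace (beta_xi > 0), negative when
    protective.
    """
    if "q" not in results.columns:
        raise ValueError("run add_fdr before significance_map")
    kept = results[results["q"].notna() & (results["q"] <= alpha)].copy()
    risk_sign = np.where(
        kept["parameter"] == "onset",
        -np.sign(kept["beta"]),   # earlier onset (negative beta) = risk
        np.sign(kept["beta"]),    # faster pace (positive beta) = risk
    )
    kept["signed_neglog10_q"] = -np.log10(kept["q"]) * risk_sign
    return kept[["region", "parameter", "covariate",
                 "signed_neglog10_q"]].reset_index(drop=True)


def covariate_correlations(covariates: pd.DataFrame) -> pd.DataFrame:
    """Absolute pairwise Pearson correlations between the three covariates."""
    if len(covariates) < 3:
        raise ValueError("need >= 3 subjects for correlations")
    pairs = [
        ("apoe4_count", "sex_female"),
        ("apoe4_count", "education_years"),
        ("sex_female", "education_years"),
    ]
    rows = []
    for a, b in pairs:
        xa = covariates[a].to_numpy(dtype=float)
        xb = covariates[b].to_numpy(dtype=float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            warnings.warn(f"zero-variance covariate in pair ({a}, {b})",
                          stacklevel=2)
            r = np.nan
        else:
            r = abs(float(np.corrcoef(xa, xb)[0, 1]))
        rows.append({"covariate_a": a, "covariate_b": b, "abs_correlation": r})
    return pd.DataFrame(rows)
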