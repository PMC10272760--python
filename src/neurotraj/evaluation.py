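"""Goodness-of-fit evaluation and trajectory-family comparison.

Reconstruction errors of the calibrated models are compared against the
measurement noise estimated from same-day test-retest duplicate scans: when
the two distributions overlap, the model explains the data down to the
measurement uncertainty and further flexibility would amount to overfitting.
A residual-bias audit regresses per-subject mean absolute residuals on
covariates and acquisition factors to check that misfit is not systematic.
Finally, linear and logistic trajectory families are compared on fitted
noise level and convergence stability.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import Family
from .saem import CalibrationResult, ObservationSet, SaemSettings, calibrate

_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


def test_retest_errors(visits: pd.DataFrame,
                       regions: list[str] | None = None) -> pd.DataFrame:
    """Noise sample from duplicate acquisitions.

    For every set of scans of one subject at one age containing at least one
    duplicate-flagged row, all pairwise differences contribute the proxy
    (y1 - y2) / sqrt(2), whose standard deviation estimates the
    single-measurement noise sd.  Returns long-format rows
    (subject_id, age_years, region, error).
    """
    if regions is None:
        regions = [c for c in visits.columns if c.startswith("region_")]
    dup_keys = visits.loc[visits["is_duplicate"] == 1,
                          ["subject_id", "age_years"]].drop_duplicates()
    if dup_keys.empty:
        warnings.warn("no duplicate visits found; empty test-retest sample",
                      stacklevel=2)
        return pd.DataFrame(columns=["subject_id", "age_years", "region", "error"])

    rows = []
    grouped = visits.merge(dup_keys, on=["subject_id", "age_years"]).groupby(
        ["subject_id", "age_years"], sort=True)
    for (sid, age), scans in grouped:
        for region in regions:
            vals = scans[region].to_numpy(dtype=float)
            for y1, y2 in itertools.combinations(vals, 2):
                rows.append({"subject_id": sid, "age_years": age,
                             "region": region,
                             "error": (y1 - y2) / np.sqrt(2.0)})
    return pd.DataFrame(rows)


@dataclass
class GofReport:
    """Quantile comparison of reconstruction errors vs test-retest noise."""

    table: pd.DataFrame   # per region: error quantiles, noise quantiles, overlap

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def gof_compare(residuals: pd.DataFrame,
                retest: pd.DataFrame) -> GofReport:
    """Per-region quantiles of |model residual| distribution vs test-retest
    errors, plus an interquartile-range overlap indicator."""
    if residuals.empty:
        raise ValueError("empty residual table")
    rows = []
    has_region = "region" in residuals.columns
    for region, sub in (residuals.groupby("region") if has_region
                        else [("all", residuals)]):
        r = sub["residual"].to_numpy(dtype=float)
        row = {"region": region}
        for qlev, val in zip(_QUANTILES, np.quantile(r, _QUANTILES)):
            row[f"resid_q{int(qlev * 100)}"] = val
        noise = retest.loc[retest["region"] == region, "error"] \
            if ("region" in retest.columns and not retest.empty) else retest.get("error", pd.Series(dtype=float))
        noise = np.asarray(noise, dtype=float)
        if noise.size:
            for qlev, val in zip(_QUANTILES, np.quantile(noise, _QUANTILES)):
                row[f"noise_q{int(qlev * 100)}"] = val
            # overlap is judged on error magnitudes: signed IQRs of two
            # zero-centered distributions always intersect regardless of scale
            r_iqr = np.quantile(np.abs(r), [0.25, 0.75])
            n_iqr = np.quantile(np.abs(noise), [0.25, 0.75])
            row["overlap"] = bool(max(r_iqr[0], n_iqr[0]) <= min(r_iqr[1], n_iqr[1]))
        else:
            for qlev in _QUANTILES:
                row[f"noise_q{int(qlev * 100)}"] = np.nan
            row["overlap"] = None
        rows.append(row)
    return GofReport(table=pd.DataFrame(rows))


def residual_bias_audit(residuals: pd.DataFrame,
                        covariates: pd.DataFrame,
                        visits: pd.DataFrame | None = None,
                        acquisition_cols: tuple = ("field_strength",),
                        signed: bool = False) -> pd.DataFrame:
    """Regression check that model misfit is unrelated to covariates or
    acquisition factors.

    The per-subject mean |residual| (or signed mean with ``signed=True``) is
    regressed by OLS on each factor separately; a small p-value flags a
    systematic bias.  Acquisition factors are summarized per subject as the
    mean of the factor over that subject's visits.
    """
    agg = (residuals.assign(val=residuals["residual"] if signed
                            else residuals["residual"].abs())
           .groupby("subject_id")["val"].mean().rename("mean_resid"))
    df = agg.reset_index().merge(covariates, on="subject_id", how="inner")
    factors = {c: df[c] for c in
               ("sex_female", "apoe4_count", "education_years")
               if c in df.columns}
    if visits is not None:
        for col in acquisition_cols:
            if col in visits.columns:
                per_subj = visits.groupby("subject_id")[col].mean()
                factors[col] = df["subject_id"].map(per_subj)
    rows = []
    y = df["mean_resid"].to_numpy(dtype=float)
    for name, x in factors.items():
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            rows.append({"factor": name, "beta": np.nan, "p": np.nan})
            continue
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        rows.append({"factor": name, "beta": float(fit.params[1]),
                     "p": float(fit.pvalues[1])})
    return pd.DataFrame(rows)


def compare_families(obs: ObservationSet, settings: SaemSettings,
                     tie_tolerance: float = 0.02) -> dict:
    """Calibrate both trajectory families and pick the better one.

    Selection is by lower fitted noise sd; fits within ``tie_tolerance``
    relative difference are reported as a tie and resolved toward the
    logistic family (bounded trajectories are the natural shape for
    normalized atrophy features).  Convergence stability (final-window trace
    sd of sigma_eps) is reported as secondary evidence.  If one family
    diverges the other is selected and flagged.
    """
    results: dict[Family, CalibrationResult | None] = {}
    for family in ("logistic", "linear"):
        try:
            results[family] = calibrate(obs, family, settings)
        except FloatingPointError:
            results[family] = None

    evidence = {}
    for family, res in results.items():
        if res is None:
            evidence[family] = {"sigma_eps": np.inf, "stability_sd": np.inf,
                                "diverged": True}
        else:
            evidence[family] = {
                "sigma_eps": res.fixed_effects.sigma_eps,
                "stability_sd": res.diagnostics["sigma_eps"],
                "diverged": False,
            }

    se_log = evidence["logistic"]["sigma_eps"]
    se_lin = evidence["linear"]["sigma_eps"]
    if np.isinf(se_log) and np.isinf(se_lin):
        raise FloatingPointError("both trajectory families diverged")
    if np.isinf(se_lin):
        selected, tie = "logistic", False
    elif np.isinf(se_log):
        selected, tie = "linear", False
    else:
        rel = abs(se_log - se_lin) / max(se_log, se_lin)
        tie = rel <= tie_tolerance
        if tie:
            selected = "logistic"
        else:
            selected = "logistic" if se_log < se_lin else "linear"
    return {"selected": selected, "tie": tie, "evidence": evidence,
            "results": results}
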