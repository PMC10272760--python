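"""MCMC-SAEM calibration of the nonlinear mixed-effects trajectory model.

The fixed effects are estimated by Maximum a Posteriori via stochastic
approximation EM: the E-step expectation is replaced by a Metropolis-within-
Gibbs sweep over each subject's (tau, xi), sufficient statistics are blended
with a Robbins-Monro step size, and the M-step updates the fixed effects in
closed form (t0 and the three variances) or by a damped quasi-Newton step on
the penalized data attachment (p0, v0).

Personalization (estimating a new subject's random effects under frozen
population parameters) is a deterministic multi-start MAP optimization.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import (
    Family,
    FixedEffects,
    Hyperpriors,
    IndividualParameters,
    curve_value,
)

logger = logging.getLogger(__name__)


@dataclass
class SaemSettings:
    """Tuning knobs of the MCMC-SAEM run.

    ``gamma`` is the Robbins-Monro step exponent: after burn-in the
    stochastic-approximation step is (k - n_burn_in)^(-gamma); convergence
    requires gamma in (0.5, 1].
    """

    n_iterations: int = 2000
    n_burn_in: int = 1000
    gamma: float = 0.65
    prop_tau: float = 2.0          # initial random-walk sd for tau (years)
    prop_xi: float = 0.2           # initial random-walk sd for xi
    target_accept: float = 0.3
    adapt_interval: int = 25
    seed: int = 0
    convergence_window: int = 200

    def validate(self) -> None:
        if not (0 < self.n_burn_in < self.n_iterations):
            raise ValueError("need 0 < n_burn_in < n_iterations")
        if not (0.5 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0.5, 1] for convergence")
        if self.prop_tau <= 0 or self.prop_xi <= 0:
            raise ValueError("proposal sds must be positive")
        if not (0 < self.target_accept < 1):
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class CalibrationResult:
    fixed_effects: FixedEffects
    family: Family
    # posterior-mean individual parameters (quadrature under the fitted
    # fixed effects; *_sa columns hold the stochastic-approximation average)
    individual: pd.DataFrame          # subject_id, tau, xi, pace, tau_sa, xi_sa
    traces: pd.DataFrame              # one row per iteration, fixed effects
    acceptance: dict                  # parameter -> overall acceptance rate
    diagnostics: dict                 # fixed effect -> sd over final window

    def individual_parameters(self) -> dict[str, IndividualParameters]:
        return {
            row.subject_id: IndividualParameters(tau=row.tau, xi=row.xi)
            for row in self.individual.itertuples()
        }


@dataclass
class ObservationSet:
    """Flat observation arrays for one region, sorted by (subject, age).

    ``subj_idx`` maps observations to positions in ``subject_ids``; sorting
    makes calibration invariant to the input row order.
    """

    t: np.ndarray
    y: np.ndarray
    subj_idx: np.ndarray
    subject_ids: list

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @classmethod
    def from_table(cls, visits: pd.DataFrame, region: str,
                   age_col: str = "age_years",
                   id_col: str = "subject_id",
                   drop_sparse: bool = True) -> "ObservationSet":
        df = visits[[id_col, age_col, region]].dropna()
        # the region value joins the sort key so that same-day duplicate
        # scans land in a canonical order whatever the input row order
        df = df.sort_values([id_col, age_col, region], kind="mergesort")
        counts = df[id_col].value_counts()
        few = sorted(counts[counts < 2].index.tolist())
        if few:
            # longitudinal modeling needs repeated measures; subjects can
            # drop below 2 visits after outlier filtering
            if drop_sparse:
                logger.warning(
                    "dropping %d subject(s) with fewer than 2 visits for %s: %s",
                    len(few), region, few)
                df = df[~df[id_col].isin(few)]
            else:
                raise ValueError(
                    f"subjects with fewer than 2 visits for {region}: {few}"
                )
        ids = sorted(df[id_col].unique().tolist())
        pos = {s: k for k, s in enumerate(ids)}
        return cls(
            t=df[age_col].to_numpy(dtype=float),
            y=df[region].to_numpy(dtype=float),
            subj_idx=df[id_col].map(pos).to_numpy(dtype=np.intp),
            subject_ids=ids,
        )


def _pooled_slope_and_resid_sd(obs: ObservationSet) -> tuple[float, float]:
    """Within-subject-centered OLS: common slope of y on age, residual sd."""
    df = pd.DataFrame({"s": obs.subj_idx, "t": obs.t, "y": obs.y})
    g = df.groupby("s")[["t", "y"]]
    centered = df[["t", "y"]] - g.transform("mean")
    denom = float(np.sum(centered["t"] ** 2))
    slope = float(np.sum(centered["t"] * centered["y"]) / denom) if denom else 0.0
    resid = centered["y"].to_numpy() - slope * centered["t"].to_numpy()
    return slope, float(np.std(resid))


def initialize(obs: ObservationSet) -> tuple[FixedEffects, np.ndarray, np.ndarray]:
    """Data-driven starting point.

    t0 = mean visit age; p0 = 0.5 (features min-max normalized); v0 = pooled
    within-subject slope, floored at 1e-4/y; sigma_eps = pooled residual sd;
    sigma_tau = sd of visit ages; sigma_xi = 0.5.  Each subject's onset age
    starts at the age where its mean-level line of slope v0 crosses p0
    (clipped to t0 +/- 3 sigma_tau), so the sampler does not have to travel
    tens of years from a common start; xi_i starts at 0.
    """
    slope, resid_sd = _pooled_slope_and_resid_sd(obs)
    if slope < 1e-4:
        logger.info("pooled slope %.3g below floor; v0 initialized at 1e-4", slope)
    v0 = max(slope, 1e-4)
    fx = FixedEffects(
        t0=float(np.mean(obs.t)),
        p0=0.5,
        v0=v0,
        sigma_eps=max(resid_sd, 1e-3),
        sigma_tau=max(float(np.std(obs.t)), 1.0),
        sigma_xi=0.5,
    )
    n = obs.n_subjects
    counts = np.bincount(obs.subj_idx, minlength=n)
    t_mean = np.bincount(obs.subj_idx, weights=obs.t, minlength=n) / counts
    y_mean = np.bincount(obs.subj_idx, weights=obs.y, minlength=n) / counts
    tau0 = t_mean + (fx.p0 - y_mean) / v0
    tau0 = np.clip(tau0, fx.t0 - 3 * fx.sigma_tau, fx.t0 + 3 * fx.sigma_tau)
    return fx, tau0, np.zeros(n)


def _predictions(obs: ObservationSet, fx: FixedEffects, tau, xi,
                 family: Family) -> np.ndarray:
    u = np.exp(xi[obs.subj_idx]) * (obs.t - tau[obs.subj_idx]) + fx.t0
    return curve_value(u, fx, family)


def _subject_sse(obs: ObservationSet, fx: FixedEffects, tau, xi,
                 family: Family) -> np.ndarray:
    resid = obs.y - _predictions(obs, fx, tau, xi, family)
    return np.bincount(obs.subj_idx, weights=resid**2, minlength=obs.n_subjects)


def _theta_from_fx(fx: FixedEffects, family: Family) -> np.ndarray:
    if family == "logistic":
        return np.array([math.log(fx.p0 / (1 - fx.p0)), math.log(fx.v0)])
    return np.array([fx.p0, math.log(fx.v0)])


def _fx_with_theta(fx: FixedEffects, theta, family: Family) -> FixedEffects:
    p0 = 1.0 / (1.0 + math.exp(-theta[0])) if family == "logistic" else float(theta[0])
    return FixedEffects(t0=fx.t0, p0=p0, v0=float(math.exp(theta[1])),
                        sigma_eps=fx.sigma_eps, sigma_tau=fx.sigma_tau,
                        sigma_xi=fx.sigma_xi)


def calibrate(obs: ObservationSet, family: Family, settings: SaemSettings,
              hyperpriors: Hyperpriors | None = None) -> CalibrationResult:
    """Run MCMC-SAEM on one region's observations.

    Each iteration performs (S) one Metropolis-within-Gibbs sweep over every
    subject's tau then xi with Gaussian random-walk proposals, (SA) a
    stochastic-approximation update of the sufficient statistics, and (M)
    closed-form / damped quasi-Newton updates of the fixed effects.  The
    log-pace gauge (v0 <-> mean xi) is fixed by absorbing the sampled mean of
    xi into v0 after every sweep, which leaves all predictions unchanged.
    """
    settings.validate()
    fx, tau, xi = initialize(obs)
    if hyperpriors is None:
        hyperpriors = Hyperpriors.anchored_at(fx, family)
    rng = np.random.default_rng(settings.seed)
    n, m = obs.n_subjects, obs.t.size

    anchors = {
        "sigma_tau": math.exp(hyperpriors.log_sigma_tau_mean),
        "sigma_xi": math.exp(hyperpriors.log_sigma_xi_mean),
        "sigma_eps": math.exp(hyperpriors.log_sigma_eps_mean),
    }
    prior_w = 1.0  # pseudo-count blending the sigma updates with the hyperprior

    # sufficient statistics: mean tau, mean tau^2, mean xi^2, mean sq residual
    sse = _subject_sse(obs, fx, tau, xi, family)
    stats = np.array([tau.mean(), np.mean(tau**2), np.mean(xi**2), sse.sum() / m])
    ip_tau, ip_xi = tau.copy(), xi.copy()   # SA posterior-mean estimates

    # per-subject random-walk scales, adapted independently during burn-in
    prop = {"tau": np.full(n, settings.prop_tau),
            "xi": np.full(n, settings.prop_xi)}
    acc_count = {"tau": 0, "xi": 0}
    acc_window = {"tau": np.zeros(n), "xi": np.zeros(n)}
    trace = np.empty((settings.n_iterations, 6))

    for k in range(settings.n_iterations):
        inv_2se2 = 0.5 / fx.sigma_eps**2
        # --- (S) Metropolis-within-Gibbs sweep, vectorized over subjects ---
        for name in ("tau", "xi"):
            if name == "tau":
                cand = tau + rng.normal(0.0, prop["tau"], n)
                sse_new = _subject_sse(obs, fx, cand, xi, family)
                d_prior = (
                    (tau - fx.t0) ** 2 - (cand - fx.t0) ** 2
                ) * (0.5 / fx.sigma_tau**2)
            else:
                cand = xi + rng.normal(0.0, prop["xi"], n)
                sse_new = _subject_sse(obs, fx, tau, cand, family)
                d_prior = (xi**2 - cand**2) * (0.5 / fx.sigma_xi**2)
            log_alpha = (sse - sse_new) * inv_2se2 + d_prior
            accept = np.log(rng.random(n)) < log_alpha
            if name == "tau":
                tau = np.where(accept, cand, tau)
            else:
                xi = np.where(accept, cand, xi)
            sse = np.where(accept, sse_new, sse)
            acc_count[name] += int(accept.sum())
            acc_window[name] += accept

        # --- gauge fixing: absorb mean(xi) into v0 (predictions unchanged) ---
        xi_mean = xi.mean()
        if abs(xi_mean) > 1e-12:
            xi = xi - xi_mean
            fx.v0 = fx.v0 * math.exp(xi_mean)

        # --- proposal adaptation during burn-in ---
        if k < settings.n_burn_in and (k + 1) % settings.adapt_interval == 0:
            for name in ("tau", "xi"):
                rate = acc_window[name] / settings.adapt_interval
                prop[name] = prop[name] * np.exp(rate - settings.target_accept)
                acc_window[name] = np.zeros(n)

        # --- (SA) sufficient-statistic update ---
        eps_k = 1.0 if k < settings.n_burn_in else (k - settings.n_burn_in + 1) ** (-settings.gamma)
        current = np.array([tau.mean(), np.mean(tau**2), np.mean(xi**2), sse.sum() / m])
        stats += eps_k * (current - stats)
        ip_tau += eps_k * (tau - ip_tau)
        ip_xi += eps_k * (xi - ip_xi)

        # --- (M) fixed-effect updates ---
        s1, s2, s3, s4 = stats
        prec = n / fx.sigma_tau**2 + 1.0 / hyperpriors.t0_sd**2
        fx.t0 = (n * s1 / fx.sigma_tau**2
                 + hyperpriors.t0_mean / hyperpriors.t0_sd**2) / prec
        var_tau = max(s2 - s1**2, 0.0)
        fx.sigma_tau = math.sqrt(
            (n * var_tau + prior_w * anchors["sigma_tau"] ** 2) / (n + prior_w)
        )
        fx.sigma_xi = math.sqrt(
            (n * s3 + prior_w * anchors["sigma_xi"] ** 2) / (n + prior_w)
        )
        fx.sigma_eps = math.sqrt(
            max((m * s4 + prior_w * anchors["sigma_eps"] ** 2) / (m + prior_w), 1e-8)
        )

        # (p0, v0): damped quasi-Newton step on the penalized data attachment
        theta0 = _theta_from_fx(fx, family)

        def neg_pen_loglik(theta):
            fx_c = _fx_with_theta(fx, theta, family)
            resid = obs.y - _predictions(obs, fx_c, tau, xi, family)
            nll = 0.5 * np.sum(resid**2) / fx.sigma_eps**2
            nll += 0.5 * ((theta[0] - hyperpriors.p0_loc) / hyperpriors.p0_sd) ** 2
            nll += 0.5 * ((theta[1] - hyperpriors.log_v0_mean) / hyperpriors.log_v0_sd) ** 2
            return nll

        res = optimize.minimize(neg_pen_loglik, theta0, method="L-BFGS-B",
                                options={"maxiter": 3})
        theta = theta0 + 0.5 * (res.x - theta0)
        fx = _fx_with_theta(fx, theta, family)

        # p0 is a pure gauge freedom (it only chooses the reference point on
        # the curve): re-express the model at p0 = p_ref with the exact
        # prediction-preserving compensation of every tau_i, so that tau
        # always means "age at crossing p_ref" and t0 stays comparable.
        p_ref = 0.5
        if family == "logistic" and fx.p0 != p_ref:
            a = fx.v0 / (fx.p0 * (1.0 - fx.p0))
            delta = math.log(fx.p0 / (1 - fx.p0)) - math.log(p_ref / (1 - p_ref))
            tau = tau - delta / (a * np.exp(xi))
            fx.v0 = a * p_ref * (1.0 - p_ref)
            fx.p0 = p_ref
        elif family == "linear" and fx.p0 != p_ref:
            tau = tau + (p_ref - fx.p0) / (fx.v0 * np.exp(xi))
            fx.p0 = p_ref

        trace[k] = [fx.t0, fx.p0, fx.v0, fx.sigma_eps, fx.sigma_tau, fx.sigma_xi]
        if not np.all(np.isfinite(trace[k])):
            raise FloatingPointError(
                f"MCMC-SAEM diverged at iteration {k}; trace tail:\n"
                f"{trace[max(0, k - 5): k + 1]}"
            )
        sse = _subject_sse(obs, fx, tau, xi, family)

    total_props = settings.n_iterations * n
    acceptance = {name: acc_count[name] / total_props for name in acc_count}
    for name, rate in acceptance.items():
        if rate < 0.01:
            warnings.warn(
                f"acceptance rate for {name} is {rate:.3f} (<1%); "
                "the chain is likely stuck", stacklevel=2)

    cols = ["t0", "p0", "v0", "sigma_eps", "sigma_tau", "sigma_xi"]
    traces = pd.DataFrame(trace, columns=cols)
    window = traces.iloc[-settings.convergence_window:]
    diagnostics = {c: float(window[c].std(ddof=1)) for c in cols}

    # Final E-step: exact posterior means of (tau, xi) under the fitted
    # fixed effects, replacing the noisier stochastic-approximation average
    # (kept alongside as *_sa for diagnostics).
    individual = posterior_mean_individual(obs, fx, family)
    individual["tau_sa"] = ip_tau
    individual["xi_sa"] = ip_xi
    return CalibrationResult(
        fixed_effects=fx,
        family=family,
        individual=individual,
        traces=traces,
        acceptance=acceptance,
        diagnostics=diagnostics,
    )


def _quad_moments(t, y, tg, xg, fx: FixedEffects, family: Family):
    """Posterior moments of (tau, xi) for one subject on a tensor grid."""
    TT, XX = np.meshgrid(tg, xg, indexing="ij")
    u = np.exp(XX)[..., None] * (t - TT[..., None]) + fx.t0
    pred = curve_value(u, fx, family)
    ll = -0.5 * np.sum((y - pred) ** 2, axis=-1) / fx.sigma_eps**2
    ll -= 0.5 * ((TT - fx.t0) / fx.sigma_tau) ** 2
    ll -= 0.5 * (XX / fx.sigma_xi) ** 2
    w = np.exp(ll - ll.max())
    w /= w.sum()
    e_tau = float(np.sum(w * TT))
    e_xi = float(np.sum(w * XX))
    v_tau = float(np.sum(w * (TT - e_tau) ** 2))
    v_xi = float(np.sum(w * (XX - e_xi) ** 2))
    return e_tau, e_xi, v_tau, v_xi


def posterior_mean_individual(obs: ObservationSet, fx: FixedEffects,
                              family: Family,
                              n_tau: int = 141, n_xi: int = 81) -> pd.DataFrame:
    """Posterior mean and variance of each subject's (tau, xi) by adaptive
    2-D quadrature.

    A first pass on a grid spanning +/- 4 prior sd locates each subject's
    posterior; a second pass re-integrates on a grid covering the located
    mean +/- 6 posterior sd, so sharply peaked posteriors (visit noise much
    smaller than the prior spread) are resolved instead of rounded to the
    coarse grid.  Deterministic, and more efficient than averaging
    correlated sampler states, so calibration uses this as its final E-step.
    """
    tg = np.linspace(fx.t0 - 4 * fx.sigma_tau, fx.t0 + 4 * fx.sigma_tau, n_tau)
    xg = np.linspace(-4 * fx.sigma_xi, 4 * fx.sigma_xi, n_xi)
    rows = []
    for s, sid in enumerate(obs.subject_ids):
        m = obs.subj_idx == s
        t, y = obs.t[m], obs.y[m]
        e_tau, e_xi, v_tau, v_xi = _quad_moments(t, y, tg, xg, fx, family)
        # refinement: local grid, at least as fine as needed and never wider
        # than the coarse one
        half_t = min(6 * math.sqrt(v_tau) + 1e-9, 4 * fx.sigma_tau)
        half_x = min(6 * math.sqrt(v_xi) + 1e-9, 4 * fx.sigma_xi)
        tg2 = np.linspace(e_tau - half_t, e_tau + half_t, n_tau)
        xg2 = np.linspace(e_xi - half_x, e_xi + half_x, n_xi)
        e_tau, e_xi, v_tau, v_xi = _quad_moments(t, y, tg2, xg2, fx, family)
        rows.append({"subject_id": sid, "tau": e_tau, "xi": e_xi,
                     "tau_var": v_tau, "xi_var": v_xi})
    out = pd.DataFrame(rows)
    out["pace"] = np.exp(out["xi"])
    return out


def _subject_neg_log_post(params, t, y, fx: FixedEffects, family: Family):
    tau, xi = params
    u = math.exp(xi) * (t - tau) + fx.t0
    pred = curve_value(u, fx, family)
    nll = 0.5 * np.sum((y - pred) ** 2) / fx.sigma_eps**2
    nll += 0.5 * ((tau - fx.t0) / fx.sigma_tau) ** 2
    nll += 0.5 * (xi / fx.sigma_xi) ** 2
    return nll


def personalize(obs: ObservationSet, fx: FixedEffects,
                family: Family = "logistic") -> pd.DataFrame:
    """MAP estimate of each subject's (tau, xi) under frozen fixed effects.

    Deterministic multi-start local optimization; starts are the prior mode
    and its +/- one-sd neighbors.  Ties (within 1e-9 of the best objective)
    are resolved toward the smallest absolute log-pace.  Subjects for which
    every start fails are flagged (``converged=False``) and should be
    excluded downstream.
    """
    fx.validate(family)
    starts = [
        (t_start, x_start)
        for t_start in (fx.t0, fx.t0 - fx.sigma_tau, fx.t0 + fx.sigma_tau)
        for x_start in (0.0, -fx.sigma_xi, fx.sigma_xi)
    ]
    rows = []
    for s, sid in enumerate(obs.subject_ids):
        mask = obs.subj_idx == s
        t, y = obs.t[mask], obs.y[mask]
        best = None
        for start in starts:
            res = optimize.minimize(
                _subject_neg_log_post, np.array(start), args=(t, y, fx, family),
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
            )
            if not np.isfinite(res.fun):
                continue
            if (
                best is None
                or res.fun < best.fun - 1e-9
                or (abs(res.fun - best.fun) <= 1e-9
                    and abs(res.x[1]) < abs(best.x[1]))
            ):
                best = res
        if best is None:
            logger.warning("personalization failed for subject %r", sid)
            rows.append({"subject_id": sid, "tau": np.nan, "xi": np.nan,
                         "pace": np.nan, "converged": False})
        else:
            tau, xi = best.x
            rows.append({"subject_id": sid, "tau": float(tau), "xi": float(xi),
                         "pace": float(math.exp(xi)), "converged": True})
    return pd.DataFrame(rows)


def reconstruct(obs: ObservationSet, fx: FixedEffects,
                individual: pd.DataFrame, family: Family = "logistic",
                region: str | None = None) -> pd.DataFrame:
    """Residuals y_ij - prediction at each visit for calibrated parameters."""
    ip = individual.set_index("subject_id")
    tau = np.array([ip.loc[s, "tau"] for s in obs.subject_ids])
    xi = np.array([ip.loc[s, "xi"] for s in obs.subject_ids])
    pred = _predictions(obs, fx, tau, xi, family)
    out = pd.DataFrame(
        {
            "subject_id": np.asarray(obs.subject_ids, dtype=object)[obs.subj_idx],
            "age_years": obs.t,
            "observed": obs.y,
            "predicted": pred,
            "residual": obs.y - pred,
        }
    )
    if region is not None:
        out.insert(1, "region", region)
    return out
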