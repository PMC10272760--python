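"""Nonlinear mixed-effects trajectory model for longitudinal atrophy features.

Each feature (cortical thickness or normalized subcortical volume of one
region) is modeled independently.  A subject's measurements follow the
population curve after an affine time warp:

    y_ij = f( e^{xi_i} * (t_ij - tau_i) + t0 ) + eps_ij

where ``tau_i`` is the subject's onset age (the age at which the feature
crosses the population reference value ``p0``) and ``e^{xi_i}`` the subject's
progression pace.  ``f`` is either an affine function or a logistic curve with
asymptotes 0 and 1; both satisfy f(t0) = p0 and f'(t0) = v0.

Priors: eps ~ N(0, sigma_eps^2), tau ~ N(t0, sigma_tau^2),
xi ~ N(0, sigma_xi^2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy import special

Family = Literal["logistic", "linear"]

_SERIAL_VERSION = 1


@dataclass
class FixedEffects:
    """Population parameters of one feature's trajectory model.

    Parameters
    ----------
    t0 : float
        Reference time (years): age at which the average trajectory crosses
        ``p0``.
    p0 : float
        Reference position; must lie in (0, 1) for the logistic family.
    v0 : float
        Reference velocity (feature units per year) at ``t0``; positive for
        features oriented to increase over time.
    sigma_eps : float
        Observation-noise standard deviation (normalized feature units).
    sigma_tau : float
        Standard deviation of the onset-age random effect (years).
    sigma_xi : float
        Standard deviation of the log-pace random effect (dimensionless).
    """

    t0: float
    p0: float
    v0: float
    sigma_eps: float
    sigma_tau: float
    sigma_xi: float

    def validate(self, family: Family = "logistic") -> None:
        for name in ("sigma_eps", "sigma_tau", "sigma_xi"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if family == "logistic" and not (0.0 < self.p0 < 1.0):
            raise ValueError(
                f"logistic family requires 0 < p0 < 1, got p0={self.p0}"
            )
        for name in ("t0", "p0", "v0"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_json(self, family: Family = "logistic") -> str:
        d = asdict(self)
        d["family"] = family
        d["version"] = _SERIAL_VERSION
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> tuple["FixedEffects", Family]:
        d = json.loads(text)
        family = d.pop("family", "logistic")
        d.pop("version", None)
        return cls(**d), family


@dataclass
class IndividualParameters:
    """Per-subject random effects: onset age ``tau`` and log-pace ``xi``."""

    tau: float
    xi: float

    @property
    def pace(self) -> float:
        """Multiplicative progression pace ``e^xi`` (always positive)."""
        return math.exp(self.xi)

    def to_dict(self) -> dict:
        return {"tau": self.tau, "xi": self.xi, "pace": self.pace}


@dataclass
class Observation:
    """One measurement of one subject: value ``y`` at age ``t`` (years)."""

    subject: int
    visit: int
    t: float
    y: float


@dataclass
class Hyperpriors:
    """Weak priors on the fixed effects, keeping the MAP proper.

    Gaussians on t0, logit(p0) (logistic) or p0 (linear), and log(v0);
    half-Gaussians (Gaussian on the log, centered at the anchor) on the three
    standard deviations.  Anchors default to the initialization values so the
    priors act as mild regularizers, not as information.
    """

    t0_mean: float = 70.0
    t0_sd: float = 10.0
    p0_loc: float = 0.0      # on logit scale for logistic, raw for linear
    p0_sd: float = 1.0
    log_v0_mean: float = math.log(0.05)
    log_v0_sd: float = 1.0
    log_sigma_eps_mean: float = math.log(0.05)
    log_sigma_tau_mean: float = math.log(5.0)
    log_sigma_xi_mean: float = math.log(0.5)
    log_sigma_sd: float = 1.0

    def log_density(self, fx: FixedEffects, family: Family) -> float:
        def norm_lp(x: float, mu: float, sd: float) -> float:
            return -0.5 * math.log(2 * math.pi * sd**2) - 0.5 * ((x - mu) / sd) ** 2

        if family == "logistic":
            p0_x = math.log(fx.p0 / (1.0 - fx.p0))
        else:
            p0_x = fx.p0
        lp = norm_lp(fx.t0, self.t0_mean, self.t0_sd)
        lp += norm_lp(p0_x, self.p0_loc, self.p0_sd)
        lp += norm_lp(math.log(fx.v0), self.log_v0_mean, self.log_v0_sd)
        lp += norm_lp(math.log(fx.sigma_eps), self.log_sigma_eps_mean, self.log_sigma_sd)
        lp += norm_lp(math.log(fx.sigma_tau), self.log_sigma_tau_mean, self.log_sigma_sd)
        lp += norm_lp(math.log(fx.sigma_xi), self.log_sigma_xi_mean, self.log_sigma_sd)
        return lp

    @classmethod
    def anchored_at(cls, fx: FixedEffects, family: Family) -> "Hyperpriors":
        """Center the hyperpriors at a given (typically initial) estimate."""
        if family == "logistic":
            p0_loc = math.log(fx.p0 / (1.0 - fx.p0))
        else:
            p0_loc = fx.p0
        return cls(
            t0_mean=fx.t0,
            p0_loc=p0_loc,
            log_v0_mean=math.log(fx.v0),
            log_sigma_eps_mean=math.log(fx.sigma_eps),
            log_sigma_tau_mean=math.log(fx.sigma_tau),
            log_sigma_xi_mean=math.log(fx.sigma_xi),
        )


def curve_value(u, fx: FixedEffects, family: Family = "logistic"):
    """Population trajectory evaluated at reparametrized time ``u``.

    linear:    p0 + v0 * (u - t0)
    logistic:  1 / (1 + (1/p0 - 1) * exp(-v0 * (u - t0) / (p0 * (1 - p0))))

    Both satisfy curve_value(t0) = p0 and d/du curve_value at t0 = v0; the
    logistic has asymptotes 0 and 1.
    """
    u = np.asarray(u, dtype=float)
    if family == "linear":
        out = fx.p0 + fx.v0 * (u - fx.t0)
    elif family == "logistic":
        if not (0.0 < fx.p0 < 1.0):
            raise ValueError(f"logistic family requires 0 < p0 < 1, got {fx.p0}")
        z = fx.v0 * (u - fx.t0) / (fx.p0 * (1.0 - fx.p0))
        logit_p0 = math.log(fx.p0 / (1.0 - fx.p0))
        out = special.expit(z + logit_p0)
    else:
        raise ValueError(f"unknown family: {family!r}")
    return out if out.ndim else float(out)


def time_warp(t, tau, xi, t0):
    """Affine subject-to-population time reparametrization.

    u = e^xi * (t - tau) + t0.  At t = tau the subject sits at the reference
    time t0, i.e. crosses the population value p0.
    """
    t = np.asarray(t, dtype=float)
    return np.exp(xi) * (t - tau) + t0


def individual_prediction(t, fx: FixedEffects, ip: IndividualParameters,
                          family: Family = "logistic"):
    """Model prediction for one subject at age(s) ``t``."""
    return curve_value(time_warp(t, ip.tau, ip.xi, fx.t0), fx, family)


def gaussian_loglik(resid, sd):
    """Sum of N(0, sd^2) log-densities of the residuals."""
    resid = np.asarray(resid, dtype=float)
    return float(
        -0.5 * resid.size * math.log(2 * math.pi * sd**2)
        - 0.5 * np.sum(resid**2) / sd**2
    )


def data_log_likelihood(obs_t, obs_y, subj_idx, fx: FixedEffects,
                        tau: np.ndarray, xi: np.ndarray,
                        family: Family = "logistic") -> float:
    """Data-attachment term: sum over observations of log N(y | pred, sigma_eps^2).

    ``subj_idx`` maps each observation to its subject's entry in ``tau``/``xi``.
    """
    u = np.exp(xi[subj_idx]) * (obs_t - tau[subj_idx]) + fx.t0
    pred = curve_value(u, fx, family)
    return gaussian_loglik(obs_y - pred, fx.sigma_eps)


def random_effects_log_prior(fx: FixedEffects, tau: np.ndarray,
                             xi: np.ndarray) -> float:
    """Sum of log N(tau_i | t0, sigma_tau^2) + log N(xi_i | 0, sigma_xi^2)."""
    return gaussian_loglik(tau - fx.t0, fx.sigma_tau) + gaussian_loglik(xi, fx.sigma_xi)


def complete_log_posterior(obs_t, obs_y, subj_idx, fx: FixedEffects,
                           tau, xi, family: Family = "logistic",
                           hyperpriors: Hyperpriors | None = None) -> float:
    """Complete-data log posterior of fixed and random effects.

    Data term + random-effect priors + (optional) hyperpriors on the fixed
    effects.  Raises on non-finite inputs.
    """
    obs_t = np.asarray(obs_t, dtype=float)
    obs_y = np.asarray(obs_y, dtype=float)
    tau = np.asarray(tau, dtype=float)
    xi = np.asarray(xi, dtype=float)
    for name, arr in (("obs_t", obs_t), ("obs_y", obs_y), ("tau", tau), ("xi", xi)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    fx.validate(family)
    lp = data_log_likelihood(obs_t, obs_y, subj_idx, fx, tau, xi, family)
    lp += random_effects_log_prior(fx, tau, xi)
    if hyperpriors is not None:
        lp += hyperpriors.log_density(fx, family)
    if not math.isfinite(lp):
        raise ValueError("non-finite log posterior")
    return lp
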