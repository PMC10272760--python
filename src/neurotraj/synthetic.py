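"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of an ADNI-like multi-region atrophy data
set: per-region logistic (or linear) decline with subject-specific onset age
and log-pace, covariate-driven shifts of those random effects, Gaussian
measurement noise, two scanner field strengths with an additive offset,
same-day test-retest duplicate scans, and cohort demographics patterned on a
late-onset Alzheimer's study population.

The ground truth (generating fixed effects, per-subject random effects,
covariates, applied scanner offsets) is retained so downstream estimation can
be validated by parameter recovery.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import FixedEffects, Family, curve_value

# Defaults patterned on the AD arm of a large longitudinal aging study:
# ~44% women, APOE-e4 allele-count mix 19%/50%/31% (2/1/0 copies),
# education 15.5 +/- 2.8 y, baseline age 74.4 +/- 7.4 y, 2-7 scans per
# subject roughly yearly, about half of scans at 3T, ~24% of scans with a
# same-day duplicate acquisition.
_DEFAULT_COVARIATE_EFFECTS = {
    # covariate -> (shift on onset age tau in years, shift on log-pace xi)
    "apoe4_count": (-1.5, 0.0),
    "sex_female": (0.0, math.log(1.23)),
    "education_years": (0.0, 0.0),
}

COVARIATE_COLUMNS = ("sex_female", "apoe4_count", "education_years")


def default_region_params(n_regions: int = 10) -> list[FixedEffects]:
    """Identical generating fixed effects for every region.

    t0=74 y, p0=0.5, v0=0.05/y, sigma_tau=7 y, sigma_xi=0.5, sigma_eps=0.02
    (normalized units) -- trajectories traverse a visible fraction of [0,1]
    over a typical follow-up window.
    """
    return [
        FixedEffects(t0=74.0, p0=0.5, v0=0.05,
                     sigma_eps=0.02, sigma_tau=7.0, sigma_xi=0.5)
        for _ in range(n_regions)
    ]


@dataclass
class CohortConfig:
    """Generating configuration for one synthetic cohort."""

    n_subjects: int = 200
    n_regions: int = 10
    region_params: list[FixedEffects] | None = None
    # either one map applied to every region, or a list of per-region maps
    covariate_effects: dict[str, tuple[float, float]] | list[dict] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    family: Family = "logistic"
    group_label: str = "AD"
    baseline_age_mean: float = 74.4
    baseline_age_sd: float = 7.4
    visits_per_subject_min: int = 2
    visits_per_subject_max: int = 7
    visit_interval_mean: float = 1.0
    visit_interval_sd: float = 0.5
    prop_female: float = 0.442
    prop_apoe4_1: float = 0.502
    prop_apoe4_2: float = 0.192
    education_mean: float = 15.5
    education_sd: float = 2.8
    scanner_offset: float = 0.02   # additive 3T - 1.5T shift, feature units
    prop_3T: float = 0.49
    duplicate_fraction: float = 0.24
    seed: int = 0

    def __post_init__(self):
        if self.region_params is None:
            self.region_params = default_region_params(self.n_regions)

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_regions < 1:
            raise ValueError("n_subjects and n_regions must be positive")
        if len(self.region_params) != self.n_regions:
            raise ValueError(
                f"expected {self.n_regions} region_params, got {len(self.region_params)}"
            )
        for fx in self.region_params:
            fx.validate(self.family)
        probs = {
            "prop_female": self.prop_female,
            "prop_apoe4_1": self.prop_apoe4_1,
            "prop_apoe4_2": self.prop_apoe4_2,
            "prop_3T": self.prop_3T,
            "duplicate_fraction": self.duplicate_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {p}")
        if self.prop_apoe4_1 + self.prop_apoe4_2 > 1.0:
            raise ValueError("prop_apoe4_1 + prop_apoe4_2 must be <= 1")
        if self.visits_per_subject_min < 2:
            raise ValueError("visits_per_subject_min must be >= 2 "
                             "(longitudinal modeling needs repeated measures)")
        if self.visits_per_subject_max < self.visits_per_subject_min:
            raise ValueError("visits_per_subject_max < visits_per_subject_min")
        for name in ("baseline_age_sd", "visit_interval_sd", "education_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        effects = self.covariate_effects
        if isinstance(effects, list):
            if len(effects) != self.n_regions:
                raise ValueError(
                    f"per-region covariate_effects list must have "
                    f"{self.n_regions} entries, got {len(effects)}")
        else:
            effects = [effects]
        for per_region in effects:
            for cov in per_region:
                if cov not in COVARIATE_COLUMNS:
                    raise ValueError(
                        f"unknown covariate {cov!r}; expected one of "
                        f"{COVARIATE_COLUMNS}")
        if self.n_subjects < 4:
            warnings.warn(
                "fewer subjects than covariate levels: downstream OLS on "
                "[1, sex, APOE, education] will be rank-deficient",
                stacklevel=2,
            )


@dataclass
class SyntheticTruth:
    """Generating parameters retained for recovery testing."""

    region_params: list[FixedEffects]
    family: Family
    # DataFrames: individual (subject_id, region, tau, xi), covariates,
    # scanner offsets applied per visit row.
    individual: pd.DataFrame = None
    covariates: pd.DataFrame = None
    scanner_offset: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "scanner_offset": self.scanner_offset,
                "region_params": [asdict(fx) for fx in self.region_params],
                "individual": self.individual.to_dict(orient="list"),
                "covariates": self.covariates.to_dict(orient="list"),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            region_params=[FixedEffects(**p) for p in d["region_params"]],
            family=d["family"],
            individual=pd.DataFrame(d["individual"]),
            covariates=pd.DataFrame(d["covariates"]),
            scanner_offset=d["scanner_offset"],
        )


def _sample_covariates(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_subjects
    female = (rng.random(n) < cfg.prop_female).astype(int)
    u = rng.random(n)
    apoe = np.zeros(n, dtype=int)
    apoe[u < cfg.prop_apoe4_2] = 2
    apoe[(u >= cfg.prop_apoe4_2)
         & (u < cfg.prop_apoe4_2 + cfg.prop_apoe4_1)] = 1
    edu = rng.normal(cfg.education_mean, cfg.education_sd, n)
    edu = np.clip(np.round(edu), 6, 22)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "sex_female": female,
            "apoe4_count": apoe,
            "education_years": edu,
        }
    )


def _covariate_shift(cov: pd.DataFrame, effects: dict, which: int) -> np.ndarray:
    """Linear combination sum_c beta_c * x_c; ``which`` picks tau(0)/xi(1)."""
    shift = np.zeros(len(cov))
    for name, betas in effects.items():
        beta = betas[which]
        if beta != 0.0:
            shift += beta * cov[name].to_numpy(dtype=float)
    return shift


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a longitudinal cohort.

    Returns
    -------
    visits : DataFrame
        Columns subject_id, age_years, group, field_strength (1.5 or 3.0),
        is_duplicate, region_1..region_K.  One row per scan; duplicate scans
        repeat the same subject and age with fresh measurement noise.
    covariates : DataFrame
        Columns subject_id, sex_female, apoe4_count, education_years.
    truth : SyntheticTruth
        Generating fixed effects and per-subject (tau, xi) per region.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    cov = _sample_covariates(config, rng)

    # Per-subject visit schedule: baseline age + cumulative positive intervals.
    n_visits = rng.integers(config.visits_per_subject_min,
                            config.visits_per_subject_max + 1, size=n)
    baseline = rng.normal(config.baseline_age_mean, config.baseline_age_sd, n)
    subj_rows, age_rows = [], []
    for i in range(n):
        intervals = rng.normal(config.visit_interval_mean,
                               config.visit_interval_sd, n_visits[i] - 1)
        intervals = np.maximum(intervals, 0.1)
        ages = baseline[i] + np.concatenate([[0.0], np.cumsum(intervals)])
        subj_rows.append(np.full(n_visits[i], i))
        age_rows.append(ages)
    subj_idx = np.concatenate(subj_rows)
    ages = np.concatenate(age_rows)

    # Duplicate (test-retest) scans: same subject & age, fresh noise.
    is_dup = rng.random(ages.size) < config.duplicate_fraction
    dup_subj = subj_idx[is_dup]
    dup_ages = ages[is_dup]
    all_subj = np.concatenate([subj_idx, dup_subj])
    all_ages = np.concatenate([ages, dup_ages])
    dup_flag = np.concatenate(
        [np.zeros(ages.size, dtype=int), np.ones(dup_subj.size, dtype=int)]
    )

    # Scanner field strength per scan; a duplicate keeps its source's scanner.
    field = np.where(rng.random(ages.size) < config.prop_3T, 3.0, 1.5)
    all_field = np.concatenate([field, field[is_dup]])

    visits = pd.DataFrame(
        {
            "subject_id": cov["subject_id"].to_numpy()[all_subj],
            "age_years": all_ages,
            "group": config.group_label,
            "field_strength": all_field,
            "is_duplicate": dup_flag,
        }
    )

    # Per-region random effects and measurements.
    truth_rows = []
    if isinstance(config.covariate_effects, list):
        per_region_effects = config.covariate_effects
    else:
        per_region_effects = [config.covariate_effects] * config.n_regions
    region_values = {}
    for r, fx in enumerate(config.region_params):
        sh_tau = _covariate_shift(cov, per_region_effects[r], 0)
        sh_xi = _covariate_shift(cov, per_region_effects[r], 1)
        tau = rng.normal(fx.t0 + sh_tau, fx.sigma_tau)
        xi = rng.normal(sh_xi, fx.sigma_xi)
        u = np.exp(xi[all_subj]) * (all_ages - tau[all_subj]) + fx.t0
        y = curve_value(u, fx, config.family)
        y = y + rng.normal(0.0, fx.sigma_eps, all_ages.size)
        y = y + np.where(all_field == 3.0, config.scanner_offset, 0.0)
        region_values[f"region_{r + 1}"] = y
        truth_rows.append(
            pd.DataFrame(
                {
                    "subject_id": cov["subject_id"],
                    "region": f"region_{r + 1}",
                    "tau": tau,
                    "xi": xi,
                }
            )
        )

    visits = pd.concat([visits, pd.DataFrame(region_values)], axis=1)

    # Sort visits by subject then age for a stable, realistic table layout.
    visits = visits.sort_values(
        ["subject_id", "age_years", "is_duplicate"], kind="mergesort"
    ).reset_index(drop=True)

    truth = SyntheticTruth(
        region_params=list(config.region_params),
        family=config.family,
        individual=pd.concat(truth_rows, ignore_index=True),
        covariates=cov.copy(),
        scanner_offset=config.scanner_offset,
    )
    return visits, cov, truth


def summarize_demographics(visits: pd.DataFrame,
                           covariates: pd.DataFrame) -> pd.DataFrame:
    """Cohort demographics split by sex: N, scans, follow-up, age, education,
    APOE-e4 allele-count breakdown.

    Raises if the two tables reference inconsistent subject IDs.
    """
    visit_ids = set(visits["subject_id"])
    cov_ids = set(covariates["subject_id"])
    orphans = sorted(visit_ids - cov_ids)
    if orphans:
        raise ValueError(f"visit subjects missing from covariate table: {orphans}")

    merged = visits.merge(covariates, on="subject_id", how="left")
    rows = {}
    for label, female in (("Male", 0), ("Female", 1)):
        sub = merged[merged["sex_female"] == female]
        csub = covariates[covariates["sex_female"] == female]
        n = csub["subject_id"].nunique()
        if n == 0:
            rows[label] = {
                "N": 0, "N_scans": 0,
                "followup_mean": np.nan, "followup_sd": np.nan,
                "baseline_age_mean": np.nan, "baseline_age_sd": np.nan,
                "education_mean": np.nan, "education_sd": np.nan,
                "apoe4_2": 0, "apoe4_1": 0, "apoe4_0": 0,
            }
            continue
        per_subject = sub.groupby("subject_id")["age_years"]
        followup = per_subject.max() - per_subject.min()
        baseline = per_subject.min()
        counts = csub["apoe4_count"].value_counts()
        rows[label] = {
            "N": n,
            "N_scans": len(sub),
            "followup_mean": followup.mean(),
            "followup_sd": followup.std(ddof=1) if len(followup) > 1 else np.nan,
            "baseline_age_mean": baseline.mean(),
            "baseline_age_sd": baseline.std(ddof=1) if len(baseline) > 1 else np.nan,
            "education_mean": csub["education_years"].mean(),
            "education_sd": csub["education_years"].std(ddof=1) if n > 1 else np.nan,
            "apoe4_2": int(counts.get(2, 0)),
            "apoe4_1": int(counts.get(1, 0)),
            "apoe4_0": int(counts.get(0, 0)),
        }
    return pd.DataFrame(rows)
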