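"""Synthetic longitudinal cohorts with a known latent disease timeline.

The generator emulates an ADNI-like multi-site observational study of the
Alzheimer's continuum.  Each subject belongs to one of four baseline groups
(CU-Ab-, CU-Ab+, MCI-Ab+, ADD-Ab+); the groups differ by a fixed shift on a
shared latent "disease time" axis, and each subject carries an additional
Gaussian random shift.  Outcomes (cognitive scores, amyloid measures,
hippocampal volume) follow monotone group-shared mean curves of disease
time — monotone piecewise-cubic interpolants of control points — plus a
subject-level random intercept and i.i.d. Gaussian noise, clipped to the
instrument's floor/ceiling.  The true shifts and intercepts are returned as
ground truth so that latent-time recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

__all__ = [
    "GROUPS", "REFERENCE_GROUP", "OutcomeParams", "CohortSpec", "GroundTruth",
    "default_outcome_params", "generate_cohort", "simulate_baseline_table",
]

GROUPS = ("CU-Ab-", "CU-Ab+", "MCI-Ab+", "ADD-Ab+")
REFERENCE_GROUP = "CU-Ab-"

#: default average latent-time shift per baseline group (years); the
#: cognitively-unimpaired amyloid-negative group is the reference at 0.
DEFAULT_SHIFTS = {"CU-Ab-": 0.0, "CU-Ab+": 5.0, "MCI-Ab+": 10.0, "ADD-Ab+": 15.0}


class SpecError(ValueError):
    """A generator spec field failed validation."""


@dataclass
class OutcomeParams:
    """Mean-curve control points and noise structure for one outcome.

    ``control_points`` are ``(disease_time_years, value)`` pairs with
    monotone values; the mean curve is their monotone piecewise-cubic
    (PCHIP) interpolant, held flat beyond the outermost points.
    """

    control_points: tuple
    floor: float = -np.inf
    ceiling: float = np.inf
    intercept_sd: float = 1.0
    residual_sd: float = 1.0

    def __post_init__(self):
        t = np.array([p[0] for p in self.control_points], dtype=float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise SpecError("control_points: times must be strictly increasing")
        if not self.floor < self.ceiling:
            raise SpecError("floor must be below ceiling")
        if self.intercept_sd < 0 or self.residual_sd < 0:
            raise SpecError("intercept_sd/residual_sd must be >= 0")

    def mean_curve(self, t):
        """Monotone mean value at disease time(s) t (flat beyond support)."""
        tc = np.array([p[0] for p in self.control_points], dtype=float)
        vc = np.array([p[1] for p in self.control_points], dtype=float)
        f = PchipInterpolator(tc, vc, extrapolate=False)
        t = np.asarray(t, dtype=float)
        out = f(np.clip(t, tc[0], tc[-1]))
        return np.clip(out, self.floor, self.ceiling)


def default_outcome_params() -> dict:
    """Plausible outcome settings for a ~20-year disease course.

    Shapes are sigmoidal in disease time: cognition is near-normal before
    amyloid onset (time 0) and worsens over the following two decades;
    centiloid rises early; CSF amyloid falls through its positivity
    threshold around time 0; hippocampal volume declines late.  Values are
    synthetic — chosen to look like a realistic amnestic cohort, not fitted
    to any dataset.
    """
    return {
        "adas13": OutcomeParams(
            ((-15, 7.5), (-5, 8.5), (0, 10), (5, 13), (10, 20), (15, 31), (20, 44)),
            floor=0, ceiling=85, intercept_sd=3.0, residual_sd=2.5),
        "cdrsb": OutcomeParams(
            ((-15, 0.02), (-5, 0.1), (0, 0.3), (5, 0.9), (10, 2.6), (15, 6.0), (20, 10.5)),
            floor=0, ceiling=18, intercept_sd=0.5, residual_sd=0.7),
        "mmse": OutcomeParams(
            ((-15, 29.2), (-5, 29.0), (0, 28.6), (5, 27.8), (10, 26.0), (15, 22.0), (20, 16.5)),
            floor=0, ceiling=30, intercept_sd=1.0, residual_sd=1.3),
        "centiloid": OutcomeParams(
            ((-15, -3), (-10, 2), (-5, 12), (0, 28), (5, 52), (10, 74), (15, 88), (20, 97)),
            intercept_sd=6.0, residual_sd=7.0),
        "csf_ab42": OutcomeParams(
            ((-15, 1450), (-10, 1350), (-5, 1180), (0, 980), (5, 820), (10, 690),
             (15, 600), (20, 550)),
            floor=150, intercept_sd=120.0, residual_sd=90.0),
        "hippo_volume": OutcomeParams(
            ((-15, 7400), (-5, 7300), (0, 7150), (5, 6850), (10, 6300), (15, 5600), (20, 5000)),
            floor=2500, intercept_sd=500.0, residual_sd=150.0),
    }


@dataclass
class CohortSpec:
    """Generating parameters for a synthetic longitudinal cohort."""

    n_per_group: int = 100
    groups: tuple = GROUPS
    visit_schedule: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)
    dropout_rate: float = 0.08
    mcar_rate: float = 0.02
    shift_mean_by_group: dict = field(default_factory=lambda: dict(DEFAULT_SHIFTS))
    shift_sd: float = 3.0
    shift_age_slope: float = 0.0
    outcome_params: dict = field(default_factory=default_outcome_params)
    age_mean: float = 73.0
    age_sd: float = 7.0
    age_range: tuple = (55.0, 95.0)
    n_sites: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise SpecError("n_per_group must be >= 1")
        if self.shift_sd <= 0:
            raise SpecError("shift_sd must be > 0")
        v = np.asarray(self.visit_schedule, dtype=float)
        if v.size < 1 or np.any(np.diff(v) <= 0):
            raise SpecError("visit_schedule must be strictly increasing")
        if not 0 <= self.dropout_rate < 1:
            raise SpecError("dropout_rate must be in [0, 1)")
        if not 0 <= self.mcar_rate < 1:
            raise SpecError("mcar_rate must be in [0, 1)")
        for g in self.groups:
            if g not in self.shift_mean_by_group:
                raise SpecError(f"shift_mean_by_group missing group {g!r}")
        if self.age_sd <= 0:
            raise SpecError("age_sd must be > 0")


@dataclass
class GroundTruth:
    """True latent quantities behind a generated cohort."""

    subjects: pd.DataFrame      # subject_id, group_bl, age_bl, s_fixed, s_i, shift_total
    intercepts: pd.DataFrame    # subject_id x outcome random intercepts


def generate_cohort(spec: CohortSpec):
    """Generate a tidy longitudinal table plus its ground truth.

    Returns ``(table, truth)`` where ``table`` has one row per
    subject-visit-outcome with columns ``subject_id, visit_years, group_bl,
    age_bl, sex, education, icv, site, outcome, value`` and ``truth`` is a
    :class:`GroundTruth`.  Identical specs (including seed) give identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    subj_rows, rows, icp_rows = [], [], []
    outcomes = list(spec.outcome_params)
    sid = 0
    for g in spec.groups:
        for _ in range(spec.n_per_group):
            sid += 1
            subject_id = f"S{sid:05d}"
            a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
            age = float(truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd,
                                      random_state=rng))
            sex = "F" if rng.random() < 0.5 else "M"
            edu = int(np.clip(np.round(rng.normal(16, 2.5)), 6, 20))
            icv = float(rng.normal(1.5e6, 1.5e5))
            site = f"site{rng.integers(spec.n_sites):02d}"
            s_fixed = (spec.shift_mean_by_group[g]
                       + spec.shift_age_slope * (age - spec.age_mean))
            s_i = float(rng.normal(0.0, spec.shift_sd))
            icp = {k: float(rng.normal(0.0, p.intercept_sd))
                   for k, p in spec.outcome_params.items()}
            subj_rows.append(dict(subject_id=subject_id, group_bl=g, age_bl=age,
                                  sex=sex, education=edu, icv=icv, site=site,
                                  s_fixed=s_fixed, s_i=s_i,
                                  shift_total=s_fixed + s_i))
            icp_rows.append(dict(subject_id=subject_id, **icp))
            for t in spec.visit_schedule:
                if t > 0 and rng.random() < spec.dropout_rate:
                    break   # monotone dropout
                dtime = t + s_fixed + s_i
                for k in outcomes:
                    if rng.random() < spec.mcar_rate:
                        continue
                    p = spec.outcome_params[k]
                    val = float(p.mean_curve(dtime)) + icp[k]
                    if p.residual_sd > 0:
                        val += float(rng.normal(0.0, p.residual_sd))
                    val = float(np.clip(val, p.floor, p.ceiling))
                    rows.append((subject_id, float(t), g, age, sex, edu, icv,
                                 site, k, val))
    table = pd.DataFrame(rows, columns=[
        "subject_id", "visit_years", "group_bl", "age_bl", "sex", "education",
        "icv", "site", "outcome", "value"])
    subjects = pd.DataFrame(subj_rows)
    intercepts = pd.DataFrame(icp_rows).set_index("subject_id")
    return table, GroundTruth(subjects=subjects, intercepts=intercepts)


def simulate_baseline_table(n_per_group: int = 100, groups=GROUPS,
                            group_effect=None, n_sites: int = 10,
                            site_sd: float = 0.0, resid_sd: float = 1.0,
                            covariate_betas=None, seed: int = 0) -> pd.DataFrame:
    """Baseline (cross-sectional) table for group-model calibration studies.

    Outcome ``y`` = group effect + covariate effects + site random intercept
    + N(0, resid_sd) noise.  ``group_effect`` maps group -> mean shift
    (default all zero, the null); ``covariate_betas`` maps covariate name in
    {age_bl, sex_num, education, icv_z} -> slope.
    """
    rng = np.random.default_rng(seed)
    group_effect = group_effect or {}
    covariate_betas = covariate_betas or {}
    rows = []
    site_fx = rng.normal(0.0, site_sd, size=n_sites) if site_sd > 0 else np.zeros(n_sites)
    sid = 0
    for g in groups:
        for _ in range(n_per_group):
            sid += 1
            age = float(rng.normal(73, 7))
            sex = "F" if rng.random() < 0.5 else "M"
            edu = int(np.clip(np.round(rng.normal(16, 2.5)), 6, 20))
            icv = float(rng.normal(1.5e6, 1.5e5))
            site_i = int(rng.integers(n_sites))
            y = group_effect.get(g, 0.0) + site_fx[site_i]
            y += covariate_betas.get("age_bl", 0.0) * (age - 73)
            y += covariate_betas.get("sex_num", 0.0) * (sex == "F")
            y += covariate_betas.get("education", 0.0) * (edu - 16)
            y += covariate_betas.get("icv_z", 0.0) * (icv - 1.5e6) / 1.5e5
            y += float(rng.normal(0.0, resid_sd))
            rows.append(dict(subject_id=f"S{sid:05d}", group_bl=g, age_bl=age,
                             sex=sex, education=edu, icv=icv,
                             site=f"site{site_i:02d}", y=y))
    return pd.DataFrame(rows)
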