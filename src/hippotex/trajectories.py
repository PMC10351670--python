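"""Outcome trajectories over estimated disease time.

Single-timescale model: an outcome v_ij observed at predicted disease time
t~_ij follows

    v_ij = theta(t~_ij) + x_i + eps_ij

with theta a natural cubic spline (3-6 DoF, chosen by BIC under ML and
refitted by REML), x_i ~ N(0, tau2) a subject random intercept and
eps_ij ~ N(0, sigma2).  Fits use disease times with the extreme 5% quantiles
excluded (2.5% per tail by default).  Two derived curves re-express a fitted
trajectory:

* abnormality: (theta(t) - q0.5) / (q0.95 - q0.5), where q0.5 and q0.95 are
  the healthy reference group's median and 95% quantile in the direction of
  abnormality — 0 at the healthy median, 1 at the healthy 95th percentile;
* sensitivity to change: theta'(t) / sigma, the trajectory slope in units of
  residual SD per year — the signal-to-noise available for tracking change
  in one individual.

Dual-timescale models additionally disentangle ageing from disease
progression, comparing by BIC a null model, disease-only and age-only spline
models, an additive model theta_d(t~) + theta_a(a_t0) and an interaction
model that adds a (centred) disease x age spline product, where a_t0 is the
subject's age at disease Time 0 so that progressive time is not counted
twice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import NaturalCubicSpline
from .lmm import RandomInterceptLM

log = logging.getLogger(__name__)

__all__ = ["AbnormalityScale", "TrajectoryModel", "TrajectoryResults",
           "DualTimescaleModel", "DualTimescaleResults"]


# ---------------------------------------------------------------------------
@dataclass
class AbnormalityScale:
    """Healthy-group reference quantiles for one outcome.

    ``direction`` is ``"increasing"`` if larger values are more abnormal
    (e.g. CDR-SB) or ``"decreasing"`` if smaller values are (e.g. volume,
    MMSE).  ``q95`` is the 95% quantile in the direction of abnormality, so
    for a decreasing outcome it is the raw 5th percentile.
    """

    outcome: str
    q50: float
    q95: float
    direction: str = "increasing"

    @classmethod
    def from_healthy(cls, values, outcome: str = "",
                     direction: str = "increasing") -> "AbnormalityScale":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        q50 = float(np.median(v))
        q = 0.95 if direction == "increasing" else 0.05
        q95 = float(np.quantile(v, q))
        if q95 == q50:
            raise ValueError("degenerate healthy reference: q0.95 == q0.5")
        return cls(outcome=outcome, q50=q50, q95=q95, direction=direction)

    def transform(self, values):
        return (np.asarray(values, dtype=float) - self.q50) / (self.q95 - self.q50)


# ---------------------------------------------------------------------------
@dataclass
class TrajectoryResults:
    """A fitted single-timescale spline trajectory."""

    outcome: str
    basis: NaturalCubicSpline
    params: np.ndarray            # intercept followed by basis coefficients
    dof: int
    tau2: float
    sigma2: float
    fit_method: str
    support: tuple                # disease-time range after quantile trim
    bic_table: pd.DataFrame = field(repr=False, default=None)
    nobs: int = 0

    def predict(self, t) -> np.ndarray:
        return self.params[0] + self.basis.design(t) @ self.params[1:]

    def derivative(self, t) -> np.ndarray:
        return self.basis.derivative(t) @ self.params[1:]

    def abnormality_curve(self, scale: AbnormalityScale, t) -> np.ndarray:
        """Fitted trajectory re-expressed on the healthy abnormality scale."""
        return scale.transform(self.predict(t))

    def sensitivity_curve(self, t) -> np.ndarray:
        """Trajectory slope divided by the residual SD (per year)."""
        return self.derivative(t) / np.sqrt(self.sigma2)

    def summary(self) -> str:
        return (f"Trajectory of {self.outcome!r}: df={self.dof} "
                f"({self.fit_method}), tau2={self.tau2:.4g}, "
                f"sigma2={self.sigma2:.4g}, support="
                f"[{self.support[0]:.2f}, {self.support[1]:.2f}] y, "
                f"n={self.nobs}")


def _trim_times(t: np.ndarray, trim_total: float, per_tail: bool):
    frac = trim_total if per_tail else trim_total / 2.0
    lo, hi = np.quantile(t, [frac, 1.0 - frac])
    return (t >= lo) & (t <= hi), (float(lo), float(hi))


class TrajectoryModel:
    """Spline-over-disease-time model with a subject random intercept.

    ``staged`` is either a long table with ``outcome``/``value`` columns or a
    wide table where ``outcome`` names a column.  ``trim`` is the total
    fraction of extreme disease-time quantiles excluded before fitting
    (interpreted as ``trim/2`` per tail, or ``trim`` per tail when
    ``trim_per_tail`` is set).
    """

    def __init__(self, staged: pd.DataFrame, outcome: str,
                 time_col: str = "disease_time", subject_col: str = "subject_id",
                 dof_range=(3, 4, 5, 6), trim: float = 0.05,
                 trim_per_tail: bool = False):
        if ({"outcome", "value"} <= set(staged.columns)
                and outcome in set(staged["outcome"])):
            sub = staged[staged["outcome"] == outcome]
            vals = sub["value"]
        else:
            sub = staged
            vals = sub[outcome]
        ok = vals.notna() & sub[time_col].notna()
        self.t = sub.loc[ok, time_col].to_numpy(dtype=float)
        self.y = vals[ok].to_numpy(dtype=float)
        self.subjects = sub.loc[ok, subject_col].to_numpy()
        self.outcome = outcome
        self.dof_range = tuple(dof_range)
        keep, self.support = _trim_times(self.t, trim, trim_per_tail)
        self.t, self.y = self.t[keep], self.y[keep]
        self.subjects = self.subjects[keep]
        if len(self.y) < 50:
            raise ValueError(f"only {len(self.y)} observations after trimming "
                             "(need >= 50)")

    def fit(self) -> TrajectoryResults:
        rows = []
        fits = {}
        for dof in self.dof_range:
            try:
                basis = NaturalCubicSpline.from_data(self.t, dof)
                X = np.column_stack([np.ones(len(self.t)), basis.design(self.t)])
                res = RandomInterceptLM(self.y, X, self.subjects).fit(reml=False)
                rows.append(dict(dof=dof, bic=res.bic, llf=res.llf))
                fits[dof] = basis
            except (np.linalg.LinAlgError, ValueError) as exc:
                log.warning("df=%d candidate skipped: %s", dof, exc)
        if not rows:
            raise ValueError("no spline candidate could be fitted")
        table = pd.DataFrame(rows)
        best = int(table.loc[table["bic"].idxmin(), "dof"])
        basis = fits[best]
        X = np.column_stack([np.ones(len(self.t)), basis.design(self.t)])
        final = RandomInterceptLM(self.y, X, self.subjects).fit(reml=True)
        return TrajectoryResults(
            outcome=self.outcome, basis=basis, params=final.params, dof=best,
            tau2=final.tau2, sigma2=final.sigma2, fit_method="reml",
            support=self.support, bic_table=table, nobs=len(self.y))


# ---------------------------------------------------------------------------
# dual-timescale models
# ---------------------------------------------------------------------------

FORMS = ("null", "disease", "age", "additive", "interaction")


@dataclass
class DualTimescaleResults:
    """BIC-selected model of an outcome over disease time and age."""

    outcome: str
    form: str
    dof_disease: int | None
    dof_age: int | None
    params: np.ndarray
    tau2: float
    sigma2: float
    bic: float
    bic_table: pd.DataFrame = field(repr=False, default=None)
    _predictor: object = field(repr=False, default=None)

    def predict(self, disease_time, age_t0) -> np.ndarray:
        X = self._predictor(np.asarray(disease_time, float),
                            np.asarray(age_t0, float))
        return X @ self.params

    def summary(self) -> str:
        dd = "-" if self.dof_disease is None else self.dof_disease
        da = "-" if self.dof_age is None else self.dof_age
        return (f"Dual-timescale fit of {self.outcome!r}: form={self.form} "
                f"(disease df={dd}, age df={da}), BIC={self.bic:.1f}, "
                f"tau2={self.tau2:.4g}, sigma2={self.sigma2:.4g}")


class DualTimescaleModel:
    """Compare disease-time and age models of one outcome by BIC.

    ``staged`` must provide per-observation disease time, observation age
    and the outcome; the subject's age at disease Time 0 is computed as the
    within-subject mean of (age - disease time).  Five forms are scanned
    (null, disease-only, age-only, additive, interaction), each with spline
    DoF 1-6 per timescale; the interaction surface uses the tensor product
    of the centred main-effect bases with its DoF tied per timescale.  All
    models carry a subject random intercept; selection is by BIC under ML
    and the winner is refitted by REML.
    """

    def __init__(self, staged: pd.DataFrame, outcome: str,
                 time_col: str = "disease_time", age_col: str = "age",
                 subject_col: str = "subject_id", dof_range=range(1, 7),
                 trim: float = 0.05, trim_per_tail: bool = False):
        if ({"outcome", "value"} <= set(staged.columns)
                and outcome in set(staged["outcome"])):
            sub = staged[staged["outcome"] == outcome].copy()
            sub = sub.rename(columns={"value": "_y"})
        else:
            sub = staged.copy()
            sub["_y"] = sub[outcome]
        sub = sub[sub["_y"].notna() & sub[time_col].notna() & sub[age_col].notna()]
        keep, self.support = _trim_times(sub[time_col].to_numpy(float),
                                         trim, trim_per_tail)
        sub = sub.loc[keep]
        self.t = sub[time_col].to_numpy(float)
        self.age = sub[age_col].to_numpy(float)
        self.y = sub["_y"].to_numpy(float)
        self.subjects = sub[subject_col].to_numpy()
        # age at disease Time 0: constant per subject up to rounding
        a0 = pd.DataFrame({"s": self.subjects, "a0": self.age - self.t})
        self.age_t0 = a0.groupby("s")["a0"].transform("mean").to_numpy(float)
        self.outcome = outcome
        self.dof_range = list(dof_range)
        if len(self.y) < 50:
            raise ValueError("need at least 50 observations after trimming")

    # ------------------------------------------------------------------
    def _candidate(self, form, dd, da):
        """Design-matrix builder for one candidate; returns (X, predictor)."""
        n = len(self.y)
        bd = NaturalCubicSpline.from_data(self.t, dd) if dd else None
        ba_var = self.age if form == "age" else self.age_t0
        ba = NaturalCubicSpline.from_data(ba_var, da) if da else None
        Bd = bd.design(self.t) if bd else None
        Ba = ba.design(ba_var) if ba else None
        md = Bd.mean(axis=0) if bd is not None else None
        ma = Ba.mean(axis=0) if ba is not None else None

        def build(t, a):
            cols = [np.ones(len(t))]
            if bd is not None:
                cols.append(bd.design(t))
            if ba is not None:
                cols.append(ba.design(a))
            if form == "interaction":
                Dc = bd.design(t) - md
                Ac = ba.design(a) - ma
                cols.append(np.einsum("ni,nj->nij", Dc, Ac).reshape(len(t), -1))
            return np.column_stack(cols)

        return build(self.t, ba_var), build

    def fit(self) -> DualTimescaleResults:
        grid = []
        for form in FORMS:
            if form == "null":
                grid.append((form, None, None))
            elif form == "disease":
                grid += [(form, d, None) for d in self.dof_range]
            elif form == "age":
                grid += [(form, None, d) for d in self.dof_range]
            else:
                grid += [(form, d1, d2) for d1 in self.dof_range
                         for d2 in self.dof_range]
        rows, builders = [], {}
        for form, dd, da in grid:
            try:
                X, build = self._candidate(form, dd, da)
                res = RandomInterceptLM(self.y, X, self.subjects).fit(reml=False)
                rows.append(dict(form=form, dof_disease=dd, dof_age=da,
                                 bic=res.bic, llf=res.llf, k=X.shape[1]))
                builders[(form, dd, da)] = build
            except (np.linalg.LinAlgError, ValueError) as exc:
                log.warning("candidate %s(%s,%s) skipped: %s", form, dd, da, exc)
        if not rows:
            raise ValueError("all dual-timescale candidates failed")
        table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
        top = table.iloc[0]
        form = top["form"]
        dd = None if pd.isna(top["dof_disease"]) else int(top["dof_disease"])
        da = None if pd.isna(top["dof_age"]) else int(top["dof_age"])
        build = builders[(form, dd, da)]
        Xb = build(self.t, self.age if form == "age" else self.age_t0)
        final = RandomInterceptLM(self.y, Xb, self.subjects).fit(reml=True)
        return DualTimescaleResults(
            outcome=self.outcome, form=form, dof_disease=dd, dof_age=da,
            params=final.params, tau2=final.tau2, sigma2=final.sigma2,
            bic=float(top["bic"]), bic_table=table, _predictor=build)
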