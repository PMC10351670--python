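"""Latent disease-time progression model.

Multiple outcome measures (cognitive scores, amyloid burden) are modelled
jointly as smooth functions of a shared latent "disease time":

    y_ijk = theta_k(t_ij + s_fixed(i) + s_i) + x_ik + e_ijk

where ``t_ij`` is years since baseline, ``s_fixed(i)`` is a fixed time shift
determined by subject i's baseline diagnostic group (reference group
anchored at 0) plus a linear effect of centred baseline age, ``s_i`` is a
zero-mean Gaussian subject-level random shift, ``theta_k`` is a natural
cubic spline (9 DoF by default) for outcome k on its original scale,
``x_ik`` are subject-level random intercepts with an unstructured K x K
covariance across outcomes, and ``e_ijk`` is independent Gaussian noise with
a separate variance per outcome.  No subject-level random slopes enter the
model; individual deviation from the mean trajectory is carried entirely by
the time shift and the intercepts.

Estimation alternates between (a) per-outcome spline/variance updates given
the current shifts (profiled ML random-intercept fits) and (b) per-subject
posterior-mode (MAP) updates of the total shift given the current mean
curves, with a Laplace approximation supplying the shift-variance update and
the marginal log-likelihood that is monitored for convergence.  Disease
times are reported as ``t~_ij = t_ij + s_fixed(i) + s_hat_i``; Time 0 can
subsequently be anchored at the point where the running median of CSF
amyloid first crosses the healthy reference bound.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .basis import NaturalCubicSpline
from .lmm import RandomInterceptLM
from .simulate.cohort import REFERENCE_GROUP

log = logging.getLogger(__name__)

__all__ = ["ProgressionModel", "ProgressionResults", "anchor_offset",
           "ConvergenceError"]


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


@dataclass
class ProgressionResults:
    """Fitted latent-time model: mean curves, shifts and variance components."""

    outcomes: list
    basis: NaturalCubicSpline
    theta: dict                  # outcome -> (1 + dof) coefficients (intercept first)
    group_offsets: dict          # group -> fixed shift (reference = 0)
    age_slope: float
    age_center: float
    reference: str
    shift_sd: float              # SD of the subject random shift
    intercept_cov: pd.DataFrame  # K x K unstructured covariance of x_ik
    resid_vars: dict             # outcome -> residual variance
    loglik: float
    loglik_trace: list = field(repr=False, default_factory=list)
    shifts: pd.DataFrame = field(repr=False, default=None)
    time_zero_offset: float = 0.0
    n_iter: int = 0
    _data: pd.DataFrame = field(repr=False, default=None)

    # ------------------------------------------------------------------
    def mean_curve(self, outcome: str, t) -> np.ndarray:
        """theta_k evaluated on the (anchored) disease-time grid ``t``."""
        th = self.theta[outcome]
        t = np.asarray(t, dtype=float) - self.time_zero_offset
        return th[0] + self.basis.design(t) @ th[1:]

    def s_fixed(self, group, age_bl) -> float:
        return (self.group_offsets[group]
                + self.age_slope * (age_bl - self.age_center))

    # ------------------------------------------------------------------
    def predict_disease_time(self, data: pd.DataFrame = None) -> pd.DataFrame:
        """Stage observations on disease time via MAP prediction of s_i.

        ``data`` is a long table (subject_id, visit_years, group_bl, age_bl,
        outcome, value); defaults to the training data.  Returns the table
        with added columns ``disease_time`` and ``s_hat``.  Subjects with no
        usable observation get fixed-effect-only staging and ``map_flag`` =
        ``"fixed_only"``.
        """
        data = (self._data if data is None else data).copy()
        out_shift, out_flag = {}, {}
        for sid, sub in data.groupby("subject_id"):
            grp = sub["group_bl"].iloc[0]
            age = float(sub["age_bl"].iloc[0])
            sf = self.s_fixed(grp, age)
            obs = sub[sub["outcome"].isin(self.outcomes) & sub["value"].notna()]
            if len(obs) == 0:
                out_shift[sid], out_flag[sid] = sf, "fixed_only"
                continue
            s_hat = self._map_shift(obs["visit_years"].to_numpy(float),
                                    obs["outcome"].to_numpy(),
                                    obs["value"].to_numpy(float), sf)
            out_shift[sid], out_flag[sid] = sf + s_hat, "map"
        data["total_shift"] = data["subject_id"].map(out_shift)
        data["map_flag"] = data["subject_id"].map(out_flag)
        data["disease_time"] = (data["visit_years"] + data["total_shift"]
                                + self.time_zero_offset)
        data["s_hat"] = data["total_shift"] - data.apply(
            lambda r: self.s_fixed(r["group_bl"], r["age_bl"]), axis=1)
        return data

    def _subject_cov(self, out_idx: np.ndarray):
        Sig = self.intercept_cov.to_numpy()
        sig2 = np.array([self.resid_vars[self.outcomes[k]] for k in out_idx])
        V = Sig[np.ix_(out_idx, out_idx)] + np.diag(sig2)
        return cho_factor(V)

    def _map_shift(self, t, outs, y, s_fixed, grid_step=0.5, span=None) -> float:
        """Posterior mode of the random shift s_i for one subject."""
        out_idx = np.array([self.outcomes.index(o) for o in outs])
        cf = self._subject_cov(out_idx)
        omega2 = max(self.shift_sd**2, 1e-10)
        th = np.array([self.theta[o] for o in self.outcomes])

        def nll(s):
            tt = t + s_fixed + s
            B = self.basis.design(tt)
            mu = th[out_idx, 0] + np.einsum("ij,ij->i", B, th[out_idx, 1:])
            r = y - mu
            return 0.5 * float(r @ cho_solve(cf, r)) + 0.5 * s * s / omega2

        span = span if span is not None else max(4.0 * self.shift_sd, 6.0)
        grid = np.arange(-span, span + grid_step, grid_step)
        vals = np.array([nll(s) for s in grid])
        j = int(np.argmin(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        if hi <= lo:
            return float(grid[j])
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        # tie toward zero: prefer 0 if it is (numerically) as good
        if nll(0.0) <= res.fun + 1e-12:
            return 0.0
        return float(res.x)

    # ------------------------------------------------------------------
    def anchor_time_zero(self, ab_table: pd.DataFrame, healthy_values,
                         direction: str = "decreasing", window: float = 2.0,
                         quantile: float = 0.95) -> float:
        """Anchor Time 0 where median CSF amyloid exceeds healthy bounds.

        ``ab_table`` must have columns ``disease_time`` and ``value``
        (CSF Abeta1-42 observations staged on disease time);
        ``healthy_values`` is the amyloid-negative reference sample.  The
        threshold is the healthy group's ``quantile`` quantile *in the
        direction of abnormality* (for a decreasing marker this is the
        lower-tail raw quantile).  The running median of the staged values
        (window of +/- ``window``/2 years) is scanned from early to late
        disease time; the first point at which it crosses the threshold
        (ties resolved to the first such point) defines Time 0, and all
        disease times are shifted so that this crossing sits at 0.
        Returns the offset applied.
        """
        offset = anchor_offset(ab_table["disease_time"].to_numpy(float),
                               ab_table["value"].to_numpy(float),
                               np.asarray(healthy_values, float),
                               direction=direction, window=window,
                               quantile=quantile)
        self.time_zero_offset += offset
        return offset

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = [f"Latent disease-time model  (K={len(self.outcomes)} outcomes, "
                 f"spline df={self.basis.df}, iterations={self.n_iter})",
                 f"log-likelihood (Laplace): {self.loglik:.2f}",
                 f"shift SD: {self.shift_sd:.3f} y   "
                 f"age slope: {self.age_slope:+.4f} y/y"]
        lines.append("group offsets (years):")
        for g, v in self.group_offsets.items():
            tag = " (reference)" if g == self.reference else ""
            lines.append(f"  {g:>10}: {v:+8.3f}{tag}")
        lines.append("residual SDs:")
        for k in self.outcomes:
            lines.append(f"  {k:>14}: {np.sqrt(self.resid_vars[k]):8.3f}")
        return "\n".join(lines)


class ProgressionModel:
    """Joint multivariate model of outcome trajectories on latent disease time.

    Parameters
    ----------
    data : DataFrame
        Long table with columns ``subject_id, visit_years, group_bl, age_bl,
        outcome, value``.
    outcomes : sequence of str
        The K outcome names to model jointly (K >= 2 for well-identified
        shifts).
    dof : int
        Degrees of freedom of the natural cubic spline mean curves.
    """

    def __init__(self, data: pd.DataFrame, outcomes, dof: int = 9,
                 reference=REFERENCE_GROUP, subject_col="subject_id",
                 time_col="visit_years", group_col="group_bl",
                 age_col="age_bl"):
        outcomes = list(outcomes)
        if len(outcomes) < 1:
            raise ValueError("need at least one outcome")
        if len(outcomes) == 1:
            warnings.warn("K=1 outcome: shifts weakly identified",
                          UserWarning, stacklevel=2)
        d = data[data["outcome"].isin(outcomes) & data["value"].notna()].copy()
        d = d.rename(columns={subject_col: "subject_id", time_col: "visit_years",
                              group_col: "group_bl", age_col: "age_bl"})
        if d.empty:
            raise ValueError("no usable observations for the given outcomes")
        counts = d.groupby("subject_id").size()
        if (counts < 1).any():
            raise ValueError("every subject needs at least one observation")
        if reference not in set(d["group_bl"]):
            raise ValueError(f"reference group {reference!r} absent from data")
        self.data, self.outcomes, self.dof = d, outcomes, dof
        self.reference = reference

    # ------------------------------------------------------------------
    @staticmethod
    def _initial_shifts(d: pd.DataFrame, subjects) -> pd.Series:
        """Moment-based starting shifts from a composite severity score.

        Each outcome is z-scored and oriented so that larger means more
        advanced (orientation = sign of the pooled within-subject slope
        over follow-up time).  A subject's mean composite, divided by the
        pooled within-subject progression rate of the composite, estimates
        how many years of progression separate the subject from the cohort
        centre — a coarse but unbiased alignment that starts the
        alternating optimization away from the flat-curve local optimum.
        """
        z = d.copy()
        stats_k = z.groupby("outcome")["value"].agg(["mean", "std"])
        z["z"] = (z["value"] - z["outcome"].map(stats_k["mean"])) \
            / z["outcome"].map(stats_k["std"]).replace(0.0, 1.0)
        # orientation from pooled within-subject covariance with time
        orient = {}
        for k, sub in z.groupby("outcome"):
            tc = sub["visit_years"] - sub.groupby("subject_id")["visit_years"] \
                .transform("mean")
            yc = sub["z"] - sub.groupby("subject_id")["z"].transform("mean")
            cov = float((tc * yc).sum())
            orient[k] = 1.0 if cov >= 0 else -1.0
        z["zo"] = z["z"] * z["outcome"].map(orient)
        comp = z.groupby(["subject_id", "visit_years"])["zo"].mean().reset_index()
        tc = comp["visit_years"] - comp.groupby("subject_id")["visit_years"] \
            .transform("mean")
        yc = comp["zo"] - comp.groupby("subject_id")["zo"].transform("mean")
        denom = float((tc * tc).sum())
        slope = float((tc * yc).sum()) / denom if denom > 0 else 0.0
        if slope <= 1e-6:
            return pd.Series(0.0, index=subjects)
        c_i = comp.groupby("subject_id")["zo"].mean()
        u0 = ((c_i - c_i.mean()) / slope).clip(-25.0, 25.0)
        return u0.reindex(subjects).fillna(0.0)

    def fit(self, max_iter: int = 100, tol: float = 1e-5,
            knot_refresh_iters: int = 4, grid_step: float = 0.5,
            verbose: bool = False) -> ProgressionResults:
        """Fit by alternating optimization.

        Convergence is declared when the Laplace marginal log-likelihood
        changes by less than ``tol * (1 + |loglik|)`` between outer
        iterations (after the knot-refresh phase); otherwise a
        :class:`ConvergenceError` carrying the likelihood trace is raised.
        """
        d = self.data
        subjects = d["subject_id"].unique()
        subj_info = d.groupby("subject_id").agg(
            group_bl=("group_bl", "first"), age_bl=("age_bl", "first"))
        age_center = float(subj_info["age_bl"].mean())
        groups = list(dict.fromkeys([self.reference] +
                                    sorted(set(subj_info["group_bl"]))))
        sub_arrays = {}
        for sid, sub in d.groupby("subject_id"):
            sub_arrays[sid] = (sub["visit_years"].to_numpy(float),
                               sub["outcome"].to_numpy(),
                               sub["value"].to_numpy(float))
        u = self._initial_shifts(d, subjects)   # total shift per subject
        u_prev = u.copy()
        omega2 = max(float(u.var()), 1.0)
        K = len(self.outcomes)
        Sigma = np.eye(K)
        sigma2 = {k: 1.0 for k in self.outcomes}
        group_offsets = {g: 0.0 for g in groups}
        age_slope = 0.0
        theta, basis = None, None
        ll_trace = []
        prev_ll = -np.inf
        out_of = {k: i for i, k in enumerate(self.outcomes)}

        def fit_outcome_curves(u_cur, cur_basis, refresh):
            """Step (a): per-outcome spline + variance fits at given shifts."""
            shifted = d["visit_years"].to_numpy(float) + \
                u_cur.reindex(d["subject_id"]).to_numpy(float)
            if cur_basis is None or refresh:
                cur_basis = NaturalCubicSpline.from_data(
                    shifted, self.dof, boundary_quantiles=(0.01, 0.99))
            theta_new, sigma2_new, tau2_new = {}, {}, {}
            blup_mat = pd.DataFrame(0.0, index=subjects, columns=self.outcomes)
            for k in self.outcomes:
                rows = d["outcome"].to_numpy() == k
                B = cur_basis.design(shifted[rows])
                Xk = np.column_stack([np.ones(B.shape[0]), B])
                res = RandomInterceptLM(d.loc[rows, "value"], Xk,
                                        d.loc[rows, "subject_id"]).fit(reml=False)
                theta_new[k] = res.params.copy()
                sigma2_new[k] = max(res.sigma2, 1e-8)
                tau2_new[k] = max(res.tau2, 1e-10)
                blup_mat.loc[res.group_labels, k] = res.blups
            # unstructured intercept covariance: BLUP correlations scaled to
            # the per-outcome ML intercept variances (keeps the matrix PSD)
            if len(self.outcomes) == 1:
                C = np.array([[1.0]])
            else:
                C = np.corrcoef(blup_mat.to_numpy(), rowvar=False)
                C = np.nan_to_num(C, nan=0.0)
                np.fill_diagonal(C, 1.0)
            sd = np.sqrt([tau2_new[k] for k in self.outcomes])
            return cur_basis, theta_new, sigma2_new, C * np.outer(sd, sd)

        for it in range(max_iter):
            basis, theta, sigma2, Sigma = fit_outcome_curves(
                u, basis, refresh=(it < knot_refresh_iters))

            # ---- (b) MAP update of each subject's total shift ------------
            helper = ProgressionResults(
                outcomes=self.outcomes, basis=basis, theta=theta,
                group_offsets=group_offsets, age_slope=age_slope,
                age_center=age_center, reference=self.reference,
                shift_sd=float(np.sqrt(omega2)),
                intercept_cov=pd.DataFrame(Sigma, index=self.outcomes,
                                           columns=self.outcomes),
                resid_vars=dict(sigma2), loglik=np.nan)
            new_u = {}
            post_var = {}
            marg_ll = 0.0
            for sid in subjects:
                t, outs, y = sub_arrays[sid]
                grp = subj_info.loc[sid, "group_bl"]
                age = float(subj_info.loc[sid, "age_bl"])
                sf = helper.s_fixed(grp, age)
                s_hat = helper._map_shift(t, outs, y, sf, grid_step=grid_step)
                new_u[sid] = sf + s_hat
                # Laplace: curvature of the negative log posterior at the mode
                out_idx = np.array([out_of[o] for o in outs])
                cf = helper._subject_cov(out_idx)
                th = np.array([theta[o] for o in self.outcomes])

                def nll(s):
                    tt = t + sf + s
                    Bm = basis.design(tt)
                    mu = th[out_idx, 0] + np.einsum("ij,ij->i", Bm, th[out_idx, 1:])
                    r = y - mu
                    return 0.5 * float(r @ cho_solve(cf, r)) + 0.5 * s * s / omega2

                h = 0.05
                curv = (nll(s_hat - h) - 2 * nll(s_hat) + nll(s_hat + h)) / h**2
                v = 1.0 / curv if curv > 1e-8 else omega2
                post_var[sid] = min(max(v, 1e-8), 100.0 * omega2)
                # marginal loglik contribution (Laplace), constants included
                Vlogdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
                n_i = len(y)
                marg_ll += (-nll(s_hat) - 0.5 * Vlogdet
                            - 0.5 * n_i * np.log(2 * np.pi)
                            - 0.5 * np.log(omega2)
                            + 0.5 * np.log(2 * np.pi * post_var[sid])
                            - 0.5 * np.log(2 * np.pi))
            u = pd.Series(new_u)

            # ---- (c) fixed-shift regression + identifiability ------------
            si = subj_info.copy()
            si["u"] = u.reindex(si.index)
            Xf = np.column_stack(
                [np.ones(len(si))] +
                [(si["group_bl"] == g).to_numpy(float) for g in groups[1:]] +
                [(si["age_bl"] - age_center).to_numpy(float)])
            coef, *_ = np.linalg.lstsq(Xf, si["u"].to_numpy(float), rcond=None)
            c0 = coef[0]
            group_offsets = {self.reference: 0.0}
            for g, b in zip(groups[1:], coef[1:-1]):
                group_offsets[g] = float(b)
            age_slope = float(coef[-1])
            u = u - c0          # translate so the reference group sits at 0
            s_fixed_all = si.apply(
                lambda r: group_offsets[r["group_bl"]]
                + age_slope * (r["age_bl"] - age_center), axis=1)
            s_rand = u.reindex(si.index) - s_fixed_all
            omega2 = float(np.mean(s_rand**2)
                           + np.mean(pd.Series(post_var).reindex(si.index)))
            omega2 = max(omega2, 1e-6)

            ll_trace.append(marg_ll)
            max_du = float((u - u_prev).abs().max()) if it else np.inf
            if verbose:
                log.info("iter %d: ll=%.4f  omega=%.3f  max|du|=%.4f",
                         it, marg_ll, np.sqrt(omega2), max_du)
            if it >= knot_refresh_iters and (
                    abs(marg_ll - prev_ll) < tol * (1.0 + abs(marg_ll))
                    or max_du < 0.01):
                break
            prev_ll = marg_ll
            u_prev = u.copy()
        else:
            last_dll = (abs(ll_trace[-1] - ll_trace[-2])
                        if len(ll_trace) > 1 else np.inf)
            raise ConvergenceError(
                f"no convergence after {max_iter} iterations "
                f"(last |dll|={last_dll:.3g})", trace=ll_trace)

        # final consistency pass: mean curves refit at the final shifts
        basis, theta, sigma2, Sigma = fit_outcome_curves(u, basis, refresh=False)
        shifts = subj_info.copy()
        shifts["total_shift"] = u.reindex(shifts.index)
        shifts["s_fixed"] = shifts.apply(
            lambda r: group_offsets[r["group_bl"]]
            + age_slope * (r["age_bl"] - age_center), axis=1)
        shifts["s_hat"] = shifts["total_shift"] - shifts["s_fixed"]
        result = ProgressionResults(
            outcomes=self.outcomes, basis=basis, theta=theta,
            group_offsets=group_offsets, age_slope=age_slope,
            age_center=age_center, reference=self.reference,
            shift_sd=float(np.sqrt(omega2)),
            intercept_cov=pd.DataFrame(Sigma, index=self.outcomes,
                                       columns=self.outcomes),
            resid_vars=dict(sigma2), loglik=float(ll_trace[-1]),
            loglik_trace=ll_trace, shifts=shifts.reset_index(),
            n_iter=len(ll_trace), _data=self.data)
        return result


# ---------------------------------------------------------------------------
def anchor_offset(disease_time, values, healthy_values,
                  direction: str = "decreasing", window: float = 2.0,
                  quantile: float = 0.95) -> float:
    """Offset putting the healthy-bound crossing of the running median at 0."""
    if direction not in ("decreasing", "increasing"):
        raise ValueError("direction must be 'decreasing' or 'increasing'")
    q = 1.0 - quantile if direction == "decreasing" else quantile
    thr = float(np.quantile(healthy_values, q))
    order = np.argsort(disease_time)
    t_sorted = np.asarray(disease_time, float)[order]
    v_sorted = np.asarray(values, float)[order]
    half = window / 2.0
    med = np.array([np.median(v_sorted[(t_sorted >= t - half)
                                       & (t_sorted <= t + half)])
                    for t in t_sorted])
    crossed = med <= thr if direction == "decreasing" else med >= thr
    if not crossed.any():
        raise ValueError("cannot anchor: running median never crosses the "
                         "healthy bound within the observed range")
    j = int(np.argmax(crossed))     # first crossing (tie -> first index)
    if j == 0:
        t_star = t_sorted[0]
    else:
        m0, m1 = med[j - 1], med[j]
        t0, t1 = t_sorted[j - 1], t_sorted[j]
        t_star = t0 + (thr - m0) / (m1 - m0) * (t1 - t0) if m1 != m0 else t1
    return float(-t_star)
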