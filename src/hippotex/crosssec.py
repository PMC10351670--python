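"""Baseline group comparisons and amyloid-status classification.

The group model regresses one imaging variable (a texture component or
hippocampal volume) on the four-level baseline diagnostic group plus
baseline age, sex, years of education and intracranial volume, with a random
intercept per scan site:

    y ~ C(group) + age_bl + sex + education + icv + (1 | site)

Omnibus and per-term Wald F tests use residual denominator degrees of
freedom.  Pairwise post-hoc models refit the same structure on two groups at
a time against a reference group, reporting Cohen's d.  P-values across the
analysis family are adjusted with the Holm step-down procedure
(Benjamini-Hochberg available via the ``method`` argument).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .lmm import RandomInterceptLM
from .simulate.cohort import REFERENCE_GROUP

log = logging.getLogger(__name__)

__all__ = [
    "AmyloidConfig", "classify_amyloid", "exclude_outliers",
    "GroupModel", "GroupModelResults", "pairwise_contrasts",
    "cohens_d", "cohens_f", "adjust_pvalues",
]


# ---------------------------------------------------------------------------
# amyloid status
# ---------------------------------------------------------------------------

@dataclass
class AmyloidConfig:
    """Thresholds for amyloid-positivity classification.

    CSF Abeta1-42 below ``csf_threshold`` pg/mL is positive; values within
    ``borderline_frac`` of a threshold are excluded as borderline.  The PET
    centiloid threshold is study-specific and configurable (the default is a
    commonly used visual-read-anchored value; no single canonical value
    exists).
    """

    csf_threshold: float = 980.0
    centiloid_threshold: float = 24.0
    borderline_frac: float = 0.05


def classify_amyloid(csf_ab42=None, centiloid=None,
                     config: AmyloidConfig = AmyloidConfig()) -> str:
    """Classify amyloid status from CSF (preferred) or PET centiloid.

    Returns one of ``positive``, ``negative``, ``excluded_borderline``,
    ``unknown``.
    """
    def is_missing(x):
        return x is None or (isinstance(x, float) and np.isnan(x))

    if not is_missing(csf_ab42):
        if csf_ab42 < 0:
            raise ValueError("negative CSF concentration")
        thr, frac = config.csf_threshold, config.borderline_frac
        if thr * (1 - frac) <= csf_ab42 <= thr * (1 + frac):
            return "excluded_borderline"
        return "positive" if csf_ab42 < thr else "negative"
    if not is_missing(centiloid):
        thr, frac = config.centiloid_threshold, config.borderline_frac
        band = abs(thr) * frac
        if thr - band <= centiloid <= thr + band:
            return "excluded_borderline"
        return "positive" if centiloid > thr else "negative"
    return "unknown"


# ---------------------------------------------------------------------------
# outlier fences
# ---------------------------------------------------------------------------

def exclude_outliers(values, mult: float = 1.5, fence: str = "mean"):
    """Flag values outside an IQR fence.

    ``fence='mean'`` uses ``mean +/- mult * IQR``; ``fence='quartile'`` uses
    the conventional ``[Q1 - mult*IQR, Q3 + mult*IQR]``.  Returns
    ``(kept_values, outlier_flags)``.  With a degenerate IQR of 0 under the
    mean fence, only values exactly at the mean are kept.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    if fence == "mean":
        lo, hi = v.mean() - mult * iqr, v.mean() + mult * iqr
    elif fence == "quartile":
        lo, hi = q1 - mult * iqr, q3 + mult * iqr
    else:
        raise ValueError("fence must be 'mean' or 'quartile'")
    flags = (v < lo) | (v > hi)
    return v[~flags], flags


# ---------------------------------------------------------------------------
# effect sizes and p-value adjustment
# ---------------------------------------------------------------------------

def cohens_d(x, y) -> float:
    """Standardized mean difference with pooled within-group SD."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                 / (nx + ny - 2))
    return float((x.mean() - y.mean()) / sp)


def cohens_f(values, groups) -> float:
    """Multi-group effect size: between-group SD over within-group SD."""
    df = pd.DataFrame({"v": np.asarray(values, float), "g": np.asarray(groups)})
    grand = df["v"].mean()
    stats_g = df.groupby("g")["v"].agg(["mean", "var", "count"])
    between = float((stats_g["count"] * (stats_g["mean"] - grand) ** 2).sum()
                    / stats_g["count"].sum())
    within = float((stats_g["count"] * stats_g["var"]).sum() / stats_g["count"].sum())
    return float(np.sqrt(between / within))


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Holm step-down (default) or Benjamini-Hochberg adjusted p-values."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if p.size == 1:
        return p.copy()
    key = {"holm": "holm", "bh": "fdr_bh", "benjamini-hochberg": "fdr_bh"}[method]
    return multipletests(p, method=key)[1]


# ---------------------------------------------------------------------------
# the group model
# ---------------------------------------------------------------------------

@dataclass
class TermTest:
    term: str
    f_stat: float
    df_num: int
    df_den: float
    p_value: float


@dataclass
class GroupModelResults:
    """Wald F tests per fixed term, effect sizes, and model internals."""

    outcome: str
    terms: list
    params: pd.Series
    cohens_f_group: float
    site_sd: float
    resid_sd: float
    nobs: int
    contrasts: list = field(default_factory=list)
    p_adjusted: dict = field(default_factory=dict)

    def term(self, name) -> TermTest:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def summary(self) -> str:
        lines = [f"Group model for {self.outcome!r}  (n={self.nobs}, "
                 f"site SD={self.site_sd:.3g}, resid SD={self.resid_sd:.3g})",
                 f"{'term':<12}{'F':>10}{'df':>10}{'p':>12}"]
        for t in self.terms:
            lines.append(f"{t.term:<12}{t.f_stat:>10.3f}"
                         f"{f'{t.df_num},{t.df_den:.0f}':>10}{t.p_value:>12.4g}")
        lines.append(f"Cohen's f (group) = {self.cohens_f_group:.3f}")
        for c in self.contrasts:
            lines.append(f"  {c['group']:>8} vs ref: est={c['estimate']:+.3f} "
                         f"d={c['cohens_d']:+.3f} p={c['p_value']:.4g}")
        return "\n".join(lines)


def _design(data: pd.DataFrame, group_col, covariates, reference):
    """Fixed-effects design matrix with treatment-coded group dummies."""
    levels = [g for g in pd.unique(data[group_col]) if g != reference]
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    for g in levels:
        X[f"group[{g}]"] = (data[group_col] == g).astype(float)
    for c in covariates:
        col = data[c]
        if col.dtype == object or str(col.dtype) == "category":
            cats = pd.unique(col)
            for lev in cats[1:]:
                X[f"{c}[{lev}]"] = (col == lev).astype(float)
        else:
            X[c] = (col - col.mean()) / (col.std(ddof=1) if col.std(ddof=1) else 1.0)
    groups_cols = [f"group[{g}]" for g in levels]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by greedy QR-style elimination
        aliased = []
        keep = []
        for c in X.columns:
            trial = X[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(c)
            else:
                aliased.append(c)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return X, groups_cols


class GroupModel:
    """Linear mixed model of one baseline variable on diagnostic group.

    Parameters
    ----------
    data : DataFrame
        One row per subject (baseline), with the outcome, group, covariates
        and a site column.
    outcome : str
        Column to model.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, group_col="group_bl",
                 covariates=("age_bl", "sex", "education", "icv"),
                 site_col="site", reference=REFERENCE_GROUP):
        data = data.dropna(subset=[outcome]).copy()
        if data[group_col].nunique() < 2:
            raise ValueError("need at least 2 groups")
        self.data, self.outcome = data, outcome
        self.group_col, self.covariates = group_col, list(covariates)
        self.site_col, self.reference = site_col, reference

    def fit(self, reml: bool = True) -> GroupModelResults:
        data = self.data
        X, group_cols = _design(data, self.group_col, self.covariates,
                                self.reference)
        y = data[self.outcome].to_numpy(dtype=float)
        n_sites = data[self.site_col].nunique()
        if n_sites >= 2:
            fit = RandomInterceptLM(y, X.to_numpy(),
                                    data[self.site_col]).fit(reml=reml)
            beta = pd.Series(fit.params, index=X.columns)
            cov = fit.cov_params
            site_sd = float(np.sqrt(fit.tau2))
            resid_sd = float(np.sqrt(fit.sigma2))
        else:
            log.warning("single site: dropping the site random intercept")
            ols = sm.OLS(y, X.to_numpy()).fit()
            beta = pd.Series(ols.params, index=X.columns)
            cov = ols.cov_params()
            site_sd, resid_sd = 0.0, float(np.sqrt(ols.scale))
        n, p = len(y), X.shape[1]
        ddf = n - p

        def wald(cols) -> TermTest:
            idx = [X.columns.get_loc(c) for c in cols]
            b = beta.iloc[idx].to_numpy()
            V = cov[np.ix_(idx, idx)]
            q = len(idx)
            F = float(b @ np.linalg.solve(V, b) / q)
            return TermTest("", F, q, ddf, float(stats.f.sf(F, q, ddf)))

        terms = []
        t = wald(group_cols)
        t.term = "group"
        terms.append(t)
        for c in X.columns:
            if c == "Intercept" or c in group_cols:
                continue
            t = wald([c])
            t.term = c
            terms.append(t)
        f_grp = float(np.sqrt(terms[0].df_num * terms[0].f_stat / ddf))
        return GroupModelResults(outcome=self.outcome, terms=terms, params=beta,
                                 cohens_f_group=f_grp, site_sd=site_sd,
                                 resid_sd=resid_sd, nobs=n)


def pairwise_contrasts(data: pd.DataFrame, outcome: str, reference=REFERENCE_GROUP,
                       group_col="group_bl", covariates=("age_bl", "sex",
                                                         "education", "icv"),
                       site_col="site", method: str = "holm") -> list:
    """Post-hoc two-group refits of the group model against the reference.

    For each non-reference group the model is refitted on that group plus the
    reference; the adjusted group contrast, a Cohen's d (contrast divided by
    the pooled within-group SD of the raw outcome) and Holm-adjusted p-values
    are returned.
    """
    others = [g for g in pd.unique(data[group_col]) if g != reference]
    if not others:
        raise ValueError("no non-reference group to contrast")
    out = []
    for g in others:
        if g == reference:
            raise ValueError("cannot contrast a group with itself")
        sub = data[data[group_col].isin([reference, g])]
        res = GroupModel(sub, outcome, group_col=group_col,
                         covariates=covariates, site_col=site_col,
                         reference=reference).fit()
        est = float(res.params[f"group[{g}]"])
        x = sub.loc[sub[group_col] == g, outcome].dropna()
        y = sub.loc[sub[group_col] == reference, outcome].dropna()
        sp = np.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
                     / (len(x) + len(y) - 2))
        out.append(dict(group=g, estimate=est, cohens_d=est / sp,
                        p_value=res.term("group").p_value))
    padj = adjust_pvalues([c["p_value"] for c in out], method=method)
    for c, pa in zip(out, padj):
        c["p_adjusted"] = float(pa)
    return out
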