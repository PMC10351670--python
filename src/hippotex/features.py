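"""Feature-table cleaning and PCA reduction trained on healthy baselines.

Cleaning: per-feature extreme outliers (outside mean +/- 3 x IQR) are set
missing cell-wise, and near-constant features (variance < 1e-10) are dropped.
The PCA rotation is computed only on a designated training subset — baseline
scans of cognitively unimpaired participants — after z-scoring each feature
with the training mean and SD, and is then applied to the entire table.
Components explaining at least 5% of training variance are retained by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CleanReport", "clean_features", "PcaModel", "fit_pca", "project"]


@dataclass
class CleanReport:
    n_cells_masked: int
    dropped_features: list


def clean_features(table: pd.DataFrame, iqr_mult: float = 3.0,
                   var_tol: float = 1e-10):
    """Mask extreme cells and drop near-constant features.

    Returns ``(cleaned, report)``.  Cells outside ``mean +/- iqr_mult * IQR``
    of their column become NaN; columns whose variance is below ``var_tol``
    are dropped entirely.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    num = table.select_dtypes(include=[np.number])
    out = table.copy()
    masked = 0
    dropped = []
    for col in num.columns:
        v = out[col].astype(float)
        if v.var(ddof=1) < var_tol or not np.isfinite(v.var(ddof=1)):
            dropped.append(col)
            continue
        q1, q3 = v.quantile([0.25, 0.75])
        iqr = q3 - q1
        lo, hi = v.mean() - iqr_mult * iqr, v.mean() + iqr_mult * iqr
        bad = (v < lo) | (v > hi)
        masked += int(bad.sum())
        out.loc[bad, col] = np.nan
    out = out.drop(columns=dropped)
    if not out.select_dtypes(include=[np.number]).columns.size:
        raise ValueError("all features dropped during cleaning")
    return out, CleanReport(n_cells_masked=masked, dropped_features=dropped)


@dataclass
class PcaModel:
    """A PCA rotation frozen on a training subset.

    ``loadings`` has one orthonormal column per component (features x
    components, all components kept for bookkeeping); ``retained`` indexes
    the components whose training variance share meets the threshold.
    """

    features: list
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    retained: list
    training_index: list

    def component_names(self):
        return [f"txpc{i + 1}" for i in range(len(self.retained))]

    # -- serialization -------------------------------------------------
    def to_json(self, path):
        obj = dict(features=self.features,
                   means=self.means.tolist(), sds=self.sds.tolist(),
                   loadings=self.loadings.tolist(),
                   variance_explained=self.variance_explained.tolist(),
                   retained=list(self.retained),
                   training_index=[str(i) for i in self.training_index])
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            obj = json.load(fh)
        return cls(features=obj["features"], means=np.array(obj["means"]),
                   sds=np.array(obj["sds"]), loadings=np.array(obj["loadings"]),
                   variance_explained=np.array(obj["variance_explained"]),
                   retained=list(obj["retained"]),
                   training_index=list(obj["training_index"]))


def fit_pca(table: pd.DataFrame, training_rows, feature_cols=None,
            retain_threshold: float = 0.05) -> PcaModel:
    """Fit the PCA rotation on ``training_rows`` of ``table``.

    ``training_rows`` is a boolean mask or index selector.  Training rows
    must be complete cases on the feature columns.  Features are z-scored
    with training means/SDs; the rotation is the eigenbasis of the training
    correlation structure (via SVD).  Component signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    feature_cols = list(feature_cols) if feature_cols is not None else \
        list(table.select_dtypes(include=[np.number]).columns)
    train = table.loc[training_rows, feature_cols].dropna()
    if len(train) < 2:
        raise ValueError("fewer than 2 complete training rows")
    X = train.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        zero = [feature_cols[i] for i in np.where(sds == 0)[0]]
        raise ValueError(f"constant feature(s) in training data: {zero}")
    Z = (X - means) / sds
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T
    var = svals**2
    shares = var / var.sum()
    # deterministic sign convention: largest |loading| positive per component
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
    retained = [int(i) for i in np.where(shares >= retain_threshold)[0]]
    if not retained:
        raise ValueError("no component reaches the retention threshold")
    return PcaModel(features=feature_cols, means=means, sds=sds,
                    loadings=loadings, variance_explained=shares,
                    retained=retained, training_index=list(train.index))


def project(model: PcaModel, table: pd.DataFrame) -> pd.DataFrame:
    """Project rows onto the retained components.

    Rows are standardized with the *training* means/SDs.  Missing cells
    propagate: any row with a missing feature gets NaN scores.
    """
    missing = [c for c in model.features if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks feature column(s): {missing}")
    X = table[model.features].to_numpy(dtype=float)
    Z = (X - model.means) / model.sds
    scores = Z @ model.loadings[:, model.retained]
    scores[np.isnan(Z).any(axis=1)] = np.nan
    return pd.DataFrame(scores, index=table.index,
                        columns=model.component_names())
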