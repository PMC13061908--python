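"""PCA score plots with per-group confidence ellipses, and Ward clustering.

These exploratory views answer the "natural grouping" question: do samples
organise by stress group, time point, sex, age — or by participant? On the
real study the dominant structure was participant identity, which is the
motivation for the ratio-based normalisation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .tables import FeatureTable, ValidationError

__all__ = ["PCAResult", "pca", "confidence_ellipse", "ward_cluster"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca(table: FeatureTable, n_components: int = 2) -> PCAResult:
    """PCA of a z-scored table with a deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is positive.
    """
    X = table.values.to_numpy(dtype=float)
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        raise ValidationError(f"n_components={n_components} exceeds the data rank ({rank})")
    fit = PCA(n_components=n_components, svd_solver="full").fit(X)
    load = fit.components_.T.copy()  # features x components
    scores = fit.transform(X)
    for c in range(n_components):
        j = int(np.argmax(np.abs(load[:, c])))
        if load[j, c] < 0:
            load[:, c] *= -1
            scores[:, c] *= -1
    cols = [f"PC{c + 1}" for c in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.values.index, columns=cols),
        loadings=pd.DataFrame(load, index=table.values.columns, columns=cols),
        explained_variance_ratio=fit.explained_variance_ratio_.copy(),
    )


def confidence_ellipse(scores: pd.DataFrame, grouping, level: float = 0.95) -> tuple[pd.DataFrame, pd.Series]:
    """Per-group 95 % confidence ellipses in a 2-D score plane.

    Each group's ellipse is the set {x : (x - m)' S^-1 (x - m) <= chi2_2(level)}
    from the group sample mean m and covariance S. Returns (per-group
    ellipse parameters, per-point inside/outside flag for its own group's
    ellipse). Groups with singular covariance yield a degenerate flag and
    every exactly-coincident point counts as inside.
    """
    if scores.shape[1] != 2:
        raise ValidationError("confidence_ellipse expects exactly 2 score columns")
    g = pd.Series(np.asarray(grouping), index=scores.index)
    q = stats.chi2.ppf(level, df=2)
    rows = []
    inside = pd.Series(False, index=scores.index)
    for lev, idx in g.groupby(g).groups.items():
        pts = scores.loc[idx].to_numpy(dtype=float)
        if pts.shape[0] < 3:
            raise ValidationError(f"group {lev!r} has fewer than 3 points")
        m = pts.mean(axis=0)
        S = np.cov(pts, rowvar=False)
        degenerate = np.linalg.matrix_rank(S) < 2
        Sinv = np.linalg.pinv(S)
        d2 = np.einsum("ij,jk,ik->i", pts - m, Sinv, pts - m)
        if degenerate:
            inside.loc[idx] = d2 <= q + 1e-9
            width = height = angle = 0.0
        else:
            inside.loc[idx] = d2 <= q
            evals, evecs = np.linalg.eigh(S)
            width, height = 2 * np.sqrt(evals[1] * q), 2 * np.sqrt(evals[0] * q)
            angle = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
        rows.append(
            {
                "group": lev,
                "center_x": m[0],
                "center_y": m[1],
                "width": width,
                "height": height,
                "angle_deg": angle,
                "degenerate": degenerate,
                "n": pts.shape[0],
                "frac_inside": float(inside.loc[idx].mean()),
            }
        )
    return pd.DataFrame(rows), inside


def ward_cluster(table: FeatureTable):
    """Hierarchical clustering of samples: Euclidean distance, Ward linkage.

    Returns (linkage matrix in scipy format, leaf order). Scipy's linkage
    breaks ties by cluster index, which is deterministic for a fixed row
    order.
    """
    X = table.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    return Z, list(table.values.index[leaves])
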