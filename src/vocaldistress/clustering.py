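"""k-means grouping of speech frames and cluster-derived predictors.

Frames are clustered on the z-scored selected features; k is chosen from a
scree of between-cluster variance (elbow rule); the two leading principal
components of the same feature space are appended to the frame table as
extra predictors for the boosting stage.  Cluster quality is checked two
ways: association with caller sex (Cramer's V — should be near 0 if the
clusters capture phonation style rather than anatomy) and a logistic
regression of cluster membership on the features (McFadden pseudo-R²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ClusterModel",
    "ClusterValidation",
    "kmeans_fit",
    "scree_select",
    "cramers_v",
    "cluster_pcs",
    "validate_clusters",
]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # (k, p), standardized space
    assignments: np.ndarray  # values in 1..k, renumbered by descending size
    explained_variance_fraction: float  # between-cluster SS / total SS
    seed: int
    n_init: int


@dataclass
class ClusterValidation:
    cramers_v_sex: float
    pseudo_r2: float
    direction_summary: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    return (x - x.mean(axis=0)) / sd


def kmeans_fit(
    table: pd.DataFrame,
    k: int,
    seed: int,
    n_init: int = 25,
    feature_cols: list[str] | None = None,
) -> ClusterModel:
    """Best-of-n_init k-means++ on z-scored features; labels sorted by size."""
    cols = feature_cols or [c for c in table.columns if table[c].dtype.kind == "f"]
    x = _zscore(table[cols].to_numpy(dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(x) < k:
        raise ValueError(f"{len(x)} rows < k={k}")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    total_ss = float(((x - x.mean(axis=0)) ** 2).sum())
    between = 0.0 if (total_ss == 0 or k == 1) else 1.0 - km.inertia_ / total_ss
    # renumber clusters 1..k by descending size for stable reporting
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_[order],
        assignments=remap[km.labels_],
        explained_variance_fraction=float(np.clip(between, 0.0, 1.0)),
        seed=seed,
        n_init=n_init,
    )


def scree_select(
    table: pd.DataFrame,
    k_range: range = range(1, 6),
    seed: int = 0,
    gain_fraction: float = 0.25,
    feature_cols: list[str] | None = None,
) -> tuple[dict[int, float], int, list[str]]:
    """Explained-variance scree over k and the elbow choice.

    The chosen k is the smallest k whose marginal gain in explained
    variance falls below gain_fraction of the first gain ("levels off"
    made explicit).  Returns (scree, chosen_k, flags).
    """
    ks = sorted(k_range)
    scree: dict[int, float] = {}
    prev = 0.0
    for k in ks:
        try:
            prev = kmeans_fit(
                table, k, seed=seed, feature_cols=feature_cols
            ).explained_variance_fraction
        except ValueError:  # fewer distinct points than k: no further gain
            pass
        scree[k] = prev
    flags: list[str] = []
    gains = [scree[ks[i + 1]] - scree[ks[i]] for i in range(len(ks) - 1)]
    if not gains or gains[0] <= 0.0:
        return scree, ks[0], ["no variance gain beyond k=1"]
    chosen = ks[-1]
    for i, g in enumerate(gains):
        if g < gain_fraction * gains[0]:
            chosen = ks[i]
            break
    spread = max(gains) - min(gains)
    if spread < 0.25 * gains[0]:
        flags.append("weak elbow: marginal gains are all similar")
    return scree, chosen, flags


def cramers_v(labels_a, labels_b) -> float:
    """Cramer's V: sqrt(chi2 / (n * (min(r, c) - 1))) from the contingency table."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    tab = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    r, c = tab.shape
    if min(r, c) < 2:
        return 0.0  # a single-level variable carries no association
    chi2 = chi2_contingency(tab, correction=False)[0]
    n = tab.sum()
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def cluster_pcs(
    table: pd.DataFrame, feature_cols: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Append pc1/pc2: leading principal-component scores of z-scored features.

    Signs are fixed so each component correlates positively with its
    highest-loading feature, making the coordinates reproducible across
    runs.  Rank-1 data yields a zero pc2 with a flag.
    """
    cols = feature_cols or [c for c in table.columns if table[c].dtype.kind == "f"]
    if len(cols) < 2:
        raise ValueError("need >= 2 features for principal components")
    x = _zscore(table[cols].to_numpy(dtype=float))
    flags: list[str] = []
    n_comp = min(2, np.linalg.matrix_rank(x))
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    out = table.copy()
    for i in range(2):
        if i < n_comp:
            load = pca.components_[i]
            top = int(np.argmax(np.abs(load)))
            s = scores[:, i] * (1.0 if load[top] >= 0 else -1.0)
        else:
            s = np.zeros(len(table))
            flags.append("rank-deficient features: pc2 set to 0")
        out[f"pc{i + 1}"] = s
    return out, flags


def validate_clusters(
    table: pd.DataFrame,
    assignments: np.ndarray,
    feature_cols: list[str] | None = None,
    sex_col: str = "sex",
) -> ClusterValidation:
    """Logistic validation of a 2-cluster solution.

    Regresses membership on the (z-scored) features and reports McFadden
    pseudo-R² as the variance accounted for, plus which cluster sits higher
    on each feature.  Perfect separation triggers a ridge-regularized refit.
    """
    assignments = np.asarray(assignments)
    if len(np.unique(assignments)) != 2:
        raise ValueError("cluster validation requires exactly 2 clusters")
    cols = feature_cols or [c for c in table.columns if table[c].dtype.kind == "f"]
    x = _zscore(table[cols].to_numpy(dtype=float))
    y = (assignments == assignments.max()).astype(float)
    design = sm.add_constant(x)
    flags: list[str] = []
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        llf, llnull = fit.llf, fit.llnull
        params = fit.params
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
            raise ValueError("diverging coefficients")
    except (Exception,):
        flags.append("separation detected: ridge-regularized refit (1e-6)")
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-6, L1_wt=0.0
        )
        params = np.asarray(fit.params)
        mu = 1.0 / (1.0 + np.exp(-design @ params))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        p0 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        llnull = float(len(y) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
    pseudo_r2 = float(np.clip(1.0 - llf / llnull, 0.0, 1.0)) if llnull != 0 else 0.0

    hi, lo = assignments.max(), assignments.min()
    direction = []
    for c in cols:
        mhi = table.loc[assignments == hi, c].mean()
        mlo = table.loc[assignments == lo, c].mean()
        which = hi if mhi >= mlo else lo
        direction.append(f"cluster {which} has higher {c}")
    v = (
        cramers_v(assignments, table[sex_col].to_numpy())
        if sex_col in table.columns
        else np.nan
    )
    return ClusterValidation(
        cramers_v_sex=v, pseudo_r2=pseudo_r2, direction_summary=direction, flags=flags
    )
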