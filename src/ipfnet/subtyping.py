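"""Unsupervised molecular subtyping and subgroup statistics.

Case samples are clustered by Ward agglomeration on Euclidean distances
over standardized DEG features; the number of clusters is chosen by the
silhouette maximum over k = 2..k_max, with the within-cluster SSE elbow
reported for corroboration.  Elementary subgroup comparisons (Welch t,
Fisher exact) and Pearson clinical correlations with Bonferroni
adjustment live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

logger = logging.getLogger("ipfnet")


def standardize_features(values: pd.DataFrame) -> pd.DataFrame:
    """Per-feature (row) mean 0, sd 1; constant rows left centred."""
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return pd.DataFrame((arr - mu) / sd, index=values.index, columns=values.columns)


def ward_cluster(values: pd.DataFrame, standardize: bool = True) -> np.ndarray:
    """Ward linkage over samples (columns) on Euclidean distances.

    Returns the scipy linkage matrix; merge heights are non-decreasing.
    """
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    X = standardize_features(values) if standardize else values
    return linkage(X.to_numpy(dtype=float).T, method="ward")


@dataclass
class ClusterResult:
    tree: np.ndarray
    silhouette: pd.Series          # k -> mean silhouette (k = 2..k_max)
    sse: pd.Series                 # k -> within-cluster SSE (k = 1..k_max)
    chosen_k: int
    elbow_k: int | None
    labels: pd.Series              # per-sample cluster id at chosen_k
    sizes: dict[int, int]


def _sse(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(total)


def choose_k(tree: np.ndarray, values: pd.DataFrame, k_max: int = 6,
             standardize: bool = True) -> ClusterResult:
    """Cut the tree at k = 1..k_max; pick k maximising mean silhouette.

    Silhouette is evaluated for k = 2..k_max (undefined at k = 1); the
    SSE elbow (maximum second difference) is reported alongside.
    """
    n = values.shape[1]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be < number of samples ({n})")
    Xdf = standardize_features(values) if standardize else values
    X = Xdf.to_numpy(dtype=float).T
    sil, sse = {}, {}
    labels_by_k = {}
    sse[1] = _sse(X, np.ones(n, dtype=int))
    for k in range(2, k_max + 1):
        labs = fcluster(tree, t=k, criterion="maxclust")
        labels_by_k[k] = labs
        sse[k] = _sse(X, labs)
        if len(np.unique(labs)) < 2:
            sil[k] = np.nan
        else:
            sil[k] = float(silhouette_score(X, labs, metric="euclidean"))
    sil_s = pd.Series(sil).sort_index()
    chosen = int(sil_s.idxmax())
    sse_s = pd.Series(sse).sort_index()
    elbow = None
    ks = list(sse_s.index)
    if len(ks) >= 3:
        second = {
            ks[i]: sse_s[ks[i - 1]] - 2 * sse_s[ks[i]] + sse_s[ks[i + 1]]
            for i in range(1, len(ks) - 1)
        }
        elbow = int(max(second, key=second.get))
    labs = labels_by_k[chosen]
    labels = pd.Series(labs, index=values.columns, name="cluster")
    sizes = {int(k): int(v) for k, v in zip(*np.unique(labs, return_counts=True))}
    return ClusterResult(tree, sil_s, sse_s, chosen, elbow, labels, sizes)


def compare_groups(score: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Two-sided Welch t-test between the two label groups."""
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = score[labels == levels[0]].to_numpy(dtype=float)
    b = score[labels == levels[1]].to_numpy(dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("need >= 2 observations per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.info("compare_groups: zero variance in both groups; df floored at 1")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):
        return 0.0, 1.0
    return float(t), float(p)


def compare_categorical(counts) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Reports the sample odds ratio with Haldane 0.5 correction (not the
    conditional MLE).  A zero margin gives p = 1.
    """
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b, c, d = tab.ravel()
    if min(a + b, c + d, a + c, b + d) == 0:
        p = 1.0
    else:
        _, p = stats.fisher_exact(tab.astype(int), alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a * d / (b * c)), float(p)


def clinical_correlation(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Pearson r per (score row, covariate column) with Bonferroni p.

    Samples with a missing covariate are dropped per pair; pairs with a
    constant vector are reported with missing r and a note.
    """
    if m_tests is None:
        m_tests = scores.shape[0] * covariates.shape[1]
    rows = []
    for set_name in scores.index:
        s = scores.loc[set_name]
        for cov_name in covariates.columns:
            c = covariates[cov_name]
            common = s.index.intersection(c.index)
            mask = c.loc[common].notna() & s.loc[common].notna()
            x = s.loc[common][mask].to_numpy(dtype=float)
            y = c.loc[common][mask].to_numpy(dtype=float)
            if len(x) < 3:
                rows.append((set_name, cov_name, len(x), np.nan, np.nan, np.nan, "too few pairs"))
                continue
            if x.std() == 0 or y.std() == 0:
                rows.append((set_name, cov_name, len(x), np.nan, np.nan, np.nan, "constant vector"))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((set_name, cov_name, len(x), float(r), float(p),
                         float(min(1.0, p * m_tests)), ""))
    return pd.DataFrame(
        rows, columns=["score", "covariate", "n", "r", "p", "adj_p", "note"]
    )
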