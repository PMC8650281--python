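"""Harmonisation of multi-batch compendia.

Quantile normalization forces every sample onto a common reference
distribution; the empirical-Bayes batch adjustment removes per-batch,
per-gene additive (location) and multiplicative (scale) effects while
protecting the case/control contrast via a condition covariate; PCA QC
quantifies how strongly batches separate before vs after adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("ipfnet")


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean of the column-sorted values.

    The reference distribution is the row-wise mean of the sorted
    columns; each column's entries are replaced by the reference value at
    their within-column rank.  Tied values receive the mean of the
    reference values across the tied rank span, so the transform is
    well defined and idempotent.
    """
    arr = values.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("empty matrix")
    if np.isnan(arr).any():
        raise ValueError("missing values present; quantile normalization requires a complete matrix")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        assigned = reference.copy()
        # average reference over runs of tied input values
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(col)]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[s:e] = reference[s:e].mean()
        out[order, j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    from scipy.special import polygamma

    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.all(-dif / x < 1e-10):
            break
    return x


def combat_adjust(
    values: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    condition: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene, a linear model with batch indicators (and the condition as
    covariate when estimable) is fitted; data are standardised against
    the batch-free fit; per-batch additive (gamma) and multiplicative
    (delta^2) effects are estimated and shrunk toward batch-level
    parametric priors (normal for gamma, inverse-gamma for delta^2,
    hyper-parameters by method of moments), then removed; finally the
    grand mean and covariate effects are restored.
    """
    Y = values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("missing values present")
    batch = np.asarray(batch)
    levels, batch_idx = np.unique(batch, return_inverse=True)
    n_batches = len(levels)
    if n_batches < 2:
        raise ValueError("need >= 2 batches")
    counts = np.bincount(batch_idx)
    if counts.min() < 2:
        small = levels[counts < 2].tolist()
        raise ValueError(f"batch(es) with a single sample: {small}")
    n = Y.shape[1]

    B = np.zeros((n, n_batches))
    B[np.arange(n), batch_idx] = 1.0
    X = B
    use_cond = condition is not None
    if use_cond:
        cond = np.asarray(condition)
        cvals = np.unique(cond)
        if len(cvals) < 2:
            use_cond = False
        else:
            for bi, lev in enumerate(levels):
                if len(np.unique(cond[batch_idx == bi])) < 2:
                    warnings.warn(
                        f"batch '{lev}' is confounded with condition; "
                        "proceeding without the condition covariate"
                    )
                    use_cond = False
                    break
        if use_cond:
            cind = (cond == cvals[-1]).astype(float)[:, None]
            X = np.hstack([B, cind])

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, genes)
    gamma_fit = beta[:n_batches, :]
    grand_mean = (counts / n) @ gamma_fit  # per-gene
    resid = Y.T - X @ beta
    var_pooled = (resid**2).mean(axis=0)  # per-gene
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_mean = np.tile(grand_mean, (n, 1))
    if use_cond:
        stand_mean = stand_mean + X[:, n_batches:] @ beta[n_batches:, :]
    Z = (Y.T - stand_mean) / np.sqrt(var_pooled)  # samples x genes

    Z_adj = Z.copy()
    for bi in range(n_batches):
        rows = batch_idx == bi
        nb = counts[bi]
        Zb = Z[rows, :]
        gamma_hat = Zb.mean(axis=0)
        delta_hat = Zb.var(axis=0, ddof=1)
        delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)
        # method-of-moments hyper-priors
        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        if s2 <= 0:
            lam, theta = 1.0 + 1e-8, m
        else:
            lam = (2.0 * s2 + m**2) / s2
            theta = (m * s2 + m**3) / s2
        # iterative EB solution for gamma*, delta*
        g_old = gamma_hat.copy()
        d_old = delta_hat.copy()
        ssq_base = ((Zb - gamma_hat) ** 2).sum(axis=0)
        for _ in range(200):
            g_new = (nb * t2 * gamma_hat + d_old * gamma_bar) / (nb * t2 + d_old)
            ssq = ssq_base + nb * (gamma_hat - g_new) ** 2
            d_new = (theta + 0.5 * ssq) / (nb / 2.0 + lam - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < 1e-6:
                break
        Z_adj[rows, :] = (Zb - g_old) / np.sqrt(np.maximum(d_old, 1e-12))

    out = Z_adj * np.sqrt(var_pooled) + stand_mean
    return pd.DataFrame(out.T, index=values.index, columns=values.columns)


@dataclass
class PcaSummary:
    """First two PCs per sample plus variance fractions and batch split."""

    scores: pd.DataFrame              # samples x [PC1, PC2]
    variance_fraction: np.ndarray     # all components, non-increasing
    batch_separation: float           # between/total variance of PC1 scores


def pca_qc(values: pd.DataFrame, labels: pd.Series | np.ndarray) -> PcaSummary:
    """PCA on the gene-standardised matrix with a batch-separation statistic.

    The statistic is the between-batch over total variance (eta squared)
    of the PC1 scores: ~0 when batches are well mixed, ->1 when PC1 is a
    pure batch axis.
    """
    from sklearn.decomposition import PCA

    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA QC")
    sd = arr.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("constant matrix; PCA undefined")
    std = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    n_comp = min(std.shape[1], std.shape[0])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(std.T)
    labels = np.asarray(labels)
    pc1 = scores[:, 0]
    total = pc1.var()
    if total <= 0:
        sep = 0.0
    else:
        grand = pc1.mean()
        between = sum(
            (labels == lev).sum() * (pc1[labels == lev].mean() - grand) ** 2
            for lev in np.unique(labels)
        ) / len(pc1)
        sep = float(between / total)
    score_df = pd.DataFrame(
        scores[:, :2], index=values.columns, columns=["PC1", "PC2"]
    )
    return PcaSummary(score_df, pca.explained_variance_ratio_, sep)
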