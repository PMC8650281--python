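"""Consensus differential expression.

Three independent per-gene statistics — an empirical-Bayes moderated t,
a SAM-style regularised d with permutation q-values, and a scaled
between-condition "artificial component" with a single-step permutation
FDR — are intersected, together with a fold-change filter, into
consensus up/down calls.  Requiring concordance of all three methods
minimises the realised false-discovery rate of the final DEG list.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import _trigamma_inverse

logger = logging.getLogger("ipfnet")

CASE, CONTROL = "case", "control"


def _group_masks(condition) -> tuple[np.ndarray, np.ndarray]:
    cond = np.asarray(condition)
    case = cond == CASE
    ctrl = cond == CONTROL
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("need >= 2 samples per condition")
    if case.sum() + ctrl.sum() != len(cond):
        bad = sorted(set(cond) - {CASE, CONTROL})
        raise ValueError(f"unknown condition label(s): {bad}")
    return case, ctrl


def _two_group(values: pd.DataFrame, condition):
    X = values.to_numpy(dtype=float)
    case, ctrl = _group_masks(condition)
    n1, n2 = int(case.sum()), int(ctrl.sum())
    m1 = X[:, case].mean(axis=1)
    m2 = X[:, ctrl].mean(axis=1)
    ss1 = ((X[:, case] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X[:, ctrl] - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    return X, case, ctrl, n1, n2, m1 - m2, s2, df


def moderated_t(
    values: pd.DataFrame,
    condition,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t statistics.

    Residual variances ``s2_g`` on ``d_g`` df are shrunk toward a prior
    ``s0^2`` with ``d0`` df, ``s2_post = (d0 s0^2 + d_g s2_g)/(d0+d_g)``;
    ``(d0, s0^2)`` are estimated by method of moments on ``log s2_g``
    via the digamma/trigamma identities for the log of a scaled chi-square.
    ``prior_df`` overrides the estimated ``d0`` (0 recovers the ordinary
    pooled t).  Returns a per-gene frame with log2fc, t, p, adj_p.
    """
    _, _, _, n1, n2, diff, s2, df = _two_group(values, condition)
    G = len(s2)

    if prior_df is None:
        pos = s2 > 0
        if pos.sum() < 2:
            d0, s0_sq = 0.0, float(s2.mean())
        else:
            z = np.log(s2[pos])
            e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
            emean = e.mean()
            nobs = pos.sum()
            target = ((e - emean) ** 2).sum() / (nobs - 1) * (nobs / (nobs - 1))
            target = target - special.polygamma(1, df / 2.0)
            if target <= 0:
                d0 = np.inf
                s0_sq = float(np.exp(emean))
            else:
                d0 = float(2.0 * _trigamma_inverse(np.array([target]))[0])
                s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    else:
        d0 = float(prior_df)
        s0_sq = float(np.median(s2)) if np.isfinite(d0) and d0 > 0 else float(s2.mean())

    if np.isinf(d0):
        s2_post = np.full(G, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.zeros(G)
    p = np.ones(G)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    if np.isinf(df_total):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total)
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        logger.info("moderated_t: %d zero-variance gene(s) set to t=0, p=1", n_degenerate)
    adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"log2fc": diff, "t": t, "p": p, "adj_p": adj}, index=values.index
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def _stratified_case_indicators(
    condition, batch, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_samples, n_perm) 0/1 case indicators permuted within batches.

    When fewer distinct stratified permutations exist than requested,
    all distinct ones are enumerated instead (logged).
    """
    cond = np.asarray(condition)
    n = len(cond)
    if batch is None:
        batch = np.zeros(n, dtype=int)
    batch = np.asarray(batch)
    levels = np.unique(batch)
    log_count = 0.0
    per_batch = []
    for lev in levels:
        idx = np.flatnonzero(batch == lev)
        k = int((cond[idx] == CASE).sum())
        per_batch.append((idx, k))
        log_count += math.lgamma(len(idx) + 1) - math.lgamma(k + 1) - math.lgamma(len(idx) - k + 1)
    if log_count <= math.log(max(n_perm, 1)):
        # enumerate every distinct within-batch assignment
        choices = [list(itertools.combinations(range(len(idx)), k)) for idx, k in per_batch]
        combos = list(itertools.product(*choices))
        logger.info(
            "permutation test: only %d distinct stratified permutations; using all",
            len(combos),
        )
        P = np.zeros((n, len(combos)))
        for c, combo in enumerate(combos):
            for (idx, _), sel in zip(per_batch, combo):
                P[idx[list(sel)], c] = 1.0
        return P
    P = np.zeros((n, n_perm))
    for c in range(n_perm):
        for idx, k in per_batch:
            sel = rng.choice(len(idx), size=k, replace=False)
            P[idx[sel], c] = 1.0
    return P


def _perm_d_stats(X, P, n1, n2, s0):
    """Vectorised SAM-type d statistics for each permutation column of P."""
    df = n1 + n2 - 2
    rowsum = X.sum(axis=1, keepdims=True)
    rowsq = (X**2).sum(axis=1, keepdims=True)
    S1 = X @ P
    M1 = S1 / n1
    M2 = (rowsum - S1) / n2
    SQ1 = (X**2) @ P
    ss = (SQ1 - n1 * M1**2) + ((rowsq - SQ1) - n2 * M2**2)
    sd = np.sqrt(np.maximum(ss / df, 0.0))
    return (M1 - M2) / (sd + s0)


def _tail_counts(stat_abs: np.ndarray, null_abs: np.ndarray) -> np.ndarray:
    """#{null >= threshold} for each observed threshold, per null column."""
    G, P = null_abs.shape
    counts = np.empty((G, P))
    for c in range(P):
        col = np.sort(null_abs[:, c])
        counts[:, c] = G - np.searchsorted(col, stat_abs, side="left")
    return counts


def _monotonize(q: np.ndarray, stat_abs: np.ndarray) -> np.ndarray:
    """Enforce q non-increasing in |statistic| (running min from the top)."""
    order = np.argsort(-stat_abs, kind="stable")
    out = q.copy()
    out[order] = np.minimum.accumulate(q[order][::-1])[::-1]
    return np.minimum(out, 1.0)


def sam_statistic(
    values: pd.DataFrame,
    condition,
    n_perm: int = 1000,
    seed: int = 0,
    batch=None,
    s0: float | None = None,
) -> pd.DataFrame:
    """SAM-style regularised d statistic with permutation q-values.

    ``d_g = (mean_case - mean_control) / (s_g + s0)`` with ``s_g`` the
    pooled standard deviation and fudge constant ``s0`` defaulting to the
    median of the ``s_g``.  The null comes from condition-label
    permutations stratified by batch; ``q_g`` is the median permutation
    tail count over the observed tail count at ``|d_g|``, monotonised
    and capped at 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X, case, ctrl, n1, n2, diff, s2, df = _two_group(values, condition)
    sd = np.sqrt(s2)
    if s0 is None:
        s0 = float(np.median(sd))
    d = diff / (sd + s0)
    rng = np.random.default_rng(seed)
    P = _stratified_case_indicators(condition, batch, n_perm, rng)
    d_null = _perm_d_stats(X, P, n1, n2, s0)
    d_abs = np.abs(d)
    obs = len(d) - np.searchsorted(np.sort(d_abs), d_abs, side="left")
    null_counts = _tail_counts(d_abs, np.abs(d_null))
    q = np.median(null_counts, axis=1) / np.maximum(obs, 1)
    q = _monotonize(q, d_abs)
    out = pd.DataFrame({"d": d, "q": q}, index=values.index)
    out.attrs["s0"] = s0
    out.attrs["n_perm_used"] = P.shape[1]
    return out


def artificial_components(
    values: pd.DataFrame,
    condition,
    n_perm: int = 1000,
    seed: int = 0,
    batch=None,
) -> pd.DataFrame:
    """Scaled between-condition component with single-step permutation FDR.

    ``psi2_g = (mean_case - mean_control) * sqrt(n1 n2 / n) / s_g``; the
    FDR at threshold ``t = |psi2_g|`` is the permutation-mean tail count
    over the observed tail count, monotonised and capped at 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X, case, ctrl, n1, n2, diff, s2, df = _two_group(values, condition)
    n = n1 + n2
    scale = math.sqrt(n1 * n2 / n)
    sd = np.sqrt(s2)
    psi2 = np.zeros(len(sd))
    ok = sd > 0
    psi2[ok] = diff[ok] * scale / sd[ok]
    rng = np.random.default_rng(seed)
    P = _stratified_case_indicators(condition, batch, n_perm, rng)
    # psi2 under permutation: same construction, s0 = 0 with the scale factor
    d_null = _perm_d_stats(X, P, n1, n2, 0.0)
    # _perm_d_stats returns diff/sd; multiply by the psi2 scale
    psi2_null = d_null * scale
    a = np.abs(psi2)
    obs = len(a) - np.searchsorted(np.sort(a), a, side="left")
    null_counts = _tail_counts(a, np.abs(psi2_null))
    fdr = null_counts.mean(axis=1) / np.maximum(obs, 1)
    fdr = _monotonize(fdr, a)
    return pd.DataFrame({"psi2": psi2, "fdr": fdr}, index=values.index)


def consensus_degs(
    mod_t: pd.DataFrame,
    sam: pd.DataFrame,
    ac: pd.DataFrame,
    adj_p_max: float = 0.01,
    fdr_max: float = 0.01,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Intersect the three per-gene tables into consensus up/down calls.

    A gene is consensus up iff the moderated-t BH-adjusted p, the SAM q
    and the artificial-component FDR are all below their thresholds AND
    ``log2FC > log2(fc_min)``; symmetric for down.
    """
    u1, u2, u3 = set(mod_t.index), set(sam.index), set(ac.index)
    if not (u1 == u2 == u3):
        diff = sorted((u1 ^ u2) | (u1 ^ u3))
        raise ValueError(f"gene universes differ; symmetric difference: {diff}")
    sam = sam.loc[mod_t.index]
    ac = ac.loc[mod_t.index]
    lfc = mod_t["log2fc"]
    log_fc_min = np.log2(fc_min) if np.isfinite(fc_min) else np.inf
    sig_t = mod_t["adj_p"] < adj_p_max
    sig_sam = sam["q"] < fdr_max
    sig_ac = ac["fdr"] < fdr_max
    all_sig = sig_t & sig_sam & sig_ac
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": mod_t["t"],
            "p": mod_t["p"],
            "adj_p": mod_t["adj_p"],
            "sam_d": sam["d"],
            "sam_q": sam["q"],
            "psi2": ac["psi2"],
            "ac_fdr": ac["fdr"],
            "up_t": sig_t & (lfc > 0),
            "down_t": sig_t & (lfc < 0),
            "up_sam": sig_sam & (lfc > 0),
            "down_sam": sig_sam & (lfc < 0),
            "up_ac": sig_ac & (lfc > 0),
            "down_ac": sig_ac & (lfc < 0),
            "consensus_up": all_sig & (lfc > log_fc_min),
            "consensus_down": all_sig & (lfc < -log_fc_min),
        },
        index=mod_t.index,
    )
    assert not (table["consensus_up"] & table["consensus_down"]).any()
    return table
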