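"""Gene-set and cell-marker scoring.

Term-level statistics (Fisher over-representation; running-sum GSEA with
permutation NES/FDR) and sample-level scores (ssGSEA, eigengene, z-scaled
cell-marker scores), plus the Jaccard-overlap enrichment map used to
visualise redundancy between significant terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


def ora_test(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each set.

    Each set is intersected with the universe; the 2x2 table is
    (in-query x in-set) over the universe, p is the hypergeometric upper
    tail, the odds ratio uses a Haldane 0.5 correction when a cell is 0,
    and BH adjustment runs across sets (significant: adjusted p < alpha).
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for name in sets.names():
        members = sets[name] & universe
        K = len(members)
        k = len(query & members)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append((name, k, K, a * d / (b * c), p))
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "odds_ratio", "p"]
    ).set_index("set")
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out["significant"] = out["adj_p"] < alpha
    return out


def _ranking_order(rank_stat: pd.Series) -> pd.Series:
    """Sort genes by decreasing statistic; ties broken by gene name."""
    df = pd.DataFrame({"stat": rank_stat})
    df = df.sort_values(by=["stat"], ascending=False, kind="stable")
    # stable sort on name within equal stats for determinism
    df["_name"] = df.index
    df = df.sort_values(by=["stat", "_name"], ascending=[False, True], kind="stable")
    return df["stat"]


def enrichment_score(
    rank_stat: pd.Series,
    gene_set: set[str],
    weight_p: float = 1.0,
    return_curve: bool = False,
):
    """Signed extremum of the GSEA running sum.

    Genes are walked in decreasing order of the ranking statistic; the
    running sum rises by ``|r|^p`` (normalised over hits) at set members
    and falls by ``1/(N - N_h)`` otherwise; ES is the value at maximal
    absolute deviation from zero.
    """
    ordered = _ranking_order(rank_stat)
    genes = np.array(ordered.index)
    r = ordered.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    n_hit = int(hit.sum())
    N = len(genes)
    if n_hit == 0:
        raise ValueError("gene set has no members in the ranked universe")
    if n_hit == N:
        raise ValueError("gene set covers the whole universe; ES undefined")
    w = np.abs(r) ** weight_p
    denom = w[hit].sum()
    if denom == 0:
        raise ValueError("all-zero ranking statistic over the gene set")
    steps = np.where(hit, w / denom, -1.0 / (N - n_hit))
    curve = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(curve)))
    es = float(curve[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    if return_curve:
        return es, curve, leading
    return es, leading


def signal_to_noise(values: pd.DataFrame, condition) -> pd.Series:
    """Classic GSEA phenotype ranking: (m1 - m2)/(s1 + s2), case first."""
    cond = np.asarray(condition)
    X = values.to_numpy(dtype=float)
    g1 = X[:, cond == "case"]
    g2 = X[:, cond == "control"]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    s1, s2 = g1.std(axis=1, ddof=1), g2.std(axis=1, ddof=1)
    return pd.Series((m1 - m2) / np.maximum(s1 + s2, 1e-8), index=values.index)


@dataclass
class EnrichmentResult:
    """GSEA result for one gene set."""

    name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)


def _null_es(
    rank_stat: pd.Series,
    gene_sets: dict[str, set[str]],
    weight_p: float,
    n_perm: int,
    perm_mode: str,
    rng: np.random.Generator,
    values: pd.DataFrame | None,
    condition=None,
) -> dict[str, np.ndarray]:
    null = {name: np.empty(n_perm) for name in gene_sets}
    if perm_mode == "gene":
        genes = list(rank_stat.index)
        for b in range(n_perm):
            perm_genes = rng.permutation(genes)
            permuted = pd.Series(rank_stat.to_numpy(), index=perm_genes)
            for name, gs in gene_sets.items():
                null[name][b], _ = enrichment_score(permuted, gs, weight_p)
    elif perm_mode == "phenotype":
        if values is None or condition is None:
            raise ValueError("phenotype permutation needs values and condition")
        cond = np.asarray(condition)
        for b in range(n_perm):
            perm_cond = rng.permutation(cond)
            stat = signal_to_noise(values, perm_cond)
            for name, gs in gene_sets.items():
                null[name][b], _ = enrichment_score(stat, gs, weight_p)
    else:
        raise ValueError(f"unknown perm_mode '{perm_mode}'")
    return null


def _sign_matched_p_nes(es: float, null: np.ndarray) -> tuple[float, float]:
    same = null[null >= 0] if es >= 0 else null[null < 0]
    if len(same) == 0:
        return 1.0, 0.0
    p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + len(same))
    mean_abs = np.abs(same).mean()
    nes = es / mean_abs if mean_abs > 0 else 0.0
    return float(p), float(nes)


def gsea_collection(
    rank_stat: pd.Series,
    sets: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    perm_mode: str = "gene",
    seed: int = 0,
    values: pd.DataFrame | None = None,
    condition=None,
    fdr_max: float = 0.25,
) -> pd.DataFrame:
    """GSEA over a collection with the positive/negative-tail NES FDR.

    Nominal p and NES are computed against sign-matched permutation ES;
    the FDR of a set compares the pooled null NES tail fraction with the
    observed NES tail fraction on the matching sign.  Sets are flagged
    significant at FDR < ``fdr_max`` (0.25, the conventional screen).
    """
    universe = set(rank_stat.index)
    gene_sets = {}
    for name in sets.names():
        inter = sets[name] & universe
        if inter and len(inter) < len(universe):
            gene_sets[name] = inter
    if not gene_sets:
        raise ValueError("no gene set overlaps the ranked universe")
    rng = np.random.default_rng(seed)
    null = _null_es(rank_stat, gene_sets, weight_p, n_perm, perm_mode, rng, values, condition)

    rows = {}
    null_nes_pool = []
    for name, gs in gene_sets.items():
        es, leading = enrichment_score(rank_stat, gs, weight_p)
        p, nes = _sign_matched_p_nes(es, null[name])
        pos_mean = np.abs(null[name][null[name] >= 0]).mean() if (null[name] >= 0).any() else np.nan
        neg_mean = np.abs(null[name][null[name] < 0]).mean() if (null[name] < 0).any() else np.nan
        nn = np.where(
            null[name] >= 0,
            null[name] / pos_mean if np.isfinite(pos_mean) else np.nan,
            null[name] / neg_mean if np.isfinite(neg_mean) else np.nan,
        )
        null_nes_pool.append(nn[np.isfinite(nn)])
        rows[name] = dict(es=es, nes=nes, p=p, leading_edge=leading)
    pool = np.concatenate(null_nes_pool)
    obs_nes = np.array([rows[n]["nes"] for n in rows])
    for name in rows:
        nes = rows[name]["nes"]
        if nes >= 0:
            num_tail, num_all = (pool >= nes).sum(), (pool >= 0).sum()
            den_tail, den_all = (obs_nes >= nes).sum(), (obs_nes >= 0).sum()
        else:
            num_tail, num_all = (pool <= nes).sum(), (pool < 0).sum()
            den_tail, den_all = (obs_nes <= nes).sum(), (obs_nes < 0).sum()
        num = num_tail / num_all if num_all else 1.0
        den = den_tail / max(den_all, 1)
        rows[name]["fdr"] = float(min(1.0, num / den)) if den > 0 else 1.0
    out = pd.DataFrame(
        {
            "es": {n: r["es"] for n, r in rows.items()},
            "nes": {n: r["nes"] for n, r in rows.items()},
            "p": {n: r["p"] for n, r in rows.items()},
            "fdr": {n: r["fdr"] for n, r in rows.items()},
            "leading_edge": {n: ",".join(r["leading_edge"]) for n, r in rows.items()},
        }
    )
    out.index.name = "set"
    out["significant"] = out["fdr"] < fdr_max
    return out.loc[list(gene_sets)]


def gsea(
    rank_stat: pd.Series,
    gene_set: set[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    perm_mode: str = "gene",
    seed: int = 0,
    values: pd.DataFrame | None = None,
    condition=None,
) -> EnrichmentResult:
    """Single-set GSEA; FDR degenerates to the permutation-NES tail."""
    universe = set(rank_stat.index)
    inter = gene_set & universe
    if not inter:
        raise ValueError("gene set has no members in the ranked universe")
    rng = np.random.default_rng(seed)
    null = _null_es(rank_stat, {"_": inter}, weight_p, n_perm, perm_mode, rng, values, condition)["_"]
    es, leading = enrichment_score(rank_stat, inter, weight_p)
    p, nes = _sign_matched_p_nes(es, null)
    pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
    neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
    nn = np.where(null >= 0, null / pos_mean, null / neg_mean)
    nn = nn[np.isfinite(nn)]
    fdr = float(min(1.0, (nn >= nes).mean() / 1.0)) if nes >= 0 else float(min(1.0, (nn <= nes).mean()))
    return EnrichmentResult("set", es, nes, p, fdr, leading)


def ssgsea(values: pd.DataFrame, gene_set: set[str], alpha: float = 0.25) -> pd.Series:
    """Per-sample rank-weighted enrichment score.

    Within each sample, genes are ordered by decreasing expression (ties
    broken by gene order); the score is the sum over list positions of
    the difference between the weighted in-set ECDF (weights = expression
    rank ** alpha) and the uniform out-of-set ECDF.  Rank-based, hence
    invariant to sample-wise monotone transforms.
    """
    genes = list(values.index)
    inter = gene_set & set(genes)
    if not inter:
        raise ValueError("gene set fully absent from the matrix")
    hit_vec = np.array([g in inter for g in genes])
    N = len(genes)
    n_hit = int(hit_vec.sum())
    if n_hit == N:
        raise ValueError("gene set covers every gene; score undefined")
    X = values.to_numpy(dtype=float)
    scores = {}
    for j, sample in enumerate(values.columns):
        order = np.argsort(-X[:, j], kind="stable")
        hit = hit_vec[order]
        ranks = np.arange(N, 0, -1, dtype=float)  # top gene has rank N
        w = np.where(hit, ranks**alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~hit) / (N - n_hit)
        scores[sample] = float((p_in - p_out).sum())
    return pd.Series(scores, name="ssgsea")


def eigengene_score(values: pd.DataFrame, gene_set: set[str]) -> pd.Series:
    """First principal component of the standardised member sub-matrix.

    Scores are scaled to unit variance and the sign is anchored so the
    mean correlation with the member genes is non-negative — a one-number
    per-sample summary of coordinated set activity.
    """
    members = sorted(gene_set & set(values.index))
    if not members:
        raise ValueError("gene set has no members in the matrix")
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    sub = values.loc[members].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all member genes constant; eigengene undefined")
    Z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    # first right singular vector of the genes x samples standardized matrix
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    score = vt[0]
    ssd = score.std()
    if ssd > 0:
        score = score / ssd
    corr = (Z * score[None, :]).mean(axis=1)  # correlation, rows are z-scored
    if corr.mean() < 0:
        score = -score
    return pd.Series(score, index=values.columns, name="eigengene")


def cell_scores(values: pd.DataFrame, markers: GeneSetCollection) -> pd.DataFrame:
    """ssGSEA per marker set, z-standardised across samples per set."""
    rows = {}
    for name in markers.names():
        s = ssgsea(values, markers[name]).to_numpy()
        sd = s.std()
        rows[name] = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    out = pd.DataFrame(rows, index=values.columns).T
    out.index.name = "cell_type"
    return out


def enrichment_map(
    significant_sets: list[str],
    sets: GeneSetCollection,
    jaccard_min: float = 0.10,
    weights: dict[str, float] | None = None,
) -> nx.Graph:
    """Term graph: nodes = significant sets, edges where Jaccard > cutoff.

    The cutoff is strict (overlap must exceed ``jaccard_min``).
    """
    missing = [s for s in significant_sets if s not in sets.sets]
    if missing:
        raise ValueError(f"sets absent from collection: {missing}")
    g = nx.Graph()
    for name in significant_sets:
        g.add_node(name, size=len(sets[name]), weight=(weights or {}).get(name, np.nan))
    for i, a in enumerate(significant_sets):
        for b in significant_sets[i + 1:]:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            j = inter / union if union else 0.0
            if j > jaccard_min:
                g.add_edge(a, b, weight=j)
    return g
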