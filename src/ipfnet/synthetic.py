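"""Synthetic multi-batch compendia, interactomes, gene sets and drug tables.

The generator emulates the structure of an integrated case/control lung
transcriptome compendium after gene-level summarisation: a continuous
log2-scale abundance matrix assembled from several datasets (batches),
each contributing gene-specific additive offsets and multiplicative
noise-scale distortions; a planted set of up- and down-regulated genes;
two case subgroups, each over-expressing its own pathway; a "severity"
pathway whose per-patient activity drives simulated lung-function
covariates (FVC/DLCO percent-predicted) with a negative slope; and a
scale-free-like interactome with planted key-driver hubs whose
neighbourhoods are saturated with disease-module genes.

Everything planted is recorded in :class:`SyntheticTruth`, the recovery
target for the whole test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import DrugTargetMap, ExpressionCompendium, GeneSetCollection


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic study: everything the generator planted."""

    up_genes: dict[str, float] = field(default_factory=dict)
    down_genes: dict[str, float] = field(default_factory=dict)
    batch_offset: pd.DataFrame | None = None  # genes x batches additive
    batch_scale: pd.DataFrame | None = None   # genes x batches multiplicative (noise)
    subgroup_labels: pd.Series | None = None  # case samples -> C1|C2
    pathways: dict[str, set[str]] = field(default_factory=dict)
    severity_pathway: str | None = None
    severity_activity: pd.Series | None = None  # per-case planted activity
    fvc_slope: float = 0.0
    fvc_noise_sd: float = 0.0
    dlco_slope: float = 0.0
    dlco_noise_sd: float = 0.0
    expected_fvc_r: float | None = None   # realised corr(severity mean expr, FVC)
    expected_dlco_r: float | None = None
    drivers: list[str] = field(default_factory=list)
    module_genes: set[str] = field(default_factory=set)
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("planted up and down gene sets overlap")


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_compendium(
    n_batches: int = 3,
    cases_per_batch: int = 20,
    controls_per_batch: int = 20,
    n_genes: int = 1000,
    n_up: int = 60,
    n_down: int = 40,
    effect_log2fc: float = 1.0,
    batch_sd: float = 1.0,
    noise_sd: float = 0.5,
    subgroup_effect: float = 1.5,
    pathway_size: int = 40,
    severity_size: int = 30,
    severity_activity_sd: float = 1.0,
    fvc_slope: float = 5.0,
    fvc_noise_sd: float = 5.0,
    dlco_slope: float = 4.0,
    dlco_noise_sd: float = 6.0,
    seed: int = 0,
) -> tuple[ExpressionCompendium, SyntheticTruth]:
    """Simulate a multi-batch case/control compendium with known truth.

    Model per gene g, sample i in batch b::

        x_gi = mu_g + de_g * case_i + sub_g(i) + sev_g(i)
               + offset_gb + scale_gb * eps_gi

    with baseline ``mu_g ~ N(7, 1)`` (log2 scale), planted effects
    ``de_g = +/- effect_log2fc`` for up/down genes in cases,
    subgroup effects ``sub`` adding ``subgroup_effect`` to the subgroup's
    own pathway genes, a continuous severity activity ``a_i ~ N(0,
    severity_activity_sd)`` added to severity-pathway genes of case i,
    batch offsets ``offset_gb ~ N(0, batch_sd)`` and noise scales
    ``scale_gb ~ LogNormal(0, 0.1)`` multiplying ``eps ~ N(0, noise_sd)``.

    FVC/DLCO are linear in the per-case mean expression of the severity
    pathway with negative slope plus Gaussian noise; controls have no
    clinical covariates (as in real compendia, where lung function is
    recorded for patients only).
    """
    if min(n_batches, cases_per_batch, controls_per_batch, n_genes) < 1:
        raise ValueError("all counts must be >= 1")
    special = n_up + n_down + 2 * pathway_size + severity_size
    if special > n_genes:
        raise ValueError(
            f"gene budget infeasible: {special} planted genes > {n_genes} total"
        )
    rng = np.random.default_rng(seed)
    genes = gene_names(n_genes)

    chosen = rng.choice(n_genes, size=special, replace=False)
    pos = 0

    def take(k: int) -> list[str]:
        nonlocal pos
        sel = [genes[i] for i in chosen[pos:pos + k]]
        pos += k
        return sel

    up = take(n_up)
    down = take(n_down)
    path_c1 = set(take(pathway_size))
    path_c2 = set(take(pathway_size))
    sev = set(take(severity_size))

    batches = [f"B{b + 1}" for b in range(n_batches)]
    sample_rows = []
    for b in batches:
        for i in range(cases_per_batch):
            sample_rows.append((f"{b}_case_{i + 1:03d}", b, "case"))
        for i in range(controls_per_batch):
            sample_rows.append((f"{b}_ctrl_{i + 1:03d}", b, "control"))
    samples = [r[0] for r in sample_rows]
    meta = pd.DataFrame(
        {"batch": [r[1] for r in sample_rows], "condition": [r[2] for r in sample_rows]},
        index=pd.Index(samples, name="sample"),
    )
    is_case = (meta["condition"] == "case").to_numpy()

    # alternate subgroup assignment within each batch so batches stay balanced
    subgroup = {}
    for b in batches:
        cases_b = [s for s, bb, c in sample_rows if bb == b and c == "case"]
        for j, s in enumerate(cases_b):
            subgroup[s] = "C1" if j % 2 == 0 else "C2"
    sub_series = pd.Series(subgroup, name="subgroup")
    meta["subgroup"] = sub_series.reindex(meta.index)

    n_samples = len(samples)
    mu = rng.normal(7.0, 1.0, size=n_genes)
    signal = np.tile(mu[:, None], (1, n_samples))

    gidx = {g: i for i, g in enumerate(genes)}
    de = np.zeros(n_genes)
    for g in up:
        de[gidx[g]] = effect_log2fc
    for g in down:
        de[gidx[g]] = -effect_log2fc
    signal += np.outer(de, is_case.astype(float))

    if subgroup_effect != 0 and pathway_size > 0:
        for pset, label in ((path_c1, "C1"), (path_c2, "C2")):
            mask = (meta["subgroup"] == label).to_numpy()
            rows = [gidx[g] for g in pset]
            signal[np.ix_(rows, np.nonzero(mask)[0])] += subgroup_effect

    activity = pd.Series(0.0, index=[s for s in samples if meta.loc[s, "condition"] == "case"])
    if severity_size > 0 and severity_activity_sd > 0:
        act = rng.normal(0.0, severity_activity_sd, size=int(is_case.sum()))
        activity = pd.Series(act, index=activity.index)
        rows = [gidx[g] for g in sev]
        cols = np.nonzero(is_case)[0]
        signal[np.ix_(rows, cols)] += act[None, :]

    offset = rng.normal(0.0, batch_sd, size=(n_genes, n_batches))
    scale = np.exp(rng.normal(0.0, 0.1, size=(n_genes, n_batches)))
    eps = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    values = signal.copy()
    for bi, b in enumerate(batches):
        cols = np.nonzero((meta["batch"] == b).to_numpy())[0]
        values[:, cols] += offset[:, [bi]] + scale[:, [bi]] * eps[:, cols]

    # clinical covariates: linear in severity-pathway mean signal, negative slope
    fvc = pd.Series(np.nan, index=meta.index)
    dlco = pd.Series(np.nan, index=meta.index)
    exp_fvc_r = exp_dlco_r = None
    if severity_size > 0:
        rows = [gidx[g] for g in sev]
        cols = np.nonzero(is_case)[0]
        sev_mean = signal[np.ix_(rows, cols)].mean(axis=0)
        centred = sev_mean - sev_mean.mean()
        f = 80.0 - fvc_slope * centred + rng.normal(0.0, fvc_noise_sd, size=len(cols))
        d = 70.0 - dlco_slope * centred + rng.normal(0.0, dlco_noise_sd, size=len(cols))
        case_ids = [samples[c] for c in cols]
        fvc.loc[case_ids] = f
        dlco.loc[case_ids] = d
        if len(cols) >= 3 and np.std(sev_mean) > 0:
            exp_fvc_r = float(np.corrcoef(sev_mean, f)[0, 1])
            exp_dlco_r = float(np.corrcoef(sev_mean, d)[0, 1])
    meta["fvc"] = fvc
    meta["dlco"] = dlco

    comp = ExpressionCompendium(pd.DataFrame(values, index=genes, columns=samples), meta)
    pathways = {}
    if pathway_size > 0:
        pathways["pathway_C1"] = path_c1
        pathways["pathway_C2"] = path_c2
    if severity_size > 0:
        pathways["severity_pathway"] = sev
    truth = SyntheticTruth(
        up_genes={g: effect_log2fc for g in up},
        down_genes={g: -effect_log2fc for g in down},
        batch_offset=pd.DataFrame(offset, index=genes, columns=batches),
        batch_scale=pd.DataFrame(scale, index=genes, columns=batches),
        subgroup_labels=sub_series,
        pathways=pathways,
        severity_pathway="severity_pathway" if severity_size > 0 else None,
        severity_activity=activity if severity_size > 0 else None,
        fvc_slope=-fvc_slope,
        fvc_noise_sd=fvc_noise_sd,
        dlco_slope=-dlco_slope,
        dlco_noise_sd=dlco_noise_sd,
        expected_fvc_r=exp_fvc_r,
        expected_dlco_r=exp_dlco_r,
        params=dict(
            n_batches=n_batches, cases_per_batch=cases_per_batch,
            controls_per_batch=controls_per_batch, n_genes=n_genes, n_up=n_up,
            n_down=n_down, effect_log2fc=effect_log2fc, batch_sd=batch_sd,
            noise_sd=noise_sd, subgroup_effect=subgroup_effect,
            pathway_size=pathway_size, severity_size=severity_size, seed=seed,
        ),
    )
    truth.validate()
    return comp, truth


def generate_interactome(
    n_nodes: int = 500,
    attach_edges: int = 2,
    n_drivers: int = 5,
    module_genes: set[str] | None = None,
    driver_degree: int = 20,
    seed: int = 0,
    genes: list[str] | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free-like interactome with planted key-driver hubs.

    A Barabási–Albert preferential-attachment graph over ``genes`` (default
    the compendium naming scheme) is grown; then ``n_drivers`` low-degree
    non-module nodes are promoted to drivers by wiring them to
    module genes until their degree reaches ``driver_degree``, so that at
    least 80% (by construction ~90%) of each driver's neighbours are
    module members.
    """
    if genes is None:
        genes = gene_names(n_nodes)
    if len(genes) != n_nodes:
        raise ValueError("genes list length must equal n_nodes")
    if driver_degree > n_nodes - 1:
        raise ValueError("driver_degree exceeds n_nodes - 1")
    module_genes = set(module_genes or set())
    if not module_genes <= set(genes):
        raise ValueError("module_genes not a subset of the node label space")
    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n_nodes, attach_edges, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, dict(enumerate(genes)))

    drivers: list[str] = []
    if n_drivers > 0:
        max_pre = driver_degree // 5  # existing degree <= 20% of final degree
        candidates = sorted(
            (n for n in graph.nodes if n not in module_genes and graph.degree(n) <= max_pre),
            key=lambda n: (graph.degree(n), n),
        )
        if len(candidates) < n_drivers:
            raise ValueError("not enough low-degree non-module nodes to plant drivers")
        drivers = candidates[:n_drivers]
        for drv in drivers:
            need = driver_degree - graph.degree(drv)
            avail = sorted(module_genes - set(graph.neighbors(drv)) - {drv})
            if len(avail) < need:
                raise ValueError(
                    f"module too small to supply driver neighbourhood ({len(avail)} < {need})"
                )
            for tgt in rng.choice(avail, size=need, replace=False):
                graph.add_edge(drv, str(tgt))

    if truth is None:
        truth = SyntheticTruth()
    truth.drivers = list(drivers)
    truth.module_genes = module_genes
    truth.params.update(dict(
        n_nodes=n_nodes, attach_edges=attach_edges, n_drivers=n_drivers,
        driver_degree=driver_degree, interactome_seed=seed,
    ))
    return graph, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    n_decoy_sets: int = 20,
    decoy_size: int = 40,
    seed: int = 0,
) -> GeneSetCollection:
    """Planted pathways plus random decoy sets (``decoy_`` prefix)."""
    if not truth.pathways:
        raise ValueError("truth carries no pathway definitions")
    n_genes = truth.params.get("n_genes")
    if n_genes is None:
        raise ValueError("truth lacks generator parameters")
    genes = gene_names(n_genes)
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {k: set(v) for k, v in truth.pathways.items()}
    cats = {k: "pathway" for k in sets}
    width = max(2, len(str(max(n_decoy_sets, 1))))
    for i in range(n_decoy_sets):
        name = f"decoy_{i + 1:0{width}d}"
        sets[name] = set(rng.choice(genes, size=decoy_size, replace=False).tolist())
        cats[name] = "pathway"
    return GeneSetCollection(sets, cats)


def generate_drug_targets(
    truth: SyntheticTruth,
    graph: nx.Graph,
    n_driver_drugs: int = 2,
    n_decoy_drugs: int = 5,
    targets_per_drug: int = 3,
    seed: int = 0,
) -> DrugTargetMap:
    """Drugs aimed at planted drivers vs drugs with random network targets."""
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    targets: dict[str, list[str]] = {}
    drivers = list(truth.drivers)
    for i in range(n_driver_drugs):
        if not drivers:
            break
        k = min(targets_per_drug, len(drivers))
        tg = rng.choice(drivers, size=k, replace=False).tolist()
        targets[f"drug_driver_{i + 1:02d}"] = [str(t) for t in tg]
    non_driver = [n for n in nodes if n not in set(drivers)]
    for i in range(n_decoy_drugs):
        tg = rng.choice(non_driver, size=targets_per_drug, replace=False).tolist()
        targets[f"drug_decoy_{i + 1:02d}"] = [str(t) for t in tg]
    return DrugTargetMap(targets)
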