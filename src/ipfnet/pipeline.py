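"""Pipeline orchestration: configuration, staging, provenance, determinism.

``run_pipeline`` executes preprocess -> deg -> genesets -> network ->
subtyping -> keydriver -> diffusion in order.  Every stage writes a TSV
result (rows sorted by gene/set/sample name so reruns are diffable) and
a JSON provenance record (parameters, derived seed, input hashes).  One
global seed drives every stochastic stage through a named substream, so
rerunning with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deg as deg_mod
from . import diffusion as diff_mod
from . import genesets as gs_mod
from . import keydriver as kd_mod
from . import network as net_mod
from . import preprocess as pp_mod
from . import subtyping as st_mod
from .io import (
    ExpressionCompendium,
    read_drug_targets,
    read_edge_list,
    read_expression,
    read_gmt,
)

logger = logging.getLogger("ipfnet")

FLOAT_FORMAT = "%.6g"

_STAGE_PARAM_KEYS = {
    "preprocess": {"quantile", "combat"},
    "deg": {"adj_p_max", "fdr_max", "fc_min", "n_perm"},
    "genesets": {"n_perm", "weight_p", "alpha", "jaccard_min", "gsea_fdr_max", "ora_alpha"},
    "network": {"top_frac"},
    "subtyping": {"k_max", "features"},
    "keydriver": {"depth", "n_perm", "fdr_max", "min_neighborhood"},
    "diffusion": {"n_perm", "kernel"},
}

_STAGE_DEFAULTS = {
    "preprocess": {"quantile": True, "combat": True},
    "deg": {"adj_p_max": 0.01, "fdr_max": 0.01, "fc_min": 1.5, "n_perm": 1000},
    "genesets": {"n_perm": 1000, "weight_p": 1.0, "alpha": 0.25, "jaccard_min": 0.10,
                 "gsea_fdr_max": 0.25, "ora_alpha": 0.05},
    "network": {"top_frac": 0.10},
    "subtyping": {"k_max": 6, "features": "up-degs"},
    "keydriver": {"depth": 1, "n_perm": 10000, "fdr_max": 0.01, "min_neighborhood": 3},
    "diffusion": {"n_perm": 1000, "kernel": "reg-laplacian"},
}


@dataclass
class RunConfig:
    """All inputs, stage parameters and the global seed of one run."""

    expression: str
    metadata: str
    gmt: str
    interactome: str
    outdir: str
    drugs: str | None = None
    seed: int = 0
    stages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {}
        for stage, defaults in _STAGE_DEFAULTS.items():
            given = dict(self.stages.get(stage, {}))
            unknown = set(given) - _STAGE_PARAM_KEYS[stage]
            if unknown:
                raise ValueError(f"unknown parameter(s) for stage '{stage}': {sorted(unknown)}")
            merged[stage] = {**defaults, **given}
        unknown_stages = set(self.stages) - set(_STAGE_DEFAULTS)
        if unknown_stages:
            raise ValueError(f"unknown stage(s) in config: {sorted(unknown_stages)}")
        self.stages = merged

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    return len(df)


def _provenance(outdir: Path, stage: str, params: dict, seed: int,
                input_hashes: dict, n_rows: int) -> None:
    rec = {
        "stage": stage,
        "parameters": params,
        "seed": seed,
        "input_hashes": input_hashes,
        "n_rows_out": n_rows,
    }
    with open(outdir / f"{stage}.provenance.json", "w") as fh:
        json.dump(rec, fh, sort_keys=True, indent=1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of key in-memory results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashes = {"expression": _hash_file(config.expression),
              "metadata": _hash_file(config.metadata),
              "gmt": _hash_file(config.gmt),
              "interactome": _hash_file(config.interactome)}
    if config.drugs:
        hashes["drugs"] = _hash_file(config.drugs)

    results: dict = {}
    stage = "preprocess"
    try:
        comp = read_expression(config.expression, config.metadata)
        sets = read_gmt(config.gmt)
        interactome = read_edge_list(config.interactome)
        drugs = read_drug_targets(config.drugs) if config.drugs else None

        p = config.stages[stage]
        values = comp.values
        pca_before = pp_mod.pca_qc(values, comp.batch)
        if p["quantile"]:
            values = pp_mod.quantile_normalize(values)
        if p["combat"]:
            values = pp_mod.combat_adjust(values, comp.batch, comp.condition)
        pca_after = pp_mod.pca_qc(values, comp.batch)
        adjusted = ExpressionCompendium(values.sort_index(), comp.sample_meta)
        n = _write_tsv(adjusted.values, outdir / "adjusted_expression.tsv")
        qc = pd.DataFrame(
            {
                "batch_separation": [pca_before.batch_separation, pca_after.batch_separation],
                "pc1_var_frac": [pca_before.variance_fraction[0], pca_after.variance_fraction[0]],
                "pc2_var_frac": [pca_before.variance_fraction[1], pca_after.variance_fraction[1]],
            },
            index=pd.Index(["before", "after"], name="stage"),
        )
        _write_tsv(qc, outdir / "pca_qc.tsv")
        _provenance(outdir, stage, p, config.seed, hashes, n)
        logger.info("stage preprocess: %d genes, %d samples, batch separation %.3f -> %.3f",
                    *adjusted.values.shape, pca_before.batch_separation, pca_after.batch_separation)
        results["compendium"] = adjusted

        stage = "deg"
        p = config.stages[stage]
        sseed = config.stage_seed(stage)
        mt = deg_mod.moderated_t(adjusted.values, adjusted.condition)
        sam = deg_mod.sam_statistic(adjusted.values, adjusted.condition,
                                    n_perm=p["n_perm"], seed=sseed, batch=adjusted.batch)
        ac = deg_mod.artificial_components(adjusted.values, adjusted.condition,
                                           n_perm=p["n_perm"], seed=sseed + 1,
                                           batch=adjusted.batch)
        table = deg_mod.consensus_degs(mt, sam, ac, adj_p_max=p["adj_p_max"],
                                       fdr_max=p["fdr_max"], fc_min=p["fc_min"])
        table = table.sort_index()
        n = _write_tsv(table, outdir / "deg_table.tsv")
        _provenance(outdir, stage, p, sseed, hashes, n)
        up_genes = set(table.index[table["consensus_up"]])
        logger.info("stage deg: %d consensus up, %d consensus down",
                    len(up_genes), int(table["consensus_down"].sum()))
        results["deg_table"] = table

        stage = "genesets"
        p = config.stages[stage]
        sseed = config.stage_seed(stage)
        universe = set(adjusted.genes)
        ora = gs_mod.ora_test(up_genes or universe, sets, universe, alpha=p["ora_alpha"]) \
            if up_genes else None
        rank = gs_mod.signal_to_noise(adjusted.values, adjusted.condition)
        n_per_group = min(len(adjusted.case_samples()), len(adjusted.control_samples()))
        perm_mode = "phenotype" if n_per_group >= 7 else "gene"
        gsea_df = gs_mod.gsea_collection(
            rank, sets, weight_p=p["weight_p"], n_perm=p["n_perm"], perm_mode=perm_mode,
            seed=sseed, values=adjusted.values, condition=adjusted.condition,
            fdr_max=p["gsea_fdr_max"],
        ).sort_index()
        ss_rows = {name: gs_mod.ssgsea(adjusted.values, sets[name], alpha=p["alpha"])
                   for name in sets.names() if sets[name] & universe}
        ss = pd.DataFrame(ss_rows).T.sort_index()
        ss.index.name = "set"
        eig_rows = {name: gs_mod.eigengene_score(adjusted.values, sets[name])
                    for name in sets.names() if sets[name] & universe}
        eig = pd.DataFrame(eig_rows).T.sort_index()
        eig.index.name = "set"
        if ora is not None:
            ora = ora.sort_index()
            _write_tsv(ora, outdir / "genesets_ora.tsv")
            sig = sorted(ora.index[ora["significant"]])
        else:
            sig = sorted(gsea_df.index[gsea_df["significant"]])
        emap = gs_mod.enrichment_map(sig, sets, jaccard_min=p["jaccard_min"])
        edges = pd.DataFrame(
            sorted((min(a, b), max(a, b), d["weight"]) for a, b, d in emap.edges(data=True)),
            columns=["set_a", "set_b", "jaccard"],
        ).set_index("set_a") if emap.number_of_edges() else \
            pd.DataFrame(columns=["set_a", "set_b", "jaccard"]).set_index("set_a")
        n = _write_tsv(gsea_df, outdir / "genesets_gsea.tsv")
        _write_tsv(ss, outdir / "sample_scores_ssgsea.tsv")
        _write_tsv(eig, outdir / "sample_scores_eigengene.tsv")
        _write_tsv(edges, outdir / "enrichment_map.tsv")
        _provenance(outdir, stage, {**p, "perm_mode": perm_mode}, sseed, hashes, n)
        results["gsea"] = gsea_df
        results["ora"] = ora
        results["eigengene"] = eig

        stage = "network"
        p = config.stages[stage]
        module_graph = net_mod.project_module(up_genes, interactome) if (
            up_genes and any(g in interactome for g in up_genes)) else None
        if module_graph is not None and module_graph.number_of_nodes() >= 2:
            lcc = net_mod.largest_connected_component(module_graph)
            cent = net_mod.centralities(lcc) if lcc.number_of_nodes() >= 2 else None
        else:
            lcc, cent = None, None
        if cent is not None:
            hubs = sorted(net_mod.hub_genes(cent, top_frac=p["top_frac"]))
            edges = pd.DataFrame(
                sorted((min(a, b), max(a, b)) for a, b in lcc.edges),
                columns=["gene_a", "gene_b"],
            ).set_index("gene_a")
            _write_tsv(edges, outdir / "module_edges.tsv")
            n = _write_tsv(cent.sort_index(), outdir / "centrality.tsv")
            hub_df = pd.DataFrame({"gene": hubs}).set_index("gene")
            _write_tsv(hub_df, outdir / "hubs.tsv")
        else:
            n = 0
            logger.info("stage network: no usable disease module; skipping centralities")
        _provenance(outdir, stage, p, config.seed, hashes, n)
        results["lcc"] = lcc
        results["centrality"] = cent

        stage = "subtyping"
        p = config.stages[stage]
        cases = adjusted.case_samples()
        feats = up_genes if p["features"] == "up-degs" else (
            up_genes | set(table.index[table["consensus_down"]]))
        feats = sorted(feats)
        labels = None
        if len(feats) >= 2 and len(cases) > p["k_max"]:
            case_values = adjusted.values.loc[feats, cases]
            tree = st_mod.ward_cluster(case_values)
            cres = st_mod.choose_k(tree, case_values, k_max=p["k_max"])
            labels = cres.labels
            model_sel = pd.DataFrame(
                {"silhouette": cres.silhouette.reindex(cres.sse.index), "sse": cres.sse}
            )
            model_sel.index.name = "k"
            _write_tsv(model_sel, outdir / "model_selection.tsv")
            lab_df = labels.sort_index().to_frame()
            lab_df.index.name = "sample"
            n = _write_tsv(lab_df, outdir / "cluster_labels.tsv")
            # clinical comparisons between the two largest clusters
            comp_rows = []
            if cres.chosen_k >= 2:
                top2 = sorted(cres.sizes, key=cres.sizes.get, reverse=True)[:2]
                sub = labels[labels.isin(top2)]
                for cov in ("fvc", "dlco"):
                    if cov in adjusted.sample_meta:
                        vals = adjusted.sample_meta.loc[sub.index, cov]
                        ok = vals.notna()
                        if ok.sum() >= 4 and sub[ok].nunique() == 2 and \
                                min(sub[ok].value_counts()) >= 2:
                            t, pv = st_mod.compare_groups(vals[ok], sub[ok])
                            comp_rows.append((cov, t, pv))
            comp_df = pd.DataFrame(comp_rows, columns=["covariate", "t", "p"])
            _write_tsv(comp_df.set_index("covariate"), outdir / "cluster_clinical.tsv")
            cov_cols = [c for c in ("fvc", "dlco") if c in adjusted.sample_meta]
            if cov_cols and len(eig):
                corr = st_mod.clinical_correlation(
                    eig[cases], adjusted.sample_meta.loc[cases, cov_cols])
                _write_tsv(corr.set_index("score"), outdir / "clinical_correlation.tsv")
                results["clinical_correlation"] = corr
            results["cluster"] = cres
        else:
            n = 0
            logger.info("stage subtyping: not enough features or cases; skipped")
        _provenance(outdir, stage, p, config.seed, hashes, n)

        stage = "keydriver"
        p = config.stages[stage]
        sseed = config.stage_seed(stage)
        if module_graph is not None:
            kd = kd_mod.key_driver_analysis(
                interactome, set(module_graph.nodes), depth=p["depth"], n_perm=p["n_perm"],
                fdr_max=p["fdr_max"], seed=sseed,
                min_neighborhood=p["min_neighborhood"], deg_genes=up_genes)
            n = _write_tsv(kd.sort_index(), outdir / "keydriver.tsv")
            results["keydriver"] = kd
        else:
            n = 0
        _provenance(outdir, stage, p, sseed, hashes, n)

        stage = "diffusion"
        p = config.stages[stage]
        sseed = config.stage_seed(stage)
        if module_graph is not None:
            inter_lcc = net_mod.largest_connected_component(interactome)
            seeds_set = set(module_graph.nodes) & set(inter_lcc.nodes)
            dres = diff_mod.z_diffusion(inter_lcc, seeds_set, n_perm=p["n_perm"],
                                        seed=sseed, kernel_kind=p["kernel"])
            n = _write_tsv(dres.scores.sort_index(), outdir / "diffusion.tsv")
            results["diffusion"] = dres
            if drugs is not None:
                dt = diff_mod.drug_target_scores(dres, drugs)
                _write_tsv(dt.sort_index(), outdir / "drug_scores.tsv")
                results["drug_scores"] = dt
        else:
            n = 0
        _provenance(outdir, stage, p, sseed, hashes, n)
    except Exception as exc:  # noqa: BLE001 - annotate with failing stage
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return results
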