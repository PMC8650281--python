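"""Readers and writers for the external formats the pipeline consumes.

Expression matrices are genes-in-rows / samples-in-columns TSV; gene
symbols are case-sensitive and matched exactly across the matrix, GMT
collections and the interactome (no alias resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("ipfnet")

EXPR_FLOAT_FORMAT = "%.6g"


@dataclass
class ExpressionCompendium:
    """A gene x sample log2 expression matrix with per-sample metadata.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns; ``sample_meta`` is indexed by sample id and carries at least
    ``batch`` and ``condition`` (case|control) columns, optionally
    ``subgroup``, ``fvc`` and ``dlco`` (percent-predicted lung function).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing}")
        for col in ("batch", "condition"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks required column '{col}'")
        # align metadata rows to matrix column order
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def condition(self) -> pd.Series:
        return self.sample_meta["condition"]

    @property
    def batch(self) -> pd.Series:
        return self.sample_meta["batch"]

    def case_samples(self) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["condition"] == "case"])

    def control_samples(self) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["condition"] == "control"])


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional category tag per set."""

    sets: dict[str, set[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set '{name}' is empty")
            if any(not isinstance(g, str) or g == "" for g in members):
                raise ValueError(f"gene set '{name}' has empty member symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, category: str) -> "GeneSetCollection":
        keep = {n: s for n, s in self.sets.items() if self.categories.get(n) == category}
        return GeneSetCollection(keep, {n: category for n in keep})


@dataclass
class DrugTargetMap:
    """Drug name -> non-empty list of target gene symbols."""

    targets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for drug, tg in self.targets.items():
            if not tg:
                raise ValueError(f"drug '{drug}' has no targets")


def read_expression(path: str, meta_path: str) -> ExpressionCompendium:
    """Read an expression TSV (genes x samples) plus sample-metadata TSV.

    The matrix header row holds sample ids and the first column gene
    symbols.  The metadata file is keyed by sample id and must provide
    ``batch`` and ``condition`` columns; ``fvc``/``dlco`` are optional.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbol(s) in {path}: {dup}")
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = coerced.isna() & values[col].notna()
            if bad.any():
                row = values.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(f"non-numeric cell in {path} at gene '{row}', sample '{col}'")
            values[col] = coerced
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"sample(s) in matrix absent from metadata: {missing}")
    return ExpressionCompendium(values, meta.loc[list(values.columns)])


def write_expression(comp: ExpressionCompendium, path: str, meta_path: str | None = None) -> None:
    """Write matrix (and optionally metadata) in canonical TSV form."""
    comp.values.to_csv(path, sep="\t", float_format=EXPR_FLOAT_FORMAT, index_label="gene")
    if meta_path is not None:
        comp.sample_meta.to_csv(meta_path, sep="\t", float_format=EXPR_FLOAT_FORMAT, index_label="sample")


def read_gmt(path: str, category: str | None = None) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name '{name}'")
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set '{name}' has no members")
            sets[name] = members
    cats = {n: category for n in sets} if category else {}
    return GeneSetCollection(sets, cats)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = sorted(collection[name])
            desc = collection.categories.get(name, "na")
            fh.write("\t".join([name, str(desc)] + members) + "\n")


def read_edge_list(path: str) -> nx.Graph:
    """Read a two-column TSV or three-column SIF edge list.

    Returns an undirected simple graph; self-loops are dropped (count
    logged) and duplicate edges collapsed.
    """
    graph: nx.Graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.replace("\t", " ").split()
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:  # SIF: node relation node
                a, _, b = fields
            else:
                raise ValueError(f"{path}:{lineno}: malformed edge line ({len(fields)} fields)")
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
    if n_self:
        logger.info("read_edge_list: dropped %d self-loop(s) from %s", n_self, path)
    return graph


def write_edge_list(graph: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_drug_targets(path: str) -> DrugTargetMap:
    """Read a drug-target TSV: drug name, tab, comma-separated targets."""
    targets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'drug<TAB>t1,t2,...'")
            drug, tg = fields
            if drug in targets:
                raise ValueError(f"{path}:{lineno}: duplicate drug '{drug}'")
            members = [t for t in tg.split(",") if t]
            if not members:
                raise ValueError(f"{path}:{lineno}: drug '{drug}' has no targets")
            targets[drug] = members
    return DrugTargetMap(targets)


def write_drug_targets(drugs: DrugTargetMap, path: str) -> None:
    with open(path, "w") as fh:
        for drug in sorted(drugs.targets):
            fh.write(f"{drug}\t{','.join(drugs.targets[drug])}\n")
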