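"""Readers and writers for the standard input formats.

Formats covered: GMT gene-set collections, STRING-style weighted edge
lists, wide expression / copy-number matrices (cells x genes), long-form
mutation tables, drug response tables and drug -> SMILES / target tables.
Tables are UTF-8, tab- or comma-delimited (delimiter sniffed from the
header line); gene symbols are case-preserved and matched exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "OmicsBundle",
    "DrugTable",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_omics",
    "read_response",
    "write_response",
    "read_smiles",
    "write_smiles",
    "read_target_table",
    "write_target_table",
    "write_wide_matrix",
    "read_wide_matrix",
    "write_mutations",
]

GISTIC_LEVELS = frozenset({-2, -1, 0, 1, 2})


class ParseError(ValueError):
    """Raised when an input file violates its format grammar."""


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the 196 PID cancer-signaling pathways).

    ``sets`` maps pathway name to an ordered, duplicate-free list of gene
    symbols; ``descriptions`` carries the free-text second GMT column.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class OmicsBundle:
    """Cell-line omics: log-TPM expression, mutations and GISTIC CNV.

    ``expression``: cells x genes real matrix (missing values imputed with
    the per-gene mean). ``mutations``: set of (cell, gene) pairs.
    ``cnv``: cells x genes integer matrix restricted to GISTIC levels
    -2 (deletion), -1 (loss), 0 (diploid), 1 (gain), 2 (amplification).
    """

    expression: pd.DataFrame
    mutations: frozenset[tuple[str, str]]
    cnv: pd.DataFrame


@dataclass
class DrugTable:
    """Per-drug SMILES plus primary and off-target gene sets."""

    smiles: dict[str, str]
    primary_targets: dict[str, set[str]] = field(default_factory=dict)
    off_targets: dict[str, set[str]] = field(default_factory=dict)

    def drugs_without_smiles(self) -> list[str]:
        return [d for d, s in self.smiles.items() if not s]


# ---------------------------------------------------------------------------
# delimiter sniffing

def _sniff_sep(path: str | Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sniff_sep(path), **kwargs)


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated line per set, ``name TAB
    description TAB gene1 TAB gene2 ...``.

    Duplicate genes within a line are removed preserving first occurrence.
    Lines with fewer than three fields raise :class:`ParseError` naming the
    line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# PPI edge list

def read_edge_list(path: str | Path, score_threshold: float = 700.0) -> nx.Graph:
    """Read a STRING-style weighted edge list into an undirected graph.

    Columns: gene_a, gene_b, combined_score (0-1000). Edges with score
    below ``score_threshold`` are discarded; surviving scores are rescaled
    by 1/1000 into (0, 1] and stored as the ``weight`` attribute.
    Self-loops are dropped; reversed duplicates are merged keeping the
    maximum weight.
    """
    sep = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" in first:
        sep = "\t"
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", header=None,
                     names=["gene_a", "gene_b", "score"], dtype=str, comment="#")
    # a header row is tolerated: drop it if the score column is non-numeric there
    scores = pd.to_numeric(df["score"], errors="coerce")
    if np.isnan(scores.iloc[0]) and len(df) > 1:
        df = df.iloc[1:]
        scores = scores.iloc[1:]
    if scores.isna().any():
        bad = df.loc[scores.isna()].index[0]
        raise ParseError(f"{path}: non-numeric combined score at row {bad}")
    graph = nx.Graph()
    for a, b, s in zip(df["gene_a"], df["gene_b"], scores):
        if a == b:
            graph.add_node(a)
            continue
        if s < score_threshold:
            continue
        w = float(s) / 1000.0
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = max(graph[a][b]["weight"], w)
        else:
            graph.add_edge(a, b, weight=w)
    if graph.number_of_edges() == 0:
        raise ValueError(
            f"{path}: no edges survive score_threshold={score_threshold}"
        )
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph back to the three-column STRING dialect (score 0-1000)."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, data in graph.edges(data=True):
            fh.write(f"{a}\t{b}\t{data['weight'] * 1000:.6g}\n")


# ---------------------------------------------------------------------------
# omics

def read_omics(
    expression_path: str | Path,
    mutation_path: str | Path,
    cnv_path: str | Path,
) -> OmicsBundle:
    """Load the three cell-line omics tables into one bundle.

    Expression is a wide cells x genes table; missing entries are imputed
    with the per-gene mean across cells (a gene that is entirely missing is
    an error, the mean being undefined). Mutations are long-form
    (cell, gene) rows, deduplicated. CNV entries must be GISTIC levels.
    """
    expression = _read_table(expression_path, index_col=0)
    expression = expression.astype(float)
    all_missing = expression.columns[expression.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"expression genes with no observed values (mean undefined): "
            f"{list(all_missing)}"
        )
    n_imputed = int(expression.isna().to_numpy().sum())
    if n_imputed:
        expression = expression.fillna(expression.mean(axis=0))
        logger.info("imputed %d missing expression values with per-gene means", n_imputed)

    mut = _read_table(mutation_path, dtype=str)
    cell_col, gene_col = mut.columns[:2]
    mutations = frozenset(zip(mut[cell_col], mut[gene_col]))

    cnv = _read_table(cnv_path, index_col=0)
    arr = cnv.to_numpy()
    if not np.all(np.isin(arr, list(GISTIC_LEVELS))):
        bad = sorted(set(arr.ravel()) - GISTIC_LEVELS)
        raise ValueError(f"CNV values outside GISTIC levels -2..2: {bad}")
    cnv = cnv.astype(int)
    return OmicsBundle(expression=expression, mutations=mutations, cnv=cnv)


# ---------------------------------------------------------------------------
# drug response

def read_response(path: str | Path) -> pd.DataFrame:
    """Read a (drug, cell, response) table of log-transformed IC50 values.

    Duplicate (drug, cell) rows are collapsed by their mean. The sign
    convention of the response column (ln IC50 vs -ln IC50) is taken as
    given; the model predicts whatever scale it is trained on.
    """
    df = _read_table(path)
    df.columns = ["drug", "cell", "response"] + list(df.columns[3:])
    resp = pd.to_numeric(df["response"], errors="coerce")
    if resp.isna().any():
        bad = df.loc[resp.isna()].iloc[0]
        raise ParseError(
            f"{path}: non-numeric response for ({bad['drug']}, {bad['cell']})"
        )
    df["response"] = resp
    out = (
        df.groupby(["drug", "cell"], sort=False, as_index=False)["response"].mean()
    )
    return out


def write_response(table: pd.DataFrame, path: str | Path) -> None:
    table[["drug", "cell", "response"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# drug tables

def read_smiles(path: str | Path) -> dict[str, str]:
    """Read a two-column (drug, smiles) table; empty SMILES are kept and
    flagged downstream."""
    df = _read_table(path, dtype=str).fillna("")
    drug_col, smiles_col = df.columns[:2]
    return dict(zip(df[drug_col], df[smiles_col]))


def write_smiles(smiles: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"drug": list(smiles), "smiles": list(smiles.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_target_table(path: str | Path) -> dict[str, set[str]]:
    """Read a long (drug, gene) table into drug -> gene-set form."""
    df = _read_table(path, dtype=str)
    drug_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for drug, gene in zip(df[drug_col], df[gene_col]):
        out.setdefault(drug, set()).add(gene)
    return out


def write_target_table(targets: dict[str, set[str]], path: str | Path) -> None:
    rows = [(d, g) for d, genes in targets.items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["drug", "gene"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic wide matrices and mutation long form

def write_wide_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="id")


def read_wide_matrix(path: str | Path) -> pd.DataFrame:
    return _read_table(path, index_col=0)


def write_mutations(mutations: frozenset[tuple[str, str]], path: str | Path) -> None:
    rows = sorted(mutations)
    pd.DataFrame(rows, columns=["cell", "gene"]).to_csv(path, sep="\t", index=False)
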