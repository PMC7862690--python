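"""End-to-end featurization: raw inputs -> five-block design matrix.

Glues the individual featurizers together the way the full method runs:
CHEM from SMILES, DG-Net from expanded drug targets (plain NetPEA), EXP
from ssGSEA of expression, MUT-Net and CNV-Net from expression-weighted
NetPEA of the mutation / non-diploid CNV gene sets.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .chem import fingerprint_table
from .enrichment import netpea_enrich
from .features import FeatureMatrix, assemble, cnv_gene_sets
from .io import DrugTable, GeneSetCollection, OmicsBundle
from .ssgsea import ssgsea_matrix
from .targets import expand_targets

__all__ = ["build_features"]


def build_features(
    gene_sets: GeneSetCollection,
    network: nx.Graph,
    omics: OmicsBundle,
    drugs: DrugTable,
    responses: pd.DataFrame,
    n_perm: int = 1000,
    rng_seed: int | None = None,
    alpha: float = 0.25,
    restart_prob: float = 0.7,
    fp_radius: int = 2,
    fp_bits: int = 256,
    subset: list[str] | None = None,
) -> FeatureMatrix:
    """Compute all five feature blocks and join them with the responses.

    ``subset`` restricts the assembled blocks (for data-type ablations)
    without skipping their computation dependencies: only the blocks
    actually needed are computed.
    """
    wanted = set(subset) if subset is not None else {"CHEM", "DG-Net", "EXP",
                                                     "MUT-Net", "CNV-Net"}
    blocks = []
    if "CHEM" in wanted:
        blocks.append(fingerprint_table(drugs.smiles, radius=fp_radius, n_bits=fp_bits))
    if "DG-Net" in wanted:
        expanded = expand_targets(drugs.primary_targets, drugs.off_targets, network)
        blocks.append(netpea_enrich(
            network, expanded.sets, gene_sets, n_perm=n_perm, rng_seed=rng_seed,
            restart_prob=restart_prob, block="DG-Net", entity="drug",
        ))
    expr_weights = None
    if {"EXP", "MUT-Net", "CNV-Net"} & wanted:
        expr_weights = {c: omics.expression.loc[c] for c in omics.expression.index}
    if "EXP" in wanted:
        blocks.append(ssgsea_matrix(omics.expression, gene_sets, alpha=alpha))
    if "MUT-Net" in wanted:
        mut_sets: dict[str, set[str]] = {c: set() for c in omics.expression.index}
        for cell, gene in omics.mutations:
            mut_sets.setdefault(cell, set()).add(gene)
        blocks.append(netpea_enrich(
            network, mut_sets, gene_sets, n_perm=n_perm, rng_seed=rng_seed,
            gene_weights_per_entity=expr_weights,
            restart_prob=restart_prob, block="MUT-Net", entity="cell",
        ))
    if "CNV-Net" in wanted:
        cnv_sets = cnv_gene_sets(omics.cnv)
        blocks.append(netpea_enrich(
            network, cnv_sets, gene_sets, n_perm=n_perm, rng_seed=rng_seed,
            gene_weights_per_entity=expr_weights,
            restart_prob=restart_prob, block="CNV-Net", entity="cell",
        ))
    return assemble(blocks, responses, subset=subset)
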