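"""Self-consistent synthetic dataset with a planted pathway -> response effect.

The generator emulates the full input suite of a drug-sensitivity study:
a pathway collection, a weighted PPI network enriched for within-pathway
edges, cell-line omics (log-TPM expression, sparse mutations, GISTIC CNV)
whose variation is organised around latent per-cell pathway activities,
drugs with valid SMILES and targets inside a designated driver pathway,
and a response table in which log-IC50 follows the cell's driver-pathway
activity. Ground truth (driver pathway, activities, drug offsets) is
emitted to a sidecar so recovery tests never reach into generator
internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    DrugTable,
    GeneSetCollection,
    OmicsBundle,
    write_edge_list,
    write_gmt,
    write_mutations,
    write_response,
    write_smiles,
    write_target_table,
    write_wide_matrix,
)

__all__ = ["FixtureConfig", "SyntheticFixture", "generate_fixture", "write_fixture",
           "SMILES_PANEL"]

# fixed panel of valid drug-like molecules; guarantees parseable SMILES
# without a molecule generator
SMILES_PANEL = [
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",     # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",     # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",             # paracetamol
    "c1ccccc1",                        # benzene
    "CCO",                             # ethanol
    "c1ccc2ccccc2c1",                  # naphthalene
    "CN1CCCC1c1cccnc1",                # nicotine
    "O=C(O)c1ccccc1O",                 # salicylic acid
    "NC(=O)c1ccccc1",                  # benzamide
    "Cc1ccccc1",                       # toluene
    "Oc1ccccc1",                       # phenol
    "Nc1ccccc1",                       # aniline
    "c1ccncc1",                        # pyridine
    "c1ccc2[nH]ccc2c1",                # indole
    "OCC1OC(O)C(O)C(O)C1O",            # a hexose
    "CC(=O)O",                         # acetic acid
    "NC(N)=O",                         # urea
    "C1CCCCC1",                        # cyclohexane
    "c1ccc2ncccc2c1",                  # quinoline
]


@dataclass
class FixtureConfig:
    """Knobs of the synthetic study.

    Defaults are a desk-scale analogue of a GDSC-style screen: 300 genes,
    100 cell lines, 20 drugs, 50 pathways of 8-15 genes, one globally
    planted driver pathway whose latent activity drives response with
    effect size ``effect_size`` against observation noise ``noise_sd``
    (signal sd well above 5x the noise sd at the defaults).
    """

    n_genes: int = 300
    n_cells: int = 100
    n_drugs: int = 20
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (8, 15)
    background_edge_prob: float = 0.01
    within_pathway_edge_prob: float = 0.35
    n_driver_pathways: int = 1
    effect_size: float = 2.0
    noise_sd: float = 0.3
    drug_offset_sd: float = 0.0
    expression_shift: float = 1.0
    expression_noise_sd: float = 0.5
    mutation_count_range: tuple[int, int] = (5, 50)
    cnv_count_range: tuple[int, int] = (10, 30)
    activity_bias: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cells, self.n_drugs, self.n_pathways) < 1:
            raise ValueError("all counts must be >= 1")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValueError("pathway size exceeds n_genes")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")


@dataclass
class SyntheticFixture:
    """Everything the pipeline consumes, plus the planted ground truth."""

    gene_sets: GeneSetCollection
    network: nx.Graph
    omics: OmicsBundle
    drugs: DrugTable
    responses: pd.DataFrame
    ground_truth: dict
    config: FixtureConfig = field(default_factory=FixtureConfig)


def generate_fixture(config: FixtureConfig | None = None) -> SyntheticFixture:
    """Draw one complete dataset from the generative model.

    Latent per-cell pathway activities ``a[c, p] ~ N(0, 1)`` organise every
    data type: expression of a pathway's genes shifts with its activity,
    mutation and CNV gene draws are biased toward genes of active
    pathways, and the response of drug d in cell c is
    ``effect_size * a[c, driver] + offset_d + N(0, noise_sd)``.
    Identical configs (same seed) give identical fixtures.
    """
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    cells = [f"C{i:03d}" for i in range(1, cfg.n_cells + 1)]
    drugs = [f"D{i:02d}" for i in range(1, cfg.n_drugs + 1)]
    pathways = [f"PW{i:03d}" for i in range(1, cfg.n_pathways + 1)]

    # pathway membership (sets may overlap, as real pathway collections do)
    lo, hi = cfg.pathway_size_range
    sets: dict[str, list[str]] = {}
    for name in pathways:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        sets[name] = [genes[i] for i in sorted(members)]
    collection = GeneSetCollection(
        sets=sets, descriptions={p: "synthetic pathway" for p in pathways}
    )
    membership = np.zeros((cfg.n_genes, cfg.n_pathways))
    gene_index = {g: i for i, g in enumerate(genes)}
    for j, name in enumerate(pathways):
        for g in sets[name]:
            membership[gene_index[g], j] = 1.0

    # latent activities and expression
    activity = rng.normal(size=(cfg.n_cells, cfg.n_pathways))
    base = rng.normal(5.0, 2.0, size=cfg.n_genes)
    expr = (
        base
        + cfg.expression_shift * activity @ membership.T
        + rng.normal(0.0, cfg.expression_noise_sd, size=(cfg.n_cells, cfg.n_genes))
    )
    expression = pd.DataFrame(expr, index=cells, columns=genes)

    # PPI network: within-pathway edges on top of a sparse background
    network = nx.Graph()
    network.add_nodes_from(genes)
    edges: set[tuple[str, str]] = set()
    for name in pathways:
        members = sets[name]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < cfg.within_pathway_edge_prob:
                    edges.add(tuple(sorted((members[i], members[j]))))
    n_bg = int(cfg.background_edge_prob * cfg.n_genes * (cfg.n_genes - 1) / 2)
    for _ in range(n_bg):
        i, j = rng.choice(cfg.n_genes, size=2, replace=False)
        edges.add(tuple(sorted((genes[i], genes[j]))))
    for a, b in sorted(edges):
        network.add_edge(a, b, weight=float(rng.uniform(0.5, 1.0)))

    # mutations and CNV biased toward genes of active pathways
    mut_pairs: set[tuple[str, str]] = set()
    cnv = np.zeros((cfg.n_cells, cfg.n_genes), dtype=int)
    for ci, cell in enumerate(cells):
        gene_score = membership @ activity[ci]
        w = np.exp(cfg.activity_bias * gene_score)
        p = w / w.sum()
        n_mut = int(rng.integers(cfg.mutation_count_range[0],
                                 cfg.mutation_count_range[1] + 1))
        for gi in rng.choice(cfg.n_genes, size=n_mut, replace=False, p=p):
            mut_pairs.add((cell, genes[gi]))
        n_cnv = int(rng.integers(cfg.cnv_count_range[0], cfg.cnv_count_range[1] + 1))
        for gi in rng.choice(cfg.n_genes, size=n_cnv, replace=False, p=p):
            sign = 1 if gene_score[gi] >= 0 else -1
            if rng.random() < 0.1:
                sign = -sign
            cnv[ci, gi] = sign * int(rng.integers(1, 3))
    cnv_df = pd.DataFrame(cnv, index=cells, columns=genes)
    omics = OmicsBundle(expression=expression, mutations=frozenset(mut_pairs), cnv=cnv_df)

    # drugs: targets planted inside the (shared) driver pathway
    driver_pool = pathways[: cfg.n_driver_pathways]
    driver_of = {d: driver_pool[int(rng.integers(len(driver_pool)))] for d in drugs}
    smiles = {d: SMILES_PANEL[i % len(SMILES_PANEL)] for i, d in enumerate(drugs)}
    primary: dict[str, set[str]] = {}
    off: dict[str, set[str]] = {}
    for d in drugs:
        members = sets[driver_of[d]]
        k = int(rng.integers(2, min(5, len(members)) + 1))
        primary[d] = set(rng.choice(members, size=k, replace=False))
        off[d] = set(rng.choice(genes, size=int(rng.integers(1, 4)), replace=False))
    drug_table = DrugTable(smiles=smiles, primary_targets=primary, off_targets=off)

    # responses: planted effect + drug offset + noise, over all pairs
    offsets = {d: float(rng.normal(0.0, cfg.drug_offset_sd)) for d in drugs}
    rows = []
    driver_idx = {p: j for j, p in enumerate(pathways)}
    for d in drugs:
        j = driver_idx[driver_of[d]]
        for ci, cell in enumerate(cells):
            y = (cfg.effect_size * activity[ci, j] + offsets[d]
                 + rng.normal(0.0, cfg.noise_sd))
            rows.append((d, cell, y))
    responses = pd.DataFrame(rows, columns=["drug", "cell", "response"])

    ground_truth = {
        "driver_pathways": driver_of,
        "driver_pool": driver_pool,
        "drug_offsets": offsets,
        "activity": pd.DataFrame(activity, index=cells, columns=pathways),
    }
    return SyntheticFixture(
        gene_sets=collection, network=network, omics=omics, drugs=drug_table,
        responses=responses, ground_truth=ground_truth, config=cfg,
    )


def write_fixture(fixture: SyntheticFixture, outdir) -> None:
    """Persist every component in the pipeline's standard file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gmt(fixture.gene_sets, outdir / "pathways.gmt")
    write_edge_list(fixture.network, outdir / "ppi.tsv")
    write_wide_matrix(fixture.omics.expression, outdir / "expression.tsv")
    write_mutations(fixture.omics.mutations, outdir / "mutations.tsv")
    write_wide_matrix(fixture.omics.cnv, outdir / "cnv.tsv")
    write_smiles(fixture.drugs.smiles, outdir / "smiles.tsv")
    write_target_table(fixture.drugs.primary_targets, outdir / "primary_targets.tsv")
    write_target_table(fixture.drugs.off_targets, outdir / "off_targets.tsv")
    write_response(fixture.responses, outdir / "response.tsv")
    gt = {k: v for k, v in fixture.ground_truth.items() if k != "activity"}
    gt["config"] = asdict(fixture.config)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    write_wide_matrix(fixture.ground_truth["activity"], outdir / "ground_truth_activity.tsv")
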