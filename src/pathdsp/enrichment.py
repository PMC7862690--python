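"""Network-based pathway enrichment (NetPEA).

A cell line's mutated (or copy-number-altered) genes, or a drug's expanded
target genes, are used as restart nodes for a random walk with restart
(RWR) over a weighted protein-protein interaction network. The stationary
visit probability of each node measures its closeness to the seed set. A
pathway's enrichment is the mean visit probability over its genes —
optionally weighted by each gene's expression in the cell line — and is
normalised into a z-score against size-matched random gene sets drawn from
the network's node universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "NodeScoreVector",
    "EnrichmentMatrix",
    "NetPEA",
    "random_walk_with_restart",
    "pathway_closeness",
    "netpea_enrich",
]

# networks below this size are solved exactly by a dense linear solve
EXACT_SOLVE_MAX_NODES = 500


@dataclass
class NodeScoreVector:
    """Stationary RWR visit probabilities over network nodes.

    ``scores`` is indexed by node; probabilities are non-negative and sum
    to 1. ``seeds_used`` are the restart genes that mapped to the network;
    ``seeds_dropped`` the ones that did not.
    """

    scores: pd.Series
    seeds_used: list[str]
    seeds_dropped: list[str] = field(default_factory=list)

    def __getitem__(self, node: str) -> float:
        return float(self.scores[node])


@dataclass
class EnrichmentMatrix:
    """Entities (cells or drugs) x pathways enrichment scores.

    ``values`` holds permutation z-scores (DG-Net / MUT-Net / CNV-Net) or
    size-normalised enrichment scores (EXP). ``block`` tags which feature
    block the matrix belongs to; ``entity`` says whether rows are drugs or
    cells. ``diagnostics`` may carry side information (e.g. ssGSEA
    permutation z-scores).
    """

    values: pd.DataFrame
    block: str
    entity: str  # "drug" | "cell"
    diagnostics: pd.DataFrame | None = None

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="id")


def _adjacency(network: nx.Graph) -> tuple[list[str], np.ndarray]:
    nodes = list(network.nodes)
    A = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    return nodes, A


def _column_normalize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-stochastic transition matrix; returns (W, dangling mask)."""
    col_sums = A.sum(axis=0)
    dangling = col_sums == 0
    W = np.zeros_like(A)
    nz = ~dangling
    W[:, nz] = A[:, nz] / col_sums[nz]
    return W, dangling


def random_walk_with_restart(
    network: nx.Graph,
    seeds: set[str] | list[str],
    restart_prob: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 1000,
    method: str = "auto",
) -> NodeScoreVector:
    """Fixed point of ``p = (1 - c) W p + c e`` on the weighted network.

    ``W`` is the column-normalised weighted adjacency, ``e`` the restart
    distribution, uniform over the seeds that map to the network, and
    ``c = restart_prob``. Probability mass sitting on a dangling
    (isolated) node is redistributed to the restart vector. Networks with
    fewer than ``EXACT_SOLVE_MAX_NODES`` nodes are solved exactly via the
    linear system; larger ones by power iteration until the L1 change
    drops below ``tol``. ``method`` forces ``"exact"`` or ``"iterative"``
    regardless of size.

    Raises ``ValueError`` if no seed maps to the network or
    ``restart_prob`` is outside (0, 1].
    """
    if not 0 < restart_prob <= 1:
        raise ValueError(f"restart_prob must be in (0, 1], got {restart_prob}")
    nodes, A = _adjacency(network)
    if not nodes:
        raise ValueError("network has no nodes")
    index = {g: i for i, g in enumerate(nodes)}
    seeds = list(dict.fromkeys(seeds))
    used = [g for g in seeds if g in index]
    dropped = [g for g in seeds if g not in index]
    if not used:
        raise ValueError(f"no seed maps to the network (seeds={seeds!r})")
    if dropped:
        logger.info("dropped %d seeds absent from the network: %s", len(dropped), dropped)

    n = len(nodes)
    e = np.zeros(n)
    e[[index[g] for g in used]] = 1.0 / len(used)
    c = restart_prob

    if method not in ("auto", "exact", "iterative"):
        raise ValueError(f"unknown method {method!r}")
    if c == 1.0:
        p = e.copy()
    else:
        W, dangling = _column_normalize(A)
        use_exact = method == "exact" or (method == "auto" and n <= EXACT_SOLVE_MAX_NODES)
        if use_exact:
            # dangling columns walk back to the restart distribution
            M = W + np.outer(e, dangling.astype(float))
            p = np.linalg.solve(np.eye(n) - (1 - c) * M, c * e)
        else:
            p = e.copy()
            for _ in range(max_iter):
                p_new = (1 - c) * (W @ p + e * p[dangling].sum()) + c * e
                if np.abs(p_new - p).sum() < tol:
                    p = p_new
                    break
                p = p_new
    p = np.clip(p, 0.0, None)
    return NodeScoreVector(
        scores=pd.Series(p, index=nodes), seeds_used=used, seeds_dropped=dropped
    )


def pathway_closeness(
    node_scores: NodeScoreVector,
    pathway: set[str] | list[str],
    gene_weights: dict[str, float] | pd.Series | None = None,
) -> float:
    """Mean RWR probability over the pathway genes mapped to the network.

    With ``gene_weights`` (e.g. the cell line's log-TPM expression) each
    gene's probability is multiplied by its weight before averaging;
    weights default to 1. Pathway genes absent from the network are
    excluded from the mean. Returns NaN (with a warning) when no pathway
    gene maps.
    """
    scores = node_scores.scores
    mapped = [g for g in pathway if g in scores.index]
    if not mapped:
        warnings.warn("pathway has no genes on the network; closeness is NaN")
        return float("nan")
    vals = scores[mapped].to_numpy(dtype=float)
    if gene_weights is not None:
        w = np.array([float(gene_weights.get(g, 1.0)) for g in mapped])
        vals = vals * w
    return float(vals.mean())


class NetPEA(BaseEstimator):
    """Network-based pathway enrichment scorer (scikit-learn style).

    Parameters
    ----------
    n_perm : int
        Number of size-matched random gene sets forming the null for each
        pathway (the study protocol uses 1000).
    restart_prob : float
        RWR restart probability ``c``; 0.7 is a common propagation choice.
    tol : float
        L1 convergence tolerance of the power iteration.
    random_state : int or None
        Seed for the permutation draws; fixing it makes the z-scores
        bit-reproducible.

    After :meth:`fit`, ``nodes_`` lists the network nodes and
    ``pathway_index_`` maps each pathway to its mapped node positions.
    :meth:`transform` turns per-entity seed sets into a z-score matrix.
    """

    def __init__(
        self,
        n_perm: int = 1000,
        restart_prob: float = 0.7,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_perm = n_perm
        self.restart_prob = restart_prob
        self.tol = tol
        self.random_state = random_state

    def fit(self, network: nx.Graph, pathways: GeneSetCollection) -> "NetPEA":
        if len(pathways) == 0:
            raise ValueError("pathway collection is empty")
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        self.network_ = network
        self.pathways_ = pathways
        self.nodes_ = list(network.nodes)
        index = {g: i for i, g in enumerate(self.nodes_)}
        # sorted so equal index sets average in identical order (bitwise-
        # stable null: a set equal to the whole universe gets sigma == 0)
        self.pathway_index_ = {
            name: np.sort([index[g] for g in genes if g in index]).astype(int)
            for name, genes in pathways.sets.items()
        }
        return self

    def transform(
        self,
        seed_sets: dict[str, set[str] | list[str]],
        gene_weights: dict[str, dict[str, float] | pd.Series] | None = None,
        block: str = "MUT-Net",
        entity: str = "cell",
    ) -> EnrichmentMatrix:
        """Score every entity's seed set against every pathway.

        For each entity one RWR is run from its seed set; every pathway's
        closeness is z-scored against ``n_perm`` random gene sets of the
        same mapped size, drawn from the network node universe and scored
        against the same RWR vector (and the same expression weights).
        Entities whose seed set misses the network entirely yield a row
        of zeros (reported); a degenerate null (sigma = 0) yields z = 0.
        """
        if not hasattr(self, "nodes_"):
            raise RuntimeError("NetPEA must be fit(network, pathways) before transform")
        rng = np.random.default_rng(self.random_state)
        n = len(self.nodes_)
        names = list(self.pathways_.names())
        rows = np.zeros((len(seed_sets), len(names)))
        empty_entities: list[str] = []
        zero_sigma = 0

        for i, (entity_id, seeds) in enumerate(seed_sets.items()):
            seeds = [g for g in seeds if g in self.network_]
            if not seeds:
                empty_entities.append(entity_id)
                continue
            nsv = random_walk_with_restart(
                self.network_, seeds, restart_prob=self.restart_prob, tol=self.tol
            )
            p = nsv.scores.to_numpy()
            if gene_weights is not None and entity_id in gene_weights:
                w_map = gene_weights[entity_id]
                w = np.array([float(w_map.get(g, 1.0)) for g in self.nodes_])
                values = p * w
            else:
                values = p
            null_cache: dict[int, tuple[float, float]] = {}
            for j, name in enumerate(names):
                idx = self.pathway_index_[name]
                k = len(idx)
                if k == 0:
                    rows[i, j] = 0.0
                    continue
                s = values[idx].mean()
                if k not in null_cache:
                    draws = np.empty(self.n_perm)
                    for t in range(self.n_perm):
                        pick = np.sort(rng.choice(n, size=k, replace=False))
                        draws[t] = values[pick].mean()
                    # identical draws => degenerate null, even when the
                    # accumulated mean differs from them by rounding
                    sigma = 0.0 if draws.max() == draws.min() else float(draws.std())
                    null_cache[k] = (float(draws.mean()), sigma)
                mu, sigma = null_cache[k]
                if sigma == 0:
                    zero_sigma += 1
                    rows[i, j] = 0.0
                else:
                    rows[i, j] = (s - mu) / sigma
        if empty_entities:
            logger.warning(
                "%d entities had no seed on the network (rows set to 0): %s",
                len(empty_entities), empty_entities,
            )
        if zero_sigma:
            warnings.warn(f"{zero_sigma} pathway nulls had zero variance; z set to 0")
        values_df = pd.DataFrame(rows, index=list(seed_sets), columns=names)
        return EnrichmentMatrix(values=values_df, block=block, entity=entity)


def netpea_enrich(
    network: nx.Graph,
    seed_sets: dict[str, set[str] | list[str]],
    pathways: GeneSetCollection,
    n_perm: int = 1000,
    rng_seed: int | None = None,
    gene_weights_per_entity: dict[str, dict[str, float] | pd.Series] | None = None,
    restart_prob: float = 0.7,
    tol: float = 1e-6,
    block: str = "MUT-Net",
    entity: str = "cell",
) -> EnrichmentMatrix:
    """Functional wrapper over :class:`NetPEA` fit + transform."""
    est = NetPEA(n_perm=n_perm, restart_prob=restart_prob, tol=tol, random_state=rng_seed)
    est.fit(network, pathways)
    return est.transform(
        seed_sets, gene_weights=gene_weights_per_entity, block=block, entity=entity
    )
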