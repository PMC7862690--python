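"""Single-sample GSEA (ssGSEA) of expression profiles — the EXP block.

For one cell line, genes are ranked by descending expression and the
enrichment score of a gene set is the sum over ranks of the difference
between the cumulative |expression|^alpha-weighted fraction of in-set
genes (P_hit) and the cumulative uniform fraction of out-of-set genes
(P_miss). The normalised enrichment score (NES) divides ES by the number
of gene-set members mapped to the profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .enrichment import EnrichmentMatrix
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["RankedProfile", "SSGSEA", "rank_profile", "ssgsea_es", "ssgsea_matrix"]


@dataclass
class RankedProfile:
    """One sample's genes ordered by descending expression.

    Ties are broken lexicographically by gene symbol, which makes the
    ordering a strict total order and the score deterministic.
    """

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a ranked profile needs at least 2 genes")
        if len(self.genes) != len(self.values):
            raise ValueError("genes and values lengths differ")


def rank_profile(expression: pd.Series) -> RankedProfile:
    """Order a gene -> expression series into a :class:`RankedProfile`."""
    df = pd.DataFrame({"gene": expression.index, "value": expression.to_numpy(float)})
    df = df.sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
    return RankedProfile(genes=df["gene"].tolist(), values=df["value"].to_numpy())


def ssgsea_es(
    profile: RankedProfile, gene_set: set[str] | list[str], alpha: float = 0.25
) -> float:
    """Running-sum enrichment score of ``gene_set`` in the ranked profile.

    ``ES = sum_i [P_hit(i) - P_miss(i)]`` where P_hit accumulates
    ``|expr|^alpha`` over in-set genes (normalised by the in-set total)
    and P_miss accumulates ``1/(N - N_hit)`` over out-of-set genes.

    An empty intersection returns 0.0 with a warning; a set covering the
    whole profile is an error (P_miss undefined).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    members = set(gene_set)
    hit = np.array([g in members for g in profile.genes])
    n = len(profile.genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        warnings.warn("gene set does not intersect the profile; ES = 0")
        return 0.0
    if n_hit == n:
        raise ValueError("gene set covers every profile gene; P_miss undefined")
    w = np.abs(profile.values) ** alpha
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all in-set expression values are exactly zero: fall back to uniform hits
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~hit) / (n - n_hit)
    return float(np.sum(p_hit - p_miss))


class SSGSEA(BaseEstimator):
    """ssGSEA scorer over a pathway collection (scikit-learn style).

    Parameters
    ----------
    alpha : float
        Rank weighting exponent on |expression|; 0.25 is the standard
        ssGSEA choice. With alpha = 0 the score depends only on ranks.
    n_perm : int
        If > 0, a permutation z-score of each ES against random gene sets
        of the same size is computed as a diagnostic (the reported feature
        stays NES = ES / set size).
    random_state : int or None
        Seed for the diagnostic permutations.
    """

    def __init__(self, alpha: float = 0.25, n_perm: int = 0, random_state: int | None = None):
        self.alpha = alpha
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, pathways: GeneSetCollection) -> "SSGSEA":
        self.pathways_ = pathways
        return self

    def transform(self, expression: pd.DataFrame) -> EnrichmentMatrix:
        """Score every cell (row of ``expression``) against every pathway.

        Returns NES = ES / |gene set mapped to the profile|; pathways with
        no mapped genes score 0 and are reported.
        """
        if not hasattr(self, "pathways_"):
            raise RuntimeError("SSGSEA must be fit(pathways) before transform")
        rng = np.random.default_rng(self.random_state)
        names = self.pathways_.names()
        genes = list(expression.columns)
        gene_pool = set(genes)
        mapped_sets = {
            name: [g for g in self.pathways_[name] if g in gene_pool] for name in names
        }
        unmapped = [name for name, m in mapped_sets.items() if not m]
        if unmapped:
            logger.warning("%d pathways have no genes in the profile: %s",
                           len(unmapped), unmapped)
        nes = np.zeros((len(expression), len(names)))
        diag = np.zeros_like(nes) if self.n_perm > 0 else None
        for i, (_, row) in enumerate(expression.iterrows()):
            profile = rank_profile(row)
            for j, name in enumerate(names):
                mapped = mapped_sets[name]
                if not mapped:
                    continue
                es = ssgsea_es(profile, mapped, alpha=self.alpha)
                nes[i, j] = es / len(mapped)
                if diag is not None:
                    draws = np.empty(self.n_perm)
                    for t in range(self.n_perm):
                        rand_set = rng.choice(genes, size=len(mapped), replace=False)
                        draws[t] = ssgsea_es(profile, set(rand_set), alpha=self.alpha)
                    sd = draws.std()
                    diag[i, j] = 0.0 if sd == 0 else (es - draws.mean()) / sd
        values = pd.DataFrame(nes, index=expression.index, columns=names)
        diagnostics = (
            pd.DataFrame(diag, index=expression.index, columns=names)
            if diag is not None else None
        )
        return EnrichmentMatrix(values=values, block="EXP", entity="cell",
                                diagnostics=diagnostics)


def ssgsea_matrix(
    expression: pd.DataFrame,
    pathways: GeneSetCollection,
    alpha: float = 0.25,
    n_perm: int = 0,
    rng_seed: int | None = None,
) -> EnrichmentMatrix:
    """Functional wrapper over :class:`SSGSEA` fit + transform."""
    return SSGSEA(alpha=alpha, n_perm=n_perm, random_state=rng_seed).fit(pathways).transform(expression)
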