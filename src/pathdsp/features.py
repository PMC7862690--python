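"""Feature-block assembly and normalisation.

Drug-level blocks (CHEM fingerprints, DG-Net enrichment) are broadcast
across every cell line a drug was screened on; cell-level blocks (EXP,
MUT-Net, CNV-Net) across every drug. A (drug, cell) response record makes
it into the design matrix only when all selected blocks cover it.
Features are z-scored column-wise with statistics fit on training rows
only, so no test-fold information leaks into the normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .chem import FingerprintBlock
from .enrichment import EnrichmentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "NormalizationStats",
    "ZScoreNormalizer",
    "cnv_gene_sets",
    "assemble",
    "zscore",
]

DEFAULT_BLOCK_ORDER = ["CHEM", "DG-Net", "EXP", "MUT-Net", "CNV-Net"]


def cnv_gene_sets(cnv: pd.DataFrame) -> dict[str, set[str]]:
    """Per cell line, the genes with a non-zero GISTIC score.

    Diploid genes (score 0) are excluded; gains and losses both count.
    Cells whose whole row is diploid yield an empty set and are reported
    (their CNV-Net feature row becomes zeros downstream).
    """
    arr = cnv.to_numpy()
    if not np.all(np.isin(arr, [-2, -1, 0, 1, 2])):
        raise ValueError("CNV matrix contains values outside GISTIC levels -2..2")
    out: dict[str, set[str]] = {}
    empty = []
    for cell, row in cnv.iterrows():
        genes = set(row.index[row.to_numpy() != 0])
        out[cell] = genes
        if not genes:
            empty.append(cell)
    if empty:
        logger.warning("%d cells have an all-diploid CNV row: %s", len(empty), empty)
    return out


@dataclass
class FeatureMatrix:
    """Design matrix over (drug, cell) pairs with block-labelled columns.

    ``X`` has a (drug, cell) MultiIndex on rows and a (block, feature)
    MultiIndex on columns; ``y`` is the response aligned to the rows.
    """

    X: pd.DataFrame
    y: pd.Series | None = None

    @property
    def blocks(self) -> list[str]:
        return list(dict.fromkeys(self.X.columns.get_level_values(0)))

    @property
    def width(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return len(self.X)

    def block_width(self, block: str) -> int:
        return int((self.X.columns.get_level_values(0) == block).sum())

    def to_tsv(self, path) -> None:
        """Persist with a two-row header (block tag, feature name)."""
        out = self.X.copy()
        if self.y is not None:
            out[("response", "response")] = self.y
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=[0, 1])
        y = None
        if ("response", "response") in df.columns:
            y = df[("response", "response")]
            df = df.drop(columns=[("response", "response")])
        return cls(X=df, y=y)


def _block_frames(
    blocks: list[EnrichmentMatrix | FingerprintBlock],
) -> dict[str, tuple[pd.DataFrame, str]]:
    """Normalise heterogeneous block objects to name -> (frame, entity kind)."""
    out: dict[str, tuple[pd.DataFrame, str]] = {}
    for b in blocks:
        if isinstance(b, FingerprintBlock):
            out["CHEM"] = (b.bits, "drug")
        elif isinstance(b, EnrichmentMatrix):
            out[b.block] = (b.values, b.entity)
        else:
            raise TypeError(f"unsupported block object: {type(b).__name__}")
    return out


def assemble(
    blocks: list[EnrichmentMatrix | FingerprintBlock],
    response: pd.DataFrame,
    subset: list[str] | None = None,
) -> FeatureMatrix:
    """Join feature blocks with the response table into one design matrix.

    ``response`` has columns (drug, cell, response). ``subset`` restricts
    to the named blocks (reproducing data-type ablations); default is every
    supplied block in canonical order CHEM, DG-Net, EXP, MUT-Net, CNV-Net.
    Pairs missing any selected block are dropped with a logged count;
    NaN enrichment values are zero-filled (with a logged count) before
    assembly.
    """
    frames = _block_frames(blocks)
    if subset is None:
        names = [b for b in DEFAULT_BLOCK_ORDER if b in frames]
        names += [b for b in frames if b not in names]
    else:
        missing = [b for b in subset if b not in frames]
        if missing:
            raise ValueError(f"requested blocks not supplied: {missing}")
        names = list(subset)

    pairs = response[["drug", "cell"]]
    keep = np.ones(len(response), dtype=bool)
    for name in names:
        frame, kind = frames[name]
        ids = pairs["drug"] if kind == "drug" else pairs["cell"]
        keep &= ids.isin(frame.index).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d response pairs missing a feature block", n_dropped)
    kept = response.loc[keep]
    if kept.empty:
        raise ValueError("no response pair is covered by all selected blocks")

    parts = []
    for name in names:
        frame, kind = frames[name]
        n_nan = int(frame.isna().to_numpy().sum())
        if n_nan:
            logger.warning("block %s: %d NaN values set to 0", name, n_nan)
            frame = frame.fillna(0.0)
        ids = kept["drug"] if kind == "drug" else kept["cell"]
        part = frame.loc[ids].reset_index(drop=True)
        part.columns = pd.MultiIndex.from_product([[name], part.columns])
        parts.append(part)
    X = pd.concat(parts, axis=1)
    X.index = pd.MultiIndex.from_frame(kept[["drug", "cell"]].reset_index(drop=True))
    y = pd.Series(kept["response"].to_numpy(), index=X.index, name="response")
    return FeatureMatrix(X=X, y=y)


@dataclass
class NormalizationStats:
    """Per-column mean/sd fit on training rows; zero-variance columns recorded."""

    mean: pd.Series
    scale: pd.Series
    dropped: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"mean": self.mean, "scale": self.scale}).to_csv(path, sep="\t")


class ZScoreNormalizer(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring with population standard deviation.

    Zero-variance columns are dropped at fit time and recorded in
    ``dropped_``; ``transform`` applies the stored statistics only, so
    test rows never influence them.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "ZScoreNormalizer":
        arr = X.to_numpy(dtype=float)
        mean = arr.mean(axis=0)
        scale = arr.std(axis=0)  # population sd
        keep = scale > 0
        self.columns_ = X.columns[keep]
        self.dropped_ = list(X.columns[~keep])
        self.mean_ = pd.Series(mean[keep], index=self.columns_)
        self.scale_ = pd.Series(scale[keep], index=self.columns_)
        if self.dropped_:
            logger.info("dropped %d zero-variance columns", len(self.dropped_))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        Z = X[self.columns_]
        return (Z - self.mean_) / self.scale_

    @property
    def stats_(self) -> NormalizationStats:
        check_is_fitted(self, "mean_")
        return NormalizationStats(mean=self.mean_, scale=self.scale_, dropped=self.dropped_)


def zscore(
    matrix: FeatureMatrix, stats: NormalizationStats | None = None
) -> tuple[FeatureMatrix, NormalizationStats]:
    """Fit-and-apply (training mode) or apply-only (test mode) z-scoring."""
    if stats is None:
        norm = ZScoreNormalizer().fit(matrix.X)
        Xz = norm.transform(matrix.X)
        return FeatureMatrix(X=Xz, y=matrix.y), norm.stats_
    cols = stats.mean.index
    missing = [c for c in cols if c not in matrix.X.columns]
    if missing:
        raise ValueError(f"columns missing from matrix: {missing[:5]}")
    Xz = (matrix.X[cols] - stats.mean) / stats.scale
    return FeatureMatrix(X=Xz, y=matrix.y), stats
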