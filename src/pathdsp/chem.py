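"""Morgan (circular / ECFP-type) fingerprints of drug SMILES — the CHEM block."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")

__all__ = ["FingerprintBlock", "MorganFeaturizer", "morgan_fingerprint", "fingerprint_table"]


@dataclass
class FingerprintBlock:
    """Drugs x bits binary fingerprint matrix with its hashing parameters."""

    bits: pd.DataFrame
    radius: int
    n_bits: int
    dropped: list[str]

    @property
    def drugs(self) -> list[str]:
        return list(self.bits.index)


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 256) -> np.ndarray:
    """Fold a molecule's circular substructure hashes into an n-bit 0/1 vector.

    Counts are collapsed to presence/absence. Raises ``ValueError`` on an
    empty or unparseable SMILES.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=np.uint8)


class MorganFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless SMILES -> fingerprint transformer (scikit-learn style)."""

    def __init__(self, radius: int = 2, n_bits: int = 256):
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X=None, y=None) -> "MorganFeaturizer":
        self.n_features_out_ = self.n_bits
        return self

    def transform(self, X: list[str]) -> np.ndarray:
        """Fingerprint a list of SMILES; every entry must parse."""
        return np.vstack([
            morgan_fingerprint(s, radius=self.radius, n_bits=self.n_bits) for s in X
        ])


def fingerprint_table(
    smiles_map: dict[str, str], radius: int = 2, n_bits: int = 256
) -> FingerprintBlock:
    """Fingerprint a drug -> SMILES map, dropping (and reporting) drugs whose
    SMILES fail to parse. Output rows keep the input order."""
    if not smiles_map:
        raise ValueError("empty SMILES map")
    rows, kept, dropped = [], [], []
    for drug, smiles in smiles_map.items():
        try:
            rows.append(morgan_fingerprint(smiles, radius=radius, n_bits=n_bits))
            kept.append(drug)
        except ValueError:
            dropped.append(drug)
    if not kept:
        raise ValueError("no drug has a valid SMILES")
    if dropped:
        logger.warning("dropped %d drugs with invalid SMILES: %s", len(dropped), dropped)
    bits = pd.DataFrame(
        np.vstack(rows), index=kept, columns=[f"bit_{i}" for i in range(n_bits)]
    )
    return FingerprintBlock(bits=bits, radius=radius, n_bits=n_bits, dropped=dropped)
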