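"""Experiment drivers and metrics.

Supports repeated k-fold cross-validation plus the two extrapolation
schemes: leave-one-drug-out (LODO; every pair of one drug held out) and
leave-one-cell-out (LOCO; every pair of one cell line held out).
Normalisation statistics are re-fit inside each training fold and the
early-stopping validation split is carved from within the training fold,
so no test information reaches the model. Metrics are MAE, RMSE, R^2 and
Pearson correlation; a Kolmogorov-Smirnov test against a fitted Laplace
distribution serves as the residual-distribution diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import KFold

from .features import FeatureMatrix
from .model import TrainedModel, train_fnn

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "make_splits",
    "compute_metrics",
    "laplace_residual_test",
    "theoretical_floor",
    "run_experiment",
]


@dataclass
class SplitPlan:
    """Train/test row-position folds for one evaluation scheme.

    ``folds`` holds (train positions, test positions) pairs; ``labels``
    names each fold (``"r{repeat}f{fold}"`` for k-fold, the held-out
    entity for LODO/LOCO).
    """

    mode: str  # "kfold" | "lodo" | "loco"
    folds: list[tuple[np.ndarray, np.ndarray]]
    labels: list[str]
    k: int | None = None
    repeats: int = 1
    rng_seed: int | None = None

    def __len__(self) -> int:
        return len(self.folds)


def make_splits(
    pairs: list[tuple[str, str]] | pd.MultiIndex,
    mode: str = "kfold",
    k: int = 10,
    repeats: int = 1,
    rng_seed: int | None = None,
) -> SplitPlan:
    """Build a deterministic split plan over (drug, cell) rows.

    kfold: ``repeats`` independent shuffled k-fold partitions (fold sizes
    within one of each other). lodo/loco: one fold per distinct drug /
    cell, whose test set is every row of that entity.
    """
    pairs = list(pairs)
    n = len(pairs)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    labels: list[str] = []
    if mode == "kfold":
        if k > n:
            raise ValueError(f"k={k} exceeds number of rows ({n})")
        ss = np.random.SeedSequence(rng_seed)
        for r, child in enumerate(ss.spawn(repeats)):
            seed = int(child.generate_state(1)[0] % (2**31))
            kf = KFold(n_splits=k, shuffle=True, random_state=seed)
            for f, (tr, te) in enumerate(kf.split(np.arange(n))):
                folds.append((tr, te))
                labels.append(f"r{r}f{f}")
    elif mode in ("lodo", "loco"):
        key = 0 if mode == "lodo" else 1
        entities = sorted({p[key] for p in pairs})
        if len(entities) < 2:
            raise ValueError(f"{mode} needs >= 2 distinct entities")
        ids = np.array([p[key] for p in pairs])
        for ent in entities:
            te = np.flatnonzero(ids == ent)
            tr = np.flatnonzero(ids != ent)
            folds.append((tr, te))
            labels.append(str(ent))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SplitPlan(mode=mode, folds=folds, labels=labels,
                     k=k if mode == "kfold" else None,
                     repeats=repeats if mode == "kfold" else 1,
                     rng_seed=rng_seed)


def compute_metrics(y_true, y_pred) -> dict[str, float]:
    """MAE, RMSE, R^2 and Pearson correlation of one prediction set."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan")
    if y_true.std() == 0 or y_pred.std() == 0:
        warnings.warn("zero-variance input; PCC undefined (NaN)")
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(y_true, y_pred)[0, 1])
    return {"MAE": mae, "RMSE": rmse, "R2": r2, "PCC": pcc}


def laplace_residual_test(residuals) -> dict[str, float]:
    """Fit a Laplace distribution to residuals and KS-test the fit.

    Location is the median, scale the mean absolute deviation from it
    (the Laplace maximum-likelihood estimates). Returns the fitted
    parameters with the Kolmogorov-Smirnov statistic and p-value; at
    least 30 residuals are required.
    """
    res = np.asarray(residuals, dtype=float)
    if len(res) < 30:
        raise ValueError(f"need >= 30 residuals, got {len(res)}")
    loc = float(np.median(res))
    scale = float(np.mean(np.abs(res - loc)))
    if scale == 0:
        raise ValueError("all residuals identical; Laplace scale is 0")
    ks = sps.kstest(res, "laplace", args=(loc, scale))
    return {"loc": loc, "scale": scale,
            "ks_stat": float(ks.statistic), "p_value": float(ks.pvalue)}


def theoretical_floor(
    responses_a: pd.DataFrame, responses_b: pd.DataFrame
) -> tuple[float, float]:
    """MAE/RMSE between two response tables on their shared (drug, cell)
    pairs — the error floor of any model trained on one dataset and
    evaluated on the other (the datasets disagree on the pairs they share).
    """
    merged = responses_a.merge(
        responses_b, on=["drug", "cell"], suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("the two response tables share no (drug, cell) pair")
    diff = merged["response_a"].to_numpy() - merged["response_b"].to_numpy()
    return float(np.mean(np.abs(diff))), float(np.sqrt(np.mean(diff**2)))


@dataclass
class ExperimentResult:
    """Per-fold metrics plus pooled predictions of one experiment."""

    plan: SplitPlan
    fold_metrics: pd.DataFrame  # indexed by fold label
    predictions: pd.DataFrame   # columns: drug, cell, fold, y_true, y_pred
    models: list[TrainedModel] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        """mean ± sd of each metric across folds (and across repeats for
        repeated k-fold, reported separately)."""
        agg = self.fold_metrics.agg(["mean", "std"])
        return agg

    def pooled_metrics(self) -> dict[str, float]:
        return compute_metrics(self.predictions["y_true"], self.predictions["y_pred"])


def run_experiment(
    matrix: FeatureMatrix,
    plan: SplitPlan,
    fnn_params: dict | None = None,
    rng_seed: int | None = None,
    keep_models: bool = False,
) -> ExperimentResult:
    """Train/evaluate the FNN over every fold of a split plan.

    Within each fold, z-score statistics are fit on the training rows
    only, and the FNN carves its early-stopping validation split from
    those same training rows (nested, leak-free). Per-fold model seeds
    are derived deterministically from ``rng_seed``.
    """
    if matrix.y is None:
        raise ValueError("feature matrix has no response")
    fnn_params = dict(fnn_params or {})
    ss = np.random.SeedSequence(rng_seed)
    fold_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(plan))]

    records = []
    rows = []
    models = []
    index = matrix.X.index
    for (tr, te), label, seed in zip(plan.folds, plan.labels, fold_seeds):
        train_fm = FeatureMatrix(X=matrix.X.iloc[tr], y=matrix.y.iloc[tr])
        test_fm = FeatureMatrix(X=matrix.X.iloc[te], y=matrix.y.iloc[te])
        model = train_fnn(train_fm, random_state=seed, **fnn_params)
        y_pred = model.predict(test_fm)
        y_true = test_fm.y.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singleton LODO folds have zero variance
            m = compute_metrics(y_true, y_pred)
        m["fold"] = label
        records.append(m)
        for pos, yt, yp in zip(te, y_true, y_pred):
            drug, cell = index[pos]
            rows.append((drug, cell, label, yt, yp))
        if keep_models:
            models.append(model)
        logger.info("fold %s: MAE=%.4f RMSE=%.4f", label, m["MAE"], m["RMSE"])
    fold_metrics = pd.DataFrame(records).set_index("fold")
    predictions = pd.DataFrame(rows, columns=["drug", "cell", "fold", "y_true", "y_pred"])
    return ExperimentResult(plan=plan, fold_metrics=fold_metrics,
                            predictions=predictions, models=models)
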