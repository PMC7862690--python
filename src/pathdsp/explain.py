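"""Shapley-value attribution of model predictions to features.

Permutation-sampling Shapley estimation with background replacement:
"removing" a feature means substituting its value from a background row.
Each sampling round draws a random feature ordering and walks it, crediting
every feature with the change in model output when its value flips from
background to the explained sample. The telescoping sum over one round
equals f(x) - f(background row), so cycling deterministically through the
background rows makes the estimates exactly additive for linear models; a
final additive correction distributes any residual so that local accuracy
(base value + sum of attributions = prediction) holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .model import TrainedModel

__all__ = ["Attribution", "shapley_attributions", "rank_features"]


@dataclass
class Attribution:
    """Per-(sample, feature) Shapley values and the background base value.

    ``values`` is samples x features (same column labels as the feature
    matrix, so the block tag rides along); ``base_value`` is the expected
    model output over the background set.
    """

    values: pd.DataFrame
    base_value: float

    @property
    def blocks(self) -> list[str]:
        cols = self.values.columns
        if isinstance(cols, pd.MultiIndex):
            return list(dict.fromkeys(cols.get_level_values(0)))
        return []


def _as_predict_fn(model, schema):
    if isinstance(model, TrainedModel):
        if schema is not None and list(schema) != list(model.schema):
            raise ValueError("feature schema does not match the model's schema")
        def fn(arr: np.ndarray, columns) -> np.ndarray:
            fm = FeatureMatrix(X=pd.DataFrame(arr, columns=columns))
            return model.predict(fm)
        return fn
    if callable(getattr(model, "predict", None)):
        return lambda arr, columns: np.asarray(model.predict(arr)).ravel()
    if callable(model):
        return lambda arr, columns: np.asarray(model(arr)).ravel()
    raise TypeError("model must be a TrainedModel, an estimator, or a callable")


def shapley_attributions(
    model,
    X: FeatureMatrix | pd.DataFrame,
    background: FeatureMatrix | pd.DataFrame,
    n_samples: int = 25,
    rng_seed: int | None = None,
) -> Attribution:
    """Estimate Shapley values for every row of ``X``.

    Parameters
    ----------
    model : TrainedModel, sklearn-style estimator, or callable
        Anything that maps a feature array to predictions.
    X : rows to explain (raw, un-normalised feature space).
    background : reference rows defining "feature absent"; the base value
        is the mean prediction over this set. A default background is a
        fixed-seed sample of ~100 training rows.
    n_samples : number of permutation rounds per explained row. Each round
        uses the next background row in cyclic order; making ``n_samples``
        a multiple of the background size removes background-sampling bias
        entirely (and is what makes linear models exact).
    rng_seed : seed for the permutation draws.
    """
    Xdf = X.X if isinstance(X, FeatureMatrix) else X
    Bdf = background.X if isinstance(background, FeatureMatrix) else background
    if len(Bdf) == 0:
        raise ValueError("background set is empty")
    if list(Xdf.columns) != list(Bdf.columns):
        raise ValueError("X and background have different feature schemas")
    columns = Xdf.columns
    fn = _as_predict_fn(model, columns)

    Xa = Xdf.to_numpy(dtype=float)
    Ba = Bdf.to_numpy(dtype=float)
    n, d = Xa.shape
    n_bg = len(Ba)
    base = float(np.mean(fn(Ba, columns)))
    fx = fn(Xa, columns)

    rng = np.random.default_rng(rng_seed)
    phi = np.zeros((n, d))
    for s in range(n):
        x = Xa[s]
        acc = np.zeros(d)
        for k in range(n_samples):
            b = Ba[k % n_bg]
            perm = rng.permutation(d)
            # rows: background with a growing prefix of x along perm
            Z = np.tile(b, (d + 1, 1))
            for j, f in enumerate(perm):
                Z[j + 1:, f] = x[f]
            out = fn(Z, columns)
            acc[perm] += np.diff(out)
        acc /= n_samples
        # enforce local accuracy: distribute the residual evenly
        acc += (fx[s] - base - acc.sum()) / d
        phi[s] = acc
    values = pd.DataFrame(phi, index=Xdf.index, columns=columns)
    return Attribution(values=values, base_value=base)


def rank_features(
    attr: Attribution,
    direction: str = "positive",
    level: str = "global",
    k: int = 20,
    sample=None,
) -> pd.DataFrame:
    """Rank features by their Shapley values.

    ``direction``: ``positive`` ranks by the mean positive contribution
    (the positive part of each sample's Shapley value, averaged) — the
    features that push predictions up where they matter, i.e. sensitising
    under the response-increase convention. The signed mean of an
    informative but centred feature averages to ~0 across samples, so the
    positive-part mean is what isolates positive contributors.
    ``negative`` ranks by the most negative mean negative part;
    ``absolute`` by the mean magnitude. ``level='global'`` aggregates
    across samples; ``level='per_sample'`` ranks within the row named by
    ``sample``. Ties break lexicographically by feature name. Returns up
    to ``k`` rows with columns feature, block, score.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if level == "global":
        if direction == "absolute":
            scores = attr.values.abs().mean(axis=0)
        elif direction == "positive":
            scores = attr.values.clip(lower=0).mean(axis=0)
        elif direction == "negative":
            scores = attr.values.clip(upper=0).mean(axis=0)
        else:
            raise ValueError(f"unknown direction {direction!r}")
    elif level == "per_sample":
        if sample is None:
            raise ValueError("per_sample ranking needs a sample id")
        row = attr.values.loc[sample]
        scores = row.abs() if direction == "absolute" else row
    else:
        raise ValueError(f"unknown level {level!r}")

    multi = isinstance(scores.index, pd.MultiIndex)
    df = pd.DataFrame({
        "block": scores.index.get_level_values(0) if multi else "",
        "feature": scores.index.get_level_values(-1) if multi else scores.index,
        "score": scores.to_numpy(),
    })
    ascending = direction == "negative"
    df = df.sort_values(["score", "feature"], ascending=[ascending, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(k)
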