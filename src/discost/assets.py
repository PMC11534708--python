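"""Asset-index construction: the 0-100 standard-of-living score.

The standard-of-living indicator is a weighted share of binary asset
ownership and dwelling-quality indicators, rescaled so that owning nothing
scores 0 and owning everything scores 100. The default is 16 asset items
plus any number of dwelling components with equal weights; a
first-principal-component weighting is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA


@dataclass
class AssetVector:
    """One household's asset/dwelling indicators.

    ``direct_index`` is an escape hatch used by the synthetic generator's
    ``linear_index`` mode: when set, :func:`compute_index` returns it
    unchanged (already on the 0-100 scale) instead of aggregating binary
    items. Real survey data always uses binary items.
    """

    items: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dwellings: np.ndarray = field(default_factory=lambda: np.zeros(0))
    weights: np.ndarray | None = None
    direct_index: float | None = None

    def components(self) -> np.ndarray:
        return np.concatenate([np.asarray(self.items), np.asarray(self.dwellings)])


def compute_index(assets: AssetVector) -> float:
    """Score one AssetVector on the 0-100 standard-of-living scale.

    index = 100 * sum(w_j x_j) / sum(w_j); 0 when nothing is owned, 100
    when everything is. Invariant to rescaling all weights by a positive
    constant. Raises ValueError on all-zero weights or out-of-range
    indicators.
    """
    if assets.direct_index is not None:
        return float(np.clip(assets.direct_index, 0.0, 100.0))
    x = assets.components().astype(float)
    if x.size == 0:
        raise ValueError("asset vector has no components")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("indicators must be binary 0/1")
    w = np.ones_like(x) if assets.weights is None else np.asarray(assets.weights, float)
    if w.shape != x.shape:
        raise ValueError("weights must match the number of components")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    return float(100.0 * (w * x).sum() / w.sum())


def index_from_frame(
    df: pd.DataFrame,
    asset_cols: list[str] | None = None,
    dwelling_cols: list[str] | None = None,
    weights: np.ndarray | None = None,
) -> pd.Series:
    """Vectorised index over a household table.

    When the table carries a pre-computed ``asset_index`` column (the
    generator's linear_index mode) and no component columns are named,
    that column is passed through.
    """
    if asset_cols is None:
        asset_cols = sorted(c for c in df.columns if c.startswith("asset_") and c != "asset_index")
    if dwelling_cols is None:
        dwelling_cols = sorted(c for c in df.columns if c.startswith("dwell_"))
    cols = asset_cols + dwelling_cols
    if not cols:
        if "asset_index" in df.columns:
            return df["asset_index"].clip(0.0, 100.0).astype(float)
        raise ValueError("no asset/dwelling columns and no asset_index column")
    x = df[cols].to_numpy(dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("indicators must be binary 0/1")
    w = np.ones(len(cols)) if weights is None else np.asarray(weights, float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    return pd.Series(100.0 * (x @ w) / w.sum(), index=df.index, name="sol_index")


class AssetIndexScorer(BaseEstimator, TransformerMixin):
    """Transformer computing the 0-100 standard-of-living index per household.

    Parameters
    ----------
    weighting : {"equal", "pca"}
        Component weights. ``pca`` uses the loadings of the first principal
        component of the indicator matrix (shifted to be non-negative),
        a common sensitivity check on equal weighting.
    asset_cols, dwelling_cols : explicit component column lists; by default
        every ``asset_*`` / ``dwell_*`` column is used.
    """

    def __init__(self, weighting="equal", asset_cols=None, dwelling_cols=None):
        self.weighting = weighting
        self.asset_cols = asset_cols
        self.dwelling_cols = dwelling_cols

    def _cols(self, X):
        a = self.asset_cols
        d = self.dwelling_cols
        if a is None:
            a = sorted(c for c in X.columns if c.startswith("asset_") and c != "asset_index")
        if d is None:
            d = sorted(c for c in X.columns if c.startswith("dwell_"))
        return a, d

    def fit(self, X: pd.DataFrame, y=None):
        a, d = self._cols(X)
        cols = a + d
        if self.weighting == "equal" or not cols:
            self.weights_ = np.ones(len(cols))
        elif self.weighting == "pca":
            load = PCA(n_components=1).fit(X[cols].to_numpy(float)).components_[0]
            if load.sum() < 0:  # orient so ownership raises the index
                load = -load
            self.weights_ = np.clip(load, 0.0, None)
            if self.weights_.sum() <= 0:
                raise ValueError("degenerate PCA loadings; use equal weighting")
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        self.component_cols_ = cols
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        a, d = self._cols(X)
        out = X.copy()
        out["sol_index"] = index_from_frame(
            X, a, d, self.weights_ if (a + d) else None
        )
        return out
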