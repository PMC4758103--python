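"""PCA of the feature table and the loading-quartile rule.

Features with extreme loadings on the first two principal components of
a multi-cell-type feature table are the ones that carry cell-type or
protocol identity; removing them (together with features that depend on
the experimental setting, such as library size) leaves the "common"
features that transfer across cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from cellqc.exceptions import ValidationError
from cellqc.features import FeatureTable

logger = logging.getLogger(__name__)

#: Features removed by default as experiment-setting dependent.
DEFAULT_EXCLUDE = ("total_reads", "n_detected_genes")


@dataclass
class FeatureScaling:
    """Stored center/scale so new cells get the training-time transform."""

    center: pd.Series
    scale: pd.Series
    zero_variance: pd.Series  # bool per feature

    def apply(self, ft: FeatureTable) -> FeatureTable:
        missing = [f for f in self.center.index if f not in ft.feature_names]
        if missing:
            raise ValidationError(f"features missing for scaling: {missing[:5]}")
        values = (ft.values[self.center.index] - self.center) / self.scale
        return FeatureTable(
            values,
            ft.kind.reindex(self.center.index),
            ft.common_flag.reindex(self.center.index),
        )


def scale_features(ft: FeatureTable) -> tuple[FeatureTable, FeatureScaling]:
    """Center each feature to mean 0 and scale to unit variance.

    Zero-variance features are left centered at 0 and flagged (scale 1).
    """
    if ft.n_cells < 2:
        raise ValidationError("need >= 2 cells to scale features")
    center = ft.values.mean(axis=0)
    std = ft.values.std(axis=0, ddof=1)
    zero_var = std == 0
    if zero_var.any():
        logger.warning(
            "%d zero-variance features left centered", int(zero_var.sum())
        )
    scale = std.where(~zero_var, 1.0)
    scaling = FeatureScaling(center, scale, zero_var)
    return scaling.apply(ft), scaling


@dataclass
class PCAResult:
    """Deterministic PCA of a scaled feature table.

    Component signs are fixed by making each component's
    largest-magnitude loading positive, so reruns are bit-identical.
    """

    scores: pd.DataFrame  # cells x components
    loadings: pd.DataFrame  # features x components
    explained_variance: np.ndarray
    scaling: FeatureScaling | None = None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


def run_pca(ft: FeatureTable, n_components: int | None = None) -> PCAResult:
    """PCA (full SVD) on an already-scaled feature table."""
    if ft.n_cells < 2:
        raise ValidationError("need >= 2 cells for PCA")
    max_k = min(ft.n_cells - 1, len(ft.feature_names))
    if n_components is None:
        n_components = max_k
    if n_components > max_k:
        raise ValidationError(
            f"n_components={n_components} exceeds min(cells-1, features)={max_k}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(ft.values.to_numpy())
    loadings = pca.components_.T  # features x components
    # fix signs: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=ft.values.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=ft.values.columns, columns=comp_names),
        explained_variance=pca.explained_variance_,
    )


def select_common_features(
    p: PCAResult,
    quantile: float = 0.25,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> list[str]:
    """Drop features with extreme PC1 or PC2 loadings, then the exclude
    list; return survivors in original order.

    A feature is removed when its loading on PC1 or on PC2 falls in the
    lowest or highest ``quantile`` fraction of the loading range, with
    the range taken over the pooled PC1 and PC2 loading values
    (strictly below ``min + quantile * range`` or strictly above
    ``max - quantile * range``). Features whose loadings sit near the
    middle of the range — the cell-type-independent ones — survive even
    when a handful of type-carrying features stretch the extremes.
    """
    if not 0 <= quantile < 0.5:
        raise ValidationError("quantile must be in [0, 0.5)")
    if p.loadings.shape[1] < 2:
        raise ValidationError("need >= 2 principal components")
    removed: set[str] = set()
    if quantile > 0:
        pooled = p.loadings[["PC1", "PC2"]].to_numpy().ravel()
        span = pooled.max() - pooled.min()
        cut_lo = pooled.min() + quantile * span
        cut_hi = pooled.max() - quantile * span
        for pc in ("PC1", "PC2"):
            lo = p.loadings[pc].to_numpy()
            extreme = (lo < cut_lo) | (lo > cut_hi)
            removed |= set(p.loadings.index[extreme])
    removed |= set(exclude)
    survivors = [f for f in p.loadings.index if f not in removed]
    if not survivors:
        raise ValidationError(
            "loading-quantile rule removed every feature; use a smaller quantile"
        )
    return survivors
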