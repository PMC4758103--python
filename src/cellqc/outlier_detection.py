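"""Unsupervised, feature-based outlier detection.

Cells are scaled, projected onto the top principal components of the
feature table, and scored by squared robust Mahalanobis distance under
a minimum-covariance-determinant (MCD) location/scatter estimate. Cells
whose squared distance exceeds the chi-square quantile (df = number of
components) at the configured level are flagged as outliers — the
unsupervised complement to the supervised classifier, and the tool used
to call "deceptive" cells (visually intact, transcriptomically broken).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.covariance import MinCovDet

from cellqc.exceptions import ValidationError
from cellqc.features import FeatureTable
from cellqc.feature_selection import run_pca, scale_features

logger = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    """Per-cell robust distances and flags, plus the decision rule used."""

    robust_distance: pd.Series  # sqrt of squared Mahalanobis distance
    is_outlier: pd.Series
    threshold: float  # chi-square cutoff on the squared distance
    n_components_used: int
    level: float
    seed: int

    @property
    def n_outliers(self) -> int:
        return int(self.is_outlier.sum())


def detect_outliers(
    ft: FeatureTable,
    n_components: int = 2,
    level: float = 0.975,
    seed: int = 0,
) -> OutlierReport:
    """Flag outlying cells by robust Mahalanobis distance in PCA space.

    Parameters
    ----------
    ft
        Raw (unscaled) feature table.
    n_components
        Number of leading principal components to score in.
    level
        Chi-square quantile defining the outlier cutoff (default 0.975).
    seed
        Seed of the MCD subset search, recorded in the report.
    """
    if not 0.5 < level < 1:
        raise ValidationError("level must be in (0.5, 1)")
    if ft.n_cells < 2 * (n_components + 1):
        raise ValidationError(
            f"need >= {2 * (n_components + 1)} cells for {n_components} components"
        )
    scaled, _ = scale_features(ft)
    pca = run_pca(scaled, n_components=n_components)
    X = pca.scores.to_numpy()
    try:
        mcd = MinCovDet(random_state=seed).fit(X)
        d2 = mcd.mahalanobis(X)
        if not np.all(np.isfinite(d2)):
            raise ValueError("non-finite distances")
    except (ValueError, np.linalg.LinAlgError):
        logger.warning("singular robust scatter; falling back to diagonal scatter")
        center = np.median(X, axis=0)
        mad = scipy.stats.median_abs_deviation(X, axis=0, scale="normal")
        mad[mad == 0] = 1.0
        d2 = (((X - center) / mad) ** 2).sum(axis=1)
    threshold = float(scipy.stats.chi2.ppf(level, df=n_components))
    dist = pd.Series(np.sqrt(d2), index=ft.values.index, name="robust_distance")
    flags = pd.Series(d2 > threshold, index=ft.values.index, name="is_outlier")
    return OutlierReport(
        robust_distance=dist,
        is_outlier=flags,
        threshold=threshold,
        n_components_used=n_components,
        level=level,
        seed=seed,
    )


def write_outlier_report(report: OutlierReport, path) -> None:
    df = pd.DataFrame(
        {
            "robust_distance": report.robust_distance,
            "is_outlier": report.is_outlier,
        }
    )
    df.to_csv(path, sep="\t", index_label="cell_id", float_format="%.6g")
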