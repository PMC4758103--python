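"""Statistical characterization of low- vs high-quality cells.

* Distance-to-median (DM): a mean-independent gene-noise measure — the
  deviation of a gene's log10 squared coefficient of variation from the
  rolling median at its expression level.
* GO-level paired t-tests: for each gene set, low- vs high-quality cells
  are compared gene by gene on mean normalized expression and on DM.
* Fisher enrichment of annotated cells in a detector's outlier area.
* Classification accuracy metrics with LOW quality as the positive
  class: sensitivity, specificity, accuracy, F-beta, MCC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from cellqc.exceptions import ValidationError
from cellqc.io import GeneSetCollection, QualityLabels
from cellqc.features import NormalizedMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distance-to-median
# ---------------------------------------------------------------------------


def compute_dm(
    nm: NormalizedMatrix,
    cells: Sequence[str] | None = None,
    window: int = 50,
) -> pd.Series:
    """Distance-to-median noise per gene.

    For non-ERCC genes with positive mean over the chosen cells, compute
    CV^2 = variance / mean^2, sort genes by log10(mean), and subtract
    from log10(CV^2) its centered rolling median (window shrinks at the
    edges). Genes with zero mean or zero CV^2 are excluded.

    Returns a Series indexed by gene ID, in the input gene order.
    """
    if window < 3:
        raise ValidationError("window must be >= 3")
    values = nm.endogenous()
    if cells is not None:
        values = values[list(cells)]
    mean = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    ok = mean > 0
    cv2 = var[ok] / mean[ok] ** 2
    positive = cv2 > 0
    n_dropped = int((~ok).sum() + (~positive).sum())
    if n_dropped:
        logger.info("DM: %d genes with zero mean or zero CV^2 excluded", n_dropped)
    cv2 = cv2[positive]
    if len(cv2) < window:
        raise ValidationError(
            f"only {len(cv2)} expressed genes, fewer than window={window}"
        )
    log_mean = np.log10(mean[cv2.index])
    log_cv2 = np.log10(cv2)
    order = np.argsort(log_mean.to_numpy(), kind="stable")
    sorted_log_cv2 = log_cv2.iloc[order]
    roll_med = sorted_log_cv2.rolling(window, center=True, min_periods=1).median()
    dm_sorted = sorted_log_cv2 - roll_med
    return dm_sorted.reindex(cv2.index)


# ---------------------------------------------------------------------------
# GO-level paired t-tests
# ---------------------------------------------------------------------------


def _paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test; all-zero differences give (0, 1), other
    zero-variance differences are undefined (NaN)."""
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        logger.warning("zero-variance nonzero paired differences: p undefined")
        return math.copysign(math.inf, d.mean()), float("nan")
    res = scipy.stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def _adjust(p: pd.Series, method: str) -> pd.Series:
    out = pd.Series(np.nan, index=p.index)
    mask = p.notna()
    if mask.any():
        method_key = {"fdr_bh": "fdr_bh", "bh": "fdr_bh", "bonferroni": "bonferroni"}[
            method
        ]
        out[mask] = multipletests(p[mask].to_numpy(), method=method_key)[1]
    return out


def _signed_log10(p: pd.Series, t: pd.Series) -> pd.Series:
    with np.errstate(divide="ignore"):
        mag = -np.log10(p)
    return mag * np.sign(t)


def go_paired_ttest(
    nm: NormalizedMatrix,
    labels: QualityLabels,
    gs: GeneSetCollection,
    adjust: str = "fdr_bh",
    dm_window: int = 50,
) -> pd.DataFrame:
    """Two-sided paired t-tests per gene set, LOW vs HIGH cells.

    Genes are the pairing units. The mean test pairs per-gene mean
    normalized expression in the two classes; the DM test pairs the
    distance-to-median computed within each class (genes with undefined
    DM in either class are excluded). P-values are adjusted across sets
    (Benjamini-Hochberg by default). A positive t means the value is
    higher in LOW cells.

    Returns a DataFrame indexed by set name with columns ``n_genes_used``,
    ``t_mean``, ``p_mean``, ``p_adjusted_mean``, ``signed_log10_p_mean``
    and the DM analogues.
    """
    labels = labels.reindex(nm.cell_ids)
    low_cells = [c for c, is_low in labels.is_low().items() if is_low]
    high_cells = [c for c in nm.cell_ids if c not in set(low_cells)]
    if len(low_cells) < 2 or len(high_cells) < 2:
        raise ValidationError("need >= 2 cells in each quality class")

    endo = nm.endogenous()
    mean_low = endo[low_cells].mean(axis=1)
    mean_high = endo[high_cells].mean(axis=1)
    dm_low = compute_dm(nm, cells=low_cells, window=dm_window)
    dm_high = compute_dm(nm, cells=high_cells, window=dm_window)
    dm_genes = dm_low.index.intersection(dm_high.index)

    rows = {}
    for name, members in gs.items():
        genes = endo.index.intersection(members)
        if len(genes) < 2:
            logger.warning("gene set %r: <2 usable genes, skipped", name)
            continue
        t_mean, p_mean = _paired_ttest(
            mean_low[genes].to_numpy(), mean_high[genes].to_numpy()
        )
        g_dm = dm_genes.intersection(genes)
        if len(g_dm) >= 2:
            t_dm, p_dm = _paired_ttest(
                dm_low[g_dm].to_numpy(), dm_high[g_dm].to_numpy()
            )
        else:
            t_dm, p_dm = float("nan"), float("nan")
        rows[name] = {
            "n_genes_used": len(genes),
            "n_genes_dm": len(g_dm),
            "t_mean": t_mean,
            "p_mean": p_mean,
            "t_dm": t_dm,
            "p_dm": p_dm,
        }
    if not rows:
        raise ValidationError("no gene set had >= 2 usable genes")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["p_adjusted_mean"] = _adjust(df["p_mean"], adjust)
    df["p_adjusted_dm"] = _adjust(df["p_dm"], adjust)
    df["signed_log10_p_mean"] = _signed_log10(df["p_mean"], df["t_mean"])
    df["signed_log10_p_dm"] = _signed_log10(df["p_dm"], df["t_dm"])
    return df


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(
    flags: Sequence[bool],
    labels: Sequence[bool],
    alternative: str = "greater",
) -> tuple[float, float]:
    """Fisher's exact test for enrichment of annotated cells among
    outlier-flagged cells.

    Returns ``(p_value, odds_ratio)``. Degenerate tables (all cells in
    one category of either margin) return p = 1 with a warning.
    """
    flags = np.asarray(flags, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if flags.shape != labels.shape or flags.size == 0:
        raise ValidationError("flags and labels must be same-length, non-empty")
    a = int((flags & labels).sum())
    b = int((flags & ~labels).sum())
    c = int((~flags & labels).sum())
    d = int((~flags & ~labels).sum())
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        logger.warning("degenerate 2x2 table %s: p = 1", [[a, b], [c, d]])
        return 1.0, float("nan")
    res = scipy.stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(res.pvalue), float(res.statistic)


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Confusion counts and derived metrics; LOW is the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int
    beta: float = 2.0

    @property
    def sensitivity(self) -> float:
        den = self.TP + self.FN
        return self.TP / den if den else 0.0

    @property
    def specificity(self) -> float:
        den = self.TN + self.FP
        return self.TN / den if den else 0.0

    @property
    def accuracy(self) -> float:
        den = self.TP + self.TN + self.FP + self.FN
        return (self.TP + self.TN) / den if den else 0.0

    @property
    def f_beta(self) -> float:
        b2 = self.beta**2
        den = (1 + b2) * self.TP + b2 * self.FN + self.FP
        return (1 + b2) * self.TP / den if den else 0.0

    @property
    def mcc(self) -> float:
        tp, tn, fp, fn = self.TP, self.TN, self.FP, self.FN
        den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if den == 0:
            return 0.0
        return (tp * tn - fp * fn) / math.sqrt(den)

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f_beta": self.f_beta,
            "mcc": self.mcc,
            "beta": self.beta,
        }

    def __str__(self) -> str:
        return (
            f"TP={self.TP} TN={self.TN} FP={self.FP} FN={self.FN} | "
            f"sens={self.sensitivity:.3f} spec={self.specificity:.3f} "
            f"acc={self.accuracy:.3f} F{self.beta:g}={self.f_beta:.3f} "
            f"MCC={self.mcc:.3f}"
        )


def _as_low_bool(labels) -> pd.Series:
    if isinstance(labels, QualityLabels):
        return labels.is_low()
    s = pd.Series(labels)
    if s.dtype == object:
        return s.astype(str).str.upper() == "LOW"
    return s.astype(bool)


def classification_metrics(
    predicted, truth, beta: float = 2.0
) -> MetricsReport:
    """Confusion counts and metrics of a prediction against truth.

    Accepts QualityLabels or boolean (LOW=True) sequences; when both are
    QualityLabels their cell sets must match.
    """
    if beta <= 0:
        raise ValidationError("beta must be positive")
    p = _as_low_bool(predicted)
    t = _as_low_bool(truth)
    if isinstance(predicted, QualityLabels) and isinstance(truth, QualityLabels):
        if set(p.index) != set(t.index):
            raise ValidationError("predicted and truth cover different cells")
        t = t.reindex(p.index)
    elif len(p) != len(t):
        raise ValidationError("predicted and truth have different lengths")
    p_arr, t_arr = p.to_numpy(), t.to_numpy()
    return MetricsReport(
        TP=int((p_arr & t_arr).sum()),
        TN=int((~p_arr & ~t_arr).sum()),
        FP=int((p_arr & ~t_arr).sum()),
        FN=int((~p_arr & t_arr).sum()),
        beta=beta,
    )
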