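"""UMI-to-read-count transformation.

UMI protocols count absolute transcript molecules, while the quality
features and the shipped classifier expect read-count-scale values. The
bridge is a cubic polynomial regression on the log scale between
per-gene mean transcript counts (x) and per-gene mean read counts (y),
each offset by a pseudo count of 0.1:

    log10(y + 0.1) = a0 + a1*t + a2*t^2 + a3*t^3,  t = log10(x + 0.1)

The model is linear in the coefficients, so ordinary least squares on
the polynomial basis gives the exact solution. The fitted curve is then
applied entry-wise to a transcript-count matrix; back-transformed
values are clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cellqc.exceptions import ValidationError
from cellqc.io import CountMatrix

DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class UMITransformModel:
    """Fitted cubic curve from transcript to read scale (log10)."""

    coefficients: np.ndarray  # a0..a3
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    rss: float = 0.0
    n_genes_fit: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (4,):
            raise ValidationError("expected 4 polynomial coefficients")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")

    def transform_values(self, c: np.ndarray) -> np.ndarray:
        """Map transcript counts to pseudo-read counts, clipped at 0."""
        t = np.log10(np.asarray(c, dtype=float) + self.pseudocount)
        log_y = np.polyval(self.coefficients[::-1], t)
        return np.maximum(0.0, 10.0**log_y - self.pseudocount)


def fit_umi_transform(
    mean_transcripts,
    mean_reads,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> UMITransformModel:
    """Least-squares fit of the log-scale cubic from paired per-gene
    means (transcripts, reads)."""
    x = np.asarray(mean_transcripts, dtype=float)
    y = np.asarray(mean_reads, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("mean_transcripts and mean_reads differ in length")
    if x.ndim != 1 or len(x) < 4:
        raise ValidationError("need >= 4 paired gene means")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("negative input values")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    t = np.log10(x + pseudocount)
    z = np.log10(y + pseudocount)
    design = np.vander(t, N=4, increasing=True)
    if np.linalg.matrix_rank(design) < 4:
        raise ValidationError(
            "rank-deficient design: transcript means span too few values"
        )
    coef, _, _, _ = np.linalg.lstsq(design, z, rcond=None)
    rss = float(((design @ coef - z) ** 2).sum())
    return UMITransformModel(coef, pseudocount, rss, len(x))


def apply_umi_transform(model: UMITransformModel, m: CountMatrix) -> CountMatrix:
    """Apply the fitted curve entry-wise to a transcript-count matrix."""
    if m.unit != "raw_counts":
        raise ValidationError("UMI transform expects transcript counts")
    values = m.values.copy()
    values.loc[:, :] = model.transform_values(values.to_numpy())
    return CountMatrix(values, m.ercc_mask, unit="raw_counts")
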