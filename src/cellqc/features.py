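"""Cell-level biological and technical quality features.

Biological features are proportions of a cell's library falling into
curated gene sets (GO categories, mtDNA-encoded genes, mitochondrially
localized proteins, housekeeping genes): a broken cell loses cytoplasmic
transcripts but retains mitochondrially enclosed RNA, so its mtDNA
proportion rises while its cytoplasm proportion falls.

Technical features summarize read accounting (mapping, duplication and
spike-in rates) and the shape of the expression profile (detected genes,
expression-level bin counts, transcriptome variance, correlation with
the dataset mean profile, and the number of highly expressed, highly
variable genes detected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from cellqc.exceptions import ValidationError
from cellqc.io import AlignmentStats, CountMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

#: The cell-type- and protocol-independent feature subset obtained by
#: the PCA loading-quartile rule (see :mod:`cellqc.feature_selection`).
COMMON_FEATURES = (
    "go_cytoplasm",
    "mito_localized",
    "mtDNA_encoded",
    "prop_mapped",
    "prop_multimapped",
    "prop_non_exonic",
    "transcriptome_variance",
)


@dataclass
class NormalizedMatrix:
    """Per-cell library-size-normalized expression.

    Each cell's values are divided by the cell's total over non-ERCC
    genes, so that non-ERCC values sum to 1 per cell. ERCC rows are
    carried through, divided by the same denominator. Cells with a zero
    non-ERCC total are set to 0 and flagged.
    """

    values: pd.DataFrame  # genes x cells
    ercc_mask: np.ndarray
    provenance: str = "from_counts"
    flagged_cells: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    def endogenous(self) -> pd.DataFrame:
        """The non-ERCC rows."""
        return self.values.loc[~self.ercc_mask]


@dataclass
class FeatureTable:
    """Cells x features numeric matrix with per-feature metadata."""

    values: pd.DataFrame  # cells x features
    kind: pd.Series  # per feature: "biological" | "technical"
    common_flag: pd.Series  # per feature bool

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = list(self.values.columns[self.values.columns.duplicated()])
            raise ValidationError(f"duplicate feature names: {dups[:5]}")
        if self.values.isna().to_numpy().any():
            raise ValidationError("feature table contains missing values")
        self.kind = self.kind.reindex(self.values.columns)
        self.common_flag = (
            self.common_flag.reindex(self.values.columns).fillna(False).astype(bool)
        )

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def common_subset(self) -> "FeatureTable":
        cols = [c for c in self.values.columns if self.common_flag[c]]
        return FeatureTable(self.values[cols], self.kind[cols], self.common_flag[cols])


def normalize_counts(m: CountMatrix) -> NormalizedMatrix:
    """Divide each cell by its total count over non-ERCC genes.

    Works for raw counts and for TPM input alike (for TPM the division
    is by total non-ERCC TPM, which reduces to TPM/1e6 on a complete
    matrix). Cells with zero non-ERCC total are zeroed and flagged.
    """
    endo = m.values.loc[~m.ercc_mask]
    totals = endo.sum(axis=0)
    zero = totals <= 0
    flagged = list(totals.index[zero])
    if flagged:
        logger.warning("%d cells with zero non-ERCC total flagged", len(flagged))
    denom = totals.where(~zero, 1.0)
    values = m.values.div(denom, axis=1)
    values.loc[:, zero] = 0.0
    provenance = "from_tpm" if m.unit == "tpm" else "from_counts"
    return NormalizedMatrix(values, m.ercc_mask, provenance, flagged)


def extract_biological_features(
    nm: NormalizedMatrix, gs: GeneSetCollection
) -> FeatureTable:
    """One feature per gene set: the summed normalized expression of its
    member genes in each cell (the proportion of the cell's library in
    that set). Sets with no gene present in the matrix yield 0 with a
    warning."""
    if len(gs) == 0:
        raise ValidationError("empty gene-set collection")
    index = pd.Index(nm.gene_ids)
    cols: dict[str, pd.Series] = {}
    for name, members in gs.items():
        present = index.intersection(members)
        if len(present) == 0:
            logger.warning("gene set %r has no genes in the matrix", name)
            cols[name] = pd.Series(0.0, index=nm.cell_ids)
        else:
            cols[name] = nm.values.loc[present].sum(axis=0)
    values = pd.DataFrame(cols)
    kind = pd.Series("biological", index=values.columns)
    flag = pd.Series(False, index=values.columns)
    return FeatureTable(values, kind, flag)


@dataclass
class TechnicalConfig:
    """Tunables of the technical feature extraction.

    bin_edges
        Upper edges (on the counts-per-million scale) of the first four
        expression bins; the fifth bin is everything above the last edge.
    log_pseudo
        Pseudo value added before log10 in the transcriptome variance.
    dm_window
        Rolling-median window for the distance-to-median noise measure
        used to define the highly-variable gene set.
    """

    bin_edges: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    log_pseudo: float = 1e-6
    dm_window: int = 50


def _safe_ratio(num: pd.Series, den: pd.Series, name: str) -> pd.Series:
    zero = den == 0
    if zero.any():
        logger.warning(
            "%s: %d cells with zero denominator imputed 0", name, int(zero.sum())
        )
    out = num / den.where(~zero, 1)
    return out.where(~zero, 0.0)


def extract_technical_features(
    m: CountMatrix,
    st: AlignmentStats,
    cfg: TechnicalConfig | None = None,
) -> FeatureTable:
    """Alignment-accounting ratios plus expression-shape summaries."""
    from cellqc.quality_stats import compute_dm  # local: avoids import cycle

    cfg = cfg or TechnicalConfig()
    m_cells, s_cells = set(m.cell_ids), set(st.cell_ids)
    if m_cells != s_cells:
        raise ValidationError(
            f"cell sets differ: matrix-only {sorted(m_cells - s_cells)[:5]}, "
            f"stats-only {sorted(s_cells - m_cells)[:5]}"
        )
    t = st.table.loc[m.cell_ids]
    nm = normalize_counts(m)
    endo_counts = m.values.loc[~m.ercc_mask]
    endo_norm = nm.endogenous()

    cols: dict[str, pd.Series] = {}
    cols["total_reads"] = t["total_reads"].astype(float)
    cols["prop_mapped"] = _safe_ratio(t["mapped"], t["total_reads"], "prop_mapped")
    cols["prop_multimapped"] = _safe_ratio(
        t["multimapped"], t["total_reads"], "prop_multimapped"
    )
    cols["prop_unmapped"] = _safe_ratio(t["unmapped"], t["total_reads"], "prop_unmapped")
    cols["prop_non_exonic"] = _safe_ratio(t["non_exonic"], t["mapped"], "prop_non_exonic")
    cols["prop_duplicated"] = _safe_ratio(t["duplicated"], t["mapped"], "prop_duplicated")
    cols["ercc_to_exonic"] = _safe_ratio(t["ercc_reads"], t["exonic"], "ercc_to_exonic")

    detected = endo_counts > 0
    cols["n_detected_genes"] = detected.sum(axis=0).astype(float)

    logged = np.log10(endo_norm + cfg.log_pseudo)
    cols["transcriptome_variance"] = logged.var(axis=0, ddof=1)

    # correlation of each cell with the dataset mean profile, on genes
    # detected in at least one cell (rank correlation: robust to the
    # heavy right tail of expression values)
    ever_detected = detected.any(axis=1)
    sub = endo_norm.loc[ever_detected]
    mean_profile = sub.mean(axis=1)
    corr = {}
    for cell in sub.columns:
        if sub[cell].nunique() <= 1 or mean_profile.nunique() <= 1:
            corr[cell] = 0.0
        else:
            rho = scipy.stats.spearmanr(sub[cell], mean_profile).statistic
            corr[cell] = float(rho) if np.isfinite(rho) else 0.0
    cols["cell_to_mean_correlation"] = pd.Series(corr)

    # highly expressed AND highly variable genes (dataset-level set):
    # mean above the across-gene median and positive distance-to-median
    gene_means = endo_norm.mean(axis=1)
    expressed = gene_means > 0
    n_expressed = int(expressed.sum())
    try:
        window = min(cfg.dm_window, max(3, n_expressed))
        dm = compute_dm(nm, window=window)
        median_mean = gene_means[expressed].median()
        hv = dm.index[(gene_means.reindex(dm.index) > median_mean) & (dm > 0)]
        cols["n_high_var_high_expr"] = (
            detected.loc[detected.index.intersection(hv)].sum(axis=0).astype(float)
        )
    except ValidationError:
        logger.warning("too few variable genes for the highly-variable set")
        cols["n_high_var_high_expr"] = pd.Series(0.0, index=m.cell_ids)

    cpm = endo_norm * 1e6
    edges = cfg.bin_edges
    lower = (0.0, *edges)
    upper = (*edges, np.inf)
    for i, (lo, hi) in enumerate(zip(lower, upper), start=1):
        in_bin = (cpm > lo) & (cpm <= hi) & detected
        cols[f"n_genes_bin{i}"] = in_bin.sum(axis=0).astype(float)

    values = pd.DataFrame(cols).loc[m.cell_ids]
    kind = pd.Series("technical", index=values.columns)
    flag = pd.Series(False, index=values.columns)
    return FeatureTable(values, kind, flag)


def assemble_features(*parts: FeatureTable) -> FeatureTable:
    """Concatenate partial tables and flag the canonical common set."""
    if not parts:
        raise ValidationError("no feature tables to assemble")
    cells = set(parts[0].cell_ids)
    seen: set[str] = set()
    for p in parts:
        if set(p.cell_ids) != cells:
            raise ValidationError("feature tables cover different cell sets")
        clash = seen & set(p.feature_names)
        if clash:
            raise ValidationError(f"duplicate feature names: {sorted(clash)[:5]}")
        seen |= set(p.feature_names)
    index = parts[0].values.index
    values = pd.concat([p.values.loc[index] for p in parts], axis=1)
    kind = pd.concat([p.kind for p in parts])
    flag = pd.Series(
        [name in COMMON_FEATURES for name in values.columns], index=values.columns
    )
    return FeatureTable(values, kind, flag)


def extract_features(
    m: CountMatrix,
    st: AlignmentStats,
    gs: GeneSetCollection,
    cfg: TechnicalConfig | None = None,
) -> FeatureTable:
    """Full pipeline: normalize, extract biological and technical
    features, assemble into one table."""
    nm = normalize_counts(m)
    bio = extract_biological_features(nm, gs)
    tech = extract_technical_features(m, st, cfg)
    return assemble_features(bio, tech)


def write_feature_table(ft: FeatureTable, path) -> None:
    """Write features as TSV (cells in rows) plus a ``.meta.tsv`` sidecar
    of per-feature kind and common flag."""
    from pathlib import Path

    path = Path(path)
    ft.values.to_csv(path, sep="\t", index_label="cell_id", float_format="%.12g")
    meta = pd.DataFrame({"kind": ft.kind, "common_flag": ft.common_flag})
    meta.to_csv(
        path.with_suffix(path.suffix + ".meta.tsv"), sep="\t", index_label="feature"
    )


def read_feature_table(path) -> FeatureTable:
    from pathlib import Path

    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="cell_id")
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="feature")
        kind = meta["kind"]
        flag = meta["common_flag"].astype(bool)
    else:
        kind = pd.Series("technical", index=values.columns)
        flag = pd.Series(
            [c in COMMON_FEATURES for c in values.columns], index=values.columns
        )
    return FeatureTable(values, kind, flag)
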