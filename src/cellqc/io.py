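"""Readers and writers for the formats the tool touches.

Count matrices are genes x cells on disk and in memory: dense TSV/CSV
(first column gene IDs, header row of cell IDs) or MatrixMarket MTX with
two sibling single-column name files (``<stem>.genes.txt`` and
``<stem>.cells.txt``). Gene sets travel as GMT, per-cell tables
(alignment statistics, quality labels, predictions) as TSV with header.

ERCC spike-in rows are recognized by a configurable gene-ID prefix
(default ``"ERCC-"``) and carried as a boolean mask on the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from cellqc.exceptions import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ERCC_PREFIX = "ERCC-"

#: Required columns of an alignment-statistics table, beside cell_id.
ALIGNMENT_COLUMNS = (
    "total_reads",
    "mapped",
    "multimapped",
    "unmapped",
    "exonic",
    "non_exonic",
    "duplicated",
    "ercc_reads",
)

HIGH = "HIGH"
LOW = "LOW"
SUBTYPES = ("broken", "empty", "multiple", "deceptive", "none")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """A genes x cells expression matrix (raw counts or TPM).

    Parameters
    ----------
    values
        DataFrame of non-negative expression values, index = gene IDs,
        columns = cell IDs.
    ercc_mask
        Boolean array over genes, True for spike-in rows.
    unit
        Either ``"raw_counts"`` or ``"tpm"``.
    """

    values: pd.DataFrame
    ercc_mask: np.ndarray
    unit: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = None
        self.values.columns.name = None
        self.ercc_mask = np.asarray(self.ercc_mask, dtype=bool)
        if self.unit not in ("raw_counts", "tpm"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.ercc_mask.shape != (self.values.shape[0],):
            raise ValidationError(
                "ercc_mask length does not match number of genes"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()][:5]
            raise ValidationError(f"duplicate gene IDs: {list(dups)}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()][:5]
            raise ValidationError(f"duplicate cell IDs: {list(dups)}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise ValidationError("count matrix contains missing values")
        if (arr < 0).any():
            g, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.values.index[g]!r}, "
                f"cell {self.values.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values[list(cell_ids)], self.ercc_mask, self.unit)


@dataclass
class GeneSetCollection:
    """Named gene sets (GO categories and curated lists).

    Sets may overlap; each is scored independently downstream. Member
    order is preserved, duplicates within a set are dropped.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "gene set %r: %d duplicated members dropped",
                    name, len(members) - len(unique),
                )
            if not unique:
                raise ValidationError(f"gene set {name!r} is empty")
            cleaned[name] = unique
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def items(self):
        return self.sets.items()


@dataclass
class AlignmentStats:
    """Per-cell read accounting used for the technical features.

    The table is indexed by cell ID and holds the eight columns in
    :data:`ALIGNMENT_COLUMNS`. Accounting invariants (mapped + unmapped
    <= total, exonic + non-exonic <= mapped, ...) are enforced.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ALIGNMENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"alignment stats missing columns: {missing}")
        self.table = self.table[list(ALIGNMENT_COLUMNS)].astype(np.int64)
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate cell IDs in alignment stats")
        t = self.table
        if (t.to_numpy() < 0).any():
            raise ValidationError("alignment stats contain negative counts")
        checks = [
            (t["mapped"] + t["unmapped"] > t["total_reads"],
             "mapped + unmapped > total_reads"),
            (t["exonic"] + t["non_exonic"] > t["mapped"],
             "exonic + non_exonic > mapped"),
            (t["duplicated"] > t["mapped"], "duplicated > mapped"),
            (t["ercc_reads"] > t["mapped"], "ercc_reads > mapped"),
        ]
        for bad, what in checks:
            if bad.any():
                cells = list(t.index[bad][:5])
                raise ValidationError(f"{what} for cells {cells}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_cells(self) -> int:
        return len(self.table)


@dataclass
class QualityLabels:
    """Per-cell HIGH/LOW annotation with optional subtype.

    LOW is the positive class throughout: a true positive is a
    correctly identified low-quality cell.
    """

    quality: pd.Series  # values in {HIGH, LOW}, index = cell IDs
    subtype: pd.Series | None = None

    def __post_init__(self) -> None:
        original = self.quality.astype(str)
        self.quality = original.str.upper()
        self.quality.index.name = None
        self.quality.name = None
        bad = ~self.quality.isin([HIGH, LOW])
        if bad.any():
            tok = original[bad.to_numpy()].iloc[0]
            raise ParseError(f"unknown quality label {tok!r}")
        if self.quality.index.duplicated().any():
            raise ValidationError("duplicate cell IDs in labels")
        if self.subtype is None:
            self.subtype = pd.Series("none", index=self.quality.index)
        else:
            self.subtype = self.subtype.fillna("none").astype(str).str.lower()
            self.subtype = self.subtype.reindex(self.quality.index, fill_value="none")
            bad = ~self.subtype.isin(SUBTYPES)
            if bad.any():
                tok = self.subtype[bad].iloc[0]
                raise ParseError(f"unknown quality subtype {tok!r}")
        self.subtype.name = None

    @property
    def cell_ids(self) -> list[str]:
        return list(self.quality.index)

    def is_low(self) -> pd.Series:
        """Boolean Series, True where the cell is labeled LOW."""
        return self.quality == LOW

    def reindex(self, cell_ids: Sequence[str]) -> "QualityLabels":
        missing = [c for c in cell_ids if c not in self.quality.index]
        if missing:
            raise ValidationError(f"labels missing for cells {missing[:5]}")
        return QualityLabels(
            self.quality.loc[list(cell_ids)], self.subtype.loc[list(cell_ids)]
        )

    def __len__(self) -> int:
        return len(self.quality)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def _mtx_sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.txt"), stem.with_suffix(".cells.txt")


def read_count_matrix(
    path: str | Path,
    format: str | None = None,
    ercc_prefix: str = DEFAULT_ERCC_PREFIX,
    unit: str = "raw_counts",
) -> CountMatrix:
    """Read a genes x cells matrix from TSV, CSV or MatrixMarket MTX.

    For MTX, two sibling files ``<stem>.genes.txt`` and
    ``<stem>.cells.txt`` supply row and column names. ``format`` is
    inferred from the suffix when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not ercc_prefix:
        raise ValidationError("ercc_prefix must be non-empty")
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValidationError(f"cannot infer format from {path.name!r}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            col = next(c for c, dt in df.dtypes.items()
                       if not np.issubdtype(dt, np.number))
            raise ParseError(f"{path}: non-numeric values in column {col!r}")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        genes_path, cells_path = _mtx_sidecar_paths(path)
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"missing MTX name file {p}")
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        genes = genes_path.read_text().split()
        cells = cells_path.read_text().split()
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"{path}: matrix shape {dense.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        df = pd.DataFrame(dense, index=genes, columns=cells)
    else:
        raise ValidationError(f"unknown format {format!r}")
    mask = np.asarray(df.index.str.startswith(ercc_prefix))
    return CountMatrix(df, mask, unit=unit)


def write_count_matrix(
    m: CountMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write a CountMatrix; the exact inverse of :func:`read_count_matrix`."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        values = m.values
        if np.allclose(values.to_numpy() % 1, 0):
            values = values.astype(np.int64)
        values.to_csv(path, sep=sep, index_label="gene_id")
    elif format == "mtx":
        genes_path, cells_path = _mtx_sidecar_paths(path)
        arr = m.values.to_numpy()
        if np.allclose(arr % 1, 0):
            sp = scipy.sparse.coo_matrix(arr.astype(np.int64))
        else:
            sp = scipy.sparse.coo_matrix(arr)
        scipy.io.mmwrite(str(path), sp)
        genes_path.write_text("\n".join(m.gene_ids) + "\n")
        cells_path.write_text("\n".join(m.cell_ids) + "\n")
    else:
        raise ValidationError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected >= 3 (name, description, members...)"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate gene set name {name!r}"
                )
            members = [g for g in fields[2:] if g]
            if not members:
                raise ValidationError(
                    f"{path}:{lineno}: gene set {name!r} has no members"
                )
            sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(
    gs: GeneSetCollection,
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in gs.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# alignment stats
# ---------------------------------------------------------------------------


def read_alignment_stats(path: str | Path) -> AlignmentStats:
    """Read a TSV of per-cell read accounting (header required)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "cell_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'cell_id' column")
    df = df.set_index("cell_id")
    df.index = df.index.astype(str)
    return AlignmentStats(df)


def write_alignment_stats(st: AlignmentStats, path: str | Path) -> None:
    st.table.to_csv(path, sep="\t", index_label="cell_id")


# ---------------------------------------------------------------------------
# labels and predictions
# ---------------------------------------------------------------------------


def read_labels(path: str | Path) -> QualityLabels:
    """Read a label TSV: cell_id, quality (HIGH/LOW), optional subtype."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns or "quality" not in df.columns:
        raise SchemaError(f"{path}: need 'cell_id' and 'quality' columns")
    df = df.set_index("cell_id")
    subtype = df["subtype"] if "subtype" in df.columns else None
    return QualityLabels(df["quality"], subtype)


def write_labels(labels: QualityLabels, path: str | Path) -> None:
    df = pd.DataFrame(
        {"quality": labels.quality, "subtype": labels.subtype},
        index=labels.quality.index,
    )
    df.to_csv(path, sep="\t", index_label="cell_id")


def write_predictions(
    path: str | Path,
    labels: QualityLabels,
    scores: pd.Series,
) -> None:
    """Write predicted quality and the ensemble LOW-vote fraction."""
    scores = scores.reindex(labels.quality.index)
    df = pd.DataFrame(
        {"quality": labels.quality, "low_vote_fraction": scores},
        index=labels.quality.index,
    )
    df.to_csv(path, sep="\t", index_label="cell_id", float_format="%.6g")


def read_predictions(path: str | Path) -> tuple[QualityLabels, pd.Series]:
    df = pd.read_csv(path, sep="\t").set_index("cell_id")
    labels = QualityLabels(df["quality"])
    return labels, df["low_vote_fraction"]
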