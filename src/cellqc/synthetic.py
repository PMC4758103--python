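"""Synthetic single-cell RNA-seq datasets with planted quality classes.

The generator emulates the structure the quality-control method
assumes: a gene-level log-normal expression program sampled with
negative-binomial (Gamma-Poisson) counting noise, ERCC spike-ins added
at a fixed absolute amount per well, and four cell classes —

* HIGH: intact cells at baseline library size;
* broken: the cell membrane ruptured before lysis, so cytoplasmic
  transcripts are lost (retention fraction < 1) while mitochondrially
  enclosed RNA (mtDNA-encoded genes) is retained and therefore
  relatively amplified; mapping rate drops and the non-exonic fraction
  rises; spike-ins, added in constant amounts, come to dominate;
* empty: a capture site without a cell — a tiny endogenous library
  dominated by the spike-ins;
* multiple: two cells in one site, giving an inflated library and more
  detected genes.

Defaults produce 200 cells with the 80/20 HIGH/LOW class imbalance of a
typical annotated training set. "Deceptive" cells — broken expression
profiles on cells a microscope would call intact — can be planted among
the HIGH cells and optionally mislabeled HIGH to exercise relabeling
workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cellqc.exceptions import ValidationError
from cellqc.io import (
    AlignmentStats,
    CountMatrix,
    GeneSetCollection,
    QualityLabels,
)

#: canonical role-set names; these double as biological feature names
ROLE_SETS = (
    "go_cytoplasm",
    "go_membrane",
    "go_mitochondrion",
    "go_metabolism",
    "go_extracellular_region",
    "go_ribosome",
    "go_programmed_cell_death",
    "housekeeping",
    "mtDNA_encoded",
    "mito_localized",
)


@dataclass
class SimulationParams:
    """Study conditions of the synthetic dataset.

    Class sizes default to 160 HIGH / 40 LOW (24 broken, 8 empty,
    8 multiple): the 80/20 imbalance of an annotated microfluidic
    training set. Effect sizes encode the broken-cell mechanism
    (cytoplasmic loss, relative mtDNA amplification, degraded mapping),
    spike-in dominance in empty wells, and library inflation in
    multiples.
    """

    n_high: int = 160
    n_broken: int = 24
    n_empty: int = 8
    n_multiple: int = 8
    n_genes: int = 2000
    n_ercc: int = 92
    # baseline library
    library_mean: float = 50_000.0
    library_sigma: float = 0.25  # log-normal sd of library size
    nb_dispersion: float = 0.2  # Gamma-Poisson overdispersion
    ercc_total_mean: float = 2_500.0  # absolute spike-in reads per well
    cell_noise_sigma: float = 0.25  # per-cell jitter of the gene program
    # broken-cell effects
    broken_retention: float = 0.2  # cytoplasmic RNA retained
    mtDNA_amplification: float = 2.0  # relative boost of mtDNA RNA
    mapped_rate_decrement: float = 0.15
    non_exonic_increment: float = 0.10
    # empty-well effects
    empty_endo_fraction: float = 0.01  # endogenous library vs baseline
    # multiples
    multiple_library_factor: float = 1.9
    # deceptive cells: fraction of nominal HIGH cells given broken profiles
    deceptive_fraction: float = 0.0
    mislabel_deceptive: bool = False
    # baseline alignment rates
    mapped_rate: float = 0.85
    non_exonic_rate: float = 0.18
    multimapped_rate: float = 0.05
    duplicated_rate: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_high, self.n_broken, self.n_empty, self.n_multiple) < 0:
            raise ValidationError("class sizes must be non-negative")
        if self.n_high + self.n_broken + self.n_empty + self.n_multiple < 2:
            raise ValidationError("need at least 2 cells")
        for name in ("broken_retention", "empty_endo_fraction",
                     "deceptive_fraction", "mapped_rate", "non_exonic_rate",
                     "multimapped_rate", "duplicated_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValidationError(f"{name} must be in [0, 1)")
        if self.mtDNA_amplification < 1:
            raise ValidationError("mtDNA_amplification must be >= 1")
        if self.n_genes < 200:
            raise ValidationError(
                "n_genes must exceed the designated gene sets (>= 200)"
            )


@dataclass
class _GeneProgram:
    base: np.ndarray  # relative expression, endogenous genes
    ercc: np.ndarray  # relative expression, spike-ins
    sets: dict[str, np.ndarray] = field(default_factory=dict)  # name -> index


def _build_program(p: SimulationParams, rng: np.random.Generator) -> _GeneProgram:
    base = rng.lognormal(mean=0.0, sigma=1.5, size=p.n_genes)
    ercc = rng.lognormal(mean=0.0, sigma=1.0, size=p.n_ercc)
    idx = rng.permutation(p.n_genes)
    n = p.n_genes
    sets: dict[str, np.ndarray] = {}
    sets["mtDNA_encoded"] = idx[:37]
    sets["mito_localized"] = idx[37 : 37 + max(40, int(0.075 * n))]
    rest = idx[37 + max(40, int(0.075 * n)) :]
    k = len(rest)
    sets["go_cytoplasm"] = rest[: int(0.55 * k)]
    # remaining role sets sampled independently (sets may overlap)
    fractions = {
        "go_membrane": 0.10,
        "go_metabolism": 0.15,
        "go_extracellular_region": 0.05,
        "go_ribosome": 0.04,
        "go_programmed_cell_death": 0.03,
        "housekeeping": 0.05,
    }
    for name, frac in fractions.items():
        sets[name] = rng.choice(n, size=max(5, int(frac * n)), replace=False)
    sets["go_mitochondrion"] = np.unique(
        np.concatenate([sets["mtDNA_encoded"], sets["mito_localized"]])
    )
    # mtDNA genes are strongly expressed in real cells; lift their base
    base[sets["mtDNA_encoded"]] *= 8.0
    return _GeneProgram(base=base, ercc=ercc, sets=sets)


def _nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-12)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate_dataset(
    p: SimulationParams | None = None,
) -> tuple[CountMatrix, AlignmentStats, GeneSetCollection, QualityLabels]:
    """Generate counts, alignment statistics, gene sets and labels."""
    p = p or SimulationParams()
    p.validate()
    rng = np.random.default_rng(p.seed)
    prog = _build_program(p, rng)

    mt = np.zeros(p.n_genes, dtype=bool)
    mt[prog.sets["mtDNA_encoded"]] = True
    mito_loc = np.zeros(p.n_genes, dtype=bool)
    mito_loc[prog.sets["mito_localized"]] = True

    classes = (
        ["high"] * p.n_high
        + ["broken"] * p.n_broken
        + ["empty"] * p.n_empty
        + ["multiple"] * p.n_multiple
    )
    n_deceptive = int(round(p.deceptive_fraction * p.n_high))
    deceptive_idx = set(
        rng.choice(p.n_high, size=n_deceptive, replace=False).tolist()
        if n_deceptive
        else []
    )

    counts = np.zeros((p.n_genes + p.n_ercc, len(classes)), dtype=np.int64)
    stats_rows = []
    quality, subtype = [], []

    def endo_expected(library: float) -> np.ndarray:
        noisy = prog.base * rng.lognormal(0.0, p.cell_noise_sigma, p.n_genes)
        return library * noisy / noisy.sum()

    def broken_profile(library: float) -> np.ndarray:
        mu = endo_expected(library)
        scale = np.full(p.n_genes, p.broken_retention)  # cytoplasmic loss
        scale[mito_loc] = np.sqrt(p.broken_retention)  # partially protected
        scale[mt] = p.mtDNA_amplification  # enclosed in mitochondria
        return mu * scale

    for j, cls in enumerate(classes):
        library = float(
            rng.lognormal(np.log(p.library_mean), p.library_sigma)
        )
        mapped_rate = float(
            np.clip(rng.normal(p.mapped_rate, 0.02), 0.3, 0.99)
        )
        ne_rate = float(np.clip(rng.normal(p.non_exonic_rate, 0.02), 0.01, 0.8))
        deceptive = cls == "high" and j in deceptive_idx

        if cls == "high" and not deceptive:
            mu = endo_expected(library)
        elif cls == "broken" or deceptive:
            mu = broken_profile(library)
            mapped_rate = max(0.05, mapped_rate - p.mapped_rate_decrement)
            ne_rate = min(0.9, ne_rate + p.non_exonic_increment)
        elif cls == "empty":
            mu = endo_expected(library * p.empty_endo_fraction)
        else:  # multiple: two cells in one site
            mu = endo_expected(library * p.multiple_library_factor / 2)
            mu = mu + endo_expected(library * p.multiple_library_factor / 2)

        endo = _nb_counts(mu, p.nb_dispersion, rng)
        ercc_total = rng.lognormal(np.log(p.ercc_total_mean), 0.2)
        ercc_mu = ercc_total * prog.ercc / prog.ercc.sum()
        ercc = _nb_counts(ercc_mu, p.nb_dispersion, rng)
        counts[: p.n_genes, j] = endo
        counts[p.n_genes :, j] = ercc

        exonic = int(endo.sum())
        ercc_reads = int(ercc.sum())
        non_exonic = int(round((exonic + ercc_reads) * ne_rate / (1 - ne_rate)))
        mapped = exonic + ercc_reads + non_exonic
        total = int(np.ceil(mapped / mapped_rate))
        dup_rate = p.duplicated_rate * (1.15 if cls == "multiple" else 1.0)
        stats_rows.append(
            {
                "total_reads": total,
                "mapped": mapped,
                "multimapped": int(rng.binomial(mapped, p.multimapped_rate)),
                "unmapped": total - mapped,
                "exonic": exonic + ercc_reads,
                "non_exonic": non_exonic,
                "duplicated": int(rng.binomial(mapped, min(dup_rate, 0.95))),
                "ercc_reads": ercc_reads,
            }
        )
        if cls == "high" and not deceptive:
            quality.append("HIGH")
            subtype.append("none")
        elif deceptive:
            quality.append("HIGH" if p.mislabel_deceptive else "LOW")
            subtype.append("deceptive")
        else:
            quality.append("LOW")
            subtype.append(cls)

    cell_ids = [f"cell_{j:04d}" for j in range(len(classes))]
    gene_ids = [f"gene_{g:05d}" for g in range(p.n_genes)] + [
        f"ERCC-{g:05d}" for g in range(p.n_ercc)
    ]
    values = pd.DataFrame(counts, index=gene_ids, columns=cell_ids)
    ercc_mask = np.array([g.startswith("ERCC-") for g in gene_ids])
    matrix = CountMatrix(values, ercc_mask, unit="raw_counts")
    stats = AlignmentStats(pd.DataFrame(stats_rows, index=pd.Index(cell_ids)))
    sets = GeneSetCollection(
        {
            name: [gene_ids[i] for i in np.sort(members)]
            for name, members in prog.sets.items()
        }
    )
    labels = QualityLabels(
        pd.Series(quality, index=cell_ids), pd.Series(subtype, index=cell_ids)
    )
    return matrix, stats, sets, labels


def simulate_celltype_feature_table(
    n_types: int = 3,
    n_cells_per_type: int = 40,
    n_features: int = 22,
    n_separating: int = 2,
    shift: float = 6.0,
    seed: int = 0,
):
    """A feature table for exercising the common-feature selection rule.

    Most features are cell-type independent standard normals; the first
    ``n_separating`` features carry a large between-type mean shift
    (alternating direction, so they occupy opposite extremes of the
    leading principal component) and should be removed by the loading
    rule.

    Returns ``(FeatureTable, separating_names, independent_names)``.
    """
    from cellqc.features import FeatureTable

    rng = np.random.default_rng(seed)
    n_cells = n_types * n_cells_per_type
    X = rng.normal(size=(n_cells, n_features))
    type_of_cell = np.repeat(np.arange(n_types), n_cells_per_type)
    for f in range(n_separating):
        if f % 2 == 0:
            offsets = np.arange(n_types) * shift
        else:
            offsets = np.arange(n_types)[::-1] * shift
        X[:, f] += offsets[type_of_cell]
    names = [f"feat_{i:02d}" for i in range(n_features)]
    cells = [f"cell_{i:04d}" for i in range(n_cells)]
    values = pd.DataFrame(X, index=cells, columns=names)
    kind = pd.Series("technical", index=values.columns)
    flag = pd.Series(False, index=values.columns)
    return (
        FeatureTable(values, kind, flag),
        names[:n_separating],
        names[n_separating:],
    )
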