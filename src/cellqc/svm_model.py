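"""Supervised classification of low-quality cells.

A radial-kernel support-vector machine with class weights (LOW is the
positive, minority class) is tuned by F-beta score over a grid of
(gamma, cost, class weight) via stratified cross-validation. Nested
cross-validation (an outer accuracy loop around the inner tuning loop)
estimates generalization without selection optimism. The final
predictor is an ensemble: the tuning run is repeated (default 50 times)
with reshuffled CV splits, one SVM is fitted per selected grid point,
and cells are classified by majority vote, with an exact tie resolved
to LOW — quality control should err toward discarding a questionable
cell.

The statsmodels-style entry points are :class:`CellQualityModel` (data
in) and :class:`CellQualityResults` (fitted ensemble out); the
module-level functions expose the individual steps.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from cellqc.exceptions import ModelIOError, ValidationError
from cellqc.features import FeatureTable
from cellqc.feature_selection import FeatureScaling, scale_features
from cellqc.io import HIGH, LOW, QualityLabels
from cellqc.quality_stats import MetricsReport

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SVMHyperparams:
    """One grid point: RBF width, soft-margin cost, LOW-class weight."""

    gamma: float
    cost: float
    class_weight_low: float = 1.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        if min(self.gamma, self.cost, self.class_weight_low, self.beta) <= 0:
            raise ValidationError("hyperparameters must be positive")


def default_grid(
    gammas: Sequence[float] | None = None,
    costs: Sequence[float] | None = None,
    class_weights: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
    beta: float = 2.0,
) -> list[SVMHyperparams]:
    """The default search grid: gamma 2^-10..2^2 and cost 2^-4..2^12 in
    powers of four, LOW-class weights {1, 2, 4, 8}."""
    if gammas is None:
        gammas = [2.0**e for e in range(-10, 4, 2)]
    if costs is None:
        costs = [2.0**e for e in range(-4, 13, 2)]
    return [
        SVMHyperparams(g, c, w, beta)
        for g in gammas
        for c in costs
        for w in class_weights
    ]


def small_grid(beta: float = 2.0) -> list[SVMHyperparams]:
    """A reduced 18-point grid for quick runs."""
    return default_grid(
        gammas=[2.0**-6, 2.0**-3, 1.0],
        costs=[0.5, 4.0, 32.0],
        class_weights=(1.0, 4.0),
        beta=beta,
    )


# ---------------------------------------------------------------------------
# internals on numpy arrays (y: 1 = LOW, 0 = HIGH)
# ---------------------------------------------------------------------------


def _fit_svc(X: np.ndarray, y: np.ndarray, hp: SVMHyperparams) -> SVC:
    clf = SVC(
        kernel="rbf",
        C=hp.cost,
        gamma=hp.gamma,
        class_weight={1: hp.class_weight_low, 0: 1.0},
        random_state=0,
    )
    clf.fit(X, y)
    return clf


def _scale_train_apply(
    X_train: np.ndarray, X_other: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    center = X_train.mean(axis=0)
    std = X_train.std(axis=0, ddof=1)
    std[std == 0] = 1.0
    return (X_train - center) / std, (X_other - center) / std


def _fold_fbeta(y_true: np.ndarray, y_pred: np.ndarray, beta: float) -> float:
    return MetricsReport(
        TP=int(((y_pred == 1) & (y_true == 1)).sum()),
        TN=int(((y_pred == 0) & (y_true == 0)).sum()),
        FP=int(((y_pred == 1) & (y_true == 0)).sum()),
        FN=int(((y_pred == 0) & (y_true == 1)).sum()),
        beta=beta,
    ).f_beta


def _search(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[SVMHyperparams],
    k: int,
    beta: float,
    seed: int,
) -> SVMHyperparams:
    if len(grid) == 0:
        raise ValidationError("empty hyperparameter grid")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("single class in labels; cannot tune an SVM")
    if counts.min() < k:
        raise ValidationError(
            f"need >= {k} members of each class for {k}-fold CV"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        (tr, te)
        for tr, te in skf.split(X, y)
        if len(np.unique(y[tr])) == 2
    ]
    scores = np.empty(len(grid))
    for i, hp in enumerate(grid):
        fold_scores = []
        for tr, te in folds:
            Xtr, Xte = _scale_train_apply(X[tr], X[te])
            clf = _fit_svc(Xtr, y[tr], hp)
            fold_scores.append(_fold_fbeta(y[te], clf.predict(Xte), beta))
        scores[i] = float(np.mean(fold_scores))
    best = scores.max()
    # ties broken toward the smoothest model: smaller cost, then gamma
    candidates = [
        hp for hp, s in zip(grid, scores) if s >= best - 1e-12
    ]
    candidates.sort(key=lambda hp: (hp.cost, hp.gamma, hp.class_weight_low))
    return candidates[0]


def _align(
    ft: FeatureTable, labels: QualityLabels
) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(ft.cell_ids)
    X = ft.values.to_numpy(dtype=float)
    y = labels.is_low().to_numpy().astype(int)
    return X, y


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def hyperparameter_search(
    ft: FeatureTable,
    labels: QualityLabels,
    grid: Sequence[SVMHyperparams] | None = None,
    k: int = 10,
    beta: float = 2.0,
    seed: int = 0,
) -> SVMHyperparams:
    """Pick the grid point maximizing mean F-beta over stratified k-fold
    CV; ties go to the smaller cost, then the smaller gamma."""
    grid = grid if grid is not None else default_grid(beta=beta)
    X, y = _align(ft, labels)
    return _search(X, y, grid, k, beta, seed)


@dataclass
class CVReport:
    """Outer-fold metrics and chosen hyperparameters of a nested CV."""

    folds: list[tuple[MetricsReport, SVMHyperparams]]
    beta: float

    def _collect(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m, _ in self.folds])

    @property
    def mean_sensitivity(self) -> float:
        return float(self._collect("sensitivity").mean())

    @property
    def mean_specificity(self) -> float:
        return float(self._collect("specificity").mean())

    @property
    def mean_f_beta(self) -> float:
        return float(self._collect("f_beta").mean())

    @property
    def sd_f_beta(self) -> float:
        return float(self._collect("f_beta").std(ddof=1))

    def summary(self) -> str:
        lines = [
            f"Nested cross-validation ({len(self.folds)} outer folds, "
            f"beta={self.beta:g})",
            f"{'fold':>4} {'sens':>6} {'spec':>6} {'F_b':>6} "
            f"{'gamma':>10} {'cost':>8} {'w_low':>6}",
        ]
        for i, (m, hp) in enumerate(self.folds, 1):
            lines.append(
                f"{i:>4} {m.sensitivity:6.3f} {m.specificity:6.3f} "
                f"{m.f_beta:6.3f} {hp.gamma:10.4g} {hp.cost:8.4g} "
                f"{hp.class_weight_low:6.3g}"
            )
        lines.append(
            f"mean sensitivity={self.mean_sensitivity:.3f} "
            f"specificity={self.mean_specificity:.3f} "
            f"F_beta={self.mean_f_beta:.3f}"
        )
        return "\n".join(lines)


def nested_cross_validation(
    ft: FeatureTable,
    labels: QualityLabels,
    grid: Sequence[SVMHyperparams] | None = None,
    k_outer: int = 10,
    k_inner: int = 10,
    beta: float = 2.0,
    seed: int = 0,
) -> CVReport:
    """Outer loop measures accuracy on held-out folds; inner loop tunes
    hyperparameters on the remaining folds only."""
    grid = grid if grid is not None else default_grid(beta=beta)
    X, y = _align(ft, labels)
    if np.bincount(y, minlength=2).min() < k_outer:
        raise ValidationError(
            f"need >= {k_outer} members of each class for the outer loop"
        )
    rng = np.random.RandomState(seed)
    inner_seeds = rng.randint(0, _MAX_SEED, size=k_outer)
    skf = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    folds = []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        hp = _search(X[tr], y[tr], grid, k_inner, beta, int(inner_seeds[i]))
        Xtr, Xte = _scale_train_apply(X[tr], X[te])
        clf = _fit_svc(Xtr, y[tr], hp)
        pred = clf.predict(Xte)
        m = MetricsReport(
            TP=int(((pred == 1) & (y[te] == 1)).sum()),
            TN=int(((pred == 0) & (y[te] == 0)).sum()),
            FP=int(((pred == 1) & (y[te] == 0)).sum()),
            FN=int(((pred == 0) & (y[te] == 1)).sum()),
            beta=beta,
        )
        folds.append((m, hp))
    return CVReport(folds=folds, beta=beta)


@dataclass
class EnsembleModel:
    """A majority-vote ensemble of tuned radial-kernel SVMs."""

    members: list[tuple[SVC, SVMHyperparams]]
    feature_names: list[str]
    scaling: FeatureScaling
    metadata: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def vote_fractions(self, ft: FeatureTable) -> pd.Series:
        missing = [f for f in self.feature_names if f not in ft.feature_names]
        if missing:
            raise ValidationError(f"feature table missing features: {missing}")
        extra = [f for f in ft.feature_names if f not in self.feature_names]
        if extra:
            logger.warning("ignoring %d extra features", len(extra))
        X = self.scaling.apply(
            FeatureTable(
                ft.values[self.feature_names],
                ft.kind.reindex(self.feature_names),
                ft.common_flag.reindex(self.feature_names),
            )
        ).values.to_numpy()
        votes = np.zeros(X.shape[0])
        for clf, _ in self.members:
            votes += clf.predict(X) == 1
        return pd.Series(votes / self.n_members, index=ft.values.index,
                         name="low_vote_fraction")

    def predict(self, ft: FeatureTable) -> tuple[QualityLabels, pd.Series]:
        frac = self.vote_fractions(ft)
        is_low = frac >= 0.5  # exact tie resolves to LOW
        quality = pd.Series(np.where(is_low, LOW, HIGH), index=frac.index)
        return QualityLabels(quality), frac


def train_ensemble(
    ft: FeatureTable,
    labels: QualityLabels,
    grid: Sequence[SVMHyperparams] | None = None,
    n_members: int = 50,
    k: int = 10,
    beta: float = 2.0,
    seed: int = 0,
) -> EnsembleModel:
    """Repeat the tuning run ``n_members`` times with reshuffled CV
    splits and fit one SVM per selected grid point on the full data."""
    if n_members < 1:
        raise ValidationError("n_members must be >= 1")
    grid = grid if grid is not None else default_grid(beta=beta)
    X_raw, y = _align(ft, labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("single class in labels; cannot train")
    scaled, scaling = scale_features(ft)
    X = scaled.values.to_numpy()
    rng = np.random.RandomState(seed)
    member_seeds = rng.randint(0, _MAX_SEED, size=n_members)
    members = []
    for s in member_seeds:
        hp = _search(X_raw, y, grid, k, beta, int(s))
        members.append((_fit_svc(X, y, hp), hp))
    metadata = {
        "seed": int(seed),
        "n_low": int(y.sum()),
        "n_high": int(len(y) - y.sum()),
        "beta": float(beta),
        "k": int(k),
        "version": SCHEMA_VERSION,
    }
    return EnsembleModel(members, list(ft.feature_names), scaling, metadata)


def predict(
    model: EnsembleModel, ft: FeatureTable
) -> tuple[QualityLabels, pd.Series]:
    """Majority-vote prediction; returns labels and LOW-vote fractions."""
    return model.predict(ft)


def save_model(model: EnsembleModel, path) -> None:
    """Serialize an ensemble to a single versioned archive."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "feature_names": model.feature_names,
        "scaling": {
            "center": model.scaling.center,
            "scale": model.scaling.scale,
            "zero_variance": model.scaling.zero_variance,
        },
        "members": model.members,
        "metadata": model.metadata,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=4)


def load_model(path) -> EnsembleModel:
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError, ValueError) as exc:
        raise ModelIOError(f"{path}: corrupt or truncated model file") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ModelIOError(f"{path}: not a cellqc model file")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise ModelIOError(
            f"{path}: schema version {payload['schema_version']} "
            f"not supported (expected {SCHEMA_VERSION})"
        )
    scaling = FeatureScaling(
        payload["scaling"]["center"],
        payload["scaling"]["scale"],
        payload["scaling"]["zero_variance"],
    )
    return EnsembleModel(
        payload["members"], payload["feature_names"], scaling, payload["metadata"]
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class CellQualityModel:
    """Cell-quality classification model.

    Built from a feature table and per-cell HIGH/LOW annotations;
    ``fit`` trains the SVM ensemble and returns a
    :class:`CellQualityResults`.

    Parameters
    ----------
    features
        FeatureTable of training cells.
    labels
        QualityLabels covering every training cell.
    common_only
        Restrict training to the cell-type-independent common features.
    """

    def __init__(
        self,
        features: FeatureTable,
        labels: QualityLabels,
        common_only: bool = False,
    ) -> None:
        if common_only:
            features = features.common_subset()
            if not features.feature_names:
                raise ValidationError("no common features present")
        self.features = features
        self.labels = labels.reindex(features.cell_ids)

    @classmethod
    def from_dataframe(
        cls,
        features: pd.DataFrame,
        quality: pd.Series,
        common_only: bool = False,
    ) -> "CellQualityModel":
        """Build from a plain cells x features DataFrame and a Series of
        HIGH/LOW labels (kind/common metadata inferred from names)."""
        from cellqc.features import COMMON_FEATURES

        kind = pd.Series(
            [
                "technical" if c.startswith(("prop_", "n_", "total_",
                                             "ercc_", "transcriptome",
                                             "cell_to_mean"))
                else "biological"
                for c in features.columns
            ],
            index=features.columns,
        )
        flag = pd.Series(
            [c in COMMON_FEATURES for c in features.columns],
            index=features.columns,
        )
        ft = FeatureTable(features, kind, flag)
        return cls(ft, QualityLabels(quality), common_only=common_only)

    def fit(
        self,
        n_members: int = 50,
        grid: Sequence[SVMHyperparams] | None = None,
        k: int = 10,
        beta: float = 2.0,
        seed: int = 0,
    ) -> "CellQualityResults":
        ensemble = train_ensemble(
            self.features, self.labels, grid=grid, n_members=n_members,
            k=k, beta=beta, seed=seed,
        )
        return CellQualityResults(self, ensemble)

    def cross_validate(
        self,
        grid: Sequence[SVMHyperparams] | None = None,
        k_outer: int = 10,
        k_inner: int = 10,
        beta: float = 2.0,
        seed: int = 0,
    ) -> CVReport:
        """Nested CV estimate of out-of-sample accuracy."""
        return nested_cross_validation(
            self.features, self.labels, grid=grid, k_outer=k_outer,
            k_inner=k_inner, beta=beta, seed=seed,
        )


class CellQualityResults:
    """Fitted ensemble plus training diagnostics."""

    def __init__(self, model: CellQualityModel, ensemble: EnsembleModel) -> None:
        self.model = model
        self.ensemble = ensemble

    @property
    def n_members(self) -> int:
        return self.ensemble.n_members

    @property
    def hyperparams(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gamma": hp.gamma, "cost": hp.cost,
                 "class_weight_low": hp.class_weight_low}
                for _, hp in self.ensemble.members
            ]
        )

    def predict(self, features) -> tuple[QualityLabels, pd.Series]:
        """Classify new cells; accepts a FeatureTable or DataFrame."""
        if isinstance(features, pd.DataFrame):
            kind = pd.Series("technical", index=features.columns)
            flag = pd.Series(False, index=features.columns)
            features = FeatureTable(features, kind, flag)
        return self.ensemble.predict(features)

    def training_metrics(self, beta: float | None = None) -> MetricsReport:
        from cellqc.quality_stats import classification_metrics

        pred, _ = self.ensemble.predict(self.model.features)
        beta = beta if beta is not None else self.ensemble.metadata["beta"]
        return classification_metrics(pred, self.model.labels, beta=beta)

    def save(self, path) -> None:
        save_model(self.ensemble, path)

    def summary(self) -> str:
        md = self.ensemble.metadata
        hp = self.hyperparams
        m = self.training_metrics()
        lines = [
            "Cell-quality SVM ensemble",
            "=" * 52,
            f"members:            {self.n_members}",
            f"features:           {len(self.ensemble.feature_names)}",
            f"training cells:     {md['n_high']} HIGH / {md['n_low']} LOW",
            f"beta (selection):   {md['beta']:g}",
            f"seed:               {md['seed']}",
            "selected hyperparameters (median [min, max]):",
            f"  gamma:            {hp['gamma'].median():.4g} "
            f"[{hp['gamma'].min():.4g}, {hp['gamma'].max():.4g}]",
            f"  cost:             {hp['cost'].median():.4g} "
            f"[{hp['cost'].min():.4g}, {hp['cost'].max():.4g}]",
            f"  LOW class weight: {hp['class_weight_low'].median():.3g} "
            f"[{hp['class_weight_low'].min():.3g}, "
            f"{hp['class_weight_low'].max():.3g}]",
            "training-set (resubstitution) performance:",
            f"  {m}",
        ]
        return "\n".join(lines)
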