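"""Gaussian-kernel SVM training, prediction and hyperparameter scanning.

The classifier is a soft-margin support vector machine with the RBF kernel
K(u, v) = exp(-gamma * ||u - v||^2), multiclass by one-vs-one voting (the
libsvm default).  The working defaults C = 16 and gamma = 0.001 were chosen
as a compromise between per-measurement accuracy and generalization; a
five-fold cross-validated grid scan over a wide (C, gamma) range is provided
to reproduce that choice on any dataset.

Normalization is always fitted on training data only — inside each
cross-validation fold on that fold's training split — so held-out windows
never leak into the feature scaling.  Sensor-subset masks (accelerometer-only
45 columns, gyroscope-only 69 columns) restrict the feature matrix before
the normalizer is fitted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .featurize import (
    DEFAULT_MANIFEST,
    FeatureDataset,
    FeatureSpec,
    NormalizationParams,
)
from .sensor_io import BehaviorCategory, ValidationError

__all__ = [
    "SvmConfig",
    "MASKS",
    "mask_columns",
    "TrainedModel",
    "train",
    "predict",
    "save_model",
    "load_model",
    "cross_validate",
    "grid_scan",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

#: Standard coarse scan grids (powers of two).
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-15, 4, 2))

MASKS = ("all", "acc_only", "gyro_only")


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameters: soft margin C and kernel width gamma."""

    C: float = 16.0
    gamma: float = 0.001

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


def mask_columns(
    manifest: Sequence[FeatureSpec] = DEFAULT_MANIFEST, mask: str = "all"
) -> np.ndarray:
    """Column indices selected by a sensor-subset mask.

    ``acc_only`` and ``gyro_only`` select exactly the features computed from
    that sensor alone; mixed-sensor features belong to neither subset.
    """
    if mask not in MASKS:
        raise ValueError(f"mask must be one of {MASKS}, got {mask!r}")
    if mask == "all":
        return np.arange(len(manifest))
    return np.array([i for i, s in enumerate(manifest) if s.group == mask])


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its normalizer and column mask."""

    svc: SVC
    norm: NormalizationParams
    mask: str
    columns: np.ndarray
    feature_names: tuple[str, ...]
    categories: tuple[BehaviorCategory, ...]
    config: SvmConfig


def _class_codes(ds: FeatureDataset) -> np.ndarray:
    return np.array([c.value for c in ds.y])


def train(
    ds: FeatureDataset,
    cfg: SvmConfig = SvmConfig(),
    mask: str = "all",
) -> TrainedModel:
    """Fit the RBF-SVM on *ds* (normalizer fitted on *ds* only).

    Deterministic given identical input ordering.  Raises if fewer than two
    categories are present or if any selected feature is non-finite.
    """
    if len(ds) == 0:
        raise ValidationError("cannot train on an empty dataset")
    cats = sorted({c for c in ds.y}, key=lambda c: c.value)
    if len(cats) < 2:
        raise ValidationError("training data must contain at least 2 categories")
    cols = _columns_for(ds.feature_names, mask)
    Xm = ds.X[:, cols]
    if not np.isfinite(Xm).all():
        raise ValidationError("training features contain non-finite values")
    norm = NormalizationParams.fit(Xm)
    svc = SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf")
    svc.fit(norm.transform(Xm), _class_codes(ds))
    return TrainedModel(
        svc=svc, norm=norm, mask=mask, columns=cols,
        feature_names=ds.feature_names, categories=tuple(cats), config=cfg,
    )


def _columns_for(feature_names: tuple[str, ...], mask: str) -> np.ndarray:
    """Resolve a mask against a dataset's feature names via the manifest."""
    if mask not in MASKS:
        raise ValueError(f"mask must be one of {MASKS}, got {mask!r}")
    if mask == "all":
        return np.arange(len(feature_names))
    by_name = {s.name: s.group for s in DEFAULT_MANIFEST}
    groups = [by_name.get(n) for n in feature_names]
    if any(g is None for g in groups):
        raise ValidationError(
            "sensor-subset masks require manifest-named features"
        )
    return np.array([i for i, g in enumerate(groups) if g == mask])


def predict(model: TrainedModel, ds: FeatureDataset) -> np.ndarray:
    """Predict one category per window (no abstention).

    The model applies its own column mask and normalizer; the dataset must
    carry the same feature manifest the model was trained with.
    """
    if ds.feature_names != model.feature_names:
        raise ValidationError("feature manifest mismatch between model and data")
    if len(ds) == 0:
        return np.empty(0, dtype=object)
    Xm = ds.X[:, model.columns]
    if not np.isfinite(Xm).all():
        raise ValidationError("prediction features contain non-finite values")
    labels = model.svc.predict(model.norm.transform(Xm))
    return np.array([BehaviorCategory(v) for v in labels], dtype=object)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the model (classifier + normalizer + mask) as one archive."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise ValidationError(f"{path} does not contain a TrainedModel")
    return model


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


def _stratified_splits(
    ds: FeatureDataset, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    if folds < 2:
        raise ValueError("folds must be >= 2")
    codes = _class_codes(ds)
    _, counts = np.unique(codes, return_counts=True)
    if counts.min() < folds:
        raise ValidationError(
            f"a category has only {counts.min()} windows, fewer than "
            f"{folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(ds.X, codes))


def cross_validate(
    ds: FeatureDataset,
    cfg: SvmConfig = SvmConfig(),
    mask: str = "all",
    folds: int = 5,
    seed: int = 0,
    return_details: bool = False,
):
    """Stratified seeded k-fold CV accuracy (fraction in [0, 1]).

    The min-max normalizer is refitted inside each fold on the training
    split only.  With ``return_details`` also returns the per-fold
    accuracies and normalizers (useful for leakage auditing).
    """
    cols = _columns_for(ds.feature_names, mask)
    codes = _class_codes(ds)
    accs, norms = [], []
    for tr_idx, te_idx in _stratified_splits(ds, folds, seed):
        Xtr = ds.X[np.ix_(tr_idx, cols)]
        norm = NormalizationParams.fit(Xtr)
        svc = SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf")
        svc.fit(norm.transform(Xtr), codes[tr_idx])
        pred = svc.predict(norm.transform(ds.X[np.ix_(te_idx, cols)]))
        accs.append(float(np.mean(pred == codes[te_idx])))
        norms.append(norm)
    accuracy = float(np.mean(accs))
    if return_details:
        return accuracy, accs, norms
    return accuracy


def grid_scan(
    ds: FeatureDataset,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
    mask: str = "all",
) -> pd.DataFrame:
    """Scan (C, gamma) with stratified k-fold CV; one row per grid cell.

    Folds are fixed across cells (seeded shuffle) and the normalizer is
    refitted per fold, so cells are directly comparable.  Returns a
    DataFrame with columns C, gamma, cv_accuracy.
    """
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("scan grids must be non-empty")
    cols = _columns_for(ds.feature_names, mask)
    codes = _class_codes(ds)
    splits = _stratified_splits(ds, folds, seed)
    # precompute per-fold normalized matrices once
    prepared = []
    for tr_idx, te_idx in splits:
        Xtr = ds.X[np.ix_(tr_idx, cols)]
        norm = NormalizationParams.fit(Xtr)
        prepared.append(
            (norm.transform(Xtr), codes[tr_idx],
             norm.transform(ds.X[np.ix_(te_idx, cols)]), codes[te_idx])
        )
    rows = []
    for C, gamma in itertools.product(C_grid, gamma_grid):
        accs = []
        for Ztr, ytr, Zte, yte in prepared:
            svc = SVC(C=C, gamma=gamma, kernel="rbf")
            svc.fit(Ztr, ytr)
            accs.append(float(np.mean(svc.predict(Zte) == yte)))
        rows.append({"C": C, "gamma": gamma, "cv_accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)
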