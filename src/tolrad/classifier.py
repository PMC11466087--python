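"""Train, evaluate, persist, and apply the random-forest tolerance classifier.

The classifier consumes per-genome relative Pfam-domain frequencies over
a fixed predictor set and votes each genome *radiosensitive* or
*tolerant*.  Genomes missing too many predictor domains (frequency
exactly 0 for ≥ 2 predictors by default) are excluded from
classification rather than silently classified, mirroring how incomplete
metagenome-assembled genomes are handled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from tolrad import _importance
from tolrad.annotations_io import FrequencyTable
from tolrad.labels import RADIOSENSITIVE, TOLERANT

__all__ = [
    "TrainedModel",
    "ClassificationReport",
    "train",
    "predict",
    "permutation_importance",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainedModel:
    """A fitted forest plus its predictor domains and training metadata."""

    predictor_domains: list[str]
    forest: RandomForestClassifier
    n_trees: int
    mtry: int
    cv_accuracy: float
    class_labels: tuple[str, str] = (RADIOSENSITIVE, TOLERANT)
    training_meta: dict = field(default_factory=dict)


@dataclass
class ClassificationReport:
    """Per-genome predictions with missing-predictor accounting.

    Columns: genome_id, predicted_class (empty for excluded rows),
    vote_fraction_radiosensitive, n_zero_predictors, excluded.
    """

    frame: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        df = self.frame.copy()
        df["vote_fraction_radiosensitive"] = df["vote_fraction_radiosensitive"].map(
            lambda v: "" if pd.isna(v) else f"{v:.6f}"
        )
        df["predicted_class"] = df["predicted_class"].fillna("")
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, FrequencyTable):
        return X.frequencies
    return pd.DataFrame(X)


def train(
    X,
    y,
    cv_folds: int = 10,
    n_trees: int = 500,
    seed: int = 0,
) -> TrainedModel:
    """Fit the forest, tuning mtry over {1..n_predictors} by stratified CV.

    The number of features tried at each split (mtry) is selected by
    stratified ``cv_folds``-fold cross-validated accuracy (ties go to the
    smallest mtry); the final forest is refit on all data at the best
    mtry.  Deterministic for a fixed seed.
    """
    df = _as_frame(X)
    y = np.asarray(y)
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training needs both classes present")
    if cv_folds > class_counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds smallest class size ({class_counts.min()})"
        )
    if cv_folds > len(y):
        raise ValueError("fewer genomes than folds")
    Xv = df.to_numpy(dtype=np.float64)
    n_feat = df.shape[1]
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_mtry, best_acc = 1, -1.0
    for mtry in range(1, n_feat + 1):
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features=mtry, random_state=seed
        )
        acc = float(np.mean(cross_val_score(forest, Xv, y, cv=cv)))
        if acc > best_acc:
            best_mtry, best_acc = mtry, acc
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=best_mtry, random_state=seed, oob_score=True
    )
    forest.fit(df, y)  # DataFrame fit records feature_names_in_
    meta = {
        "seed": int(seed),
        "cv_folds": int(cv_folds),
        "cohort_size": int(len(y)),
        "class_counts": {str(c): int(n) for c, n in zip(classes, class_counts)},
        "sklearn_version": sklearn.__version__,
    }
    return TrainedModel(
        predictor_domains=list(df.columns),
        forest=forest,
        n_trees=n_trees,
        mtry=best_mtry,
        cv_accuracy=best_acc,
        class_labels=(RADIOSENSITIVE, TOLERANT),
        training_meta=meta,
    )


def _vote_fractions(model: TrainedModel, Xv: np.ndarray) -> np.ndarray:
    """Fraction of trees voting radiosensitive for each row."""
    classes = list(model.forest.classes_)
    rs_idx = classes.index(RADIOSENSITIVE)
    preds = _importance.tree_votes(model.forest, Xv.astype(np.float32))
    return (preds == rs_idx).mean(axis=1)


def predict(
    model: TrainedModel, table, exclusion_threshold: int = 2
) -> ClassificationReport:
    """Classify each genome, excluding those missing too many predictors.

    A predictor is *missing* when its relative frequency is exactly 0.
    Genomes with ``n_zero_predictors >= exclusion_threshold`` are
    excluded and carry no predicted class.  For the rest, the class is
    the majority tree vote; exactly tied votes go to tolerant.
    """
    df = _as_frame(table)
    if df.shape[0] == 0:
        raise ValueError("empty table: nothing to classify")
    order = list(model.forest.feature_names_in_)
    df = df.reindex(columns=order, fill_value=0.0)
    n_zero = (df.to_numpy() == 0.0).sum(axis=1).astype(int)
    excluded = n_zero >= exclusion_threshold
    vote_rs = np.full(df.shape[0], np.nan)
    if (~excluded).any():
        vote_rs[~excluded] = _vote_fractions(model, df.to_numpy()[~excluded])
    pred = np.where(vote_rs > 0.5, RADIOSENSITIVE, TOLERANT).astype(object)
    pred[excluded] = None
    frame = pd.DataFrame(
        {
            "genome_id": list(df.index),
            "predicted_class": pred,
            "vote_fraction_radiosensitive": vote_rs,
            "n_zero_predictors": n_zero,
            "excluded": excluded,
        }
    )
    return ClassificationReport(frame=frame)


def permutation_importance(
    model: TrainedModel, X, y, n_repeats: int = 20, seed: int = 0
) -> dict[str, float]:
    """Permutation mean decrease in accuracy per predictor, percent scale.

    Out-of-bag accuracy minus mean accuracy over ``n_repeats``
    independent permutations of each column, averaged over trees,
    multiplied by 100.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    df = _as_frame(X)
    order = list(model.forest.feature_names_in_)
    df = df.reindex(columns=order, fill_value=0.0)
    rng = np.random.default_rng(seed)
    mda = _importance.oob_mda(
        model.forest, df.to_numpy(dtype=np.float64), np.asarray(y), rng, n_repeats=n_repeats
    )
    return {feat: float(100.0 * v) for feat, v in zip(order, mda)}


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model bundle: ``model.json`` sidecar + joblib ensemble."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "format_version": MODEL_FORMAT_VERSION,
        "predictor_domains": model.predictor_domains,
        "n_trees": model.n_trees,
        "mtry": model.mtry,
        "cv_accuracy": model.cv_accuracy,
        "class_labels": list(model.class_labels),
        "training_meta": model.training_meta,
    }
    (path / "model.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    joblib.dump(model.forest, path / "forest.joblib")


def load_model(path: str | Path) -> TrainedModel:
    """Load a model bundle written by :func:`save_model`.

    Predictions are insensitive to the order of the sidecar's predictor
    list: the design-matrix column order is taken from the fitted forest
    itself.
    """
    path = Path(path)
    try:
        sidecar = json.loads((path / "model.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read model sidecar at {path/'model.json'}: {exc}") from exc
    version = sidecar.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version mismatch: bundle has {version!r}, "
            f"this package reads {MODEL_FORMAT_VERSION!r}"
        )
    forest = joblib.load(path / "forest.joblib")
    return TrainedModel(
        predictor_domains=list(sidecar["predictor_domains"]),
        forest=forest,
        n_trees=int(sidecar["n_trees"]),
        mtry=int(sidecar["mtry"]),
        cv_accuracy=float(sidecar["cv_accuracy"]),
        class_labels=tuple(sidecar["class_labels"]),
        training_meta=dict(sidecar.get("training_meta", {})),
    )
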