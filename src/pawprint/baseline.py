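"""Expert-measures baseline: standard classifiers over the six kinematic
measures, under the same grouped cross-validation folds as the sequence
classifier, plus a principal-component view of the measure space.

The point of this baseline is the contrast it sets up: hand-designed
per-trial summary measures discard temporal structure, so when the
groups differ only in *when* movements happen (periodic stereotypy) the
baseline hovers near chance while the sequence classifier does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["BaselineReport", "PCAResult", "MODEL_NAMES", "fit_baselines", "pca_projection"]

MODEL_NAMES = (
    "decision_tree",
    "random_forest",
    "logistic_regression",
    "k_nearest_neighbors",
    "support_vector_machine",
)


def _make_models(seed: int) -> dict:
    return {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
        "logistic_regression": LogisticRegression(max_iter=1000, random_state=seed),
        "k_nearest_neighbors": KNeighborsClassifier(),
        "support_vector_machine": SVC(random_state=seed),
    }


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_trials, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_measures, n_components)
    class_overlap: float | None = None


@dataclass
class BaselineReport:
    accuracies: dict  # model name -> cross-validated accuracy
    predictions: pd.DataFrame  # out-of-fold predicted label per model
    fold_scheme: str
    pca: PCAResult | None = None
    dropped_columns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, acc in self.accuracies.items():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"{name}: accuracy {acc} outside [0, 1]")


def _clean_measures(measure_table: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    dropped = [c for c in measure_table.columns if measure_table[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant measure columns: {dropped}", stacklevel=3)
    return measure_table.drop(columns=dropped), dropped


def fit_baselines(
    measure_table: pd.DataFrame,
    labels,
    folds,
    seed: int = 0,
) -> BaselineReport:
    """Cross-validated accuracy of five standard classifier families.

    ``measure_table`` holds one row per trial (the six measures);
    ``folds`` is a fold index per trial (same grouped scheme as the
    sequence classifier).  Measures are z-scored on the training folds
    only; each model family uses library-default hyperparameters with a
    fixed seed.
    """
    labels = np.asarray(labels)
    folds = np.asarray(folds)
    X_df, dropped = _clean_measures(measure_table)
    X = X_df.to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise ValueError("no non-constant measure columns remain")
    preds = pd.DataFrame(index=measure_table.index, columns=MODEL_NAMES, dtype=object)
    accuracies = {}
    for name in MODEL_NAMES:
        out = np.empty(len(labels), dtype=object)
        for fold in np.unique(folds):
            test = folds == fold
            train = ~test
            if len(np.unique(labels[train])) < 2:
                raise ValueError(f"fold {fold}: training labels are single-class")
            pipe = make_pipeline(StandardScaler(), _make_models(seed)[name])
            pipe.fit(X[train], labels[train])
            out[test] = pipe.predict(X[test])
        preds[name] = out
        accuracies[name] = float(np.mean(out == labels))
    return BaselineReport(
        accuracies=accuracies,
        predictions=preds,
        fold_scheme=f"grouped {len(np.unique(folds))}-fold",
        dropped_columns=dropped,
    )


def pca_projection(
    measure_table: pd.DataFrame,
    labels=None,
    n_components: int | None = None,
    standardize: bool = True,
) -> PCAResult:
    """Standardize the measures and project them onto principal components.

    ``standardize=False`` runs plain centered PCA (whose variance
    spectrum is invariant to orthogonal rotation of the inputs; per-
    measure z-scoring, the default, deliberately is not).
    ``class_overlap`` (when labels are given) is the within-class share
    of total variance of the PC scores, in [0, 1]: ~1 means the classes
    occupy the same region of measure space, smaller values mean
    separation.
    """
    X = measure_table.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("PCA needs at least 2 trials and 2 measures")
    if n_components is not None and n_components > min(n, m):
        raise ValueError(
            f"cannot extract {n_components} components from {n} trials x {m} measures"
        )
    Xs = StandardScaler().fit_transform(X) if standardize else X - X.mean(axis=0)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xs)
    overlap = None
    if labels is not None:
        labels = np.asarray(labels)
        total = scores.var(axis=0).sum()
        within = sum(
            scores[labels == g].var(axis=0).sum() * np.mean(labels == g)
            for g in np.unique(labels)
        )
        overlap = float(within / total) if total > 0 else 1.0
    return PCAResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pca.components_.T,
        class_overlap=overlap,
    )
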