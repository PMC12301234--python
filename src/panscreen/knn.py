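"""KNN triage workflow: training-set assembly, F-beta scoring and
grid-search hyperparameter tuning over PCA components x neighbor count.

The workflow mirrors a screening-campaign triage: binder/non-binder labels
from binding measurements (optionally supplemented with round-4-enriched
positives and library-background negatives), sequence descriptors, z-score
normalization, PCA, and a k-nearest-neighbor classifier tuned by
cross-validated F-beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .features import NormalizationStats, SignFixedPCA, featurize, normalize


class ClassImbalanceError(ValueError):
    pass


class StratificationError(ValueError):
    pass


@dataclass
class TrainingSet:
    sequences: list[str]
    labels: np.ndarray  # 1 = binder, 0 = non-binder
    provenance: list[str]
    conflict_count: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary")


def build_training_set(
    spr_labels: Sequence[tuple[str, bool]] = (),
    round4_enriched: Sequence[str] = (),
    initial_library_sample: Sequence[str] = (),
    neg_sample_size: int | None = None,
    seed: int = 0,
) -> TrainingSet:
    """Assemble binder/non-binder training data.

    Positives: measured binders plus round-4-enriched variants. Negatives:
    measured non-binders plus a seeded random draw from the initial library.
    A sequence appearing with conflicting labels is resolved to binder and
    counted in ``conflict_count``.
    """
    rng = np.random.default_rng(seed)
    entries: dict[str, tuple[int, str]] = {}
    conflicts = 0

    def add(seq: str, label: int, prov: str):
        nonlocal conflicts
        if seq in entries:
            old_label, old_prov = entries[seq]
            if old_label != label:
                conflicts += 1
            entries[seq] = (max(old_label, label),
                            old_prov if old_label >= label else prov)
        else:
            entries[seq] = (label, prov)

    for seq, is_binder in spr_labels:
        add(seq, int(bool(is_binder)), "spr")
    for seq in round4_enriched:
        add(seq, 1, "enriched_r4")
    pool = list(initial_library_sample)
    if pool and neg_sample_size:
        idx = rng.choice(len(pool), size=min(neg_sample_size, len(pool)),
                         replace=False)
        for i in sorted(int(j) for j in idx):
            add(pool[i], 0, "library_background")
    seqs = sorted(entries)
    labels = np.array([entries[s][0] for s in seqs])
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ClassImbalanceError("training set needs both classes")
    return TrainingSet(sequences=seqs, labels=labels,
                       provenance=[entries[s][1] for s in seqs],
                       conflict_count=conflicts)


def fbeta(precision: float, recall: float, beta: float) -> float:
    """F-beta score: (1+b^2) P R / (b^2 P + R); 0 when the denominator is 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    denom = beta**2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


def fbeta_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                           beta: float) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return fbeta(precision, recall, beta)


DEFAULT_GRID = {"pca_components": (2, 5, 10, 15), "k_neighbors": (3, 5, 7, 9)}


@dataclass
class KnnTriageModel:
    pca_components: int
    k_neighbors: int
    beta: float
    stats: NormalizationStats
    projection: SignFixedPCA
    classifier: KNeighborsClassifier
    tuning_record: pd.DataFrame = field(repr=False, default=None)
    best_score: float = float("nan")

    def _project(self, sequences: Sequence[str]) -> np.ndarray:
        matrix, errors = featurize(list(sequences))
        if errors:
            raise ValueError(f"{len(errors)} sequences with non-standard residues")
        return self.projection.transform(self.stats.apply(matrix).to_numpy())

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        return self.classifier.predict(self._project(sequences))

    def predict_proba(self, sequences: Sequence[str]) -> np.ndarray:
        return self.classifier.predict_proba(self._project(sequences))[:, 1]


def tune_knn(
    training: TrainingSet,
    grid: dict | None = None,
    beta: float = 1.0,
    cv_folds: int = 5,
    seed: int = 0,
) -> KnnTriageModel:
    """Grid-search (PCA components x k) by mean cross-validated F-beta.

    Ties resolve to fewer components, then smaller k. The selected model is
    refit on all training data. ``k`` must be odd (tie avoidance) and grid
    points infeasible for the data (components above rank, k above the
    smallest training fold) are skipped.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    comps_grid = sorted(grid["pca_components"])
    k_grid = sorted(grid["k_neighbors"])
    if not comps_grid or not k_grid:
        raise ValueError("grid must be non-empty")
    if any(k % 2 == 0 for k in k_grid):
        raise ValueError("k_neighbors must be odd")
    matrix, errors = featurize(training.sequences)
    if errors:
        raise ValueError(f"{len(errors)} training sequences with non-standard residues")
    y = training.labels
    if min(np.bincount(y, minlength=2)) < cv_folds:
        raise StratificationError(
            "too few members of a class for the requested fold count")
    X = matrix.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    records = []
    for n_comp in comps_grid:
        for k in k_grid:
            scores = []
            feasible = True
            for train_idx, val_idx in skf.split(X, y):
                if len(np.unique(y[train_idx])) < 2:
                    raise StratificationError("single-class training fold")
                if k > len(train_idx):
                    feasible = False
                    break
                df_train = matrix.iloc[train_idx]
                z_train, stats = normalize(df_train)
                rank = min(len(train_idx) - 1, z_train.shape[1])
                if n_comp > rank:
                    feasible = False
                    break
                proj = SignFixedPCA(n_comp).fit(z_train.to_numpy())
                clf = KNeighborsClassifier(n_neighbors=k)
                clf.fit(proj.transform(z_train.to_numpy()), y[train_idx])
                z_val = stats.apply(matrix.iloc[val_idx]).to_numpy()
                pred = clf.predict(proj.transform(z_val))
                scores.append(fbeta_from_predictions(y[val_idx], pred, beta))
            if feasible:
                records.append({"pca_components": n_comp, "k_neighbors": k,
                                "fbeta": float(np.mean(scores))})
    if not records:
        raise ValueError("no feasible grid point")
    record = pd.DataFrame(records)
    best = record.sort_values(
        by=["fbeta", "pca_components", "k_neighbors"],
        ascending=[False, True, True], kind="mergesort").iloc[0]
    n_comp, k = int(best["pca_components"]), int(best["k_neighbors"])
    z_all, stats = normalize(matrix)
    proj = SignFixedPCA(n_comp).fit(z_all.to_numpy())
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(proj.transform(z_all.to_numpy()), y)
    return KnnTriageModel(pca_components=n_comp, k_neighbors=k, beta=beta,
                          stats=stats, projection=proj, classifier=clf,
                          tuning_record=record, best_score=float(best["fbeta"]))
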