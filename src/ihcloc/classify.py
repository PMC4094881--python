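"""Binary-relevance SVM multilabel classifier.

"Cross-training": one binary classifier per subcellular class; all training
samples carrying the class are its positives, everything else negative.
Each per-class scorer is an RBF-kernel SVM whose (C, gamma) pair is chosen
by cross-validated grid search on the training data.  Scores are signed
decision values (margins) — the decision-threshold grid of the evaluation
stage is in margin units.

The stage follows the Model/Results convention: ``BinaryRelevanceSVM``
holds the data and configuration, ``fit()`` returns a
``BinaryRelevanceResults`` carrying the trained scorers, the selected
hyperparameters and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .core import CLASS_NAMES, Dataset, N_CLASSES, ProteinRecord

log = logging.getLogger(__name__)

#: Paper-scale hyperparameter grid: C = 2^-5..2^15, gamma = 2^-15..2^3,
#: both stepped by a factor of 4.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


def protein_twofold_split(
    dataset: Dataset, seed: int = 0
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Protein-level 2-fold partition, stratified by label set where possible.

    No protein's images span folds, so each fold is independent of the
    other at the protein level.  Proteins are grouped by label set and each
    group is split as evenly as possible between the folds.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    by_labelset: dict[frozenset[int], list[ProteinRecord]] = {}
    for rec in dataset.records:
        by_labelset.setdefault(rec.label_set, []).append(rec)

    folds: tuple[list[ProteinRecord], list[ProteinRecord]] = ([], [])
    parity = 0
    for labelset in sorted(by_labelset, key=lambda s: sorted(s)):
        group = by_labelset[labelset]
        order = rng.permutation(len(group))
        for i, gi in enumerate(order):
            folds[(i + parity) % 2].append(group[gi])
        parity += len(group)  # balance odd-sized groups across label sets

    _repair_label_coverage(folds)

    for l in range(1, N_CLASSES + 1):
        carriers = sum(1 for r in dataset.records if l in r.label_set)
        for f in (0, 1):
            if carriers >= 2 and not any(l in r.label_set for r in folds[f]):
                log.warning("label %d missing from fold %d despite %d carriers",
                            l, f, carriers)
        if carriers == 1:
            log.warning("label %d carried by a single protein; untestable in "
                        "one fold", l)
    return folds


def _repair_label_coverage(folds) -> None:
    """Move proteins between folds so every label with >= 2 carriers
    appears in both folds (deterministic greedy repair)."""
    for l in range(1, N_CLASSES + 1):
        have = [any(l in r.label_set for r in folds[f]) for f in (0, 1)]
        if all(have) or not any(have):
            continue
        src, dst = (0, 1) if have[0] else (1, 0)
        carriers = sorted((r for r in folds[src] if l in r.label_set),
                          key=lambda r: (len(r.label_set), r.protein_id))
        if len(carriers) < 2:
            continue  # single carrier: genuinely untestable in one fold
        mover = carriers[0]
        folds[src].remove(mover)
        folds[dst].append(mover)
        # keep fold sizes near-even: send back a protein that is not the
        # last carrier of any of its labels in the destination fold
        if len(folds[dst]) - len(folds[src]) > 1:
            for cand in sorted(folds[dst], key=lambda r: r.protein_id):
                if cand is mover:
                    continue
                safe = all(
                    sum(1 for r in folds[dst] if lbl in r.label_set) > 1
                    for lbl in cand.label_set)
                if safe:
                    folds[dst].remove(cand)
                    folds[src].append(cand)
                    break


def label_matrix(records: list[ProteinRecord]) -> np.ndarray:
    """Stack per-image +/-1 label vectors for all images of the records."""
    return np.array([rec.label_vector() for rec in records
                     for _ in rec.images])


@dataclass
class _ConstantScorer:
    """Fallback when a label has a single class in training."""

    value: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.value)


@dataclass
class BinaryRelevanceResults:
    """Fitted binary-relevance model: 6 scorers plus preprocessing state."""

    scorers: list
    params: list[dict]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES
    threshold: float | None = None
    selected_features: list[int] | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != len(self.scaler_mean):
            raise ValueError(
                f"expected {len(self.scaler_mean)} features, got {X.shape[1]}")
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, 6) signed decision values, one column per class."""
        Z = self._transform(X)
        return np.column_stack([s.decision_function(Z) for s in self.scorers])

    def score(self, x: np.ndarray) -> np.ndarray:
        """6-vector of decision values for a single sample."""
        return self.decision_scores(np.atleast_2d(x))[0]

    def summary(self) -> str:
        lines = ["Binary-relevance RBF-SVM", "=" * 40,
                 f"{'class':<14}{'C':>10}{'gamma':>12}"]
        for name, p in zip(self.class_names, self.params):
            if p.get("constant"):
                lines.append(f"{name:<14}{'constant scorer':>22}")
            else:
                lines.append(f"{name:<14}{p['C']:>10.4g}{p['gamma']:>12.4g}")
        if self.threshold is not None:
            lines.append(f"decision threshold T = {self.threshold:.2f}")
        return "\n".join(lines)


@dataclass
class BinaryRelevanceSVM:
    """Model object: features X (n, p) and +/-1 label matrix Y (n, 6)."""

    X: np.ndarray
    Y: np.ndarray
    standardize: bool = True
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    inner_cv: int = 3
    seed: int = 0
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.Y = np.asarray(self.Y, float)
        if self.X.ndim != 2 or self.Y.shape != (self.X.shape[0], N_CLASSES):
            raise ValueError("X must be (n, p) and Y (n, 6)")
        if not set(np.unique(self.Y)) <= {-1.0, 1.0}:
            raise ValueError("Y must be coded +/-1")

    @classmethod
    def from_dataframe(cls, df, label_cols=None, **kwargs):
        """Build from a DataFrame whose label columns are coded +/-1."""
        if label_cols is None:
            label_cols = [f"label_{n}" for n in CLASS_NAMES]
        Y = df[label_cols].to_numpy(float)
        X = df.drop(columns=label_cols).select_dtypes("number").to_numpy(float)
        return cls(X, Y, **kwargs)

    def target_matrix(self) -> np.ndarray:
        """0/1 cross-training targets: column l marks the positives of
        classifier l (samples whose label set contains class l)."""
        return (self.Y > 0).astype(int)

    def fit(self) -> BinaryRelevanceResults:
        if self.standardize:
            mean = self.X.mean(axis=0)
            scale = self.X.std(axis=0)
            scale[scale == 0] = 1.0
        else:
            mean = np.zeros(self.X.shape[1])
            scale = np.ones(self.X.shape[1])
        Z = (self.X - mean) / scale

        targets = self.target_matrix()
        scorers, params = [], []
        for l in range(N_CLASSES):
            t = targets[:, l]
            pos, neg = int(t.sum()), int((1 - t).sum())
            if pos == 0 or neg == 0:
                const = 1.0 if neg == 0 else -1.0
                log.warning("label %s has a single training class; using a "
                            "constant scorer (%.0f)", self.class_names[l], const)
                scorers.append(_ConstantScorer(const))
                params.append({"constant": True, "value": const})
                continue
            n_splits = max(2, min(self.inner_cv, pos, neg))
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                 random_state=self.seed)
            search = GridSearchCV(
                SVC(kernel="rbf"),
                {"C": list(self.c_grid), "gamma": list(self.gamma_grid)},
                cv=cv, scoring="accuracy", n_jobs=1,
            )
            search.fit(Z, t)
            scorers.append(search.best_estimator_)
            params.append({"C": search.best_params_["C"],
                           "gamma": search.best_params_["gamma"]})
        return BinaryRelevanceResults(
            scorers=scorers, params=params,
            scaler_mean=mean, scaler_scale=scale,
            class_names=self.class_names,
        )


def train_br(X: np.ndarray, Y: np.ndarray, **kwargs) -> BinaryRelevanceResults:
    """Functional wrapper: construct the model and fit in one call."""
    return BinaryRelevanceSVM(X, Y, **kwargs).fit()
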