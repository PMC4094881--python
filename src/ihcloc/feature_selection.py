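"""Stepwise discriminant analysis (SDA) with Wilks' lambda.

Classic forward-with-elimination stepwise selection: at each step the
candidate feature that minimises the partial Wilks' lambda enters if its
F-to-enter clears ``f_enter``; any already-included feature whose
F-to-remove drops below ``f_remove`` is then dropped.  Wilks' lambda over a
selected column set S is

    lambda(S) = det(W_S) / det(T_S)

with W and T the within-class and total scatter matrices.  A small ridge
(1e-6 * trace(W)/p on both diagonals) keeps the determinants defined when
scatter is near-singular; adding the same ridge to W and T preserves
lambda in (0, 1].

Multilabel data are handled by treating each distinct label set observed in
training as one class (default), or by a per-label one-vs-rest union
ranking (``multilabel="ovr_union"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RIDGE_SCALE = 1e-6


@dataclass
class SdaResult:
    """Ordered selection produced by :func:`sda_select`.

    ``selected`` is in entry order (rank order); ``wilks_trace`` holds the
    lambda value after each accepted entry step.
    """

    selected: list[int]
    wilks_trace: list[float]
    config_snapshot: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


def wilks_lambda(X: np.ndarray, classes: np.ndarray,
                 cols: list[int] | None = None) -> float:
    """Wilks' lambda det(W)/det(T) over the given columns (ridged)."""
    if cols is not None:
        X = X[:, cols]
    W, T = _scatter(X, classes)
    return _lambda_from_scatter(W, T, list(range(X.shape[1])))


def _scatter(X: np.ndarray, classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    Xc = X - mu
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for c in np.unique(classes):
        G = X[classes == c]
        Gc = G - G.mean(axis=0)
        W += Gc.T @ Gc
    return W, T


def _lambda_from_scatter(W: np.ndarray, T: np.ndarray, cols: list[int]) -> float:
    if not cols:
        return 1.0
    idx = np.ix_(cols, cols)
    Ws, Ts = W[idx].copy(), T[idx].copy()
    ridge = RIDGE_SCALE * np.trace(W) / W.shape[0]
    Ws[np.diag_indices_from(Ws)] += ridge
    Ts[np.diag_indices_from(Ts)] += ridge
    sign_w, logdet_w = np.linalg.slogdet(Ws)
    sign_t, logdet_t = np.linalg.slogdet(Ts)
    if sign_w <= 0 or sign_t <= 0:
        return 1.0  # numerically degenerate subset: treat as uninformative
    return float(np.exp(logdet_w - logdet_t))


def _multilabel_classes(Y: np.ndarray) -> np.ndarray:
    """Encode each distinct +/-1 label-set row as one integer class."""
    keys = [tuple(row.tolist()) for row in Y]
    mapping = {k: i for i, k in enumerate(sorted(set(keys)))}
    return np.array([mapping[k] for k in keys])


def sda_select(
    X: np.ndarray,
    class_labels: np.ndarray,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_features: int = 100,
) -> SdaResult:
    """Stepwise Wilks'-lambda feature selection.

    ``class_labels`` is an integer class per sample (use
    :func:`_multilabel_classes` upstream to collapse label sets).  Returns
    entry-ordered indices; ties on equal lambda break to the lowest index.
    """
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.asarray(class_labels)
    uniq, counts = np.unique(classes, return_counts=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    if f_enter <= f_remove:
        raise ValueError("f_enter must exceed f_remove")
    n, p = X.shape

    W, T = _scatter(X, classes)
    selected: list[int] = []
    trace: list[float] = []
    lam_cur = 1.0
    # entering beyond n - g - 1 features makes the F statistic degenerate
    hard_cap = min(max_features, max(n - g - 1, 1))

    while len(selected) < hard_cap:
        changed = False
        # --- entry step
        best_j, best_lam = -1, None
        for j in range(p):
            if j in selected:
                continue
            lam_j = _lambda_from_scatter(W, T, selected + [j])
            if best_lam is None or lam_j < best_lam - 1e-15:
                best_j, best_lam = j, lam_j
        if best_j >= 0 and best_lam is not None and best_lam > 0:
            p_new = len(selected) + 1
            dof = n - g - p_new
            if dof > 0 and best_lam < lam_cur:
                partial = best_lam / lam_cur
                f_stat = (dof / (g - 1)) * (1.0 - partial) / partial
                if f_stat >= f_enter:
                    selected.append(best_j)
                    lam_cur = best_lam
                    trace.append(lam_cur)
                    changed = True
        # --- removal step
        if changed and len(selected) > 1:
            while True:
                worst_j, worst_f, worst_lam = -1, None, None
                for j in selected[:]:
                    rest = [k for k in selected if k != j]
                    lam_rest = _lambda_from_scatter(W, T, rest)
                    partial = lam_cur / lam_rest if lam_rest > 0 else 1.0
                    dof = n - g - len(selected)
                    f_stat = (max(dof, 1) / (g - 1)) * (1.0 - partial) / max(partial, 1e-300)
                    if worst_f is None or f_stat < worst_f:
                        worst_j, worst_f, worst_lam = j, f_stat, lam_rest
                if worst_f is not None and worst_f < f_remove and len(selected) > 1:
                    selected.remove(worst_j)
                    lam_cur = worst_lam
                    # the trace records accepted entry steps; prune the last
                    trace = trace[: len(selected)]
                else:
                    break
        if not changed:
            break

    return SdaResult(
        selected=selected,
        wilks_trace=trace,
        config_snapshot={
            "f_enter": f_enter,
            "f_remove": f_remove,
            "max_features": max_features,
            "n_samples": n,
            "n_classes": g,
        },
    )


def sda_select_multilabel(
    X: np.ndarray,
    Y: np.ndarray,
    multilabel: str = "labelset",
    **kwargs,
) -> SdaResult:
    """SDA over a +/-1 label matrix Y (n_samples x 6).

    ``multilabel="labelset"`` (default) treats every distinct label set as
    one class; ``"ovr_union"`` ranks features per label one-vs-rest and
    merges the rankings round-robin.
    """
    Y = np.asarray(Y)
    if multilabel == "labelset":
        return sda_select(X, _multilabel_classes(Y), **kwargs)
    if multilabel == "ovr_union":
        per_label = []
        for l in range(Y.shape[1]):
            cls = (Y[:, l] > 0).astype(int)
            if len(np.unique(cls)) < 2 or min(np.bincount(cls)) < 2:
                per_label.append([])
                continue
            per_label.append(sda_select(X, cls, **kwargs).selected)
        merged: list[int] = []
        for depth in range(max((len(s) for s in per_label), default=0)):
            for s in per_label:
                if depth < len(s) and s[depth] not in merged:
                    merged.append(s[depth])
        cap = kwargs.get("max_features", 100)
        return SdaResult(selected=merged[:cap], wilks_trace=[],
                         config_snapshot={"multilabel": "ovr_union"})
    raise ValueError(f"unknown multilabel mode {multilabel!r}")
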