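"""Predict QC pass/fail from pre-sequencing lab metrics.

The interpretable model is a binary classification tree (CART):
greedy recursive partitioning minimizing Gini impurity, with
cost-complexity pruning indexed by a complexity parameter ``cp`` — a
split survives only if its impurity improvement (weighted by node
size, relative to the root) is at least ``cp`` times the root
impurity. ``cp`` is selected by repeated stratified k-fold
cross-validation on accuracy, breaking ties toward the largest ``cp``
(simplest tree). An alternative logistic model

    ln(p / (1 - p)) = beta0 + beta1 . x

is fit by iteratively reweighted least squares. Performance is
summarized by the F score (harmonic mean of precision and recall) on a
held-out stratified split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PASS, FAIL = "PASS", "FAIL"


# ---------------------------------------------------------------------------
# train/test split


def split_train_test(labels: pd.Series, ratio: float = 0.7, seed: int = 0):
    """Stratified train/test split of sample ids.

    Returns ``(train_ids, test_ids)``; disjoint, exhaustive, both
    classes represented in both sets whenever counts allow.
    """
    labels = pd.Series(labels)
    n = labels.size
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1); a ratio of 1 leaves an empty test set")
    rng = np.random.default_rng(seed)
    classes = labels.unique()
    if len(classes) < 2:
        warnings.warn("single-class cohort: unstratified split", stacklevel=2)
    n_train_total = int(round(ratio * n))
    train_ids: list = []
    test_ids: list = []
    # largest-remainder allocation of the train quota across classes
    sizes = {c: int((labels == c).sum()) for c in classes}
    quotas = {c: ratio * sizes[c] for c in classes}
    base = {c: int(np.floor(quotas[c])) for c in classes}
    short = n_train_total - sum(base.values())
    for c in sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True):
        if short <= 0:
            break
        base[c] += 1
        short -= 1
    for c in classes:
        ids = labels.index[labels == c].to_numpy()
        rng.shuffle(ids)
        k = min(max(base[c], 1 if sizes[c] > 1 else sizes[c]), sizes[c] - 1 if sizes[c] > 1 else sizes[c])
        train_ids.extend(ids[:k])
        test_ids.extend(ids[k:])
    return list(train_ids), list(test_ids)


# ---------------------------------------------------------------------------
# CART


@dataclass
class TreeNode:
    """One node of the fitted tree.

    ``pass_fraction`` is the fraction of QC-pass samples in the node,
    ``sample_fraction`` the share of training samples it holds, and
    ``improvement`` the split's Gini decrease weighted by node size
    relative to the root (0 for leaves).
    """

    prediction: str
    pass_fraction: float
    sample_fraction: float
    impurity: float
    feature: str | None = None
    threshold: float | None = None
    improvement: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()


@dataclass
class DecisionModel:
    root: TreeNode
    features: list
    cp: float
    cv_table: pd.DataFrame | None = None
    f_score: float | None = None
    feature_importance: pd.Series | None = None


@dataclass
class LogisticModel:
    beta0: float
    beta1: pd.Series
    converged: bool
    n_iter: int
    separated: bool = False
    f_score: float | None = None


def _gini(n_pass: float, n: float) -> float:
    if n == 0:
        return 0.0
    p = n_pass / n
    return 2.0 * p * (1.0 - p)


def best_split(x: np.ndarray, y: np.ndarray) -> tuple | None:
    """Exhaustive best Gini split over all features and thresholds.

    Candidate thresholds are midpoints of consecutive distinct sorted
    values; the left branch takes ``value < threshold``. Ties are
    broken toward the earlier feature and the smallest threshold.
    Returns ``(feature_index, threshold, weighted_child_gini)`` or
    None when no split separates the data.
    """
    n = y.size
    best: tuple | None = None
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        xs = x[order, j]
        ys = y[order]
        cum_pass = np.cumsum(ys)
        boundaries = np.nonzero(np.diff(xs) > 0)[0]
        if boundaries.size == 0:
            continue
        n_left = boundaries + 1
        pass_left = cum_pass[boundaries]
        n_right = n - n_left
        pass_right = cum_pass[-1] - pass_left
        p_l = pass_left / n_left
        p_r = pass_right / n_right
        weighted = (n_left * 2 * p_l * (1 - p_l) + n_right * 2 * p_r * (1 - p_r)) / n
        i = int(np.argmin(weighted))  # first minimum -> smallest threshold
        thr = 0.5 * (xs[boundaries[i]] + xs[boundaries[i] + 1])
        cand = (float(weighted[i]), j, float(thr))
        if best is None or cand[0] < best[0] - 1e-15:
            best = cand
    if best is None:
        return None
    return best[1], best[2], best[0]


def _grow(
    x: np.ndarray,
    y: np.ndarray,
    feature_names,
    n_root: int,
    root_gini: float,
    min_samples_split: int = 2,
    max_depth: int | None = None,
    _depth: int = 0,
) -> TreeNode:
    n = y.size
    n_pass = int(y.sum())
    g = _gini(n_pass, n)
    pass_frac = n_pass / n
    node = TreeNode(
        prediction=PASS if pass_frac >= 0.5 else FAIL,
        pass_fraction=pass_frac,
        sample_fraction=n / n_root,
        impurity=g,
    )
    if g == 0 or n < min_samples_split or (max_depth is not None and _depth >= max_depth):
        return node
    found = best_split(x, y)
    if found is None:
        return node
    j, thr, child_gini = found
    improvement = (n * g - n * child_gini) / n_root
    if improvement <= 1e-15:
        return node
    mask = x[:, j] < thr
    node.feature = feature_names[j]
    node.threshold = thr
    node.improvement = improvement
    node.left = _grow(
        x[mask], y[mask], feature_names, n_root, root_gini, min_samples_split, max_depth, _depth + 1
    )
    node.right = _grow(
        x[~mask], y[~mask], feature_names, n_root, root_gini, min_samples_split, max_depth, _depth + 1
    )
    return node


def prune(node: TreeNode, cp: float, root_impurity: float) -> TreeNode:
    """Cost-complexity pruning: collapse any split whose weighted Gini
    improvement is below ``cp * root_impurity``."""
    out = TreeNode(
        prediction=node.prediction,
        pass_fraction=node.pass_fraction,
        sample_fraction=node.sample_fraction,
        impurity=node.impurity,
    )
    if node.is_leaf or node.improvement < cp * root_impurity:
        return out
    out.feature = node.feature
    out.threshold = node.threshold
    out.improvement = node.improvement
    out.left = prune(node.left, cp, root_impurity)
    out.right = prune(node.right, cp, root_impurity)
    return out


def _predict_array(node: TreeNode, x: np.ndarray, feat_idx: dict) -> np.ndarray:
    """Vectorized descent; returns 1 for PASS, 0 for FAIL."""
    if node.is_leaf:
        return np.full(x.shape[0], int(node.prediction == PASS))
    mask = x[:, feat_idx[node.feature]] < node.threshold
    out = np.empty(x.shape[0], dtype=int)
    out[mask] = _predict_array(node.left, x[mask], feat_idx)
    out[~mask] = _predict_array(node.right, x[~mask], feat_idx)
    return out


def _predict_tree(node: TreeNode, row: pd.Series, sample_id) -> tuple[str, float]:
    while not node.is_leaf:
        if node.feature not in row.index or pd.isna(row[node.feature]):
            raise ValueError(f"sample {sample_id!r}: missing feature {node.feature!r}")
        node = node.left if row[node.feature] < node.threshold else node.right
    return node.prediction, node.pass_fraction


def default_cp_grid(n: int = 10, lo: float = 1e-4, hi: float = 0.5) -> np.ndarray:
    """Log-spaced complexity-parameter grid (10 values by default)."""
    return np.geomspace(lo, hi, n)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..k-1) per sample, stratified by class."""
    fold = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def fit_cart(
    features: pd.DataFrame,
    labels: pd.Series,
    cp_grid=None,
    cv: tuple[int, int] = (10, 3),
    seed: int = 0,
    max_depth: int | None = None,
) -> DecisionModel:
    """Fit the classification tree with CV-selected complexity.

    For each CV fold a full tree is grown once and pruned at every cp
    on the grid; the cp maximizing mean validation accuracy wins, ties
    going to the largest cp. The final tree is grown on all data and
    pruned at the selected cp.
    """
    labels = pd.Series(labels).reindex(features.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = (labels == PASS).to_numpy(dtype=int)
    x = features.to_numpy(dtype=float)
    feature_names = list(features.columns)
    n = y.size
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: returning a single-leaf model", stacklevel=2)
        root = _grow(x, y, feature_names, n, 0.0)
        return DecisionModel(root=root, features=feature_names, cp=0.0)
    if cp_grid is None:
        cp_grid = default_cp_grid()
    cp_grid = np.sort(np.asarray(cp_grid, dtype=float))
    root_gini = _gini(int(y.sum()), n)
    k, repeats = cv
    k = min(k, int(np.bincount(y).min()), n)
    rng = np.random.default_rng(seed)
    acc = np.zeros((cp_grid.size, k * repeats))
    col = 0
    for _ in range(repeats):
        fold = _stratified_folds(y, k, rng)
        for f in range(k):
            tr, va = fold != f, fold == f
            if len(np.unique(y[tr])) < 2 or va.sum() == 0:
                acc[:, col] = np.nan
                col += 1
                continue
            full = _grow(x[tr], y[tr], feature_names, int(tr.sum()), root_gini, max_depth=max_depth)
            feat_idx = {f: i for i, f in enumerate(feature_names)}
            for ci, cp in enumerate(cp_grid):
                pruned = prune(full, cp, full.impurity)
                preds = _predict_array(pruned, x[va], feat_idx)
                acc[ci, col] = float((preds == y[va]).mean())
            col += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_acc = np.nanmean(acc, axis=1)
    best_acc = np.nanmax(mean_acc)
    # ties (within fp tolerance) resolved toward largest cp = simplest tree
    best_idx = int(np.nonzero(mean_acc >= best_acc - 1e-12)[0][-1])
    cp_sel = float(cp_grid[best_idx])
    full = _grow(x, y, feature_names, n, root_gini, max_depth=max_depth)
    root = prune(full, cp_sel, full.impurity)
    cv_table = pd.DataFrame({"cp": cp_grid, "mean_cv_accuracy": mean_acc})
    model = DecisionModel(root=root, features=feature_names, cp=cp_sel, cv_table=cv_table)
    model.feature_importance = feature_importance(model)
    return model


def predict(model, features: pd.DataFrame) -> pd.DataFrame:
    """Per-sample predicted status and pass probability.

    Tree descent goes left when ``value < threshold``; the logistic
    model predicts PASS when p >= 0.5.
    """
    if isinstance(model, DecisionModel):
        rows = []
        for sid, row in features.iterrows():
            status, p = _predict_tree(model.root, row, sid)
            rows.append((status, p))
        return pd.DataFrame(rows, index=features.index, columns=["status", "p_pass"])
    if isinstance(model, LogisticModel):
        missing = [f for f in model.beta1.index if f not in features.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        nan_rows = features[model.beta1.index].isna().any(axis=1)
        if nan_rows.any():
            sid = features.index[nan_rows][0]
            feat = features.columns[features.loc[sid].isna()][0]
            raise ValueError(f"sample {sid!r}: missing feature {feat!r}")
        eta = model.beta0 + features[model.beta1.index].to_numpy(float) @ model.beta1.to_numpy()
        p = 1.0 / (1.0 + np.exp(-eta))
        return pd.DataFrame(
            {"status": np.where(p >= 0.5, PASS, FAIL), "p_pass": p}, index=features.index
        )
    raise TypeError(f"unsupported model type {type(model)!r}")


def f_score(predicted, truth, positive_class: str = PASS) -> float:
    """F1 = 2 * precision * recall / (precision + recall).

    Zero when the positive class is predicted or recalled not at all
    but present on the other side; an error when it is absent from
    both predictions and truth.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size != truth.size:
        raise ValueError("predicted and truth have different lengths")
    if predicted.size == 0:
        raise ValueError("empty inputs")
    pp = predicted == positive_class
    tp = truth == positive_class
    if not pp.any() and not tp.any():
        raise ValueError(f"positive class {positive_class!r} absent from predictions and truth")
    n_tp = int((pp & tp).sum())
    denom = 2 * n_tp + int((pp & ~tp).sum()) + int((~pp & tp).sum())
    return 2 * n_tp / denom if denom else 0.0


def feature_importance(model: DecisionModel) -> pd.Series:
    """Per-feature summed Gini improvement over splits, normalized to
    sum 1. All-zero (with a warning) for a single-leaf tree."""
    imp = pd.Series(0.0, index=model.features)

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        imp[node.feature] += node.improvement
        walk(node.left)
        walk(node.right)

    walk(model.root)
    total = imp.sum()
    if total == 0:
        warnings.warn("single-leaf tree: importance undefined, returning zeros", stacklevel=2)
        return imp
    return imp / total


def fit_logistic(
    features: pd.DataFrame,
    labels: pd.Series,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS.

    Converges when the largest coefficient change drops below ``tol``.
    Complete separation (diverging coefficients) is detected and the
    last stable iterate returned with a warning.
    """
    labels = pd.Series(labels).reindex(features.index)
    y = (labels == PASS).to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a logistic model")
    x = np.column_stack([np.ones(features.shape[0]), features.to_numpy(dtype=float)])
    beta = np.zeros(x.shape[1])
    converged = False
    separated = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(x @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        if w.max() < 1e-10:
            separated = True
            break
        wx = x * w[:, None]
        try:
            delta = np.linalg.solve(x.T @ wx, x.T @ (y - p))
        except np.linalg.LinAlgError:
            separated = True
            break
        new = beta + delta
        if not np.all(np.isfinite(new)) or np.max(np.abs(new)) > 1e8:
            separated = True
            break
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
    if separated:
        warnings.warn(
            "complete separation detected: returning last stable coefficients",
            stacklevel=2,
        )
    return LogisticModel(
        beta0=float(beta[0]),
        beta1=pd.Series(beta[1:], index=features.columns),
        converged=converged,
        n_iter=n_iter,
        separated=separated,
    )


def evaluate_split(
    features: pd.DataFrame,
    labels: pd.Series,
    model_kind: str = "cart",
    ratio: float = 0.7,
    seed: int = 0,
    positive_class: str = PASS,
    **fit_kwargs,
):
    """Stratified split, fit on train, F score on test.

    Returns the fitted model with ``f_score`` populated, plus the
    train/test ids. Convenience wrapper used by the pipeline and the
    examples.
    """
    train_ids, test_ids = split_train_test(labels, ratio=ratio, seed=seed)
    if model_kind == "cart":
        model = fit_cart(features.loc[train_ids], labels.loc[train_ids], seed=seed, **fit_kwargs)
    elif model_kind == "logistic":
        model = fit_logistic(features.loc[train_ids], labels.loc[train_ids], **fit_kwargs)
    else:
        raise ValueError("model_kind must be 'cart' or 'logistic'")
    preds = predict(model, features.loc[test_ids])
    model.f_score = f_score(preds["status"], labels.loc[test_ids], positive_class)
    return model, train_ids, test_ids
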