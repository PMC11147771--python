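"""Machine-learning subtype classification.

Feature harmonization across two reference cohorts, L1-penalized multinomial
feature selection along a glmnet-style penalty path with inner-CV deviance
selection, random-forest training, and 10-fold randomized stratified
cross-validation in which feature selection, tuning and training see only
the 90% training split of each fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

TRANSFORM_LOG2_FPKM1 = "log2(fpkm+1)"


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered shared gene list across two cohorts plus the transform tag."""

    genes: tuple[str, ...]
    transform: str = TRANSFORM_LOG2_FPKM1


@dataclass
class LassoPathResult:
    selected: list[str]
    alphas: np.ndarray
    mean_deviance: np.ndarray
    best_alpha: float
    n_nonzero: np.ndarray


@dataclass
class TrainedSubtypeModel:
    """A forest over LASSO-selected genes, with imputation medians."""

    forest: RandomForestClassifier
    selected_genes: list[str]
    classes: list[str]
    class_counts: dict[str, int]
    training_medians: pd.Series
    transform: str = TRANSFORM_LOG2_FPKM1
    cohort_tag: str = "internal"
    n_trees: int = 500


@dataclass
class CVReport:
    fold_accuracy: list[float]
    per_class_recall: pd.Series
    oof_predictions: pd.DataFrame  # sample_id -> true, predicted, fold
    fold_map: pd.Series
    seed: int
    excluded_classes: list[str] = field(default_factory=list)
    selected_genes_per_fold: list[list[str]] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        p = self.oof_predictions
        return float((p["predicted"] == p["true"]).mean())

    def macro_recall(self, min_class_size: int = 1) -> float:
        counts = self.oof_predictions["true"].value_counts()
        keep = counts[counts >= min_class_size].index
        return float(self.per_class_recall.loc[keep].mean())


def log2_fpkm(expression: pd.DataFrame) -> pd.DataFrame:
    """fpkm -> log2(fpkm + 1)."""
    return np.log2(expression + 1.0)


def _dedupe(matrix: pd.DataFrame, tag: str) -> pd.DataFrame:
    """Collapse duplicated gene symbols, keeping the highest-mean row."""
    if matrix.index.is_unique:
        return matrix
    means = matrix.mean(axis=1)
    order = np.argsort(-means.to_numpy(), kind="stable")
    deduped = matrix.iloc[order]
    dup = deduped.index.duplicated(keep="first")
    logger.warning("%s: %d duplicated gene rows collapsed (kept highest mean)", tag, int(dup.sum()))
    return deduped[~dup]


def harmonize_features(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    transform: bool = True,
) -> tuple[FeatureSpace, pd.DataFrame, pd.DataFrame]:
    """Restrict two gene x sample fpkm matrices to their shared genes.

    Duplicated gene symbols are collapsed to the highest-mean row; the
    intersection is ordered lexicographically; log2(x+1) is applied unless
    ``transform`` is False (raw-fpkm mode).
    """
    a = _dedupe(matrix_a, "matrix_a")
    b = _dedupe(matrix_b, "matrix_b")
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValueError("no shared genes between the two matrices")
    a, b = a.loc[shared], b.loc[shared]
    if transform:
        a, b = log2_fpkm(a), log2_fpkm(b)
        tag = TRANSFORM_LOG2_FPKM1
    else:
        tag = "fpkm"
    return FeatureSpace(tuple(shared), tag), a, b


def _multinomial_deviance(proba: np.ndarray, y_codes: np.ndarray) -> float:
    """Mean multinomial deviance (-2 mean log-likelihood)."""
    p = np.clip(proba[np.arange(len(y_codes)), y_codes], 1e-12, None)
    return float(-2.0 * np.mean(np.log(p)))


def _lambda_path(
    x: np.ndarray, y_codes: np.ndarray, n_classes: int, n_alphas: int, eps: float
) -> np.ndarray:
    """glmnet-style log-spaced penalty path from the all-zero penalty down."""
    n = x.shape[0]
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y_codes] = 1.0
    resid = onehot - onehot.mean(axis=0, keepdims=True)
    lam_max = np.abs(x.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps), n_alphas)


def _path_classifier(tol: float, max_iter: int) -> LogisticRegression:
    """Warm-startable L1 multinomial classifier for penalty-path fitting."""
    return LogisticRegression(
        l1_ratio=1.0, solver="saga", warm_start=True, tol=tol, max_iter=max_iter,
        fit_intercept=True,
    )


def _fit_at(clf: LogisticRegression, x, y_codes, lam: float) -> LogisticRegression:
    clf.C = 1.0 / (lam * x.shape[0])
    clf.fit(x, y_codes)
    return clf


def lasso_select(
    train: pd.DataFrame,
    labels: pd.Series,
    n_inner_folds: int = 10,
    n_alphas: int = 100,
    eps: float = 0.01,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 200,
    rule: str = "min",
) -> LassoPathResult:
    """L1-penalized multinomial feature selection.

    ``train`` is samples x genes on the classifier scale.  The penalty path
    is log-spaced over ``n_alphas`` values from the smallest penalty zeroing
    all coefficients; the penalty is chosen by minimum cross-validated
    multinomial deviance over ``n_inner_folds`` stratified inner folds
    (``rule="1se"`` picks the strongest penalty within one standard error of
    the minimum).  Returns the genes with any nonzero coefficient at the
    chosen penalty.
    """
    y = labels.loc[train.index]
    classes, y_codes = np.unique(y.to_numpy(), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("feature selection needs at least two classes")

    min_class = int(np.bincount(y_codes).min())
    folds = n_inner_folds
    if min_class < folds:
        folds = max(min_class, 2)
        logger.warning("inner folds reduced to %d (smallest class has %d members)", folds, min_class)

    mu = train.to_numpy(dtype=float).mean(axis=0)
    sd = train.to_numpy(dtype=float).std(axis=0)
    sd[sd == 0] = 1.0
    x = (train.to_numpy(dtype=float) - mu) / sd

    alphas = _lambda_path(x, y_codes, len(classes), n_alphas, eps)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y_codes))
    fold_models = [_path_classifier(tol, max_iter) for _ in splits]

    # walk the path from the strongest penalty down, keeping each fold's
    # model warm-started; stop once the CV deviance has clearly passed its
    # minimum (the dense tail of the path is never fit)
    deviances = np.full((folds, len(alphas)), np.nan)
    patience = max(len(alphas) // 10, 5)
    rising = 0
    last_idx = len(alphas) - 1
    for ai, lam in enumerate(alphas):
        for fi, (tr, te) in enumerate(splits):
            model = _fit_at(fold_models[fi], x[tr], y_codes[tr], lam)
            proba = model.predict_proba(x[te])
            # align to global class codes (a fold may miss a class)
            full = np.full((len(te), len(classes)), 1e-12)
            for ci, c in enumerate(model.classes_):
                full[:, int(c)] = proba[:, ci]
            deviances[fi, ai] = _multinomial_deviance(full, y_codes[te])
        mean_so_far = deviances[:, : ai + 1].mean(axis=0)
        if ai > 0 and mean_so_far[ai] > mean_so_far.min():
            rising += 1
        else:
            rising = 0
        if rising >= patience:
            last_idx = ai
            break

    mean_dev = deviances[:, : last_idx + 1].mean(axis=0)
    best_idx = int(np.argmin(mean_dev))
    if rule == "1se":
        se = deviances[:, : last_idx + 1].std(axis=0, ddof=1) / np.sqrt(folds)
        limit = mean_dev[best_idx] + se[best_idx]
        best_idx = int(np.flatnonzero(mean_dev <= limit)[0])

    n_nonzero = np.zeros(len(alphas), dtype=int)
    final_clf = _path_classifier(tol, max_iter)
    for ai, lam in enumerate(alphas[: best_idx + 1]):
        final = _fit_at(final_clf, x, y_codes, lam)
        n_nonzero[ai] = int(np.any(final.coef_ != 0, axis=0).sum())
    nonzero = np.any(final.coef_ != 0, axis=0)
    selected = [g for g, nz in zip(train.columns, nonzero) if nz]
    alphas = alphas[: last_idx + 1]
    mean_dev = mean_dev[: last_idx + 1]
    return LassoPathResult(
        selected=selected,
        alphas=alphas,
        mean_deviance=mean_dev,
        best_alpha=float(alphas[best_idx]),
        n_nonzero=n_nonzero,
    )


def train_random_forest(
    train: pd.DataFrame,
    labels: pd.Series,
    selected_genes: list[str],
    n_trees: int = 500,
    seed: int = 0,
    cohort_tag: str = "internal",
) -> TrainedSubtypeModel:
    """Random forest over the selected genes (sqrt(p) features per split)."""
    if not selected_genes:
        raise ValueError("selected gene set is empty")
    y = labels.loc[train.index]
    counts = y.value_counts()
    if (counts == 0).any():
        raise ValueError("every class must have at least one member")
    x = train[selected_genes]
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(x.to_numpy(), y.to_numpy())
    return TrainedSubtypeModel(
        forest=forest,
        selected_genes=list(selected_genes),
        classes=[str(c) for c in forest.classes_],
        class_counts=counts.to_dict(),
        training_medians=x.median(axis=0),
        cohort_tag=cohort_tag,
        n_trees=n_trees,
    )


def predict_subtype(
    model: TrainedSubtypeModel, expression: pd.DataFrame, is_fpkm: bool = True
) -> tuple[pd.Series, pd.DataFrame]:
    """Predict (label, class-probability vector) per sample.

    ``expression`` is genes x samples; fpkm input is transformed to the
    model's scale.  Genes missing from the matrix are imputed at the
    training median unless more than half are absent.  Ties in the
    probability vector resolve to the lexicographically smallest class.
    """
    expr = log2_fpkm(expression) if is_fpkm and model.transform == TRANSFORM_LOG2_FPKM1 else expression
    missing = [g for g in model.selected_genes if g not in expr.index]
    if len(missing) > 0.5 * len(model.selected_genes):
        raise ValueError(
            f"{len(missing)}/{len(model.selected_genes)} selected genes missing"
        )
    x = pd.DataFrame(index=model.selected_genes, columns=expr.columns, dtype=float)
    present = [g for g in model.selected_genes if g in expr.index]
    x.loc[present] = expr.loc[present].to_numpy()
    if missing:
        logger.warning("imputing %d missing genes at training median", len(missing))
        for g in missing:
            x.loc[g] = model.training_medians[g]
    proba = model.forest.predict_proba(x.T.to_numpy())
    classes = sorted(model.classes)
    order = [list(model.forest.classes_).index(c) for c in classes]
    proba = proba[:, order]
    probs = pd.DataFrame(proba, index=expr.columns, columns=classes)
    labels = probs.idxmax(axis=1)  # first (lexicographic) argmax on ties
    return labels, probs


def stratified_cv(
    matrix: pd.DataFrame,
    labels: pd.Series,
    k: int = 10,
    seed: int = 0,
    lasso_kwargs: dict | None = None,
    forest_kwargs: dict | None = None,
    fold_map: pd.Series | None = None,
) -> CVReport:
    """10-fold randomized stratified CV with untouched test folds.

    ``matrix`` is genes x samples on the classifier scale.  Per fold, LASSO
    selection and forest training run on the 90% training split only;
    predictions are recorded for the held-out 10%.  Classes with fewer than
    ``k`` members are excluded (flagged), mirroring tiny reference classes.
    A precomputed ``fold_map`` (sample -> fold index) pins the partition,
    e.g. to verify that held-out labels cannot influence training artifacts.
    """
    # coarser penalty path inside the outer CV keeps the 10x10 nested fits
    # tractable; override via lasso_kwargs for a glmnet-resolution path
    defaults = {"n_alphas": 30, "eps": 0.1, "max_iter": 80, "tol": 5e-3}
    lasso_kwargs = {**defaults, **(lasso_kwargs or {})}
    forest_kwargs = dict(forest_kwargs or {})

    y = labels.loc[matrix.columns]
    counts = y.value_counts()
    excluded = sorted(counts[counts < k].index)
    if excluded:
        logger.warning("classes excluded from CV (n < %d): %s", k, excluded)
    keep = y[~y.isin(excluded)].index
    y = y.loc[keep]
    x = matrix[keep]
    if len(keep) < 2 * k:
        raise ValueError(f"n={len(keep)} too small for k={k}; use a smaller k")

    samples = np.asarray(keep)
    if fold_map is None:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_map = pd.Series(index=keep, dtype=int, name="fold")
        for fold, (_, te) in enumerate(skf.split(samples, y.to_numpy())):
            fold_map.loc[samples[te]] = fold
    else:
        fold_map = fold_map.loc[keep].astype(int).rename("fold")
    records = []
    fold_acc = []
    selected_per_fold = []
    xt = x.T  # samples x genes

    for fold in range(k):
        te_ids = fold_map[fold_map == fold].index.to_numpy()
        tr_ids = fold_map[fold_map != fold].index.to_numpy()
        sel = lasso_select(xt.loc[tr_ids], y, seed=seed + fold, **lasso_kwargs)
        selected = sel.selected
        if not selected:
            # intercept-only optimum (no informative genes at the chosen
            # penalty): fall back to the full feature space for the forest
            logger.warning("fold %d: empty LASSO selection; using all genes", fold)
            selected = list(xt.columns)
        model = train_random_forest(
            xt.loc[tr_ids], y, selected, seed=seed + fold, **forest_kwargs
        )
        pred, _ = predict_subtype(model, x[te_ids], is_fpkm=False)
        selected_per_fold.append(selected)
        fold_acc.append(float((pred == y.loc[te_ids]).mean()))
        for sid in te_ids:
            records.append(
                {"sample_id": sid, "true": y.loc[sid], "predicted": pred.loc[sid], "fold": fold}
            )

    oof = pd.DataFrame(records).set_index("sample_id")
    hit = (oof["predicted"] == oof["true"]).astype(float)
    recall = hit.groupby(oof["true"], observed=True).mean()
    return CVReport(
        fold_accuracy=fold_acc,
        per_class_recall=recall,
        oof_predictions=oof,
        fold_map=fold_map,
        seed=seed,
        excluded_classes=excluded,
        selected_genes_per_fold=selected_per_fold,
    )
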