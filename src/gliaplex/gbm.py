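"""Boosted-tree classification of glial profiles (CTRL vs AD; states).

Stochastic gradient boosting (scikit-learn's ``GradientBoostingClassifier``
with learning rate 0.1, minimum node size 10, bag fraction 0.5) tuned over
tree count and interaction depth by stratified k-fold cross-validation on
an 80% training split; performance is reported on the 20% hold-out at the
accuracy-maximizing threshold with bootstrap 95% CIs, compared against the
no-information rate (NIR), and markers are ranked by permutation variable
importance (max scaled to 100).

``evaluate_scores`` is the shared evaluation path: the CNN module feeds its
class probabilities through the same function, so thresholds, CIs and NIR
semantics are identical across classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .profiles import IntensityMatrix

__all__ = [
    "SplitSpec",
    "ClassifierReport",
    "stratified_split",
    "train_gbm",
    "evaluate_scores",
    "evaluate_classifier",
    "variable_importance",
    "run_paper_gbm_suite",
]

DEFAULT_GRID = {"n_trees": tuple(range(50, 501, 50)), "depth": (1, 2, 3)}


@dataclass(frozen=True)
class SplitSpec:
    train_idx: np.ndarray
    test_idx: np.ndarray
    key: str
    seed: int

    def __post_init__(self):
        tr, te = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")


@dataclass
class ClassifierReport:
    accuracy: float
    accuracy_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    nir: float
    p_acc_gt_nir: float
    threshold: float | None
    sensitivity: float | None
    specificity: float | None
    n_test: int
    hyperparams: dict = field(default_factory=dict)
    importances: pd.Series | None = None

    def __post_init__(self):
        if not (self.accuracy_ci[0] - 1e-12 <= self.accuracy <= self.accuracy_ci[1] + 1e-12):
            raise ValueError("accuracy CI must bracket the point estimate")

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "nir": self.nir,
            "p_acc_gt_nir": self.p_acc_gt_nir,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_test": self.n_test,
            "hyperparams": self.hyperparams,
        }
        if self.importances is not None:
            d["importances"] = self.importances.to_dict()
        return d


def stratified_split(
    metadata: pd.DataFrame,
    p: float = 0.8,
    key: str = "diagnosis",
    seed: int = 0,
    group_by: str | None = None,
) -> SplitSpec:
    """80/20 stratified split of profile rows.

    Within each level of ``key``, a rounded ``1−p`` fraction goes to the
    hold-out test set. Strata with fewer than 5 members go entirely to
    training with a warning. With ``group_by`` (e.g. ``'subject'``), whole
    groups are assigned to one side, avoiding subject-level leakage.
    """
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, idx in metadata.groupby(key, sort=True).groups.items():
        idx = np.asarray(list(idx))
        if len(idx) < 5:
            warnings.warn(f"stratum with {len(idx)} member(s) assigned wholly to training", stacklevel=2)
            train.append(idx)
            continue
        if group_by is None:
            perm = rng.permutation(idx)
            n_test = int(round(len(idx) * (1 - p)))
            test.append(perm[:n_test])
            train.append(perm[n_test:])
        else:
            groups = metadata.loc[idx, group_by].to_numpy()
            uniq = rng.permutation(np.unique(groups))
            target = len(idx) * (1 - p)
            chosen, total = [], 0
            for g in uniq:
                if total >= target:
                    break
                chosen.append(g)
                total += int((groups == g).sum())
            mask = np.isin(groups, chosen)
            test.append(idx[mask])
            train.append(idx[~mask])
    return SplitSpec(
        train_idx=np.sort(np.concatenate(train)),
        test_idx=np.sort(np.concatenate(test)) if test else np.array([], dtype=int),
        key=key,
        seed=seed,
    )


def _make_gbm(n_trees: int, depth: int, seed: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        n_estimators=n_trees,
        max_depth=depth,
        learning_rate=0.1,
        subsample=0.5,
        min_samples_leaf=10,
        random_state=seed,
    )


def train_gbm(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
):
    """Grid-search tree count × depth by stratified k-fold CV accuracy.

    Returns ``(model, cv_table)`` where *model* is refit on all of
    ``(X, y)`` at the CV-accuracy-maximizing grid point.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    grid = grid or DEFAULT_GRID
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} observations per class for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    for n_trees in grid["n_trees"]:
        for depth in grid["depth"]:
            accs = []
            for tr, va in splits:
                m = _make_gbm(n_trees, depth, seed)
                m.fit(X[tr], y[tr])
                accs.append(float((m.predict(X[va]) == y[va]).mean()))
            rows.append({"n_trees": n_trees, "depth": depth, "cv_accuracy": float(np.mean(accs))})
    cv_table = pd.DataFrame(rows)
    best = cv_table.loc[cv_table["cv_accuracy"].idxmax()]
    model = _make_gbm(int(best["n_trees"]), int(best["depth"]), seed)
    model.fit(X, y)
    return model, cv_table


def _accuracy_max_threshold(scores: np.ndarray, y01: np.ndarray) -> tuple[float, float]:
    """Exhaustive search over midpoints of sorted scores; returns (thr, acc)."""
    s = np.sort(np.unique(scores))
    cands = [s[0] - 1e-12] + list((s[:-1] + s[1:]) / 2) + [s[-1] + 1e-12]
    best_thr, best_acc = cands[0], -1.0
    for t in cands:
        acc = float(((scores >= t).astype(int) == y01).mean())
        if acc > best_acc:
            best_acc, best_thr = acc, t
    return best_thr, best_acc


def evaluate_scores(
    scores: np.ndarray,
    y_true: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
    positive_label=None,
) -> ClassifierReport:
    """Hold-out evaluation of binary classification scores.

    Threshold maximizes test accuracy over all score midpoints; AUC is the
    rank (Mann–Whitney) statistic; 95% CIs are percentile bootstrap over
    ``n_boot`` resamples of the test set; NIR is the majority-class
    proportion and its comparison an exact one-sided binomial test on the
    number of correct predictions.
    """
    scores = np.asarray(scores, float)
    y_true = np.asarray(y_true)
    labels = np.unique(y_true)
    if len(labels) != 2:
        raise ValueError("evaluate_scores is binary; use evaluate_multiclass_scores")
    pos = positive_label if positive_label is not None else labels[-1]
    y01 = (y_true == pos).astype(int)

    thr, acc = _accuracy_max_threshold(scores, y01)
    auc = float(roc_auc_score(y01, scores))
    pred = (scores >= thr).astype(int)
    tp = int(((pred == 1) & (y01 == 1)).sum())
    tn = int(((pred == 0) & (y01 == 0)).sum())
    sens = tp / max(1, int((y01 == 1).sum()))
    spec = tn / max(1, int((y01 == 0).sum()))

    rng = np.random.default_rng(seed)
    n = len(y01)
    boot_acc, boot_auc = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb, sb = y01[idx], scores[idx]
        boot_acc.append(float(((sb >= thr).astype(int) == yb).mean()))
        if yb.min() == yb.max():
            continue
        boot_auc.append(float(roc_auc_score(yb, sb)))
    acc_ci = tuple(np.percentile(boot_acc, [2.5, 97.5]))
    auc_ci = tuple(np.percentile(boot_auc, [2.5, 97.5])) if boot_auc else (auc, auc)
    acc_ci = (min(acc_ci[0], acc), max(acc_ci[1], acc))
    auc_ci = (min(auc_ci[0], auc), max(auc_ci[1], auc))

    nir = float(max((y01 == 1).mean(), (y01 == 0).mean()))
    correct = int((pred == y01).sum())
    p_nir = float(binomtest(correct, n, p=nir, alternative="greater").pvalue)
    return ClassifierReport(
        accuracy=acc,
        accuracy_ci=acc_ci,
        auc=auc,
        auc_ci=auc_ci,
        nir=nir,
        p_acc_gt_nir=p_nir,
        threshold=float(thr),
        sensitivity=float(sens),
        specificity=float(spec),
        n_test=n,
    )


def evaluate_multiclass_scores(
    proba: np.ndarray, y_true: np.ndarray, classes, n_boot: int = 500, seed: int = 0
) -> ClassifierReport:
    """Multiclass evaluation: argmax accuracy + macro one-vs-rest AUC."""
    proba = np.asarray(proba, float)
    y_true = np.asarray(y_true)
    classes = list(classes)
    pred = np.asarray(classes)[np.argmax(proba, axis=1)]
    acc = float((pred == y_true).mean())
    auc = float(roc_auc_score(y_true, proba, multi_class="ovr", average="macro", labels=classes))
    rng = np.random.default_rng(seed)
    n = len(y_true)
    boot_acc, boot_auc = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot_acc.append(float((pred[idx] == y_true[idx]).mean()))
        if len(np.unique(y_true[idx])) == len(classes):
            boot_auc.append(
                float(
                    roc_auc_score(
                        y_true[idx], proba[idx], multi_class="ovr", average="macro", labels=classes
                    )
                )
            )
    acc_ci = tuple(np.percentile(boot_acc, [2.5, 97.5]))
    auc_ci = tuple(np.percentile(boot_auc, [2.5, 97.5])) if boot_auc else (auc, auc)
    acc_ci = (min(acc_ci[0], acc), max(acc_ci[1], acc))
    auc_ci = (min(auc_ci[0], auc), max(auc_ci[1], auc))
    counts = pd.Series(y_true).value_counts(normalize=True)
    nir = float(counts.max())
    correct = int((pred == y_true).sum())
    p_nir = float(binomtest(correct, n, p=nir, alternative="greater").pvalue)
    return ClassifierReport(
        accuracy=acc,
        accuracy_ci=acc_ci,
        auc=auc,
        auc_ci=auc_ci,
        nir=nir,
        p_acc_gt_nir=p_nir,
        threshold=None,
        sensitivity=None,
        specificity=None,
        n_test=n,
    )


def evaluate_classifier(model, X_test, y_test, n_boot: int = 500, seed: int = 0) -> ClassifierReport:
    """Evaluate a fitted probabilistic classifier on the hold-out set."""
    proba = model.predict_proba(np.asarray(X_test, float))
    classes = list(model.classes_)
    if len(classes) == 2:
        return evaluate_scores(proba[:, 1], y_test, n_boot=n_boot, seed=seed, positive_label=classes[1])
    return evaluate_multiclass_scores(proba, y_test, classes, n_boot=n_boot, seed=seed)


def variable_importance(
    model, X, y, feature_names=None, n_repeats: int = 10, seed: int = 0
) -> pd.Series:
    """Permutation variable importance on held-out data.

    Mean accuracy drop after permuting each predictor (over ``n_repeats``
    permutations), rescaled so the maximum is 100; ties broken by feature
    name. Negative drops floor at 0.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]
    base = float((model.predict(X) == y).mean())
    rng = np.random.default_rng(seed)
    drops = {}
    for j, name in enumerate(names):
        vals = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            vals.append(base - float((model.predict(Xp) == y).mean()))
        drops[name] = max(0.0, float(np.mean(vals)))
    s = pd.Series(drops)
    top = s.max()
    if top > 0:
        s = s / top * 100.0
    s = s.sort_values(ascending=False, kind="stable")
    # deterministic tie order by name
    s = s.groupby(s.values, sort=False, group_keys=False).apply(lambda g: g.sort_index())
    return s.sort_values(ascending=False, kind="stable")


def run_paper_gbm_suite(
    matrix: IntensityMatrix,
    single_markers: tuple[str, ...] | None = None,
    grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    n_boot: int = 500,
    state_col: str = "state",
) -> dict:
    """The full supervised comparison on one cohort matrix.

    Trains and evaluates: the multi-marker CTRL/AD model, single-marker
    CTRL/AD models (default: the classic reactive markers present in the
    matrix), and the 3-state phenotype model (when a state column exists in
    the metadata). Also reports whether the multi-marker AUC exceeds every
    single-marker AUC.
    """
    meta = matrix.meta.reset_index(drop=True)
    X = matrix.values.to_numpy()
    y = meta["diagnosis"].to_numpy()
    if single_markers is None:
        single_markers = tuple(m for m in ("GFAP", "MHC2", "CD68") if m in matrix.markers)

    split = stratified_split(meta, p=0.8, key="diagnosis", seed=seed)
    tr, te = split.train_idx, split.test_idx

    reports: dict[str, ClassifierReport] = {}
    model, _ = train_gbm(X[tr], y[tr], grid=grid, folds=folds, seed=seed)
    rep = evaluate_classifier(model, X[te], y[te], n_boot=n_boot, seed=seed)
    rep.hyperparams = {"n_trees": model.n_estimators, "depth": model.max_depth}
    rep.importances = variable_importance(model, X[te], y[te], matrix.markers, seed=seed)
    reports["diagnosis_multi"] = rep

    for mk in single_markers:
        j = matrix.markers.index(mk)
        m1, _ = train_gbm(X[tr][:, [j]], y[tr], grid=grid, folds=folds, seed=seed)
        reports[f"diagnosis_{mk}"] = evaluate_classifier(m1, X[te][:, [j]], y[te], n_boot=n_boot, seed=seed)

    if state_col in meta.columns:
        ys = meta[state_col].to_numpy()
        ms, _ = train_gbm(X[tr], ys[tr], grid=grid, folds=folds, seed=seed)
        srep = evaluate_classifier(ms, X[te], ys[te], n_boot=n_boot, seed=seed)
        srep.importances = variable_importance(ms, X[te], ys[te], matrix.markers, seed=seed)
        reports["state_multi"] = srep

    multi_auc = reports["diagnosis_multi"].auc
    ordering = all(
        multi_auc > reports[f"diagnosis_{mk}"].auc for mk in single_markers
    )
    return {"reports": reports, "multi_beats_singles": ordering}
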