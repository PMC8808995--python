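"""Training and hyperparameter search for the profile-image CNN."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .layers import make_optimizer
from .model import CnnConfig, GlialCNN

__all__ = ["train_cnn", "tune_cnn"]


def _stratified_holdout(y: np.ndarray, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train, val = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_val = max(1, int(round(len(idx) * fraction)))
        val.append(idx[:n_val])
        train.append(idx[n_val:])
    return np.concatenate(train), np.concatenate(val)


def train_cnn(
    X: np.ndarray,
    y: np.ndarray,
    config: CnnConfig,
    val_fraction: float = 0.2,
    val_data: tuple | None = None,
    verbose: bool = False,
):
    """Minimize cross-entropy with early stopping on validation loss.

    Stops once the validation loss has failed to improve for
    ``config.patience`` epochs and restores the best-epoch weights.
    Reproducible for a fixed ``config.seed`` (single-threaded NumPy).
    Returns ``(model, history)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain more than one class")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    yi = np.array([class_to_idx[c] for c in y])

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7E41]))
    if val_data is None:
        tr_idx, va_idx = _stratified_holdout(yi, val_fraction, rng)
        X_tr, y_tr, X_va, y_va = X[tr_idx], yi[tr_idx], X[va_idx], yi[va_idx]
    else:
        X_tr, y_tr = X, yi
        X_va = np.asarray(val_data[0], float)
        y_va = np.array([class_to_idx[c] for c in np.asarray(val_data[1])])

    model = GlialCNN(config, n_channels=X.shape[1], n_classes=len(classes))
    model.classes_ = classes
    opt = make_optimizer(config.optimizer, model.params, model.grads, config.lr, config.weight_decay)

    best_loss, best_state, best_epoch = np.inf, model.state_dict(), -1
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X_tr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            batch = order[i : i + config.batch_size]
            losses.append(model.loss_and_backward(X_tr[batch], y_tr[batch]))
            opt.step()
        val_p = model.predict_proba(X_va)
        val_loss = float(-np.log(np.maximum(val_p[np.arange(len(y_va)), y_va], 1e-12)).mean())
        val_acc = float((np.argmax(val_p, axis=1) == y_va).mean())
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss, "val_acc": val_acc}
        )
        if verbose:
            print(f"epoch {epoch}: train {np.mean(losses):.4f} val {val_loss:.4f} acc {val_acc:.3f}")
        if val_loss < best_loss - 1e-6:
            best_loss, best_state, best_epoch = val_loss, model.state_dict(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def _cv_auc(X, y, config: CnnConfig, folds: int, seed: int) -> float:
    yi = pd.factorize(pd.Series(y), sort=True)[0]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for fold, (tr, va) in enumerate(skf.split(X, yi)):
        cfg = replace(config, seed=config.seed + fold)
        model, _ = train_cnn(X[tr], yi[tr], cfg, val_fraction=0.15)
        p = model.predict_proba(X[va])[:, 1]
        aucs.append(float(roc_auc_score(yi[va], p)))
    return float(np.mean(aucs))


def tune_cnn(
    X: np.ndarray,
    y: np.ndarray,
    space: dict,
    trials: int = 10,
    folds: int = 3,
    seed: int = 0,
):
    """Random hyperparameter search maximizing mean k-fold CV AUC.

    ``space`` maps CnnConfig field names to lists of candidate values;
    ``lr`` and ``weight_decay`` may instead give ``(low, high)`` bounds
    sampled log-uniformly. The winning configuration is retrained on the
    full training set. Returns ``(model, best_config, trials_table)``.
    """
    X = np.asarray(X, float)
    rng = np.random.default_rng(seed)
    rows = []
    seen = set()
    best_cfg, best_auc = None, -np.inf
    for t in range(trials):
        draw = {}
        for key, choices in space.items():
            if key in ("lr", "weight_decay") and isinstance(choices, tuple) and len(choices) == 2:
                lo, hi = choices
                draw[key] = float(np.exp(rng.uniform(np.log(lo), np.log(max(hi, 1e-300)))))
            else:
                draw[key] = choices[rng.integers(len(choices))]
        cfg = replace(CnnConfig(seed=seed), **draw)
        key = tuple(sorted(draw.items()))
        if key in seen and len(seen) < _space_size(space):
            continue
        seen.add(key)
        auc = _cv_auc(X, y, cfg, folds=folds, seed=seed)
        rows.append({**draw, "cv_auc": auc, "trial": t})
        if auc > best_auc:
            best_auc, best_cfg = auc, cfg
    model, _ = train_cnn(X, y, best_cfg, val_fraction=0.15)
    table = pd.DataFrame(rows)
    table.attrs["best_cv_auc"] = best_auc
    return model, best_cfg, table


def _space_size(space: dict) -> int:
    size = 1
    for choices in space.values():
        if isinstance(choices, tuple) and len(choices) == 2 and not isinstance(choices[0], (tuple, str)):
            return 10**9  # continuous dimension
        size *= len(choices)
    return size
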