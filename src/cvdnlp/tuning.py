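"""Hyperparameter search and final-model selection.

Random search over the architecture grid, scored by mean binary
cross-entropy across patient-disjoint cross-validation folds, followed
by repeated retraining from different random initialisations with the
best configuration, keeping the restart with the lowest validation
loss.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from pathlib import Path

import numpy as np

from .nn import BiLSTMClassifier

logger = logging.getLogger(__name__)

__all__ = ["SEARCH_GRID", "make_group_folds", "random_search", "multi_restart"]

#: architecture grid explored by the random search
SEARCH_GRID: dict[str, list] = {
    "embedding_dim": [32, 64, 128, 256],
    "lstm_dim": [16, 32, 64, 128],
    "lstm_dropout": [0.0, 0.15, 0.3],
    "n_dense": [2, 3, 4, 5, 6],
    "dense_max_dim": [16, 32, 64, 128],
    "dense_dropout": [0.0, 0.1],
}


def make_group_folds(groups, n_folds: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-disjoint folds: no patient appears in two folds.

    Unique groups are shuffled deterministically and dealt round-robin
    into ``n_folds`` parts; fold i validates on part i.
    """
    groups = np.asarray(groups)
    unique = np.unique(groups)
    if len(unique) < n_folds:
        raise ValueError("fewer groups than folds")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique)
    parts = [shuffled[k::n_folds] for k in range(n_folds)]
    folds = []
    for part in parts:
        val_mask = np.isin(groups, part)
        folds.append((np.flatnonzero(~val_mask), np.flatnonzero(val_mask)))
    return folds


def _grid_configs(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def random_search(
    X,
    y,
    groups,
    grid: dict[str, list] | None = None,
    n_search: int = 20,
    cv_folds: int = 5,
    seed: int = 0,
    train_params: dict | None = None,
    log_path: str | Path | None = None,
) -> tuple[dict, list[dict]]:
    """Sample ``n_search`` distinct configurations uniformly without
    replacement and return the one minimising mean CV validation loss.

    ``train_params`` are forwarded to :class:`BiLSTMClassifier` (epoch
    budget, batch size, ...).  Returns ``(best_config, log)`` where the
    log holds per-config fold losses; a JSON-lines copy is written to
    ``log_path`` when given.
    """
    grid = grid or SEARCH_GRID
    configs = _grid_configs(grid)
    rng = np.random.default_rng(seed)
    if n_search > len(configs):
        warnings.warn(
            f"n_search={n_search} exceeds grid size {len(configs)}; running exhaustively"
        )
        n_search = len(configs)
    chosen = rng.choice(len(configs), size=n_search, replace=False)
    folds = make_group_folds(groups, cv_folds, seed)
    train_params = dict(train_params or {})
    X = np.asarray(X)
    y = np.asarray(y)

    log: list[dict] = []
    for rank, ci in enumerate(chosen):
        config = configs[ci]
        fold_losses = []
        for k, (tr, va) in enumerate(folds):
            model = BiLSTMClassifier(
                **config,
                **train_params,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            model.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
            fold_losses.append(float(model.best_val_loss_))
        entry = {
            "config": config,
            "fold_losses": fold_losses,
            "mean_loss": float(np.mean(fold_losses)),
        }
        log.append(entry)
        logger.info("search %d/%d: %s -> %.4f", rank + 1, n_search, config, entry["mean_loss"])
    if log_path is not None:
        with open(log_path, "w", encoding="utf-8") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    best = min(log, key=lambda e: e["mean_loss"])
    return dict(best["config"]), log


def multi_restart(
    config: dict,
    X,
    y,
    X_val,
    y_val,
    n_restarts: int = 5,
    seed: int = 0,
    train_params: dict | None = None,
    log_path: str | Path | None = None,
) -> tuple[BiLSTMClassifier, list[dict]]:
    """Retrain ``n_restarts`` times from different initialisations and
    keep the model with the lowest validation loss."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    train_params = dict(train_params or {})
    best_model = None
    log: list[dict] = []
    for r in range(n_restarts):
        model = BiLSTMClassifier(
            **config, **train_params, random_state=int(rng.integers(0, 2**31 - 1))
        )
        model.fit(X, y, X_val=X_val, y_val=y_val)
        log.append({"restart": r, "val_loss": float(model.best_val_loss_), "epochs": model.n_epochs_})
        if best_model is None or model.best_val_loss_ < best_model.best_val_loss_:
            best_model = model
    if log_path is not None:
        with open(log_path, "w", encoding="utf-8") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return best_model, log
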