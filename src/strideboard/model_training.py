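"""Grid-search tuning and fitting of per-subscore regression models.

Two model families reconstruct each board subscore from the selected
features: a CART regression tree and a multilayer perceptron.  Candidate
hyperparameters are scored by a 10-fold cross-validation over stride pairs,
stratified by label, in which

* fitting uses the bias-correcting per-pair weights, and
* the representative stride pairs used during feature selection are never
  scored: whenever one lands in a held-out fold it is moved back to the
  training side of that fold (they informed the feature set, so scoring them
  would bias the estimate upward; dropping them entirely would waste data).

The winning cell is refit on the full training partition.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.tree import DecisionTreeRegressor

from .explanation import evaluate_tree_document, export_tree
from .mlp import MLPRegressor

logger = logging.getLogger(__name__)

FAMILIES = ("dt", "mlp")

# hyperparameter grids ------------------------------------------------------

DT_MAX_FEATURES = ("sqrt", None, "log2")   # number of features tried per split
DT_SPLITTER = ("best", "random")
DT_MIN_WEIGHT_FRACTION = (0.00, 0.01, 0.02, 0.03, 0.04, 0.05)
DT_MAX_DEPTH = (3, 4, 5)

MLP_HIDDEN = ((16, 8), (32, 16, 8))
MLP_OUTPUT = ("linear", "relu")
MLP_LEARNING_RATES = (1e-3, 1e-4, 1e-5)
# finer learning rates scanned only when 1e-5 wins the base grid
MLP_REFINED_RATES = (7.5e-5, 5.0e-5, 2.5e-5, 1.0e-5, 7.5e-6, 5.0e-6, 2.5e-6)


def dt_grid() -> list[dict]:
    return [
        {"max_features": mf, "splitter": sp, "min_weight_fraction": mw, "max_depth": md}
        for mf, sp, mw, md in itertools.product(
            DT_MAX_FEATURES, DT_SPLITTER, DT_MIN_WEIGHT_FRACTION, DT_MAX_DEPTH)
    ]


def mlp_grid() -> list[dict]:
    return [
        {"hidden_layers": h, "output_activation": act, "learning_rate": lr}
        for h, act, lr in itertools.product(MLP_HIDDEN, MLP_OUTPUT, MLP_LEARNING_RATES)
    ]


# fitting -------------------------------------------------------------------


def fit_dt(X, y, sample_weight, hp: dict, seed: int = 0) -> DecisionTreeRegressor:
    """Weighted CART regression tree with the given grid-cell hyperparameters."""
    model = DecisionTreeRegressor(
        criterion="squared_error",
        splitter=hp["splitter"],
        max_features=hp["max_features"],
        min_weight_fraction_leaf=hp["min_weight_fraction"],
        max_depth=hp["max_depth"],
        random_state=seed,
    )
    return model.fit(np.asarray(X, float), np.asarray(y, float),
                     sample_weight=np.asarray(sample_weight, float))


def fit_mlp(X, y, sample_weight, hp: dict, seed: int = 0,
            epochs: int = 300, batch_size: int = 32) -> MLPRegressor:
    """Weighted-MSE multilayer perceptron for one grid cell."""
    model = MLPRegressor(
        hidden_layers=hp["hidden_layers"],
        output_activation=hp["output_activation"],
        learning_rate=hp["learning_rate"],
        epochs=hp.get("epochs", epochs),
        batch_size=hp.get("batch_size", batch_size),
        seed=seed,
    )
    return model.fit(np.asarray(X, float), np.asarray(y, float),
                     sample_weight=np.asarray(sample_weight, float))


def _fit(family: str, X, y, w, hp: dict, seed: int, mlp_epochs: int, mlp_batch: int):
    if family == "dt":
        return fit_dt(X, y, w, hp, seed)
    if family == "mlp":
        return fit_mlp(X, y, w, hp, seed, epochs=mlp_epochs, batch_size=mlp_batch)
    raise ValueError(f"unknown model family {family!r}")


# cross-validation ----------------------------------------------------------


def cv_evaluate(
    family: str,
    hp: dict,
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    rep_mask: np.ndarray,
    k: int = 10,
    seed: int = 0,
    mlp_epochs: int = 300,
    mlp_batch: int = 32,
    groups: np.ndarray | None = None,
) -> float:
    """Mean held-out R^2 of one hyperparameter cell under k-fold CV.

    Folds are stratified by label over stride pairs (patients may straddle
    folds); passing ``groups`` switches to label-stratified folds that keep
    each patient's pairs together.  Rows flagged in ``rep_mask`` (the
    representative pairs) are reinserted into the training side of any fold
    that holds them out, so they are never scored.  Folds whose validation
    side empties after reinsertion are skipped.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    weights = np.asarray(weights, float)
    rep_mask = np.asarray(rep_mask, bool)
    scores = []
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="The least populated class")
        if groups is None:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = list(skf.split(X, y.astype(int)))
        else:
            sgk = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = list(sgk.split(X, y.astype(int), np.asarray(groups)))
    for fold_i, (tr, va) in enumerate(folds):
        va_keep = va[~rep_mask[va]]
        tr_full = np.concatenate([tr, va[rep_mask[va]]])
        if len(va_keep) == 0:
            logger.warning("fold %d empty after representative-pair reinsertion; skipped",
                           fold_i)
            continue
        model = _fit(family, X[tr_full], y[tr_full], weights[tr_full], hp,
                     seed=seed + fold_i, mlp_epochs=mlp_epochs, mlp_batch=mlp_batch)
        pred = model.predict(X[va_keep])
        if np.var(y[va_keep]) == 0:
            continue
        scores.append(r2_score(y[va_keep], pred))
    if not scores:
        raise RuntimeError("no scorable fold in cross-validation")
    return float(np.mean(scores))


@dataclass
class TrainedScoreModel:
    """A fitted per-subscore predictor with its selection and CV provenance."""

    target: str
    family: str
    hyperparameters: dict
    predictor: object
    features: tuple[str, ...]
    cv_results: pd.DataFrame = field(repr=False, default=None)
    cv_mean_r2: float = float("nan")
    seed: int = 0

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table.loc[:, list(self.features)].to_numpy(dtype=float)
        return np.asarray(self.predictor.predict(X), dtype=float)


def grid_search(
    target: str,
    family: str,
    train_table: pd.DataFrame,
    features: tuple[str, ...] | list[str],
    weights: pd.Series,
    rep_index: pd.Index,
    k: int = 10,
    seed: int = 0,
    mlp_epochs: int = 300,
    mlp_batch: int = 32,
    groups: pd.Series | None = None,
) -> TrainedScoreModel:
    """Exhaustive grid search with weighted representative-aware CV.

    The MLP grid applies the conditional refinement: if the smallest base
    learning rate (1e-5) wins, seven finer rates are additionally scanned
    with the winning architecture and output activation fixed.  The winner
    is refit on the full training partition.
    """
    features = tuple(features)
    if not features:
        raise ValueError(f"empty feature set for target {target!r}")
    X = train_table.loc[:, list(features)].to_numpy(dtype=float)
    y = train_table[target].to_numpy(dtype=float)
    w = weights.loc[train_table.index].to_numpy(dtype=float)
    rep_mask = train_table.index.isin(rep_index)
    group_arr = None if groups is None else groups.loc[train_table.index].to_numpy()

    cells = dt_grid() if family == "dt" else mlp_grid()
    records = []

    def score(hp: dict) -> float:
        return cv_evaluate(family, hp, X, y, w, rep_mask, k=k, seed=seed,
                           mlp_epochs=mlp_epochs, mlp_batch=mlp_batch,
                           groups=group_arr)

    for hp in cells:
        records.append({**hp, "cv_mean_r2": score(hp)})

    if family == "mlp":
        best_base = max(records, key=lambda r: r["cv_mean_r2"])
        if best_base["learning_rate"] == min(MLP_LEARNING_RATES):
            for lr in MLP_REFINED_RATES:
                hp = {"hidden_layers": best_base["hidden_layers"],
                      "output_activation": best_base["output_activation"],
                      "learning_rate": lr}
                records.append({**hp, "cv_mean_r2": score(hp)})

    results = pd.DataFrame(records)
    best_i = int(results["cv_mean_r2"].idxmax())
    best = {}
    for key in records[0]:
        if key == "cv_mean_r2":
            continue
        v = results.loc[best_i, key]
        if isinstance(v, np.floating):
            v = float(v)
        elif isinstance(v, np.integer):
            v = int(v)
        elif not isinstance(v, (tuple, str)) and pd.isna(v):
            v = None
        best[key] = v
    predictor = _fit(family, X, y, w, best, seed=seed,
                     mlp_epochs=mlp_epochs, mlp_batch=mlp_batch)
    return TrainedScoreModel(
        target=target, family=family, hyperparameters=best, predictor=predictor,
        features=features, cv_results=results,
        cv_mean_r2=float(results.loc[best_i, "cv_mean_r2"]), seed=seed)


# model-bundle serialization ------------------------------------------------


class _TreeDocumentPredictor:
    """Predictor backed by an exported tree document (for reloaded bundles)."""

    def __init__(self, doc: dict, features: tuple[str, ...]):
        self.doc = doc
        self.features = features

    def predict(self, X) -> np.ndarray:
        df = pd.DataFrame(np.asarray(X, float), columns=list(self.features))
        return evaluate_tree_document(self.doc, df)


def save_bundle(model: TrainedScoreModel, out_dir) -> None:
    """Write a self-describing JSON model bundle (predictor, features, CV table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if model.family == "dt":
        payload = {"kind": "tree_document",
                   "document": export_tree(model.predictor, list(model.features))}
    else:
        mlp: MLPRegressor = model.predictor
        payload = {
            "kind": "mlp",
            "params": mlp.get_params(),
            "x_mean": mlp.x_mean_.tolist(),
            "x_std": mlp.x_std_.tolist(),
            "weights": [W.tolist() for W in mlp.weights_],
            "biases": [b.tolist() for b in mlp.biases_],
        }
    hp = {key: (list(v) if isinstance(v, tuple) else v)
          for key, v in model.hyperparameters.items()}
    doc = {
        "target": model.target,
        "family": model.family,
        "hyperparameters": hp,
        "features": list(model.features),
        "cv_mean_r2": model.cv_mean_r2,
        "seed": model.seed,
        "predictor": payload,
    }
    (out / "model.json").write_text(json.dumps(doc))
    if model.cv_results is not None:
        model.cv_results.to_csv(out / "cv_results.csv", index=False)


def load_bundle(in_dir) -> TrainedScoreModel:
    src = Path(in_dir)
    doc = json.loads((src / "model.json").read_text())
    features = tuple(doc["features"])
    payload = doc["predictor"]
    if payload["kind"] == "tree_document":
        predictor = _TreeDocumentPredictor(payload["document"], features)
    else:
        mlp = MLPRegressor(**payload["params"])
        mlp.x_mean_ = np.array(payload["x_mean"])
        mlp.x_std_ = np.array(payload["x_std"])
        mlp.weights_ = [np.array(W) for W in payload["weights"]]
        mlp.biases_ = [np.array(b) for b in payload["biases"]]
        predictor = mlp
    cv_path = src / "cv_results.csv"
    cv = pd.read_csv(cv_path) if cv_path.exists() else None
    return TrainedScoreModel(
        target=doc["target"], family=doc["family"],
        hyperparameters=doc["hyperparameters"], predictor=predictor,
        features=features, cv_results=cv, cv_mean_r2=doc["cv_mean_r2"],
        seed=doc["seed"])
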