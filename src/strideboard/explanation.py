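"""Global model intelligibility: tree export, tree importance, permutation importance.

Decision trees are interpreted directly from their structure: a feature's
importance is its total contribution to reducing the weighted squared error
over all splits that use it (normalized to sum 1).  Networks (or any other
predictor) are explained by permutation importance: the mean drop in R^2
when one feature's column is randomly shuffled, averaged over many
repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score
from sklearn.tree import DecisionTreeRegressor

from .gait_features import feature_side


# --------------------------------------------------------------------------
# decision-tree structure export
# --------------------------------------------------------------------------

def export_tree(tree: DecisionTreeRegressor, feature_names: list[str] | tuple[str, ...]) -> dict:
    """Nested split-record document of a fitted regression tree.

    Per node: feature, threshold, weighted sample fraction, node prediction;
    leaves carry fraction and prediction only.
    """
    t = tree.tree_
    total_w = t.weighted_n_node_samples[0]

    def node(i: int) -> dict:
        rec = {
            "weighted_fraction": float(t.weighted_n_node_samples[i] / total_w),
            "prediction": float(t.value[i].ravel()[0]),
        }
        if t.children_left[i] != -1:
            rec["feature"] = feature_names[t.feature[i]]
            rec["threshold"] = float(t.threshold[i])
            rec["left"] = node(t.children_left[i])
            rec["right"] = node(t.children_right[i])
        return rec

    return node(0)


def evaluate_tree_document(doc: dict, X: pd.DataFrame) -> np.ndarray:
    """Predict from an exported tree document (left branch: feature <= threshold)."""
    out = np.empty(len(X))
    cols = {c: X[c].to_numpy(dtype=float) for c in X.columns}
    for i in range(len(X)):
        node = doc
        while "feature" in node:
            node = node["left"] if cols[node["feature"]][i] <= node["threshold"] else node["right"]
        out[i] = node["prediction"]
    return out


def tree_depth(doc: dict) -> int:
    if "feature" not in doc:
        return 0
    return 1 + max(tree_depth(doc["left"]), tree_depth(doc["right"]))


def tree_to_dot(doc: dict, title: str = "tree") -> str:
    """Graphviz DOT rendering of an exported tree document."""
    lines = [f'digraph "{title}" {{', "node [shape=box];"]
    counter = [0]

    def walk(node: dict) -> int:
        i = counter[0]
        counter[0] += 1
        if "feature" in node:
            label = (f"{node['feature']} <= {node['threshold']:.3g}\\n"
                     f"frac={node['weighted_fraction']:.2f} "
                     f"pred={node['prediction']:.2f}")
        else:
            label = (f"frac={node['weighted_fraction']:.2f}\\n"
                     f"pred={node['prediction']:.2f}")
        lines.append(f'n{i} [label="{label}"];')
        if "feature" in node:
            left = walk(node["left"])
            right = walk(node["right"])
            lines.append(f"n{i} -> n{left};")
            lines.append(f"n{i} -> n{right};")
        return i

    walk(doc)
    lines.append("}")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# importance rankings
# --------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    target: str
    family: str
    ranking: pd.DataFrame  # columns: feature, importance, side
    repetitions: int | None = None
    tree_document: dict | None = None


def dt_importance(
    tree: DecisionTreeRegressor,
    feature_names: list[str] | tuple[str, ...],
) -> pd.DataFrame:
    """Ranked features by total weighted squared-error reduction over splits.

    Importances are normalized to sum 1; ties break by canonical feature
    order.  A single-node tree yields an empty ranking.
    """
    t = tree.tree_
    total_w = t.weighted_n_node_samples[0]
    gains: dict[int, float] = {}
    for i in range(t.node_count):
        left, right = t.children_left[i], t.children_right[i]
        if left == -1:
            continue
        w = t.weighted_n_node_samples
        gain = (w[i] * t.impurity[i]
                - w[left] * t.impurity[left]
                - w[right] * t.impurity[right]) / total_w
        gains[t.feature[i]] = gains.get(t.feature[i], 0.0) + gain
    if not gains:
        return pd.DataFrame(columns=["feature", "importance", "side"])
    total = sum(gains.values())
    rows = [{"feature": feature_names[f],
             "importance": g / total if total > 0 else 0.0,
             "side": feature_side(feature_names[f])}
            for f, g in gains.items()]
    df = pd.DataFrame(rows)
    order = {n: i for i, n in enumerate(feature_names)}
    df["_ord"] = df["feature"].map(order)
    df = (df.sort_values(["importance", "_ord"], ascending=[False, True])
            .drop(columns="_ord").reset_index(drop=True))
    return df


def permutation_importance(
    predict_fn,
    X: pd.DataFrame,
    y: np.ndarray,
    features: list[str] | tuple[str, ...] | None = None,
    repetitions: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean R^2 degradation per feature under random column shuffling.

    ``predict_fn`` maps a feature DataFrame to predictions.  Shuffling is
    global within the column.  Returns features in descending importance with
    the per-feature standard error over repetitions.
    """
    if len(X) < 2:
        raise ValueError("need at least two rows to score permutations")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    baseline = r2_score(y, predict_fn(X))
    if features is None:
        features = list(X.columns)
    rows = []
    Xw = X.copy()
    for feat in features:
        original = Xw[feat].to_numpy().copy()
        drops = np.empty(repetitions)
        for r in range(repetitions):
            Xw[feat] = original[rng.permutation(len(original))]
            drops[r] = baseline - r2_score(y, predict_fn(Xw))
        Xw[feat] = original
        rows.append({"feature": feat, "importance": float(drops.mean()),
                     "stderr": float(drops.std(ddof=1) / np.sqrt(repetitions)),
                     "side": feature_side(feat)})
    df = pd.DataFrame(rows).sort_values("importance", ascending=False).reset_index(drop=True)
    return df


def side_shares(ranking: pd.DataFrame) -> dict[str, float]:
    """Fraction of ipsilateral vs contralateral features among ranked features."""
    sided = ranking[ranking["side"].notna()]
    if sided.empty:
        return {"ipsi": float("nan"), "contra": float("nan")}
    counts = sided["side"].value_counts()
    n = counts.sum()
    return {"ipsi": float(counts.get("ipsi", 0) / n),
            "contra": float(counts.get("contra", 0) / n)}
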