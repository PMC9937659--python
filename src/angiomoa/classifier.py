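"""Fused target-prediction + DEG classification of angiogenesis modulators.

Feature fusion concatenates the binary predicted-target block (``TP:`` prefix)
and the binary DEG block (``DEG:`` prefix). An entropy decision tree (depth
<= 20, min leaf 4, balanced class weights) provides the interpretable model;
a balanced random forest (2000 trees by default) provides the predictive one.
Performance is estimated by leave-one-out cross-validation on the pooled
held-out probabilities, with the promoter class positive and an operating
probability threshold of 0.4 (shifted from 0.5 to compensate for the class
imbalance). The top-10 features by Gini importance give compact explainable
refits, and unknown compounds are ranked by their promoter probability under
the gene-only, target-only and fused models.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, export_graphviz

from .config import INHIBIT, PROMOTE, ModelConfig

logger = logging.getLogger(__name__)

MODES = ("TP_only", "DEG_only", "both")


@dataclass
class FeatureMatrix:
    """Binary compounds × features matrix with namespaced columns."""

    values: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.values.columns.has_duplicates:
            raise ValueError("feature ids must be globally unique")

    @property
    def compounds(self) -> pd.Index:
        return self.values.index


def fuse_features(tp: pd.DataFrame | None, deg: pd.DataFrame | None,
                  mode: str = "both") -> FeatureMatrix:
    """Concatenate binary TP and DEG blocks column-wise under namespaces.

    Compounds missing one required modality are excluded (logged). Width
    under mode="both" is n_TP + n_DEG columns.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    blocks = []
    if mode in ("TP_only", "both"):
        if tp is None:
            raise ValueError("mode requires a TP block")
        blocks.append(tp.add_prefix("TP:"))
    if mode in ("DEG_only", "both"):
        if deg is None:
            raise ValueError("mode requires a DEG block")
        blocks.append(deg.add_prefix("DEG:"))
    common = blocks[0].index
    for b in blocks[1:]:
        common = common.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no compound carries all required feature blocks")
    union = set().union(*(set(b.index) for b in blocks))
    dropped = sorted(union - set(common))
    if dropped:
        logger.info("fuse_features: excluded %d compounds missing a modality: %s",
                    len(dropped), dropped)
    fused = pd.concat([b.loc[common] for b in blocks], axis=1).astype(int)
    return FeatureMatrix(values=fused, mode=mode)


def class_weights(labels: pd.Series) -> tuple[dict[str, float], pd.Series]:
    """Balanced class weights w_c = n / (2 n_c) and the per-sample weights."""
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present")
    n = int(counts.sum())
    per_class = {str(c): n / (2 * int(k)) for c, k in counts.items()}
    per_sample = labels.map(per_class).astype(float)
    return per_class, per_sample


def _as_xy(X: FeatureMatrix | pd.DataFrame, labels: pd.Series):
    vals = X.values if isinstance(X, FeatureMatrix) else X
    labels = labels.loc[vals.index]
    y = (labels == PROMOTE).astype(int).to_numpy()
    return vals, labels, y


def train_tree(X: FeatureMatrix | pd.DataFrame, labels: pd.Series,
               cfg: ModelConfig | None = None) -> tuple[DecisionTreeClassifier, str, str]:
    """Fit the interpretable decision tree; returns (model, text, DOT).

    The text export lists, per node, the split feature, weighted class counts,
    entropy and the majority orientation (PROMOTE vs INHIBIT).
    """
    cfg = cfg or ModelConfig()
    vals, labels, y = _as_xy(X, labels)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 compounds per class")
    if (vals.to_numpy() == vals.to_numpy()[0]).all():
        logger.warning("all features constant; tree degenerates to its root")
    _, sw = class_weights(labels)
    model = DecisionTreeClassifier(
        criterion=cfg.tree_criterion, max_depth=cfg.tree_max_depth,
        min_samples_leaf=cfg.tree_min_samples_leaf, random_state=cfg.seed)
    model.fit(vals.to_numpy(), y, sample_weight=sw.to_numpy())
    text = export_tree_text(model, list(vals.columns))
    dot = export_graphviz(model, feature_names=list(vals.columns),
                          class_names=[INHIBIT, PROMOTE], filled=False)
    return model, text, dot


def export_tree_text(model: DecisionTreeClassifier, feature_names: list[str]) -> str:
    """Indented per-node dump: feature, weighted counts, entropy, orientation."""
    t = model.tree_
    buf = io.StringIO()

    def entropy(counts: np.ndarray) -> float:
        tot = counts.sum()
        if tot <= 0:
            return 0.0
        p = counts[counts > 0] / tot
        return float(-(p * np.log2(p)).sum()) + 0.0  # +0.0 normalizes -0.0

    def walk(node: int, depth: int) -> None:
        counts = t.value[node][0] * t.weighted_n_node_samples[node] / max(t.value[node][0].sum(), 1e-300)
        inh, pro = counts[0], counts[1]
        orient = PROMOTE if pro >= inh else INHIBIT
        head = "  " * depth
        stats = (f"n={t.n_node_samples[node]} weighted=({INHIBIT}:{inh:.2f}, "
                 f"{PROMOTE}:{pro:.2f}) entropy={entropy(counts):.3f} -> {orient}")
        if t.children_left[node] == -1:
            buf.write(f"{head}leaf: {stats}\n")
        else:
            fname = feature_names[t.feature[node]]
            buf.write(f"{head}[{fname} <= {t.threshold[node]:.3f}] {stats}\n")
            walk(t.children_left[node], depth + 1)
            walk(t.children_right[node], depth + 1)

    walk(0, 0)
    return buf.getvalue()


def train_forest(X: FeatureMatrix | pd.DataFrame, labels: pd.Series,
                 cfg: ModelConfig | None = None) -> RandomForestClassifier:
    """Fit the balanced random forest (seeded, bootstrap on)."""
    cfg = cfg or ModelConfig()
    vals, labels, y = _as_xy(X, labels)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 compounds per class")
    model = RandomForestClassifier(
        n_estimators=cfg.forest_n_trees, criterion=cfg.tree_criterion,
        class_weight="balanced", random_state=cfg.seed, n_jobs=1)
    model.fit(vals.to_numpy(), y)
    return model


def promoter_probability(model, X: pd.DataFrame) -> pd.Series:
    """P(PROMOTE) for each row of X under a fitted binary model."""
    proba = model.predict_proba(X.to_numpy())
    col = list(model.classes_).index(1)
    return pd.Series(proba[:, col], index=X.index, name="p_promote")


def concordance_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC as the pairwise-concordance probability.

    Over all (positive, negative) pairs: concordant pairs count 1, ties 0.5.
    Equals the trapezoidal area under the ROC curve.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return math.nan
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity / specificity / accuracy with promoters as positives.

    An empty class yields NaN (undefined), never a silent 0.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be nonnegative")
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else math.nan
    spec = tn / n_neg if n_neg else math.nan
    n = n_pos + n_neg
    acc = (tp + tn) / n if n else math.nan
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "tp": tp, "fn": fn, "tn": tn, "fp": fp}


def compute_metrics(labels: pd.Series, probabilities: pd.Series,
                    threshold: float = 0.4) -> dict[str, float]:
    """Threshold pooled promoter probabilities and score against labels.

    A compound is called PROMOTE iff its probability >= threshold. Returns
    sensitivity, specificity, accuracy (at the threshold) and the
    threshold-free pairwise-concordance ROC-AUC.
    """
    labels = labels.loc[probabilities.index]
    y = (labels == PROMOTE).astype(int).to_numpy()
    p = probabilities.to_numpy(dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    out = metrics_from_confusion(tp, fn, tn, fp)
    out["roc_auc"] = concordance_auc(y, p)
    out["threshold"] = threshold
    return out


@dataclass
class CVReport:
    """Leave-one-out CV result: pooled held-out probabilities and metrics."""

    probabilities: pd.Series          # compound → held-out P(PROMOTE)
    labels: pd.Series
    threshold: float
    metrics: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"p_promote": self.probabilities,
                           "label": self.labels.loc[self.probabilities.index]})
        df.index.name = "compound_id"
        return df


def loo_cv(X: FeatureMatrix | pd.DataFrame, labels: pd.Series,
           cfg: ModelConfig | None = None, model_kind: str = "forest") -> CVReport:
    """Leave-one-out CV: n fits each excluding one compound; metrics on the
    pooled held-out promoter probabilities at cfg.promoter_threshold."""
    cfg = cfg or ModelConfig()
    vals, labels, y = _as_xy(X, labels)
    n = len(vals)
    if n < 3:
        raise ValueError("leave-one-out needs >= 3 labelled compounds")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 compounds per class so every fold keeps both")
    probs = np.empty(n)
    arr = vals.to_numpy()
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = arr[mask], y[mask]
        if model_kind == "forest":
            m = RandomForestClassifier(
                n_estimators=cfg.forest_n_trees, criterion=cfg.tree_criterion,
                class_weight="balanced", random_state=cfg.seed, n_jobs=1)
            m.fit(Xi, yi)
        elif model_kind == "tree":
            m = DecisionTreeClassifier(
                criterion=cfg.tree_criterion, max_depth=cfg.tree_max_depth,
                min_samples_leaf=cfg.tree_min_samples_leaf, random_state=cfg.seed)
            frac = yi.mean()
            sw = np.where(yi == 1, 0.5 / max(frac, 1e-12), 0.5 / max(1 - frac, 1e-12))
            m.fit(Xi, yi, sample_weight=sw)
        else:
            raise ValueError("model_kind must be 'forest' or 'tree'")
        col = list(m.classes_).index(1)
        probs[i] = m.predict_proba(arr[i:i + 1])[0, col]
    series = pd.Series(probs, index=vals.index, name="p_promote")
    metrics = compute_metrics(labels, series, threshold=cfg.promoter_threshold)
    return CVReport(probabilities=series, labels=labels,
                    threshold=cfg.promoter_threshold, metrics=metrics)


def calibrate_threshold(probabilities: pd.Series, labels: pd.Series,
                        grid=None, configured: float = 0.4) -> tuple[pd.DataFrame, float]:
    """Metric curve over a threshold grid plus the operating threshold.

    Reports sensitivity/specificity/accuracy/balanced accuracy per grid point
    and the grid argmax of balanced accuracy, but always returns the
    configured operating threshold (never silently overridden).
    """
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0, 0.05), 2)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 2 or len(np.unique(grid)) < 2:
        raise ValueError("threshold grid must contain >= 2 distinct values")
    rows = []
    for t in grid:
        m = compute_metrics(labels, probabilities, threshold=float(t))
        bal = (m["sensitivity"] + m["specificity"]) / 2
        rows.append({"threshold": float(t), "sensitivity": m["sensitivity"],
                     "specificity": m["specificity"], "accuracy": m["accuracy"],
                     "balanced_accuracy": bal,
                     "n_called_promoter": int(m["tp"] + m["fp"])})
    curve = pd.DataFrame(rows)
    best = float(curve.loc[curve["balanced_accuracy"].idxmax(), "threshold"])
    logger.info("threshold calibration: balanced-accuracy argmax %.2f; "
                "operating threshold kept at %.2f", best, configured)
    curve.attrs["balanced_accuracy_argmax"] = best
    curve.attrs["operating_threshold"] = configured
    return curve, configured


def gini_top_features(forest: RandomForestClassifier, feature_names: list[str],
                      k: int = 10) -> pd.DataFrame:
    """Rank features by mean impurity-decrease (Gini) importance; top-k.

    Ties broken by feature name. k larger than the width returns everything
    (warning). The all-zero degenerate case is flagged.
    """
    imp = np.asarray(forest.feature_importances_, dtype=float)
    if len(imp) != len(feature_names):
        raise ValueError("feature_names length must match the fitted forest")
    if k > len(imp):
        logger.warning("k=%d exceeds feature count %d; returning all", k, len(imp))
        k = len(imp)
    df = pd.DataFrame({"feature": feature_names, "importance": imp})
    df["degenerate"] = bool(np.all(imp == 0))
    if df["degenerate"].iloc[0]:
        logger.warning("all feature importances are zero")
    df = df.sort_values(["importance", "feature"], ascending=[False, True],
                        kind="stable").head(k).reset_index(drop=True)
    return df


def refit_top_features(X: FeatureMatrix | pd.DataFrame, labels: pd.Series,
                       features: list[str], cfg: ModelConfig | None = None):
    """Refit compact explainable models (tree + forest) on selected columns."""
    cfg = cfg or ModelConfig()
    vals = X.values if isinstance(X, FeatureMatrix) else X
    sub = vals[features]
    tree, text, dot = train_tree(sub, labels, cfg)
    forest = train_forest(sub, labels, cfg)
    return {"tree": tree, "tree_text": text, "tree_dot": dot,
            "forest": forest, "features": list(features)}


def predict_unknowns(models: dict[str, tuple], unknown_blocks: dict[str, pd.DataFrame],
                     threshold: float = 0.4) -> pd.DataFrame:
    """Rank unknown compounds by promoter probability under each model.

    ``models`` maps column name ("both" / "gene" / "tp") to (fitted model,
    feature column list); ``unknown_blocks`` maps the same keys to the unknown
    compounds' feature matrices (columns already namespaced). Output columns
    prediction_<key>, sorted descending by prediction_both (ties: compound
    id), with the promoter/inhibitor call at the operating threshold.
    """
    cols = {}
    index: pd.Index | None = None
    for key, (model, feats) in models.items():
        block = unknown_blocks.get(key)
        if block is None:
            logger.info("no unknown features for model %s; column omitted", key)
            continue
        missing = [f for f in feats if f not in block.columns]
        if missing:
            raise ValueError(f"unknown compounds lack features for model {key}: "
                             f"{missing[:5]}...")
        if len(block) == 0:
            index = block.index if index is None else index
            continue
        cols[f"prediction_{key}"] = promoter_probability(model, block[feats])
        index = block.index if index is None else index
    if index is None or len(index) == 0 or not cols:
        return pd.DataFrame(columns=[f"prediction_{k}" for k in models] + ["call"])
    table = pd.DataFrame(cols, index=index)
    table.index.name = "compound_id"
    if "prediction_both" in table:
        table["call"] = np.where(table["prediction_both"] >= threshold,
                                 PROMOTE, INHIBIT)
        # deterministic strict ordering: descending probability, then compound id
        table = (table.reset_index()
                 .sort_values(["prediction_both", "compound_id"],
                              ascending=[False, True], kind="stable")
                 .set_index("compound_id"))
        table["rank"] = range(1, len(table) + 1)
    return table
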