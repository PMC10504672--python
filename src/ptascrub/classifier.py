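"""Random-forest artifact classifier with its two fallback models.

The main model uses all 26 features.  Because a small fraction of
candidates lack an allelic-imbalance p-value or a replication-timing
value, two additional forests are trained on the same rows minus the
missing column(s): one without allelic imbalance (25 features) and one
without allelic imbalance and replication timing (24 features).  At
scoring time a candidate is routed to the most complete model its defined
features allow.  The artifact probability is the forest's class-1 vote
fraction; higher means more likely artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ptascrub.config import PipelineConfig
from ptascrub.features import FEATURE_COLUMNS, FeatureVector, encode_features

SCHEMA_VERSION = 1

COLUMNS_FULL = list(FEATURE_COLUMNS)
COLUMNS_NO_AI = [c for c in COLUMNS_FULL if c != "ai_log_p"]
COLUMNS_NO_AI_NO_RT = [c for c in COLUMNS_NO_AI if c != "replication_timing"]

LABEL_TRUE = 0
LABEL_ARTIFACT = 1


@dataclass
class RFBundle:
    model_full: RandomForestClassifier
    model_no_ai: RandomForestClassifier
    model_no_ai_no_rt: RandomForestClassifier
    training_features: pd.DataFrame        # the balanced training rows (26 cols)
    training_labels: np.ndarray
    training_row_indices: np.ndarray       # indices into the original feature list
    seed: int
    n_trees: int
    mtry: int
    class_counts: dict[int, int] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def oob_probabilities(self) -> np.ndarray:
        """Out-of-bag artifact probability for every training row."""
        return self.model_full.oob_decision_function_[:, LABEL_ARTIFACT]

    def oob_balanced_accuracy(self) -> float:
        pred = (self.oob_probabilities() > 0.5).astype(int)
        return balanced_accuracy(self.training_labels, pred)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(true positive rate + true negative rate) / 2."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tpr = np.mean(y_pred[y_true == 1] == 1) if (y_true == 1).any() else np.nan
    tnr = np.mean(y_pred[y_true == 0] == 0) if (y_true == 0).any() else np.nan
    return float((tpr + tnr) / 2.0)


def _new_forest(n_trees: int, mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )


def train_rf(
    features: list[FeatureVector] | pd.DataFrame,
    labels,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> RFBundle:
    """Train the three-forest bundle on labeled candidates.

    Rows with an undefined allelic-imbalance or replication-timing value
    are excluded from training; the majority class is subsampled to a 1:1
    balance before fitting.  All three models are trained on identical
    rows, differing only in the dropped columns.
    """
    cfg = config or PipelineConfig()
    X = features if isinstance(features, pd.DataFrame) else encode_features(features)
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise ValueError("features and labels differ in length")

    complete = (~X[["ai_log_p", "replication_timing"]].isna().any(axis=1)).to_numpy()
    original_indices = np.flatnonzero(complete)
    X, y = X.loc[complete].reset_index(drop=True), y[complete]

    n_true = int((y == LABEL_TRUE).sum())
    n_art = int((y == LABEL_ARTIFACT).sum())
    if n_true == 0 or n_art == 0:
        raise ValueError(
            f"both classes required for training (true={n_true}, artifact={n_art})"
        )
    rng = np.random.default_rng(seed)
    n_keep = min(n_true, n_art)
    keep_idx = []
    for label, n_label in ((LABEL_TRUE, n_true), (LABEL_ARTIFACT, n_art)):
        idx = np.flatnonzero(y == label)
        if n_label > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep_idx.append(np.sort(idx))
    keep = np.concatenate(keep_idx)
    X, y = X.iloc[keep].reset_index(drop=True), y[keep]
    original_indices = original_indices[keep]

    model_full = _new_forest(cfg.rf_n_trees, cfg.rf_mtry, seed).fit(X[COLUMNS_FULL], y)
    model_no_ai = _new_forest(cfg.rf_n_trees, cfg.rf_mtry, seed).fit(X[COLUMNS_NO_AI], y)
    model_no_ai_no_rt = _new_forest(cfg.rf_n_trees, cfg.rf_mtry, seed).fit(
        X[COLUMNS_NO_AI_NO_RT], y
    )
    return RFBundle(
        model_full=model_full,
        model_no_ai=model_no_ai,
        model_no_ai_no_rt=model_no_ai_no_rt,
        training_features=X,
        training_labels=y,
        training_row_indices=original_indices,
        seed=seed,
        n_trees=cfg.rf_n_trees,
        mtry=cfg.rf_mtry,
        class_counts={LABEL_TRUE: int((y == 0).sum()), LABEL_ARTIFACT: int((y == 1).sum())},
    )


def artifact_probability(bundle: RFBundle, fv: FeatureVector) -> float:
    """Score one candidate, routing to the fallback models as needed."""
    return artifact_probabilities(bundle, [fv])[0]


def artifact_probabilities(bundle: RFBundle, vectors: list[FeatureVector]) -> np.ndarray:
    """Vectorized scoring with per-row model routing.

    Full model when every feature is defined; no-AI model when only the
    allelic imbalance is undefined; no-AI-no-RT model when replication
    timing is (also) undefined.
    """
    X = encode_features(vectors)
    out = np.empty(len(X))
    ai_ok = ~X["ai_log_p"].isna().to_numpy()
    rt_ok = ~X["replication_timing"].isna().to_numpy()
    groups = (
        (ai_ok & rt_ok, bundle.model_full, COLUMNS_FULL),
        (~ai_ok & rt_ok, bundle.model_no_ai, COLUMNS_NO_AI),
        (~rt_ok, bundle.model_no_ai_no_rt, COLUMNS_NO_AI_NO_RT),
    )
    for mask, model, cols in groups:
        if mask.any():
            out[mask] = model.predict_proba(X.loc[mask, cols])[:, LABEL_ARTIFACT]
    return out


def oob_or_predicted_probabilities(bundle: RFBundle, vectors: list[FeatureVector]) -> np.ndarray:
    """Artifact probabilities with out-of-bag values for rows the bundle trained on.

    When scoring the very set a bundle was trained from, plain
    predictions on training rows are degenerate (near 0/1); substituting
    each training row's out-of-bag vote fraction gives an unbiased
    probability while the excluded/undefined rows still go through the
    routed models.
    """
    probs = artifact_probabilities(bundle, vectors)
    probs[bundle.training_row_indices] = bundle.oob_probabilities()
    return probs


def feature_importance(bundle: RFBundle) -> pd.Series:
    """Impurity-decrease (Gini) importance of the full model, descending."""
    imp = pd.Series(bundle.model_full.feature_importances_, index=COLUMNS_FULL)
    return imp.sort_values(ascending=False)


def importance_and_ablation(bundle: RFBundle) -> tuple[pd.Series, pd.DataFrame]:
    """Ranked importance plus the balanced-accuracy-vs-k ablation curve.

    Features are removed one at a time, lowest impurity-decrease
    importance first; each reduced forest is retrained on the same rows
    and evaluated by out-of-bag balanced accuracy.
    """
    importance = feature_importance(bundle)
    X, y = bundle.training_features, bundle.training_labels
    cols = list(COLUMNS_FULL)
    records = []
    while cols:
        model = _new_forest(bundle.n_trees, min(bundle.mtry, len(cols)), bundle.seed)
        model.fit(X[cols], y)
        oob_pred = (model.oob_decision_function_[:, LABEL_ARTIFACT] > 0.5).astype(int)
        records.append({"k": len(cols), "balanced_accuracy": balanced_accuracy(y, oob_pred)})
        drop = min(cols, key=lambda c: (model.feature_importances_[cols.index(c)], c))
        cols.remove(drop)
    return importance, pd.DataFrame(records)


def save_bundle(bundle: RFBundle, path) -> None:
    """Serialize to a single versioned file with embedded config and seed."""
    import joblib

    joblib.dump(
        {
            "schema_version": bundle.schema_version,
            "feature_columns": COLUMNS_FULL,
            "bundle": bundle,
        },
        path,
    )


def load_bundle(path) -> RFBundle:
    import joblib

    payload = joblib.load(path)
    if payload.get("schema_version") != SCHEMA_VERSION or payload.get(
        "feature_columns"
    ) != COLUMNS_FULL:
        raise ValueError("model bundle schema does not match this package version")
    return payload["bundle"]
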