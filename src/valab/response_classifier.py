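"""Acute-ablation-response prediction from imaging, electrical, and lesion metrics.

A feature row is one (anatomy, strategy) case: three imaging features, two
electrical features, five lesion metrics, a one-hot strategy encoding, and a
binary label (0 = responder, 1 = non-responder). Random-forest classifiers
are trained for three nested feature sets with a grouped 70:30 anatomy-level
split, grid-searched over a fixed hyperparameter table by five-fold grouped
cross-validation maximizing balanced accuracy, with class-balanced weighting.
Per-case additive feature attributions use exact decision-path attribution
(each split's change in expected prediction is credited to its split feature),
which satisfies local accuracy: attributions sum to prediction minus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ablation_planner import STRATEGIES

IMAGING_FEATURES = ["la_body_area", "pv_area", "fibrosis_area"]
ELECTRICAL_FEATURES = ["mean_df", "hotspot_area"]
LESION_FEATURES = ["remaining_hotspot_area", "remaining_la_area",
                   "remaining_fibrosis_area", "roof_width", "min_channel_height"]
STRATEGY_FEATURES = [f"strategy_{s}" for s in STRATEGIES]

FEATURE_SETS = {
    "imaging": IMAGING_FEATURES + STRATEGY_FEATURES,
    "imaging+electrical": IMAGING_FEATURES + ELECTRICAL_FEATURES + STRATEGY_FEATURES,
    "imaging+electrical+lesion": (IMAGING_FEATURES + ELECTRICAL_FEATURES
                                  + LESION_FEATURES + STRATEGY_FEATURES),
}

#: hyperparameter grid searched by cross-validation
RF_GRID = {
    "n_estimators": [10, 20, 50, 70, 80, 100],
    "max_depth": [4, 8, 16],
    "min_samples_leaf": [5, 10, 20],
}


@dataclass
class ClassifierReport:
    feature_set: str
    model_family: str
    chosen_params: dict
    accuracy: float
    precision: float
    recall: float
    attribution_ranking: list = field(default_factory=list)  # (feature, mean |attr|)

    def metrics(self) -> tuple:
        return (self.accuracy, self.precision, self.recall)


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def build_feature_table(case_results: list) -> pd.DataFrame:
    """Assemble the per-case feature table.

    ``case_results`` holds one dict per (anatomy, strategy) with keys:
    anatomy_id, strategy, the imaging/electrical features, the lesion
    metrics, and responder (bool). Exactly n_anatomies x 6 rows must be
    present; ordering is (anatomy, strategy).
    """
    df = pd.DataFrame(case_results)
    required = (["anatomy_id", "strategy", "responder"] + IMAGING_FEATURES
                + ELECTRICAL_FEATURES + LESION_FEATURES)
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"feature rows missing columns: {missing_cols}")
    anatomies = sorted(df["anatomy_id"].unique())
    missing = [(a, s) for a in anatomies for s in STRATEGIES
               if not ((df["anatomy_id"] == a) & (df["strategy"] == s)).any()]
    if missing:
        raise ValueError(f"missing cases: {missing}")
    df = df.set_index(["anatomy_id", "strategy"]).loc[
        [(a, s) for a in anatomies for s in STRATEGIES]].reset_index()
    for s in STRATEGIES:
        df[f"strategy_{s}"] = (df["strategy"] == s).astype(float)
    df["label"] = (~df["responder"].astype(bool)).astype(int)  # 1 = non-responder
    feature_cols = (IMAGING_FEATURES + ELECTRICAL_FEATURES + LESION_FEATURES
                    + [f"strategy_{s}" for s in STRATEGIES] + ["label"])
    if df[feature_cols].isna().any().any():
        bad = df[feature_cols].columns[df[feature_cols].isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}")
    return df


def grouped_split(table: pd.DataFrame, train_fraction: float = 0.7,
                  seed: int = 0):
    """Anatomy-level train/test split: all six strategies of an anatomy stay
    together; train anatomy count = round(train_fraction * n_anatomies)."""
    if len(table) == 0:
        raise ValueError("empty feature table")
    anatomies = np.array(sorted(table["anatomy_id"].unique()))
    if len(anatomies) < 2:
        raise ValueError("need at least 2 anatomies to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(anatomies))
    n_train = int(round(train_fraction * len(anatomies)))
    n_train = min(max(n_train, 1), len(anatomies) - 1)
    train_ids = set(anatomies[perm[:n_train]].tolist())
    is_train = table["anatomy_id"].isin(train_ids)
    return table[is_train].copy(), table[~is_train].copy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _xy(table: pd.DataFrame, feature_set: str):
    cols = FEATURE_SETS[feature_set]
    return table[cols].to_numpy(float), table["label"].to_numpy(int), cols


def train_and_evaluate(train: pd.DataFrame, test: pd.DataFrame,
                       feature_set: str = "imaging+electrical+lesion",
                       seed: int = 0) -> tuple:
    """Grid-searched random forest; returns (report, fitted model, columns)."""
    if len(train) == 0 or len(test) == 0:
        raise ValueError("train and test sets must be non-empty")
    x_tr, y_tr, cols = _xy(train, feature_set)
    x_te, y_te, _ = _xy(test, feature_set)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training data contains a single class")
    groups = train["anatomy_id"].to_numpy()
    cv = GroupKFold(n_splits=min(5, len(np.unique(groups))))
    base = RandomForestClassifier(random_state=seed, class_weight="balanced")
    search = GridSearchCV(base, RF_GRID, scoring="balanced_accuracy",
                          cv=cv.split(x_tr, y_tr, groups), n_jobs=1)
    search.fit(x_tr, y_tr)
    model = search.best_estimator_
    y_hat = model.predict(x_te)
    attr = feature_attribution(model, x_te)
    ranking = sorted(zip(cols, np.abs(attr).mean(axis=0)),
                     key=lambda kv: -kv[1])
    report = ClassifierReport(
        feature_set=feature_set, model_family="random_forest",
        chosen_params=search.best_params_,
        accuracy=float(accuracy_score(y_te, y_hat)),
        precision=float(precision_score(y_te, y_hat, average="weighted",
                                        zero_division=0)),
        recall=float(recall_score(y_te, y_hat, average="weighted",
                                  zero_division=0)),
        attribution_ranking=[(c, float(v)) for c, v in ranking],
    )
    return report, model, cols


def train_baselines(train: pd.DataFrame, test: pd.DataFrame,
                    feature_set: str = "imaging+electrical+lesion",
                    seed: int = 0) -> dict:
    """Logistic-regression and support-vector baselines with 5-fold grouped CV."""
    x_tr, y_tr, _ = _xy(train, feature_set)
    x_te, y_te, _ = _xy(test, feature_set)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training data contains a single class")
    groups = train["anatomy_id"].to_numpy()
    cv = GroupKFold(n_splits=min(5, len(np.unique(groups))))
    families = {
        "logistic_regression": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", LogisticRegression(max_iter=5000,
                                                 class_weight="balanced"))]),
            {"clf__C": [0.01, 0.1, 1.0, 10.0, 100.0]}),
        "svc": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", SVC(class_weight="balanced"))]),
            {"clf__C": [0.1, 1.0, 10.0, 100.0],
             "clf__gamma": ["scale", 0.01, 0.1]}),
    }
    reports = {}
    for name, (pipe, grid) in families.items():
        search = GridSearchCV(pipe, grid, scoring="balanced_accuracy",
                              cv=cv.split(x_tr, y_tr, groups), n_jobs=1)
        search.fit(x_tr, y_tr)
        y_hat = search.best_estimator_.predict(x_te)
        reports[name] = ClassifierReport(
            feature_set=feature_set, model_family=name,
            chosen_params=search.best_params_,
            accuracy=float(accuracy_score(y_te, y_hat)),
            precision=float(precision_score(y_te, y_hat, average="weighted",
                                            zero_division=0)),
            recall=float(recall_score(y_te, y_hat, average="weighted",
                                      zero_division=0)),
        )
    return reports


# ---------------------------------------------------------------------------
# additive feature attribution (exact decision-path credit)
# ---------------------------------------------------------------------------

def _tree_path_attribution(tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Per-case additive attribution for one fitted decision tree.

    Walking each sample's decision path, the change in the node's expected
    positive-class probability across every split is credited to the split
    feature. Contributions plus the root expectation reconstruct the leaf
    prediction exactly.
    """
    t = tree.tree_
    value = t.value[:, 0, :]
    prob = value / value.sum(axis=1, keepdims=True)
    p1 = prob[:, 1] if prob.shape[1] > 1 else np.zeros(len(prob))
    attr = np.zeros((len(x), n_features))
    for i, xi in enumerate(x):
        node = 0
        while t.children_left[node] != -1:
            f = t.feature[node]
            nxt = (t.children_left[node] if xi[f] <= t.threshold[node]
                   else t.children_right[node])
            attr[i, f] += p1[nxt] - p1[node]
            node = nxt
    return attr


def feature_attribution(model, x: np.ndarray) -> np.ndarray:
    """Per-case signed additive attributions for a fitted forest.

    Satisfies local accuracy: for every case, attributions sum to the
    predicted non-responder probability minus the forest's baseline (mean of
    tree-root expectations), to numerical precision.
    """
    x = np.asarray(x, dtype=float)
    n_features = x.shape[1]
    total = np.zeros((len(x), n_features))
    for est in model.estimators_:
        total += _tree_path_attribution(est, x, n_features)
    return total / len(model.estimators_)


def attribution_baseline(model) -> float:
    """Forest baseline: mean root expected non-responder probability."""
    vals = []
    for est in model.estimators_:
        v = est.tree_.value[0, 0, :]
        p = v / v.sum()
        vals.append(p[1] if len(p) > 1 else 0.0)
    return float(np.mean(vals))
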