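"""Somatic-versus-germline classification of tumor-only variant calls.

Training labels come from the matched-normal subset: variants called in
tumor-only mode that overlap the sample's germline calls are labeled germline,
those overlapping the tumor-normal paired somatic calls are labeled somatic,
and variants in neither or both truth sources are excluded. Seven model
families (penalized logistic regression, linear SVM, random forest, gradient
boosted trees, k-NN, RBF SVM, MLP) are tuned by grid search with five-fold
cross-validation on a stratified training split and compared on held-out F1
with somatic as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .simulate import KEY

POSITIVE = "somatic"
NEGATIVE = "germline"

N_FOLDS = 5


@dataclass
class TruthLabels:
    labels: pd.DataFrame          # KEY columns + 'label'
    n_excluded_unseen: int        # tumor-only variants in neither truth source
    n_excluded_conflict: int      # variants claimed by both truth sources


def derive_truth_labels(
    tumor_only: pd.DataFrame,
    paired_somatic: pd.DataFrame,
    germline: pd.DataFrame,
) -> TruthLabels:
    """Label tumor-only calls against paired-somatic and germline call sets.

    All three tables are keyed by (sample, chrom, pos, ref, alt). A tumor-only
    variant found in the germline set is labeled germline; one found in the
    paired somatic set is labeled somatic; variants in neither, or in both,
    are excluded and counted.
    """
    t_keys = tumor_only[KEY].drop_duplicates()
    som = set(map(tuple, paired_somatic[KEY].itertuples(index=False, name=None)))
    ger = set(map(tuple, germline[KEY].itertuples(index=False, name=None)))
    labels, unseen, conflict = [], 0, 0
    for key in t_keys.itertuples(index=False, name=None):
        in_s, in_g = key in som, key in ger
        if in_s and in_g:
            conflict += 1
        elif in_s:
            labels.append(key + (POSITIVE,))
        elif in_g:
            labels.append(key + (NEGATIVE,))
        else:
            unseen += 1
    out = pd.DataFrame(labels, columns=KEY + ["label"])
    return TruthLabels(out, n_excluded_unseen=unseen, n_excluded_conflict=conflict)


def default_model_grids(seed: int = 0) -> dict[str, tuple]:
    """The seven model families with small fixed hyperparameter grids."""
    return {
        "LR": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", LogisticRegression(max_iter=2000, random_state=seed))]),
            {"clf__C": [0.1, 1.0, 10.0]},
        ),
        "linear_SVM": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", LinearSVC(random_state=seed, dual=False))]),
            {"clf__C": [0.1, 1.0, 10.0]},
        ),
        "RFC": (
            Pipeline([("clf", RandomForestClassifier(random_state=seed))]),
            {"clf__n_estimators": [100], "clf__max_depth": [None, 8]},
        ),
        "GBT": (
            Pipeline([("clf", GradientBoostingClassifier(random_state=seed))]),
            {"clf__n_estimators": [100], "clf__max_depth": [2, 3]},
        ),
        "KNN": (
            Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier())]),
            {"clf__n_neighbors": [5, 15, 31]},
        ),
        "rbf_SVM": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", SVC(random_state=seed))]),
            {"clf__C": [1.0, 10.0], "clf__gamma": ["scale"]},
        ),
        "MLP": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", MLPClassifier(max_iter=500, early_stopping=True,
                                            random_state=seed))]),
            {"clf__hidden_layer_sizes": [(32,), (64,), (128,)]},
        ),
    }


@dataclass
class ModelReport:
    cv_results: pd.DataFrame      # family, params, fold_0..fold_4, mean_cv_f1
    best_family: str
    best_params: dict
    heldout: dict                 # precision/recall/f1/accuracy (somatic positive)
    per_class: pd.DataFrame       # precision/recall/f1 per class
    confusion: pd.DataFrame       # rows true, cols predicted
    family_heldout_f1: dict = field(default_factory=dict)


def _to_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    return (y == POSITIVE).astype(int)


def evaluate(model, features: pd.DataFrame, labels) -> dict:
    """Precision/recall/F1/accuracy from the confusion matrix, somatic positive."""
    y = _to_binary(labels)
    pred = _to_binary(model.predict(features))
    if len(pred) != len(y):
        raise ValueError("shape mismatch between predictions and labels")
    cm = confusion_matrix(y, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / cm.sum()
    return {
        "precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy,
        "confusion": pd.DataFrame(
            cm, index=[NEGATIVE, POSITIVE], columns=[NEGATIVE, POSITIVE]
        ),
    }


def train_models(
    features: pd.DataFrame,
    labels,
    families: dict | None = None,
    seed: int = 0,
    test_size: float = 0.2,
):
    """Grid-search each model family with 5-fold CV; select by held-out F1.

    Returns (fitted best model, ModelReport). The best grid point per family
    maximizes mean CV F1; the winning family maximizes F1 on a stratified
    held-out split. Deterministic given ``seed``.
    """
    y = _to_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if families is None:
        families = default_model_grids(seed)
    X_tr, X_te, y_tr, y_te = train_test_split(
        features, y, test_size=test_size, stratify=y, random_state=seed
    )
    cv = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    rows, fitted, heldout_f1 = [], {}, {}
    for name, (estimator, grid) in families.items():
        gs = GridSearchCV(estimator, grid, scoring="f1", cv=cv, refit=True)
        gs.fit(X_tr, y_tr)
        res = gs.cv_results_
        for i, params in enumerate(res["params"]):
            row = {"family": name, "params": str(params),
                   "mean_cv_f1": res["mean_test_score"][i]}
            for k in range(N_FOLDS):
                row[f"fold_{k}"] = res[f"split{k}_test_score"][i]
            rows.append(row)
        fitted[name] = gs
        m = evaluate(_Wrapped(gs.best_estimator_), X_te, np.where(y_te, POSITIVE, NEGATIVE))
        heldout_f1[name] = m["f1"]
    best_family = max(heldout_f1, key=heldout_f1.get)
    best = fitted[best_family]
    model = FittedClassifier(best.best_estimator_, tuple(features.columns))
    metrics = evaluate(model, X_te, np.where(y_te, POSITIVE, NEGATIVE))
    confusion = metrics.pop("confusion")
    per_class = _per_class_metrics(confusion)
    report = ModelReport(
        cv_results=pd.DataFrame(rows),
        best_family=best_family,
        best_params=best.best_params_,
        heldout=metrics,
        per_class=per_class,
        confusion=confusion,
        family_heldout_f1=heldout_f1,
    )
    return model, report


def _per_class_metrics(confusion: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for cls in confusion.index:
        tp = confusion.loc[cls, cls]
        fp = confusion[cls].sum() - tp
        fn = confusion.loc[cls].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        out[cls] = {"precision": p, "recall": r, "f1": f1}
    return pd.DataFrame(out).T


class _Wrapped:
    """Adapter exposing string-label predict over a 0/1 estimator."""

    def __init__(self, estimator):
        self.estimator = estimator

    def predict(self, X):
        return np.where(np.asarray(self.estimator.predict(X)) == 1, POSITIVE, NEGATIVE)


class FittedClassifier:
    """A fitted pipeline bound to its feature schema.

    ``predict`` returns string labels; ``score`` returns a monotone
    calibration score in [0, 1] (class-1 probability where available,
    otherwise the logistic transform of the decision function).
    ``save``/``load`` persist the model together with a hash of the schema,
    verified on load so a model is never applied to the wrong columns.
    """

    def __init__(self, estimator, schema: tuple[str, ...]):
        self.estimator = estimator
        self.schema = schema

    @property
    def schema_hash(self) -> str:
        import hashlib

        return hashlib.sha256("|".join(self.schema).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        import joblib

        joblib.dump({"estimator": self.estimator, "schema": self.schema,
                     "schema_hash": self.schema_hash}, path)

    @classmethod
    def load(cls, path) -> "FittedClassifier":
        import joblib

        payload = joblib.load(path)
        model = cls(payload["estimator"], tuple(payload["schema"]))
        if payload.get("schema_hash") != model.schema_hash:
            raise ValueError("schema hash mismatch in persisted model")
        return model

    def _check(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.schema if c not in features.columns]
        if missing:
            raise ValueError(f"feature matrix lacks schema columns: {missing}")
        return features[list(self.schema)]

    def predict(self, features: pd.DataFrame):
        X = self._check(features)
        if not len(X):
            return np.array([], dtype=object)
        return np.where(np.asarray(self.estimator.predict(X)) == 1, POSITIVE, NEGATIVE)

    def score(self, features: pd.DataFrame) -> np.ndarray:
        X = self._check(features)
        if not len(X):
            return np.array([])
        if hasattr(self.estimator, "predict_proba"):
            try:
                return self.estimator.predict_proba(X)[:, 1]
            except AttributeError:  # e.g. SVC without probability=True
                pass
        from scipy.special import expit

        return expit(self.estimator.decision_function(X))


def classify(model: FittedClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Per-variant class label and calibration score for an unlabeled cohort."""
    return pd.DataFrame(
        {"label": model.predict(features), "score": model.score(features)},
        index=features.index,
    )
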