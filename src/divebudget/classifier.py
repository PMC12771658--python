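"""Gradient-boosted behavior classification of accelerometer bursts.

Labelled training bursts (video-verified in a dive tank, plus GPS-verified
flight) are filtered to behaviors held for at least 3 of the 5 burst seconds,
reduced to a de-correlated feature set, and fed to an XGBoost multiclass
model. Features are ranked by total gain and the top three are refit as the
final parsimonious model, which then labels the unclassified field bursts.

Evaluation is a standard confusion matrix with per-class precision, recall
and F1 (harmonic mean of the two; zero denominators give F1 = 0, flagged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .bioenergetics import BEHAVIORS

DEFAULT_HYPERPARAMS = {
    "n_estimators": 500,
    "max_depth": 3,
    "learning_rate": 0.1,
}
MIN_PURITY_S = 3.0
N_SELECTED = 3


def purity_filter(labelled: pd.DataFrame, min_purity_s: float = MIN_PURITY_S) -> pd.DataFrame:
    """Keep bursts whose behavior was held >= ``min_purity_s`` seconds.

    The boundary is inclusive: a 3.0-s behavior within a 5-s burst is kept.
    """
    return labelled[labelled["purity_seconds"] >= min_purity_s]


def _make_estimator(hyperparams: dict, seed: int, n_classes: int) -> xgb.XGBClassifier:
    hp = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    return xgb.XGBClassifier(
        objective="multi:softprob",
        num_class=n_classes,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
        **hp,
    )


@dataclass
class TrainedModel:
    """A fitted top-3-feature boosted-tree behavior model."""

    selected_features: list[str]
    classes: list[str]
    booster_json: dict
    seed: int
    n_per_class: dict[str, int]
    importances: dict[str, float]
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))

    def _booster(self) -> xgb.Booster:
        bst = xgb.Booster()
        bst.load_model(bytearray(json.dumps(self.booster_json), "utf-8"))
        return bst

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected_features": self.selected_features,
                    "classes": self.classes,
                    "seed": self.seed,
                    "n_per_class": self.n_per_class,
                    "importances": self.importances,
                    "hyperparams": self.hyperparams,
                    "booster": self.booster_json,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "TrainedModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            selected_features=d["selected_features"],
            classes=d["classes"],
            booster_json=d["booster"],
            seed=d["seed"],
            n_per_class=d["n_per_class"],
            importances=d["importances"],
            hyperparams=d["hyperparams"],
        )


def _rank_by_gain(
    X: pd.DataFrame, y_codes: np.ndarray, hyperparams: dict, seed: int, n_classes: int
) -> list[str]:
    est = _make_estimator(hyperparams, seed, n_classes)
    est.fit(X, y_codes)
    gains = est.get_booster().get_score(importance_type="total_gain")
    scored = [(gains.get(c, 0.0), c) for c in X.columns]
    # descending gain; canonical column order breaks ties
    scored.sort(key=lambda t: (-t[0], list(X.columns).index(t[1])))
    return [c for _, c in scored]


def _rank_by_forward_accuracy(
    X: pd.DataFrame, y_codes: np.ndarray, hyperparams: dict, seed: int, n_classes: int
) -> list[str]:
    """Greedy forward selection by cumulative training accuracy."""
    remaining = list(X.columns)
    chosen: list[str] = []
    while remaining and len(chosen) < N_SELECTED:
        best, best_acc = None, -1.0
        for c in remaining:
            est = _make_estimator(hyperparams, seed, n_classes)
            est.fit(X[chosen + [c]], y_codes)
            acc = float((est.predict(X[chosen + [c]]) == y_codes).mean())
            if acc > best_acc:
                best, best_acc = c, acc
        chosen.append(best)
        remaining.remove(best)
    return chosen + remaining


def train(
    labelled: pd.DataFrame,
    seed: int = 0,
    feature_names: list[str] | None = None,
    hyperparams: dict | None = None,
    selection: str = "gain",
    n_selected: int = N_SELECTED,
) -> TrainedModel:
    """Fit the behavior classifier and reduce it to its top features.

    ``labelled`` holds feature columns plus a ``behavior`` label column
    (feature set assumed already correlation-filtered; pass ``feature_names``
    to restrict). Features are ranked by total gain across the full model
    ("gain", default) or by greedy forward selection on cumulative accuracy
    ("forward"); the top ``n_selected`` are refit as the final model.
    """
    hyperparams = hyperparams or {}
    y = labelled["behavior"].astype(str)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("training needs at least 2 behavior classes")
    counts = y.value_counts()
    if (counts < 10).any():
        raise ValueError(f"each class needs >= 10 bursts (got {counts.to_dict()})")
    if feature_names is None:
        feature_names = [
            c for c in labelled.columns
            if c not in ("behavior", "burst_id", "purity_seconds", "sub_behavior")
        ]
    X = labelled[feature_names]
    codes = np.array([classes.index(v) for v in y])
    if selection == "gain":
        ranked = _rank_by_gain(X, codes, hyperparams, seed, len(classes))
    elif selection == "forward":
        ranked = _rank_by_forward_accuracy(X, codes, hyperparams, seed, len(classes))
    else:
        raise ValueError(f"unknown selection mode {selection!r}")
    selected = ranked[:n_selected]
    final = _make_estimator(hyperparams, seed, len(classes))
    final.fit(X[selected], codes)
    gains = final.get_booster().get_score(importance_type="total_gain")
    booster_json = json.loads(final.get_booster().save_raw("json").decode("utf-8"))
    return TrainedModel(
        selected_features=selected,
        classes=classes,
        booster_json=booster_json,
        seed=seed,
        n_per_class={k: int(v) for k, v in counts.items()},
        importances={c: float(gains.get(c, 0.0)) for c in selected},
        hyperparams={**DEFAULT_HYPERPARAMS, **hyperparams},
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.Series:
    """Behavior label per burst; stable under row reordering."""
    missing = [c for c in model.selected_features if c not in features.columns]
    if missing:
        raise ValueError(f"missing selected feature(s): {missing}")
    if len(features) == 0:
        return pd.Series([], dtype=object, index=features.index, name="behavior")
    bst = model._booster()
    dm = xgb.DMatrix(
        features[model.selected_features].to_numpy(dtype=float),
        feature_names=model.selected_features,
    )
    prob = bst.predict(dm)
    labels = [model.classes[i] for i in np.argmax(prob, axis=1)]
    return pd.Series(labels, index=features.index, name="behavior")


@dataclass(frozen=True)
class EvalReport:
    classes: list[str]
    matrix: np.ndarray  # true x predicted counts
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    zero_division_classes: list[str]

    @property
    def macro_f1(self) -> float:
        return float(np.mean([self.f1[c] for c in self.classes]))


def evaluate(
    y_true, y_pred, classes: list[str] | None = None
) -> EvalReport:
    """Confusion matrix, accuracy and per-class precision/recall/F1.

    F1_c = 2 P_c R_c / (P_c + R_c); classes with zero precision+recall get
    F1 = 0 and are listed in ``zero_division_classes``.
    """
    y_true = pd.Series(list(y_true), dtype=str)
    y_pred = pd.Series(list(y_pred), dtype=str)
    if len(y_true) != len(y_pred):
        raise ValueError("true and predicted label lengths differ")
    if classes is None:
        classes = sorted(set(y_true))
    bad = set(y_true) | set(y_pred)
    if bad - set(classes):
        raise ValueError(f"labels outside class list: {sorted(bad - set(classes))}")
    m = confusion_matrix(y_true, y_pred, labels=classes)
    total = m.sum()
    acc = float(np.trace(m) / total) if total else float("nan")
    precision, recall, f1 = {}, {}, {}
    flagged = []
    for i, c in enumerate(classes):
        col, row = m[:, i].sum(), m[i, :].sum()
        p = m[i, i] / col if col else 0.0
        r = m[i, i] / row if row else 0.0
        precision[c], recall[c] = float(p), float(r)
        if p + r == 0:
            f1[c] = 0.0
            flagged.append(c)
        else:
            f1[c] = float(2 * p * r / (p + r))
    return EvalReport(
        classes=list(classes), matrix=m, accuracy=acc,
        precision=precision, recall=recall, f1=f1, zero_division_classes=flagged,
    )


def stratified_split(
    labelled: pd.DataFrame, test_size: float = 0.3, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/validation split on the behavior label."""
    tr, te = train_test_split(
        labelled, test_size=test_size, random_state=seed,
        stratify=labelled["behavior"],
    )
    return tr, te
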