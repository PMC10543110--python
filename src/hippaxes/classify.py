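"""Subfield separability via multinomial L2 logistic regression.

Given per-subject, per-hemisphere subfield averages of microstructural
metrics (ODI, NDI, T1w/T2w by default), a softmax regression with L2
penalty is trained on a subject-level split and evaluated with a confusion
matrix and per-class F1 = 2 * precision * recall / (precision + recall).
Features are standardised with training-set statistics because the L2
penalty is scale-sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .surface import SUBFIELDS

__all__ = [
    "MICRO_FEATURES",
    "DTI_FEATURES",
    "SubfieldClassifierReport",
    "split_subjects",
    "train_classifier",
    "evaluate",
]

MICRO_FEATURES = ("odi", "ndi", "t1w_t2w")
DTI_FEATURES = ("fa", "md", "t1w_t2w")


def split_subjects(table: pd.DataFrame, n_train: int = 70, n_test: int = 30, seed: int = 0):
    """Disjoint subject-level train/test split; both hemispheres (all rows)
    of a subject land on the same side."""
    subjects = list(pd.unique(table["subject"]))
    if n_train + n_test > len(subjects):
        raise ValueError(
            f"requested {n_train}+{n_test} subjects but only {len(subjects)} available"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    train_ids = {subjects[i] for i in order[:n_train]}
    test_ids = {subjects[i] for i in order[n_train : n_train + n_test]}
    if train_ids & test_ids:
        raise RuntimeError("train/test subject overlap")
    train = table[table["subject"].isin(train_ids)].reset_index(drop=True)
    test = table[table["subject"].isin(test_ids)].reset_index(drop=True)
    return train, test


def train_classifier(
    train: pd.DataFrame,
    features=MICRO_FEATURES,
    label_col: str = "subfield",
    C: float = 1.0,
    max_iter: int = 2000,
) -> Pipeline:
    """Multinomial logistic regression with L2 regularisation (strength
    1/C), on standardised features; deterministic (lbfgs, no randomness)."""
    y = train[label_col]
    if y.nunique() < 2:
        raise ValueError("training data must contain at least 2 classes")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "logreg",
                # default penalty is L2; strength is 1/C
                LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter),
            ),
        ]
    )
    model.fit(train[list(features)].to_numpy(), y.to_numpy())
    model.features_ = tuple(features)
    return model


@dataclass
class SubfieldClassifierReport:
    """Confusion matrix (rows = true class) and per-class scores."""

    classes: tuple
    confusion: np.ndarray
    scores: pd.DataFrame  # class, precision, recall, f1, support
    n_train: int
    n_test: int

    @property
    def macro_f1(self) -> float:
        return float(self.scores["f1"].mean())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_json_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class_f1": dict(zip(self.scores["class"], self.scores["f1"])),
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def evaluate(
    model: Pipeline,
    test: pd.DataFrame,
    features=None,
    label_col: str = "subfield",
    n_train: int = 0,
) -> SubfieldClassifierReport:
    """Confusion matrix and per-class precision/recall/F1 on held-out rows.

    F1 is defined as 0 for a class with precision + recall = 0.  Classes
    present in the test set but unseen in training are still counted (as
    rows of the confusion matrix) with a warning.
    """
    features = features or getattr(model, "features_", MICRO_FEATURES)
    y_true = test[label_col].to_numpy()
    y_pred = model.predict(test[list(features)].to_numpy())
    model_classes = list(model.classes_)
    unseen = sorted(set(y_true) - set(model_classes))
    if unseen:
        warnings.warn(f"classes unseen in training: {unseen}", stacklevel=2)
    classes = [c for c in SUBFIELDS if c in set(model_classes) | set(y_true)]
    classes += sorted((set(model_classes) | set(y_true)) - set(classes))
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    rows = []
    for c in classes:
        i = index[c]
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        rows.append(
            {
                "class": c,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "support": int(conf[i].sum()),
            }
        )
    return SubfieldClassifierReport(
        classes=tuple(classes),
        confusion=conf,
        scores=pd.DataFrame(rows),
        n_train=n_train,
        n_test=len(test),
    )
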