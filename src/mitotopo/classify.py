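"""Subject-level cross-validated classification from MIN topology features.

Disease status is predicted per network component from a panel of
topological features (metric and motif Z-scores).  Because every subject
contributes many components, plain leave-one-out cross-validation would
leak subject identity; the modified scheme here (LOSO-CV) therefore holds
out *all* instances of one subject per fold and trains on the remaining
subjects only.  Pooled held-out scores across folds give a single ROC
curve and AUC.  A label-reshuffling control permutes group labels at the
subject level (all of a subject's instances move together) and re-runs the
full LOSO-CV per permutation, establishing the chance AUC distribution.

The default model is a single-hidden-layer perceptron (16 units, logistic
output); any scikit-learn classifier with ``predict_proba`` can be passed
instead.  Feature standardization and median imputation are fit on the
training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning

from mitotopo.errors import InvalidParameterError

__all__ = [
    "CVResult",
    "build_feature_table",
    "make_default_model",
    "leave_one_subject_out_cv",
    "reshuffle_control",
    "roc_auc",
]

_POSITIVE_LABEL = "PD"


@dataclass
class CVResult:
    """Pooled leave-one-subject-out cross-validation outcome."""

    scores: pd.DataFrame  # subject_id, label, score
    roc_points: np.ndarray  # (fpr, tpr) rows
    auc: float
    settings: dict = field(default_factory=dict)
    fold_audit: list[tuple[str, frozenset]] = field(default_factory=list)
    reshuffle_aucs: list[float] = field(default_factory=list)

    def assert_no_leakage(self) -> None:
        """Every fold's training subjects exclude the tested subject."""
        for test_subject, train_subjects in self.fold_audit:
            if test_subject in train_subjects:
                raise AssertionError(
                    f"subject {test_subject} leaked into its training fold"
                )


def build_feature_table(
    table: pd.DataFrame,
    feature_subset: Sequence[str],
    side_filter: str | None = None,
    size_filter: tuple[int, int] | None = None,
    max_undefined_fraction: float = 0.5,
) -> pd.DataFrame:
    """One classification instance per qualifying component.

    Filters the per-component metric table by ganglion side and inclusive
    component-size bounds, keeps the requested feature columns, and drops
    instances with more than ``max_undefined_fraction`` undefined features
    (remaining NaNs are imputed later, inside each training fold).
    """
    missing = [c for c in feature_subset if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"unknown feature columns: {missing}")
    sel = table
    if side_filter is not None:
        sel = sel[sel["side"] == side_filter]
    if size_filter is not None:
        lo, hi = size_filter
        if lo > hi:
            raise InvalidParameterError("inverted size filter bounds")
        sel = sel[(sel["size"] >= lo) & (sel["size"] <= hi)]
    feats = sel[list(feature_subset)]
    ok = feats.isna().mean(axis=1) <= max_undefined_fraction
    sel = sel[ok]
    if sel.empty:
        raise InvalidParameterError("no instances left after filtering")
    cols = ["subject_id", "group", "side", "size"] + list(feature_subset)
    return sel[cols].reset_index(drop=True)


def make_default_model(seed: int = 0):
    """Single-hidden-layer perceptron: 16 units, logistic output, seeded."""
    from sklearn.neural_network import MLPClassifier

    return MLPClassifier(
        hidden_layer_sizes=(16,),
        solver="lbfgs",
        max_iter=500,
        random_state=seed,
    )


def leave_one_subject_out_cv(
    instances: pd.DataFrame,
    feature_subset: Sequence[str],
    model_spec=None,
    seed: int = 0,
    labels: pd.Series | None = None,
) -> CVResult:
    """Modified LOOCV: hold out all of one subject's instances per fold.

    Parameters
    ----------
    instances
        Output of :func:`build_feature_table`.
    model_spec
        A scikit-learn classifier factory ``f(seed) -> estimator`` or an
        estimator class; default is the 16-unit perceptron.
    labels
        Optional per-subject label override (used by the reshuffle
        control); defaults to each instance's ``group`` column.

    Returns a :class:`CVResult` whose pooled held-out scores produce one
    ROC/AUC; the fold audit log proves no subject leakage.
    """
    from sklearn.base import clone
    from sklearn.impute import SimpleImputer
    from sklearn.neural_network import MLPClassifier  # noqa: F401
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    if labels is None:
        labels = instances.set_index("subject_id")["group"]
        labels = labels.groupby(level=0).first()
    subjects = instances["subject_id"].unique()
    label_of = {s: labels[s] for s in subjects}
    classes = sorted(set(label_of.values()))
    if len(classes) != 2:
        raise InvalidParameterError(
            f"need exactly 2 classes, got {classes}"
        )
    for cls in classes:
        if sum(1 for s in subjects if label_of[s] == cls) < 2:
            raise InvalidParameterError(
                f"need >= 2 subjects per class (class {cls!r})"
            )
    x_all = instances[list(feature_subset)].to_numpy(dtype=float)
    y_all = instances["subject_id"].map(label_of).to_numpy()
    rows = []
    audit = []
    for test_subject in subjects:
        test_mask = (instances["subject_id"] == test_subject).to_numpy()
        train_mask = ~test_mask
        y_train = y_all[train_mask]
        if len(set(y_train)) < 2:
            raise InvalidParameterError(
                f"training fold for subject {test_subject} is single-class"
            )
        if model_spec is None:
            model = make_default_model(seed)
        elif callable(model_spec) and not hasattr(model_spec, "fit"):
            model = model_spec(seed)
        else:
            model = clone(model_spec)
        pipe = make_pipeline(
            SimpleImputer(strategy="median"), StandardScaler(), model
        )
        with warnings.catch_warnings():
            # a fold's perceptron hitting the iteration cap is acceptable:
            # the decision function is already stable for scoring purposes
            warnings.simplefilter("ignore", ConvergenceWarning)
            pipe.fit(x_all[train_mask], y_train)
        model_classes = list(pipe[-1].classes_)
        pos = (
            _POSITIVE_LABEL
            if _POSITIVE_LABEL in model_classes
            else classes[-1]
        )
        pos_col = model_classes.index(pos)
        prob = pipe.predict_proba(x_all[test_mask])[:, pos_col]
        for p, lab in zip(prob, y_all[test_mask]):
            rows.append(
                {"subject_id": test_subject, "label": lab, "score": float(p)}
            )
        audit.append(
            (test_subject,
             frozenset(instances.loc[train_mask, "subject_id"]))
        )
    scores = pd.DataFrame(rows)
    pos = _POSITIVE_LABEL if _POSITIVE_LABEL in classes else classes[-1]
    roc, auc = roc_auc(
        scores["score"].to_numpy(),
        (scores["label"] == pos).to_numpy(),
    )
    result = CVResult(
        scores=scores,
        roc_points=roc,
        auc=auc,
        settings={"features": list(feature_subset), "positive": pos},
        fold_audit=audit,
    )
    result.assert_no_leakage()
    return result


def reshuffle_control(
    instances: pd.DataFrame,
    feature_subset: Sequence[str],
    n_reshuffles: int = 50,
    model_spec=None,
    seed: int = 0,
    rng: np.random.Generator | int | None = None,
) -> list[float]:
    """Subject-level label permutation null: AUC per reshuffle.

    Each permutation reassigns the existing subject labels (preserving the
    class counts) so that all instances of a subject carry the same
    permuted label, then runs the full LOSO-CV.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    true_labels = (
        instances.groupby("subject_id")["group"].first()
    )
    subjects = true_labels.index.to_numpy()
    aucs = []
    for _ in range(n_reshuffles):
        perm = rng.permutation(len(subjects))
        shuffled = pd.Series(
            true_labels.to_numpy()[perm], index=subjects
        )
        res = leave_one_subject_out_cv(
            instances,
            feature_subset,
            model_spec=model_spec,
            seed=seed,
            labels=shuffled,
        )
        aucs.append(res.auc)
    return aucs


def roc_auc(
    scores: Sequence[float], is_positive: Sequence[bool]
) -> tuple[np.ndarray, float]:
    """Empirical ROC curve and trapezoidal AUC with midrank tie handling.

    The AUC equals the Mann–Whitney U statistic normalized by n1*n0 (ties
    counted half).  Raises unless both classes are present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(is_positive, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidParameterError("ROC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # midranks
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # threshold sweep over unique scores, descending
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    return np.column_stack([fpr, tpr]), float(auc)
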