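"""External validation and classification statistics.

Performance is summarized from a confusion matrix whose rows are true
classes and whose columns are predicted classes plus a Not-Assigned column.
Per class (one-vs-rest among assigned samples): sensitivity, specificity
and Matthews correlation coefficient; call rate is the fraction of that
class's samples receiving any assignment. Globally: accuracy among assigned
samples and overall call rate. Two modes are reported: ``all_assigned``
(every sample goes to its most likely class) and ``with_not_assigned``
(doubtful samples rejected by the decision rule).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .classifier import PairwiseSVMClassifier
from .io import (
    NOT_ASSIGNED,
    ExpressionDataset,
    MarkernetError,
    RunConfig,
    derive_seed,
)
from .ranking import EmpiricalBayesRanker
from .selection import forward_select


@dataclasses.dataclass
class ValidationStats:
    """Statistics derived from one confusion matrix."""

    confusion: pd.DataFrame  # true x (classes + NOT_ASSIGNED), counts
    confusion_pct: pd.DataFrame  # row percentages
    per_class: pd.DataFrame  # sensitivity, specificity, mcc, call_rate
    global_accuracy: float
    global_call_rate: float
    mode: str
    degenerate: bool = False  # no sample assigned at all


def build_confusion(
    y_true, y_pred, classes, with_na: bool = True
) -> pd.DataFrame:
    """Count matrix: rows true classes, columns classes (+ NOT_ASSIGNED)."""
    cols = list(classes) + ([NOT_ASSIGNED] if with_na else [])
    cm = pd.DataFrame(0, index=list(classes), columns=cols, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    return cm


def confusion_stats(confusion: pd.DataFrame, mode: str = "with_not_assigned") -> ValidationStats:
    """Compute all per-class and global statistics from a confusion matrix.

    MCC denominator factors equal to zero yield MCC = 0 by convention. When
    no sample is assigned at all, global accuracy is reported as 1.0 with
    the ``degenerate`` flag set.
    """
    if confusion.size == 0:
        raise MarkernetError("empty confusion matrix")
    cm = confusion.astype(float)
    classes = [c for c in cm.columns if c != NOT_ASSIGNED]
    A = cm[classes].to_numpy()  # assigned-only block, rows = true classes
    totals = cm.to_numpy().sum(axis=1)
    assigned_per_class = A.sum(axis=1)
    rows = []
    for i, c in enumerate(classes):
        tp = A[i, i]
        fn = A[i].sum() - tp
        fp = A[:, i].sum() - tp
        tn = A.sum() - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        spec = tn / (tn + fp) if (tn + fp) > 0 else 0.0
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
        call = assigned_per_class[i] / totals[i] if totals[i] > 0 else 0.0
        rows.append(
            {"class": c, "sensitivity": sens, "specificity": spec,
             "mcc": mcc, "call_rate": call}
        )
    n_assigned = A.sum()
    degenerate = n_assigned == 0
    global_acc = float(np.trace(A) / n_assigned) if not degenerate else 1.0
    global_call = float(n_assigned / totals.sum()) if totals.sum() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = cm.div(cm.sum(axis=1), axis=0) * 100.0
    return ValidationStats(
        confusion=confusion.astype(int),
        confusion_pct=pct,
        per_class=pd.DataFrame(rows),
        global_accuracy=global_acc,
        global_call_rate=global_call,
        mode=mode,
        degenerate=bool(degenerate),
    )


def _run_pipeline_once(train_ds: ExpressionDataset, cfg: RunConfig):
    """Rank, select and train the final classifier on one training split."""
    Xtr, ytr = train_ds.to_xy()
    ranker = EmpiricalBayesRanker(
        significance_threshold=cfg.significance_threshold
    ).fit(Xtr, ytr)
    sel = forward_select(train_ds, ranker.ranking_, cfg)
    clf = PairwiseSVMClassifier(
        C=cfg.svm_c,
        lp_factor=cfg.lp_factor,
        diff_factor=cfg.diff_factor,
        random_state=derive_seed(cfg.seed, "final-train"),
    ).fit(Xtr[sel.all_selected], ytr)
    return ranker, sel, clf


def external_validation(
    dataset: ExpressionDataset,
    config: RunConfig | None = None,
    runs: int = 10,
    train_fraction: float = 0.5,
) -> dict[str, ValidationStats]:
    """Repeated stratified-split validation of the full pipeline.

    Each run re-ranks, re-selects and re-trains on the training part and
    queries the held-out part; per-run statistics are averaged (percentage
    confusion matrices and all rates) and reported for both assignment
    modes.
    """
    cfg = config or RunConfig()
    dataset.validate_for_analysis()
    classes = list(dataset.classes)
    X, y = dataset.to_xy()

    acc: dict[str, dict[str, list]] = {
        m: {"pct": [], "per_class": [], "ga": [], "gc": []}
        for m in ("all_assigned", "with_not_assigned")
    }
    for run in range(runs):
        idx_tr, idx_te = train_test_split(
            np.arange(len(y)),
            train_size=train_fraction,
            stratify=y,
            random_state=derive_seed(cfg.seed, "validation", run),
        )
        if min(np.bincount(pd.factorize(y[idx_tr])[0])) < 3:
            raise MarkernetError(
                "a class has fewer than 3 training samples in a split"
            )
        train_ds = dataset.subset_samples([X.index[i] for i in idx_tr])
        _, _, clf = _run_pipeline_once(train_ds, cfg)
        Xte = X.iloc[idx_te][clf.feature_names_]
        yte = y[idx_te]
        proba = clf.predict_proba(Xte)
        most_likely = clf.classes_[np.argmax(proba, axis=1)]
        assigned = clf.predict(Xte)
        for mode, pred in (
            ("all_assigned", most_likely),
            ("with_not_assigned", assigned),
        ):
            cm = build_confusion(yte, pred, classes, with_na=True)
            st = confusion_stats(cm, mode)
            acc[mode]["pct"].append(st.confusion_pct)
            acc[mode]["per_class"].append(
                st.per_class.set_index("class")
            )
            acc[mode]["ga"].append(st.global_accuracy)
            acc[mode]["gc"].append(st.global_call_rate)

    out: dict[str, ValidationStats] = {}
    for mode, d in acc.items():
        pct = sum(d["pct"]) / runs
        per_class = (sum(d["per_class"]) / runs).reset_index()
        out[mode] = ValidationStats(
            confusion=pd.DataFrame(),  # averaged result is in percentages
            confusion_pct=pct,
            per_class=per_class,
            global_accuracy=float(np.mean(d["ga"])),
            global_call_rate=float(np.mean(d["gc"])),
            mode=mode,
        )
    return out


def stats_to_dict(st: ValidationStats) -> dict:
    return {
        "mode": st.mode,
        "global_accuracy": st.global_accuracy,
        "global_call_rate": st.global_call_rate,
        "per_class": st.per_class.to_dict(orient="records"),
        "confusion_pct": st.confusion_pct.to_dict(),
        "degenerate": st.degenerate,
    }
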