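"""Wrapper forward selection of the minimum gene subset per class.

Repeated stratified cross-validation wraps the one-vs-one SVM: every fold
starts from the first-ranked gene of each class and, while held-out error
persists, adds the next ranked gene to each class that still has
misclassified held-out samples. Per repeat the smallest genes-per-class
vector attaining the minimum observed error is kept; the final per-class
count is a trimmed maximum over repeats (counts above Q3 + 1.5*IQR are
treated as outliers and discarded before taking the maximum).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .classifier import PairwiseSVMClassifier
from .io import ExpressionDataset, MarkernetError, RunConfig, derive_seed
from .ranking import EmpiricalBayesRanker, ranked_genes


@dataclasses.dataclass
class SelectionResult:
    """Outcome of the repeated-CV forward selection."""

    classes: list[str]
    counts_per_repeat: pd.DataFrame  # repeats x classes
    final_counts: dict[str, int]
    selected_genes: dict[str, list[str]]
    cv_error_trace: pd.DataFrame  # repeat, fold, step, per-class counts, error

    @property
    def all_selected(self) -> list[str]:
        out: list[str] = []
        for c in self.classes:
            out.extend(self.selected_genes[c])
        return out


def trimmed_max(counts) -> int:
    """Maximum after discarding counts above Q3 + 1.5*IQR."""
    a = np.asarray(counts, dtype=float)
    q1, q3 = np.percentile(a, [25, 75])
    upper = q3 + 1.5 * (q3 - q1)
    kept = a[a <= upper]
    return int(kept.max())


def forward_select(
    dataset: ExpressionDataset,
    ranking: pd.DataFrame,
    config: RunConfig | None = None,
) -> SelectionResult:
    """Run the repeated-CV forward selection around the SVM.

    ``ranking`` must contain at least one gene for every class of the
    dataset. Folds are stratified and capped at the smallest class size.
    """
    cfg = config or RunConfig()
    dataset.validate_for_analysis()
    classes = list(dataset.classes)
    per_class = {c: ranked_genes(ranking, c) for c in classes}
    for c in classes:
        if not per_class[c]:
            raise MarkernetError(f"ranking has no genes for class {c!r}")

    X, y = dataset.to_xy()
    min_class = min(dataset.class_counts().values())
    n_folds = min(cfg.cv_folds, min_class)
    if n_folds < 2:
        raise MarkernetError(
            "smallest class too small for cross-validation; need >= 2 samples"
        )

    caps = {
        c: min(cfg.max_genes_train, len(per_class[c])) for c in classes
    }

    trace_rows = []
    kept_vectors = []
    for rep in range(cfg.cv_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds,
            shuffle=True,
            random_state=derive_seed(cfg.seed, "selection", rep),
        )
        folds = list(skf.split(X, y))
        for tr, _ in folds:
            ytr = y[tr]
            present = set(np.unique(ytr))
            small = [c for c in classes if int((ytr == c).sum()) < 2]
            if len(present) < len(classes) or small:
                raise MarkernetError(
                    f"class(es) {small or sorted(set(classes) - present)} "
                    "have fewer than 2 training samples in a fold; "
                    "use fewer cv_folds"
                )
        rep_entries: list[tuple[tuple[int, ...], float]] = []
        counts = {c: 1 for c in classes}
        step = 0
        while True:
            # evaluate the current genes-per-class vector by full CV
            genes = [g for c in classes for g in per_class[c][: counts[c]]]
            n_wrong = 0
            n_total = 0
            wrong_classes: set[str] = set()
            for fold, (tr, te) in enumerate(folds):
                ytr, yte = y[tr], y[te]
                clf = PairwiseSVMClassifier(
                    C=cfg.svm_c,
                    probability=False,
                    random_state=derive_seed(cfg.seed, "selection", rep, fold),
                )
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    clf.fit(X.iloc[tr][genes], ytr)
                pred = clf.predict_most_likely(X.iloc[te][genes])
                bad = pred != yte
                n_wrong += int(bad.sum())
                n_total += len(yte)
                wrong_classes.update(yte[bad])
            err = n_wrong / n_total
            vec = tuple(counts[c] for c in classes)
            rep_entries.append((vec, err))
            trace_rows.append(
                {"repeat": rep, "step": step, "error": err,
                 **{f"n_{c}": counts[c] for c in classes}}
            )
            step += 1
            if err == 0.0 and not cfg.continue_zero_error:
                break
            # grow the classes that were not perfectly predicted
            bad_classes = (
                list(classes) if err == 0.0 else
                [c for c in classes if c in wrong_classes]
            )
            grown = False
            for c in bad_classes:
                if counts[c] < caps[c]:
                    counts[c] += 1
                    grown = True
            if not grown:
                break

        min_err = min(e for _, e in rep_entries)
        best = min(
            (v for v, e in rep_entries if e == min_err),
            key=lambda v: (sum(v), v),
        )
        kept_vectors.append(best)

    counts_df = pd.DataFrame(kept_vectors, columns=classes)
    final = {c: max(1, trimmed_max(counts_df[c])) for c in classes}
    selected = {c: per_class[c][: final[c]] for c in classes}
    return SelectionResult(
        classes=classes,
        counts_per_repeat=counts_df,
        final_counts=final,
        selected_genes=selected,
        cv_error_trace=pd.DataFrame(trace_rows),
    )


def selection_report(result: SelectionResult) -> pd.DataFrame:
    """Tabular report: one row per selected gene with its class and rank."""
    rows = []
    for c in result.classes:
        for i, g in enumerate(result.selected_genes[c], start=1):
            rows.append(
                {"class": c, "gene": g, "rank": i,
                 "final_count": result.final_counts[c]}
            )
    return pd.DataFrame(rows, columns=["class", "gene", "rank", "final_count"])


class ForwardGeneSelector(BaseEstimator):
    """Estimator facade: rank (if needed) then forward-select gene subsets.

    Parameters mirror :class:`~markernet.io.RunConfig`. When ``ranking`` is
    None a fresh :class:`EmpiricalBayesRanker` is fitted on the training
    data; otherwise the provided ranking table is used.

    Attributes
    ----------
    result_ : SelectionResult
    selected_genes_ : flat list of selected genes (class order)
    ranker_ : the internally fitted ranker, when one was fitted
    """

    def __init__(self, config: RunConfig | None = None, ranking=None):
        self.config = config
        self.ranking = ranking

    def fit(self, X, y):
        from .ranking import _dataset_from_xy

        cfg = self.config or RunConfig()
        dataset = _dataset_from_xy(X, y)
        if self.ranking is None:
            self.ranker_ = EmpiricalBayesRanker(
                significance_threshold=cfg.significance_threshold
            ).fit(X, y)
            ranking = self.ranker_.ranking_
        else:
            ranking = self.ranking
        self.result_ = forward_select(dataset, ranking, cfg)
        self.selected_genes_ = self.result_.all_selected
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "selected_genes_")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            X, columns=[f"g{j:05d}" for j in range(np.asarray(X).shape[1])]
        )
        return Xdf[self.selected_genes_]
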