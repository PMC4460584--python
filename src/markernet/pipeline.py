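"""End-to-end estimator: rank genes, select the minimum subset, train the SVM.

:class:`MarkerPipelineClassifier` is the single-object interface to the
whole workflow. ``fit(X, y)`` runs the empirical-Bayes ranking, the
repeated-CV forward selection and the final one-vs-one SVM on the selected
genes; ``predict`` applies the Not-Assigned rule to queries and
``networks()`` builds the per-class association networks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .classifier import PairwiseSVMClassifier
from .io import ExpressionDataset, RunConfig, derive_seed
from .network import build_network
from .ranking import EmpiricalBayesRanker, _dataset_from_xy
from .selection import forward_select


class MarkerPipelineClassifier(ClassifierMixin, BaseEstimator):
    """Full marker-discovery pipeline as one scikit-learn classifier.

    Parameters
    ----------
    config : RunConfig or None
        All pipeline settings (thresholds, CV layout, seed); defaults used
        when None.

    Attributes
    ----------
    ranker_ : fitted :class:`EmpiricalBayesRanker`
    selection_ : :class:`~markernet.selection.SelectionResult`
    classifier_ : fitted :class:`PairwiseSVMClassifier` on the selected genes
    discriminant_power_ : DataFrame of per-gene piles and signed DP
    classes_ : ndarray
    """

    def __init__(self, config: RunConfig | None = None):
        self.config = config

    def fit(self, X, y):
        cfg = self.config or RunConfig()
        dataset = _dataset_from_xy(X, y)
        dataset.validate_for_analysis()
        Xdf, yarr = dataset.to_xy()
        self.dataset_ = dataset
        self.ranker_ = EmpiricalBayesRanker(
            significance_threshold=cfg.significance_threshold
        ).fit(Xdf, yarr)
        self.selection_ = forward_select(dataset, self.ranker_.ranking_, cfg)
        self.classifier_ = PairwiseSVMClassifier(
            C=cfg.svm_c,
            lp_factor=cfg.lp_factor,
            diff_factor=cfg.diff_factor,
            random_state=derive_seed(cfg.seed, "final-train"),
        ).fit(Xdf[self.selection_.all_selected], yarr)
        self.discriminant_power_ = self.classifier_.discriminant_power()
        self.classes_ = self.classifier_.classes_
        return self

    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict(X)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict_proba(X)

    def query(self, X) -> pd.DataFrame:
        check_is_fitted(self, "classifier_")
        return self.classifier_.query(X)

    @property
    def ranking_(self) -> pd.DataFrame:
        check_is_fitted(self, "ranker_")
        return self.ranker_.ranking_

    def networks(self, dataset: ExpressionDataset | None = None) -> dict:
        """Per-class annotated gene networks (defaults to training data)."""
        check_is_fitted(self, "classifier_")
        cfg = self.config or RunConfig()
        ds = dataset or self.dataset_
        return {
            c: build_network(
                self.ranking_,
                ds,
                c,
                selected_genes=self.selection_.all_selected,
                dp=self.discriminant_power_,
                top_n=cfg.network_top_n,
                correlations_threshold=cfg.correlations_threshold,
                interactions_threshold=cfg.interactions_threshold,
            )
            for c in ds.classes
        }
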