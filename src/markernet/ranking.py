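"""Empirical-Bayes gene ranking.

A hierarchical lognormal-normal (LNN) mixture is fitted to the genes x
samples matrix: within a group of exchangeable samples, a gene's log-scale
observations share a latent mean drawn from Normal(mu0, tau2) and carry
i.i.d. Normal(0, sigma2) measurement noise, so the group's marginal is an
n-variate normal with covariance ``sigma2*I + tau2*J``.

Each gene follows one of K+1 expression patterns: pattern 0 (equivalent
expression, one latent mean across all samples) or pattern k (one-versus-rest:
class-k samples draw their own latent mean, the remaining samples share
another). EM estimates the pattern mixing proportions and the shared
hyperparameters; the per-gene pattern responsibilities are the posterior
probabilities of differential expression that drive the ranking.

The ranking orders genes per class by posterior probability, breaks ties by
the expression difference to the closest other class, assigns each gene only
to the class where it ranks best (so per-class lists never overlap), and
filters out genes whose most probable pattern is equivalent expression.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionDataset, MarkernetError

_LOG2PI = np.log(2.0 * np.pi)


def lnn_group_logdensity(
    x: np.ndarray, mu0: float, tau2: float, sigma2: float
) -> float:
    """Log marginal density of one group of observations under the LNN model.

    ``x_i = mu + eps_i`` with ``mu ~ N(mu0, tau2)`` and
    ``eps_i ~ N(0, sigma2)`` i.i.d.; marginally ``x`` is n-variate normal
    with mean ``mu0`` and covariance ``sigma2*I + tau2*J``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("x must be a 1-D vector with n >= 1")
    if tau2 <= 0 or sigma2 <= 0:
        raise ValueError("tau2 and sigma2 must be positive")
    n = x.size
    mean = x.mean()
    ss = float(((x - mean) ** 2).sum())
    return float(
        _logdensity_from_stats(n, np.array(mean), np.array(ss), mu0, tau2, sigma2)
    )


def _logdensity_from_stats(n, mean, ss, mu0, tau2, sigma2):
    """Vectorized LNN group log density from (n, group mean, within-group SS).

    Uses the closed-form determinant and inverse of ``sigma2*I + tau2*J``:
    ``det = sigma2^(n-1) * (sigma2 + n*tau2)`` and the quadratic form splits
    into within-group scatter and a shrunken mean term.
    """
    v = sigma2 + n * tau2
    return -0.5 * (
        n * _LOG2PI
        + (n - 1) * np.log(sigma2)
        + np.log(v)
        + ss / sigma2
        + n * (mean - mu0) ** 2 / v
    )


@dataclasses.dataclass
class EBModel:
    """Fitted mixture: shared hyperparameters and pattern proportions.

    ``mix[0]`` is the proportion of equivalently expressed genes; ``mix[k]``
    the proportion following class-k's one-versus-rest pattern.
    """

    mu0: float
    tau2: float
    sigma2: float
    mix: np.ndarray
    loglik_trace: np.ndarray
    classes: list[str]
    n_iter: int
    converged: bool


class _SuffStats:
    """Per-gene sufficient statistics for every sample group the patterns use.

    Groups: all samples, each class, and each class's complement. The LNN
    group density depends only on (n, mean, within-group SS), so EM never
    touches the raw matrix again after this pass.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, classes: list[str]):
        # X is genes x samples here
        self.classes = classes
        n_all = X.shape[1]
        sum_all = X.sum(axis=1)
        sumsq_all = (X**2).sum(axis=1)
        self.groups: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}
        self.groups["all"] = self._finalize(n_all, sum_all, sumsq_all)
        for c in classes:
            mask = y == c
            n_c = int(mask.sum())
            s_c = X[:, mask].sum(axis=1)
            q_c = (X[:, mask] ** 2).sum(axis=1)
            self.groups[f"class:{c}"] = self._finalize(n_c, s_c, q_c)
            self.groups[f"rest:{c}"] = self._finalize(
                n_all - n_c, sum_all - s_c, sumsq_all - q_c
            )

    @staticmethod
    def _finalize(n, s, q):
        mean = s / n
        ss = np.maximum(q - n * mean**2, 0.0)
        return n, mean, ss

    def pattern_logliks(self, mu0, tau2, sigma2) -> np.ndarray:
        """Genes x (K+1) log marginal likelihood matrix."""
        n, mean, ss = self.groups["all"]
        cols = [_logdensity_from_stats(n, mean, ss, mu0, tau2, sigma2)]
        for c in self.classes:
            nc, mc, sc = self.groups[f"class:{c}"]
            nr, mr, sr = self.groups[f"rest:{c}"]
            cols.append(
                _logdensity_from_stats(nc, mc, sc, mu0, tau2, sigma2)
                + _logdensity_from_stats(nr, mr, sr, mu0, tau2, sigma2)
            )
        return np.column_stack(cols)


def fit_eb_model(
    dataset: ExpressionDataset, tol: float = 1e-6, max_iter: int = 250
) -> EBModel:
    """Fit the K+1-pattern LNN mixture by (generalized) EM.

    The E-step computes pattern responsibilities; the M-step updates the
    mixing proportions in closed form and the shared hyperparameters by
    bounded quasi-Newton ascent of the expected complete log-likelihood on
    (mu0, log tau2, log sigma2), started at the current point so the observed
    log-likelihood never decreases.
    """
    dataset.validate_for_analysis()
    X, y = dataset.to_xy()
    return _fit_eb(X.to_numpy().T, y, list(dataset.classes), tol, max_iter)


def _fit_eb(Xg, y, classes, tol=1e-6, max_iter=250) -> EBModel:
    stats = _SuffStats(Xg, y, classes)
    K = len(classes)

    # initialization from the data's gene-level moments
    gene_means = Xg.mean(axis=1)
    mu0 = float(gene_means.mean())
    tau2 = max(float(gene_means.var()), 1e-6)
    within = 0.0
    for c in classes:
        n_c, mean_c, ss_c = stats.groups[f"class:{c}"]
        within += ss_c.sum() / max(n_c - 1, 1)
    sigma2 = max(within / (Xg.shape[0] * K), 1e-6)
    mix = np.full(K + 1, 0.0)
    mix[0] = 0.8
    mix[1:] = 0.2 / K

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        L = stats.pattern_logliks(mu0, tau2, sigma2)
        joint = L + np.log(mix)
        norm = logsumexp(joint, axis=1)
        loglik = float(norm.sum())
        if not np.isfinite(loglik):
            raise MarkernetError(
                f"EM diverged (non-finite log-likelihood) at iteration {it}"
            )
        R = np.exp(joint - norm[:, None])
        trace.append(loglik)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
            if rel < tol:
                converged = True
                break

        mix = np.clip(R.mean(axis=0), 1e-12, None)
        mix = mix / mix.sum()

        def neg_q(theta, R=R):
            m, lt, ls = theta
            Lq = stats.pattern_logliks(m, np.exp(lt), np.exp(ls))
            return -float((R * Lq).sum())

        x0 = np.array([mu0, np.log(tau2), np.log(sigma2)])
        res = minimize(
            neg_q,
            x0,
            method="L-BFGS-B",
            bounds=[(None, None), (-30.0, 30.0), (-30.0, 30.0)],
        )
        if res.fun <= neg_q(x0):  # generalized EM: accept only improvements
            mu0 = float(res.x[0])
            tau2 = float(np.exp(res.x[1]))
            sigma2 = float(np.exp(res.x[2]))

    return EBModel(
        mu0=mu0,
        tau2=tau2,
        sigma2=sigma2,
        mix=mix,
        loglik_trace=np.array(trace),
        classes=list(classes),
        n_iter=it,
        converged=converged,
    )


def posterior_probabilities(
    model: EBModel, dataset: ExpressionDataset
) -> pd.DataFrame:
    """Per-gene posterior responsibility of each pattern (rows sum to 1).

    Columns: ``EE`` (equivalent expression) then one column per class.
    """
    X, y = dataset.to_xy()
    stats = _SuffStats(X.to_numpy().T, y, model.classes)
    L = stats.pattern_logliks(model.mu0, model.tau2, model.sigma2)
    joint = L + np.log(model.mix)
    R = np.exp(joint - logsumexp(joint, axis=1)[:, None])
    return pd.DataFrame(
        R, index=dataset.gene_ids, columns=["EE"] + list(model.classes)
    )


def _class_means(dataset: ExpressionDataset) -> pd.DataFrame:
    X, y = dataset.to_xy()
    return pd.DataFrame(
        {c: X.to_numpy()[y == c].mean(axis=0) for c in dataset.classes},
        index=dataset.gene_ids,
    )


def expression_differences(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per gene and class: class mean minus the mean of the closest other class.

    The closest class is the one whose mean for that gene is nearest to the
    given class's mean; the signed difference breaks posterior ties and sets
    the UP/DOWN direction.
    """
    M = _class_means(dataset).to_numpy()
    K = M.shape[1]
    diffs = np.empty_like(M)
    for k in range(K):
        delta = M[:, [k]] - M  # gene x class
        delta[:, k] = np.inf
        closest = np.argmin(np.abs(delta), axis=1)
        diffs[:, k] = delta[np.arange(M.shape[0]), closest]
    return pd.DataFrame(
        diffs, index=dataset.gene_ids, columns=list(dataset.classes)
    )


def build_ranking(
    posteriors: pd.DataFrame,
    dataset: ExpressionDataset,
    significance_threshold: float = 0.95,
) -> pd.DataFrame:
    """Assemble the non-overlapping per-class ranked gene lists.

    Step 1: per class, order all genes by posterior (descending), breaking
    ties by |expression difference to the closest class| (descending), then
    gene id. Step 2: assign each gene to the class where its rank position
    is best; cross-class ties go to the higher posterior, then larger
    |difference|. Step 3: drop genes whose most probable pattern is
    equivalent expression, and renumber ranks consecutively per class.

    Returns a DataFrame with columns gene, class, rank, posterior_prob,
    expr_diff, direction, significant.
    """
    classes = [c for c in posteriors.columns if c != "EE"]
    genes = list(posteriors.index)
    G, K = len(genes), len(classes)
    diffs = expression_differences(dataset).loc[genes, classes]
    P = posteriors[classes].to_numpy()
    D = diffs.to_numpy()

    positions = np.empty((G, K), dtype=int)
    for k in range(K):
        order = sorted(
            range(G), key=lambda g: (-P[g, k], -abs(D[g, k]), genes[g])
        )
        positions[order, k] = np.arange(1, G + 1)

    ee_is_max = posteriors.to_numpy().argmax(axis=1) == list(
        posteriors.columns
    ).index("EE")

    rows = []
    for g in range(G):
        if ee_is_max[g]:
            continue
        best = min(
            range(K),
            key=lambda k: (positions[g, k], -P[g, k], -abs(D[g, k]), k),
        )
        rows.append(
            {
                "gene": genes[g],
                "class": classes[best],
                "_pos": positions[g, best],
                "posterior_prob": P[g, best],
                "expr_diff": D[g, best],
            }
        )
    ranking = pd.DataFrame(
        rows,
        columns=["gene", "class", "_pos", "posterior_prob", "expr_diff"],
    )
    if ranking.empty:
        ranking["rank"] = pd.Series(dtype=int)
    else:
        ranking = ranking.sort_values(["class", "_pos"], kind="stable")
        ranking["rank"] = ranking.groupby("class").cumcount() + 1
    ranking = ranking.drop(columns="_pos")
    ranking["direction"] = np.where(ranking["expr_diff"] > 0, "UP", "DOWN")
    ranking["significant"] = ranking["posterior_prob"] > significance_threshold
    order = {c: i for i, c in enumerate(classes)}
    ranking = ranking.sort_values(
        ["class", "rank"], key=lambda s: s.map(order) if s.name == "class" else s
    ).reset_index(drop=True)
    return ranking[
        ["gene", "class", "rank", "posterior_prob", "expr_diff",
         "direction", "significant"]
    ]


def count_significant(ranking: pd.DataFrame, threshold: float) -> dict[str, int]:
    """Number of ranked genes per class with posterior above ``threshold``."""
    out: dict[str, int] = {}
    for c, grp in ranking.groupby("class", sort=False):
        out[str(c)] = int((grp["posterior_prob"] > threshold).sum())
    return out


def ranked_genes(ranking: pd.DataFrame, cls: str) -> list[str]:
    """Genes of one class in rank order."""
    grp = ranking[ranking["class"] == cls].sort_values("rank")
    return list(grp["gene"])


class EmpiricalBayesRanker(BaseEstimator):
    """Scikit-learn-style wrapper around the EB mixture ranking.

    Parameters
    ----------
    significance_threshold : float, default 0.95
        Posterior cutoff for the ``significant`` flag.
    tol, max_iter : EM stopping rule (relative log-likelihood change).

    Attributes (after :meth:`fit`)
    ------------------------------
    model_ : EBModel
    posteriors_ : DataFrame, genes x (EE + classes), rows sum to 1
    ranking_ : DataFrame of the per-class ranked lists
    classes_ : ndarray of class labels
    """

    def __init__(
        self,
        significance_threshold: float = 0.95,
        tol: float = 1e-6,
        max_iter: int = 250,
    ):
        self.significance_threshold = significance_threshold
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        """Fit on a samples x genes matrix (DataFrame preferred) and labels."""
        dataset = _dataset_from_xy(X, y)
        self.model_ = fit_eb_model(dataset, tol=self.tol, max_iter=self.max_iter)
        self.posteriors_ = posterior_probabilities(self.model_, dataset)
        self.ranking_ = build_ranking(
            self.posteriors_, dataset, self.significance_threshold
        )
        self.classes_ = np.array(dataset.classes)
        return self

    def significant_counts(self, threshold: float | None = None) -> dict[str, int]:
        check_is_fitted(self, "ranking_")
        thr = self.significance_threshold if threshold is None else threshold
        return count_significant(self.ranking_, thr)


def _dataset_from_xy(X, y) -> ExpressionDataset:
    if isinstance(X, ExpressionDataset):
        return X
    Xdf = pd.DataFrame(X)
    if not isinstance(X, pd.DataFrame):
        Xdf.columns = [f"g{j:05d}" for j in range(Xdf.shape[1])]
        Xdf.index = [f"s{i:04d}" for i in range(Xdf.shape[0])]
    Xdf.index = Xdf.index.astype(str)
    Xdf.columns = Xdf.columns.astype(str)
    labels = {str(s): str(c) for s, c in zip(Xdf.index, y)}
    return ExpressionDataset(Xdf.T, labels)
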