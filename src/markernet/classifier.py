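"""One-vs-one linear SVM with a reject option and discriminant power.

The multiclass machine is the classical one-versus-one construction: one
linear binary SVM per unordered class pair, each calibrated with a Platt
sigmoid fitted on the training decision values (with Platt's prior-corrected
targets), and the calibrated pairwise probabilities combined into one class
probability vector by pairwise coupling (the iterative second method of Wu,
Lin & Weng, the fixed point of which minimizes the weighted KL divergence to
the pairwise estimates). Genes are standardized to the training mean/sd.
Training is fully deterministic: no internal resampling is involved.

On top of the probability vector sits an expert-decision rule: a query is
assigned to its most likely class only when that probability is at least
``lp_factor`` times the random probability 1/K and beats the runner-up by
more than ``diff_factor`` times 1/K; otherwise it is left Not-Assigned.

The discriminant power of a gene summarizes how much weight the trained
machines give it: for each class, the Lagrange coefficients (dual weights)
of that class's support vectors, times each support vector's standardized
expression of the gene, are piled up; |dp| is the gap between the largest
pile and the closest one, signed positive when the gene is over-expressed
in the winning class and negative when repressed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .io import NOT_ASSIGNED, MarkernetError, RunConfig


def assign(
    probabilities,
    lp_factor: float = 2.0,
    diff_factor: float = 0.8,
    classes=None,
):
    """Apply the Not-Assigned decision rule to one probability vector.

    With K classes and random probability ``r = 1/K``, the top class wins
    iff ``p(1) >= lp_factor*r`` and ``p(1) - p(2) > diff_factor*r``.
    Returns the class label (index if ``classes`` is None) or NOT_ASSIGNED.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("probabilities must be a vector of length K >= 2")
    r = 1.0 / p.size
    order = np.argsort(-p, kind="stable")
    top, second = p[order[0]], p[order[1]]
    if top >= lp_factor * r and (top - second) > diff_factor * r:
        return classes[order[0]] if classes is not None else int(order[0])
    return NOT_ASSIGNED


def fit_platt_sigmoid(decisions: np.ndarray, is_positive: np.ndarray):
    """Platt scaling: fit (A, B) so P(+|f) = 1/(1+exp(A*f+B)).

    Targets use Platt's prior correction (t+ = (N+ + 1)/(N+ + 2),
    t- = 1/(N- + 2)) so the sigmoid stays finite even on separable data.
    The cross-entropy is minimized by Newton iterations with a
    backtracking line search (the standard libsvm procedure).
    """
    f = np.asarray(decisions, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))

    def nll(a, b):
        z = a * f + b
        # cross-entropy log(1+exp(z)) - (1-t)*z, numerically stable
        softplus = np.where(z >= 0, z + np.log1p(np.exp(-z)),
                            np.log1p(np.exp(z)))
        return float(np.sum(softplus - (1.0 - t) * z))

    val = nll(A, B)
    for _ in range(100):
        z = A * f + B
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))  # P(positive)
        # gradient and Hessian of the cross-entropy in (A, B)
        d1 = t - p
        g1 = float(np.sum(f * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-10 and abs(g2) < 1e-10:
            break
        w = p * (1.0 - p)
        h11 = float(np.sum(f * f * w)) + 1e-12
        h22 = float(np.sum(w)) + 1e-12
        h21 = float(np.sum(f * w))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        step = 1.0
        while step >= 1e-10:
            nA, nB = A + step * dA, B + step * dB
            nval = nll(nA, nB)
            if nval < val + 1e-4 * step * (g1 * dA + g2 * dB):
                A, B, val = nA, nB, nval
                break
            step *= 0.5
        else:
            break
    return float(A), float(B)


def pairwise_coupling(R: np.ndarray, max_iter: int = 200, eps: float = 1e-12):
    """Combine pairwise probabilities into one K-vector (Wu-Lin-Weng 2).

    ``R[i, j]`` estimates P(class i | class i or j); the returned vector p
    is the fixed point of the iterative scheme whose solution minimizes the
    coupled Kullback-Leibler objective; rows sum to 1.
    """
    K = R.shape[0]
    Q = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if i == j:
                Q[i, i] = sum(R[j2, i] ** 2 for j2 in range(K) if j2 != i)
            else:
                Q[i, j] = -R[j, i] * R[i, j]
    p = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        pQp = float(p @ Q @ p)
        max_err = 0.0
        for t_ in range(K):
            Qp_t = float(Q[t_] @ p)
            max_err = max(max_err, abs(Qp_t - pQp))
            p[t_] += (pQp - Qp_t) / Q[t_, t_]
            p /= p.sum()
            pQp = float(p @ Q @ p)
        if max_err < eps:
            break
    return p / p.sum()


@dataclasses.dataclass
class _BinaryMachine:
    """One linear SVM for an unordered class pair, with its calibration."""

    pos_class: str
    neg_class: str
    svc: SVC
    sample_idx: np.ndarray  # training rows (into the full training set)
    sigmoid_a: float
    sigmoid_b: float

    def decision(self, Z: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(Z)

    def prob_pos(self, Z: np.ndarray) -> np.ndarray:
        z = self.sigmoid_a * self.decision(Z) + self.sigmoid_b
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        # guard the coupling against exact 0/1
        return np.clip(p, 1e-7, 1.0 - 1e-7)


class PairwiseSVMClassifier(ClassifierMixin, BaseEstimator):
    """Linear one-vs-one SVM with calibrated probabilities and a reject option.

    Parameters
    ----------
    C : float, default 1.0
        SVM regularization (linear kernel only).
    lp_factor, diff_factor : float
        Multipliers of the random probability in the assignment rule.
    probability : bool, default True
        Fit per-machine Platt calibration (needed for predict_proba and the
        reject option; plain voting predictions work without it).
    random_state : int
        Recorded for provenance; training itself is deterministic.

    Attributes
    ----------
    classes_ : ndarray, label order of probability columns
    machines_ : list of per-pair binary machines (K(K-1)/2 of them)
    feature_names_ : gene ids used (zero-variance genes dropped, warned)
    scale_mean_, scale_sd_ : per-gene standardization parameters
    """

    def __init__(
        self,
        C: float = 1.0,
        lp_factor: float = 2.0,
        diff_factor: float = 0.8,
        probability: bool = True,
        random_state: int = 0,
    ):
        self.C = C
        self.lp_factor = lp_factor
        self.diff_factor = diff_factor
        self.probability = probability
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        Xdf = _as_frame(X)
        y = np.asarray([str(v) for v in y])
        classes = list(dict.fromkeys(y))  # order of first appearance
        if len(classes) < 2:
            raise MarkernetError("at least 2 classes are required to train")
        sd = Xdf.to_numpy().std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = list(Xdf.columns[~keep])
            warnings.warn(
                f"dropping zero-variance genes in training: {dropped[:10]}",
                stacklevel=2,
            )
        if not keep.any():
            raise MarkernetError("all genes have zero training variance")
        Xdf = Xdf.loc[:, Xdf.columns[keep]]
        self.feature_names_ = [str(c) for c in Xdf.columns]
        arr = Xdf.to_numpy(dtype=float)
        self.scale_mean_ = arr.mean(axis=0)
        self.scale_sd_ = arr.std(axis=0, ddof=0)
        Z = (arr - self.scale_mean_) / self.scale_sd_
        self.classes_ = np.array(classes)
        self._train_Z_ = Z
        self._train_y_ = y

        self.machines_ = []
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                a, b = classes[i], classes[j]
                mask = (y == a) | (y == b)
                idx = np.where(mask)[0]
                ypm = np.where(y[idx] == a, 1, -1)
                svc = SVC(kernel="linear", C=self.C)
                svc.fit(Z[idx], ypm)
                if self.probability:
                    dec = svc.decision_function(Z[idx])
                    A, B = fit_platt_sigmoid(dec, ypm == 1)
                else:
                    A, B = float("nan"), float("nan")
                self.machines_.append(
                    _BinaryMachine(a, b, svc, idx, A, B)
                )
        return self

    @property
    def n_machines_(self) -> int:
        check_is_fitted(self, "machines_")
        return len(self.machines_)

    def _standardize(self, X) -> np.ndarray:
        check_is_fitted(self, "machines_")
        Xdf = _as_frame(X)
        missing = [g for g in self.feature_names_ if g not in Xdf.columns]
        if missing:
            raise MarkernetError(
                f"query is missing model genes: {missing[:10]}"
            )
        Z = Xdf.loc[:, self.feature_names_].to_numpy(dtype=float)
        return (Z - self.scale_mean_) / self.scale_sd_

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Coupled pairwise class probabilities (rows sum to 1)."""
        if not self.probability:
            raise MarkernetError("classifier trained without probability=True")
        Z = self._standardize(X)
        K = len(self.classes_)
        cls_index = {c: k for k, c in enumerate(self.classes_)}
        pair_probs = np.empty((Z.shape[0], len(self.machines_)))
        for m, mach in enumerate(self.machines_):
            pair_probs[:, m] = mach.prob_pos(Z)
        out = np.empty((Z.shape[0], K))
        for s in range(Z.shape[0]):
            R = np.full((K, K), 0.5)
            for m, mach in enumerate(self.machines_):
                i, j = cls_index[mach.pos_class], cls_index[mach.neg_class]
                R[i, j] = pair_probs[s, m]
                R[j, i] = 1.0 - pair_probs[s, m]
            if K == 2:
                out[s] = [R[0, 1], R[1, 0]]
            else:
                out[s] = pairwise_coupling(R)
        return out

    def predict_votes(self, X) -> np.ndarray:
        """One-vs-one voting tally, samples x classes."""
        Z = self._standardize(X)
        cls_index = {c: k for k, c in enumerate(self.classes_)}
        votes = np.zeros((Z.shape[0], len(self.classes_)), dtype=int)
        for mach in self.machines_:
            dec = mach.decision(Z)
            votes[dec > 0, cls_index[mach.pos_class]] += 1
            votes[dec <= 0, cls_index[mach.neg_class]] += 1
        return votes

    def predict_most_likely(self, X) -> np.ndarray:
        """Most likely class per query, ignoring the reject option.

        Argmax of the coupled probabilities when calibration is available,
        otherwise the one-vs-one voting winner.
        """
        if self.probability:
            return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
        return self.classes_[np.argmax(self.predict_votes(X), axis=1)]

    def predict(self, X) -> np.ndarray:
        """Class per query, or NOT_ASSIGNED when the decision rule fails."""
        proba = self.predict_proba(X)
        return np.array(
            [
                assign(p, self.lp_factor, self.diff_factor, self.classes_)
                for p in proba
            ],
            dtype=object,
        )

    def query(self, X) -> pd.DataFrame:
        """Full query report: per-class probabilities, top two, assignment."""
        Xdf = _as_frame(X)
        proba = self.predict_proba(Xdf)
        order = np.argsort(-proba, axis=1, kind="stable")
        out = pd.DataFrame(
            proba, columns=[f"prob_{c}" for c in self.classes_],
            index=Xdf.index,
        )
        out.insert(0, "sample", [str(s) for s in Xdf.index])
        out["most_likely"] = self.classes_[order[:, 0]]
        out["second"] = self.classes_[order[:, 1]]
        out["assigned"] = [
            assign(p, self.lp_factor, self.diff_factor, self.classes_)
            for p in proba
        ]
        return out.reset_index(drop=True)

    # ------------------------------------------------------------------
    def discriminant_power(self) -> pd.DataFrame:
        """Per-gene class piles and signed discriminant power.

        For gene g and class c the pile is
        ``sum over machines involving c, sum over support vectors s of that
        machine with label c, of |alpha_s| * z_{s,g}`` with z standardized
        training expression. The gene's class is the most extreme pile
        (tallest bar in either direction); ``|dp|`` is the distance from
        that pile to the closest other pile (for an up-regulated marker,
        largest minus second-largest); the sign follows the gene's
        direction (UP/DOWN) in the winning class.
        """
        check_is_fitted(self, "machines_")
        K = len(self.classes_)
        cls_index = {c: k for k, c in enumerate(self.classes_)}
        piles = np.zeros((len(self.feature_names_), K))
        for mach in self.machines_:
            sv_rows = mach.sample_idx[mach.svc.support_]
            alphas = np.abs(mach.svc.dual_coef_[0])
            sv_labels = self._train_y_[sv_rows]
            for c in (mach.pos_class, mach.neg_class):
                mask = sv_labels == c
                if mask.any():
                    piles[:, cls_index[c]] += (
                        alphas[mask][:, None] * self._train_Z_[sv_rows[mask]]
                    ).sum(axis=0)
        rows = []
        for gi, gene in enumerate(self.feature_names_):
            p = piles[gi]
            # dominant pile = most extreme bar (a repressed marker's own
            # class pile is strongly negative); dp = distance to the
            # closest other pile, which for an up-regulated marker is just
            # largest minus second largest
            ext = int(np.argmax(np.abs(p)))
            gap = float(np.min(np.abs(p[ext] - np.delete(p, ext))))
            win = self.classes_[ext]
            in_cls = self._train_y_ == win
            up = (
                self._train_Z_[in_cls, gi].mean()
                > self._train_Z_[~in_cls, gi].mean()
            )
            row = {"gene": gene, "dp": gap if up else -gap, "dp_class": win}
            for ci, c in enumerate(self.classes_):
                row[f"pile_{c}"] = p[ci]
            rows.append(row)
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def to_bundle(self) -> dict:
        """JSON-serializable model bundle.

        Stores the training submatrix and parameters; loading refits the
        (deterministic) machines and reproduces the model exactly.
        """
        check_is_fitted(self, "machines_")
        return {
            "format": "markernet-model",
            "version": 1,
            "params": {
                "C": self.C,
                "lp_factor": self.lp_factor,
                "diff_factor": self.diff_factor,
                "probability": self.probability,
                "random_state": self.random_state,
            },
            "feature_names": self.feature_names_,
            "scale_mean": self.scale_mean_.tolist(),
            "scale_sd": self.scale_sd_.tolist(),
            "train_X": (
                self._train_Z_ * self.scale_sd_ + self.scale_mean_
            ).tolist(),
            "train_y": [str(v) for v in self._train_y_],
        }

    @classmethod
    def from_bundle(cls, bundle: dict) -> "PairwiseSVMClassifier":
        if bundle.get("format") != "markernet-model":
            raise MarkernetError("not a markernet model bundle")
        clf = cls(**bundle["params"])
        X = pd.DataFrame(
            np.asarray(bundle["train_X"], dtype=float),
            columns=bundle["feature_names"],
        )
        clf.fit(X, np.array(bundle["train_y"]))
        return clf


def train(
    X,
    y,
    C: float = 1.0,
    config: RunConfig | None = None,
    probability: bool = True,
) -> PairwiseSVMClassifier:
    """Train a one-vs-one linear SVM on a samples x genes matrix."""
    cfg = config or RunConfig()
    clf = PairwiseSVMClassifier(
        C=C if config is None else cfg.svm_c,
        lp_factor=cfg.lp_factor,
        diff_factor=cfg.diff_factor,
        probability=probability,
        random_state=cfg.seed,
    )
    return clf.fit(X, y)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        out = X.copy()
        out.columns = out.columns.astype(str)
        return out
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"g{j:05d}" for j in range(X.shape[1])])
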