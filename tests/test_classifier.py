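"""One-vs-one SVM, probability coupling, reject option, discriminant power."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import markernet as mn
from markernet.classifier import fit_platt_sigmoid, pairwise_coupling


class TestAssignmentRule:
    """The 2x / 0.8x random-probability decision rule, exhaustively."""

    @pytest.mark.parametrize(
        "probs,expected",
        [
            # K=5, r=0.2: thresholds are 0.40 (level) and 0.16 (gap)
            ((0.50, 0.30, 0.10, 0.06, 0.04), 0),  # both conditions met
            ((0.35, 0.30, 0.15, 0.12, 0.08), "NA"),  # 0.35 < 0.40
            ((0.45, 0.35, 0.10, 0.06, 0.04), "NA"),  # gap 0.10 < 0.16
            ((0.40, 0.20, 0.20, 0.10, 0.10), 0),  # boundary: 0.40 >= 0.40, gap 0.20 > 0.16
            ((0.40, 0.24, 0.16, 0.12, 0.08), "NA"),  # gap exactly 0.16, not strict
            ((0.2, 0.2, 0.2, 0.2, 0.2), "NA"),  # uniform
            # K=2, r=0.5: need p >= 1.0 and gap > 0.4 -> only a certain call
            ((1.0, 0.0), 0),
            ((0.9, 0.1), "NA"),
            ((0.5, 0.5), "NA"),
            # K=4, r=0.25: need 0.5 and gap 0.2
            ((0.55, 0.30, 0.10, 0.05), 0),
            ((0.55, 0.40, 0.04, 0.01), "NA"),
        ],
    )
    def test_rule(self, probs, expected):
        got = mn.assign(np.array(probs))
        want = mn.NOT_ASSIGNED if expected == "NA" else expected
        assert got == want

    def test_uniform_not_assigned_for_any_k(self):
        for k in range(2, 9):
            assert mn.assign(np.full(k, 1.0 / k)) == mn.NOT_ASSIGNED

    def test_class_labels_passed_through(self):
        got = mn.assign(np.array([0.7, 0.2, 0.1]), classes=np.array(list("XYZ")))
        assert got == "X"

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError):
            mn.assign(np.array([1.0]))


def _cloud(rng, center, n, sd=0.3):
    return center + rng.normal(scale=sd, size=(n, len(center)))


def _three_class_data(n=20, sd=0.3, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            _cloud(rng, [4.0, 0.0], n, sd),
            _cloud(rng, [0.0, 4.0], n, sd),
            _cloud(rng, [-4.0, -4.0], n, sd),
        ]
    )
    y = np.array(["A"] * n + ["B"] * n + ["C"] * n)
    return pd.DataFrame(X, columns=["g1", "g2"]), y


class TestTraining:
    def test_machine_count_is_k_choose_2(self, separable_pipeline):
        clf = separable_pipeline.classifier_
        k = len(clf.classes_)
        assert clf.n_machines_ == k * (k - 1) // 2
        for mach in clf.machines_:
            assert np.isfinite(mach.sigmoid_a)
            assert np.isfinite(mach.sigmoid_b)

    def test_separable_toy_training_accuracy(self):
        X, y = _three_class_data()
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        assert (clf.predict_most_likely(X) == y).all()

    def test_zero_variance_gene_dropped_with_warning(self):
        X, y = _three_class_data()
        X["gFlat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            clf = mn.PairwiseSVMClassifier().fit(X, y)
        assert "gFlat" not in clf.feature_names_

    def test_single_class_rejected(self):
        X, _ = _three_class_data()
        with pytest.raises(mn.MarkernetError, match="2 classes"):
            mn.PairwiseSVMClassifier().fit(X, ["A"] * len(X))

    def test_dual_coefficients_match_qp_oracle(self):
        """Signed duals of one machine agree with a direct QP solve."""
        X = np.array(
            [[0.0, 1.0], [0.4, 0.8], [0.2, 1.3],
             [2.0, -1.0], [2.3, -0.7], [1.8, -1.2]]
        )
        y = np.array(["P", "P", "P", "N", "N", "N"])
        clf = mn.PairwiseSVMClassifier(C=1.0, probability=False).fit(
            pd.DataFrame(X, columns=["g1", "g2"]), y
        )
        mach = clf.machines_[0]
        Z = clf._train_Z_
        ypm = np.where(y == mach.pos_class, 1.0, -1.0)
        K = (Z @ Z.T) * np.outer(ypm, ypm)

        def neg_dual(a):
            return 0.5 * a @ K @ a - a.sum()

        res = minimize(
            neg_dual,
            np.full(6, 0.5),
            bounds=[(0.0, 1.0)] * 6,
            constraints={"type": "eq", "fun": lambda a: a @ ypm},
            method="SLSQP",
        )
        alpha = res.x
        # the dual split among same-class support vectors may be degenerate;
        # compare the identifiable quantities: primal weights and dual mass
        signed = np.zeros(6)
        signed[mach.sample_idx[mach.svc.support_]] = mach.svc.dual_coef_[0]
        w_oracle = (alpha * ypm) @ Z
        w_got = signed @ Z
        np.testing.assert_allclose(w_got, w_oracle, atol=2e-3)
        np.testing.assert_allclose(
            np.abs(signed).sum(), alpha.sum(), atol=2e-3
        )
        # positive duals belong to the machine's first class
        sv_labels = y[mach.sample_idx[mach.svc.support_]]
        signs = np.sign(mach.svc.dual_coef_[0])
        assert all(
            (s > 0) == (lbl == mach.pos_class)
            for s, lbl in zip(signs, sv_labels)
        )


class TestProbabilities:
    def test_rows_sum_to_one(self):
        X, y = _three_class_data()
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        rng = np.random.default_rng(1)
        Q = pd.DataFrame(
            rng.normal(scale=3.0, size=(100, 2)), columns=["g1", "g2"]
        )
        P = clf.predict_proba(Q)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert (P >= 0).all()

    def test_two_classes_reduce_to_single_sigmoid(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            np.r_[_cloud(rng, [2.0, 0.0], 15), _cloud(rng, [-2.0, 0.0], 15)],
            columns=["g1", "g2"],
        )
        y = np.array(["A"] * 15 + ["B"] * 15)
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        mach = clf.machines_[0]
        P = clf.predict_proba(X)
        Z = clf._standardize(X)
        np.testing.assert_allclose(P[:, 0], mach.prob_pos(Z), atol=1e-12)

    def test_deep_training_sample_confident(self):
        """A sample far inside its class region gets probability > 0.9."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            np.r_[_cloud(rng, [5.0, 0.0], 25, 0.2),
                  _cloud(rng, [-5.0, 0.0], 25, 0.2)],
            columns=["g1", "g2"],
        )
        y = np.array(["A"] * 25 + ["B"] * 25)
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        deep = pd.DataFrame([[6.0, 0.0]], columns=["g1", "g2"])
        assert clf.predict_proba(deep)[0, 0] > 0.9

    def test_missing_gene_in_query_rejected(self):
        X, y = _three_class_data()
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        with pytest.raises(mn.MarkernetError, match="missing model genes"):
            clf.predict_proba(pd.DataFrame({"g1": [0.0]}))

    def test_most_likely_equals_argmax_of_probabilities(self):
        X, y = _three_class_data()
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        rng = np.random.default_rng(4)
        Q = pd.DataFrame(
            rng.normal(scale=3.0, size=(50, 2)), columns=["g1", "g2"]
        )
        P = clf.predict_proba(Q)
        np.testing.assert_array_equal(
            clf.predict_most_likely(Q), clf.classes_[np.argmax(P, axis=1)]
        )

    def test_query_report_schema(self):
        X, y = _three_class_data()
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        out = clf.query(X.head(4))
        assert list(out.columns) == [
            "sample", "prob_A", "prob_B", "prob_C",
            "most_likely", "second", "assigned",
        ]
        assert set(out["assigned"]) <= set(clf.classes_) | {mn.NOT_ASSIGNED}


class TestPlattAndCoupling:
    def test_sigmoid_recovers_generating_curve(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=4000) * 2
        p_true = 1.0 / (1.0 + np.exp(-2.0 * f))  # A=-2, B=0 in fitted form
        pos = rng.uniform(size=4000) < p_true
        A, B = fit_platt_sigmoid(f, pos)
        assert A == pytest.approx(-2.0, abs=0.2)
        assert B == pytest.approx(0.0, abs=0.1)

    def test_coupling_uniform_fixed_point(self):
        K = 4
        R = np.full((K, K), 0.5)
        np.testing.assert_allclose(
            pairwise_coupling(R), np.full(K, 0.25), atol=1e-8
        )

    def test_coupling_consistent_pairwise_input(self):
        """Exactly coupled input (from a known p) is recovered."""
        p = np.array([0.5, 0.3, 0.15, 0.05])
        K = 4
        R = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                if i != j:
                    R[i, j] = p[i] / (p[i] + p[j])
        np.testing.assert_allclose(pairwise_coupling(R), p, atol=1e-6)


class TestDiscriminantPower:
    def test_informative_gene_has_largest_dp(self):
        rng = np.random.default_rng(6)
        n = 15
        informative = np.r_[rng.normal(3, 0.3, n), rng.normal(-3, 0.3, n)]
        X = pd.DataFrame(
            np.column_stack(
                [informative] + [rng.normal(size=2 * n) for _ in range(5)]
            ),
            columns=["gInfo"] + [f"gNoise{i}" for i in range(5)],
        )
        y = np.array(["A"] * n + ["B"] * n)
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        dp = clf.discriminant_power().set_index("gene")
        best = dp["dp"].abs().idxmax()
        assert best == "gInfo"
        assert dp.loc["gInfo", "dp"].item() != pytest.approx(0.0)

    def test_repressed_gene_has_negative_dp(self):
        rng = np.random.default_rng(7)
        n = 15
        # gene strongly DOWN in class A
        down = np.r_[rng.normal(-3, 0.3, n), rng.normal(3, 0.3, n)]
        X = pd.DataFrame(
            np.column_stack([down, rng.normal(size=2 * n)]),
            columns=["gDown", "gNoise"],
        )
        y = np.array(["A"] * n + ["B"] * n)
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        dp = clf.discriminant_power().set_index("gene")
        row = dp.loc["gDown"]
        if row["dp_class"] == "A":
            assert row["dp"] < 0
        else:
            assert row["dp"] > 0

    def test_k_piles_per_gene_and_permutation_invariance(
        self, separable_pipeline, separable
    ):
        clf = separable_pipeline.classifier_
        dp = clf.discriminant_power()
        pile_cols = [c for c in dp.columns if c.startswith("pile_")]
        assert len(pile_cols) == len(clf.classes_)

        dataset, _ = separable
        X, y = dataset.to_xy()
        X = X[clf.feature_names_]
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(y))
        clf2 = mn.PairwiseSVMClassifier().fit(X.iloc[perm], y[perm])
        dp2 = clf2.discriminant_power()
        a = dp.sort_values("gene").reset_index(drop=True)
        b = dp2.sort_values("gene").reset_index(drop=True)
        # exact per-sample duals are degenerate under reordering; the piles
        # are stable only up to the QP solver's split among tied vectors
        np.testing.assert_allclose(
            a[["dp"] + pile_cols].to_numpy(),
            b[["dp"] + pile_cols].to_numpy(),
            atol=0.05,
        )
        assert list(a["dp_class"]) == list(b["dp_class"])

    def test_dp_class_matches_ranking_class_mostly(
        self, separable_pipeline
    ):
        """Selected genes' winning pile should be their ranking class."""
        dp = separable_pipeline.discriminant_power_
        sel = separable_pipeline.selection_.selected_genes
        hits = total = 0
        for cls, genes in sel.items():
            for g in genes:
                total += 1
                hits += int(
                    dp.set_index("gene").loc[g, "dp_class"] == cls
                )
        assert hits / total >= 0.9


class TestSerialization:
    def test_bundle_round_trip_reproduces_probabilities(self):
        X, y = _three_class_data()
        clf = mn.PairwiseSVMClassifier().fit(X, y)
        clone = mn.PairwiseSVMClassifier.from_bundle(clf.to_bundle())
        rng = np.random.default_rng(9)
        Q = pd.DataFrame(
            rng.normal(scale=3, size=(20, 2)), columns=["g1", "g2"]
        )
        np.testing.assert_allclose(
            clf.predict_proba(Q), clone.predict_proba(Q), atol=1e-12
        )

    def test_bad_bundle_rejected(self):
        with pytest.raises(mn.MarkernetError, match="bundle"):
            mn.PairwiseSVMClassifier.from_bundle({"format": "nope"})
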