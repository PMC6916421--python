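import numpy as np
import pandas as pd
import pytest

import acmkit as ak
from acmkit.ml import ConfusionMatrix, TreeNode, predict


def fv(l5h=240.0, m10h=970.0, ra=0.7, cfi=0.9, subject="s"):
    return ak.FeatureVector(subject, l5h, m10h, ra, cfi)


class TestMDLDiscretize:
    def test_clean_two_class_split_at_midpoint(self):
        values = np.arange(1.0, 7.0)
        labels = np.array(list("AAABBB"))
        assert ak.mdl_discretize(values, labels) == [3.5]

    def test_single_class_yields_no_cuts(self):
        assert ak.mdl_discretize(np.arange(4.0), np.array(list("AAAA"))) == []

    def test_interleaved_classes_fail_mdl_criterion(self):
        values = np.arange(1.0, 5.0)
        labels = np.array(list("ABAB"))
        assert ak.mdl_discretize(values, labels) == []

    def test_three_class_staircase_finds_both_cuts(self):
        values = np.repeat([1.0, 2.0, 3.0], 10)
        labels = np.repeat(["A", "B", "C"], 10)
        assert ak.mdl_discretize(values, labels) == [1.5, 2.5]


class TestScoreAttributes:
    @pytest.fixture
    def perfect_table(self):
        # two balanced classes; tap_l5h separates them perfectly, tap_ra is constant
        return pd.DataFrame(
            {
                "tap_l5h": np.repeat([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [3, 3, 4, 4, 3, 3]),
                "tap_m10h": np.r_[np.full(10, 1.0), np.full(10, 2.0)],
                "tap_ra": np.full(20, 0.5),
                "sleep_cfi": np.r_[np.arange(10) * 0.01, 0.5 + np.arange(10) * 0.01],
                "label": np.repeat(["ctl", "pat"], 10),
            }
        )

    def test_perfect_binary_predictor_scores_one_bit_and_chi2(self, perfect_table):
        scores = ak.score_attributes(perfect_table, ("tap_m10h",))
        assert scores.loc["tap_m10h", "information_gain"] == pytest.approx(1.0)
        # contingency [[10, 0], [0, 10]] under independence expects 5 per cell
        assert scores.loc["tap_m10h", "chi_squared"] == pytest.approx(20.0)

    def test_constant_attribute_scores_zero(self, perfect_table):
        scores = ak.score_attributes(perfect_table, ("tap_ra",))
        assert scores.loc["tap_ra", "information_gain"] == 0.0
        assert scores.loc["tap_ra", "chi_squared"] == 0.0

    def test_anova_f_matches_hand_computation(self):
        table = pd.DataFrame(
            {
                "tap_l5h": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "tap_m10h": 0.0,
                "tap_ra": 0.0,
                "sleep_cfi": 0.0,
                "label": ["a", "a", "a", "b", "b", "b"],
            }
        )
        scores = ak.score_attributes(table, ("tap_l5h",))
        assert scores.loc["tap_l5h", "anova_F"] == pytest.approx(13.5)

    def test_single_class_rejected(self, perfect_table):
        table = perfect_table.assign(label="same")
        with pytest.raises(ValueError):
            ak.score_attributes(table)


class TestFixedTree:
    @pytest.mark.parametrize(
        "vector, expected",
        [
            (fv(l5h=408, m10h=1087), "dspd"),
            (fv(l5h=360, m10h=900), "onset_insomnia"),
            (fv(l5h=234, ra=0.66, cfi=0.88), "control"),
            (fv(l5h=244, ra=0.53), "maintenance_insomnia"),
            (fv(l5h=240, ra=0.70, cfi=0.80), "mild_insomnia"),
        ],
    )
    def test_class_mean_vectors_route_to_own_class(self, vector, expected):
        assert ak.classify_fixed_tree(vector) == expected

    @pytest.mark.parametrize(
        "vector, expected",
        [
            (fv(l5h=327.0, ra=0.9, cfi=0.9), "control"),  # exactly at 5:27: not later
            (fv(l5h=328.0, m10h=967.0), "onset_insomnia"),  # exactly at 16:07: not later
            (fv(l5h=240.0, ra=0.629, cfi=0.8), "mild_insomnia"),  # RA cut is strict
            (fv(l5h=240.0, ra=0.7, cfi=0.852), "control"),  # CFI cut is inclusive
        ],
    )
    def test_boundary_semantics_at_printed_cuts(self, vector, expected):
        assert ak.classify_fixed_tree(vector) == expected

    def test_total_and_pure_on_random_vectors(self):
        rng = np.random.default_rng(0)
        vectors = [
            fv(rng.uniform(0, 1440), rng.uniform(0, 1440), rng.uniform(0, 1),
               rng.uniform(0, 1), subject=str(i))
            for i in range(200)
        ]
        first = [ak.classify_fixed_tree(v) for v in vectors]
        assert set(first) <= set(ak.CLASSES)
        second = [ak.classify_fixed_tree(v) for v in reversed(vectors)]
        assert first == second[::-1]

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError):
            fv(l5h=float("nan"))
        with pytest.raises(ValueError):
            fv(m10h=1500.0)


class TestBuildFeatureTable:
    def test_rows_and_required_fields(self, control_epoched):
        summaries = {
            "s1": {
                "tap": ak.summarize_variable(control_epoched, "tap", "tap"),
                "sleep": ak.summarize_variable(control_epoched, "sleep", "sleep"),
            }
        }
        table = ak.build_feature_table(summaries, {"s1": "control"})
        assert list(table.columns) == [
            "subject_id", "tap_l5h", "tap_m10h", "tap_ra", "sleep_cfi", "label",
        ]
        assert len(table) == 1

    def test_missing_summary_names_subject(self, control_epoched):
        summaries = {"s9": {"tap": ak.summarize_variable(control_epoched, "tap", "tap")}}
        with pytest.raises(ValueError, match="s9.*sleep"):
            ak.build_feature_table(summaries)


class TestInduceTree:
    def test_single_class_gives_single_leaf(self):
        table = pd.DataFrame(
            {"tap_l5h": [1.0, 2.0], "tap_m10h": [1.0, 2.0], "tap_ra": [0.1, 0.2],
             "sleep_cfi": [0.5, 0.6], "label": ["dspd", "dspd"]}
        )
        tree = ak.induce_tree(table)
        assert tree.label == "dspd"

    def test_gap_separated_classes_yield_depth_one_tree_at_gap_midpoint(self):
        rng = np.random.default_rng(4)
        l5h = np.r_[rng.uniform(100, 190, 10), rng.uniform(400, 490, 10)]
        l5h[np.argmax(l5h[:10])] = 190.0
        l5h[10 + np.argmin(l5h[10:])] = 400.0
        table = pd.DataFrame(
            {"tap_l5h": l5h, "tap_m10h": 900.0, "tap_ra": 0.7, "sleep_cfi": 0.9,
             "label": np.repeat(["control", "dspd"], 10)}
        )
        tree = ak.induce_tree(table)
        assert tree.attribute == "tap_l5h"
        assert tree.cut == pytest.approx(295.0)
        assert tree.left.label == "control" and tree.right.label == "dspd"

    def test_predict_routes_rows(self):
        tree = TreeNode(
            attribute="tap_ra", cut=0.5,
            left=TreeNode(label="maintenance_insomnia"),
            right=TreeNode(label="control"),
        )
        table = pd.DataFrame({"tap_ra": [0.4, 0.6]})
        assert list(predict(tree, table)) == ["maintenance_insomnia", "control"]


class TestMetrics:
    def test_printed_formulas(self):
        m = ak.compute_metrics(ConfusionMatrix(tp=45, fp=10, tn=90, fn=5))
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["false_positive_rate"] == pytest.approx(0.1)

    def test_f1_is_harmonic_mean(self):
        m = ak.compute_metrics(ConfusionMatrix(tp=5, fp=0, tn=10, fn=5))
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["precision"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(2 / 3, abs=1e-3)

    def test_zero_denominator_flags_nan(self):
        m = ak.compute_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert np.isnan(m["precision"])

    def test_complement_identities_on_random_counts(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            m = ak.compute_metrics(ConfusionMatrix(tp, fp, tn, fn))
            assert m["sensitivity"] + fn / (tp + fn) == pytest.approx(1.0)
            assert m["false_positive_rate"] + m["specificity"] == pytest.approx(1.0)


class TestRocAuc:
    def test_separation_ties_and_crossing(self):
        assert ak.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert ak.roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5
        assert ak.roc_auc([0.9, 0.6, 0.8, 0.7], [1, 1, 0, 0]) == 0.5

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            ak.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
            assert ak.roc_auc(scores, labels) == pytest.approx(np.mean(pairs))


@pytest.fixture(scope="module")
def labelled_table():
    rng = np.random.default_rng(8)
    n = 261
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "tap_l5h": rng.uniform(150, 550, n),
            "tap_m10h": rng.uniform(850, 1150, n),
            "tap_ra": rng.uniform(0.4, 0.9, n),
            "sleep_cfi": rng.uniform(0.7, 1.0, n),
        }
    )
    table["label"] = [
        ak.classify_fixed_tree(fv(r.tap_l5h, r.tap_m10h, r.tap_ra, r.sleep_cfi))
        for r in table.itertuples()
    ]
    return table


class TestCrossValidate:
    def test_folds_disjoint_and_covering(self, labelled_table):
        report = ak.cross_validate(labelled_table, k=10, seed=0)
        sizes = report.predictions["fold"].value_counts()
        assert sorted(sizes) == [26] * 9 + [27]
        assert report.predictions["fold"].notna().all()

    def test_deterministic_given_seed(self, labelled_table):
        a = ak.cross_validate(labelled_table, k=10, seed=3)
        b = ak.cross_validate(labelled_table, k=10, seed=3)
        pd.testing.assert_frame_equal(a.per_class, b.per_class)

    def test_fixed_tree_has_no_generalization_error_on_separable_table(self, labelled_table):
        report = ak.cross_validate(labelled_table, k=10, seed=0, model="fixed")
        assert report.overall_accuracy == 1.0
        assert (report.per_class["sensitivity"] == 1.0).all()
        assert (report.per_class["auc"] == 1.0).all()

    def test_bad_k_rejected(self, labelled_table):
        with pytest.raises(ValueError):
            ak.cross_validate(labelled_table, k=1)
        with pytest.raises(ValueError):
            ak.cross_validate(labelled_table, k=1000)
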