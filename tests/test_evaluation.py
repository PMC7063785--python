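"""Confusion metrics, resampling protocols, φ and distribution tables."""

import math

import numpy as np
import pytest
from scipy import stats

from varchain import (
    ConfusionCounts,
    Label,
    confusion,
    kfold_cv,
    level_report,
    metrics,
    monte_carlo,
    pairwise_distribution,
    phi_coefficient,
    proposed_topology,
)
from varchain.evaluation import confusion_from_bool, evaluate_topology
from varchain.features import FeatureVector
from varchain.tree import ChainTopology

FOUR = ("SPP", "ExAC", "NDamage", "COMMON")


def random_fvs(n, seed, p=None):
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.5
    if p is None:
        p = (0.8, 0.75, 0.7, 0.65)
    m = (rng.random((n, 4)) < np.where(y[:, None], p, [1 - q for q in p]))
    fvs = [FeatureVector(dict(zip(FOUR, row.astype(int)))) for row in m]
    labels = [Label.PATHOGENIC if b else Label.NEUTRAL for b in y]
    return fvs, labels


class TestConfusion:
    def test_two_variant_cases(self):
        cc = confusion(["neutral", "pathogenic"], ["neutral", "pathogenic"])
        assert (cc.true_neutral, cc.false_neutral, cc.false_pathogenic,
                cc.true_pathogenic) == (1, 0, 0, 1)
        cc = confusion(["pathogenic", "neutral"], ["neutral", "pathogenic"])
        assert (cc.true_neutral, cc.false_neutral, cc.false_pathogenic,
                cc.true_pathogenic) == (0, 1, 1, 0)

    def test_random_input_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        pred = rng.random(200) < 0.5
        truth = rng.random(200) < 0.5
        cc = confusion_from_bool(pred, truth)
        tally = {"tn": 0, "fn": 0, "fp": 0, "tp": 0}
        for p, t in zip(pred, truth):
            tally["tp" if p and t else "fp" if p else "fn" if t else "tn"] += 1
        assert (cc.true_neutral, cc.false_neutral, cc.false_pathogenic,
                cc.true_pathogenic) == (tally["tn"], tally["fn"],
                                        tally["fp"], tally["tp"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["neutral"], ["neutral", "neutral"])


class TestMetrics:
    def test_symmetric_case(self):
        rep = metrics(ConfusionCounts(90, 10, 10, 90))
        assert rep.accuracy == pytest.approx(0.90)

    def test_conditional_rates(self):
        rep = metrics(ConfusionCounts(91, 8, 9, 92))
        assert rep.rate_N_given_0 == pytest.approx(91 / 100)
        assert rep.rate_P_given_1 == pytest.approx(92 / 100)
        assert rep.rate_N_given_0 + rep.rate_P_given_0 == pytest.approx(1.0)
        assert rep.rate_N_given_1 + rep.rate_P_given_1 == pytest.approx(1.0)

    def test_one_class_input_yields_nan_not_zero(self):
        rep = metrics(ConfusionCounts(0, 0, 0, 10))
        assert rep.accuracy == 1.0
        assert math.isnan(rep.rate_N_given_0)
        assert math.isnan(rep.rate_P_given_0)

    def test_literal_formula_fields(self):
        rep = metrics(ConfusionCounts(80, 20, 10, 90))
        assert rep.paper_formula_sensitivity == pytest.approx(80 / 100)
        assert rep.paper_formula_type1 == pytest.approx(20 / 100)
        assert rep.paper_formula_specificity == pytest.approx(90 / 100)
        assert rep.paper_formula_type2 == pytest.approx(10 / 100)

    def test_accuracy_identity_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tn, fn, fp, tp = rng.integers(0, 50, 4)
            if tn + fn + fp + tp == 0:
                continue
            rep = metrics(ConfusionCounts(int(tn), int(fn), int(fp), int(tp)))
            assert rep.accuracy == pytest.approx(
                (tn + tp) / (tn + fn + fp + tp))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestKfold:
    def test_folds_partition_each_class(self):
        fvs, labels = random_fvs(100 + 100, seed=2)
        s = kfold_cv(fvs, labels, k=10, classifier=proposed_topology(),
                     seed=0)
        assert s.replicates == 10

    def test_fold_sizes_within_one(self):
        rng = np.random.default_rng(3)
        idx = rng.permutation(103)
        folds = np.array_split(idx, 10)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == sorted(idx)

    def test_equal_folds_mean_equals_whole_set_accuracy(self):
        # 100+100 variants -> 10 folds of exactly 10+10; the weighted-mean
        # identity makes the CV mean accuracy equal the full-set accuracy
        rng = np.random.default_rng(4)
        y = np.repeat([False, True], 100)
        p = (0.8, 0.75, 0.7, 0.65)
        m = rng.random((200, 4)) < np.where(y[:, None], p, [1 - q for q in p])
        fvs = [FeatureVector(dict(zip(FOUR, row.astype(int)))) for row in m]
        labels = [Label.PATHOGENIC if b else Label.NEUTRAL for b in y]
        topo = proposed_topology()
        s = kfold_cv(fvs, labels, k=10, classifier=topo, seed=1)
        full = evaluate_topology(fvs, labels, topo)
        assert s.mean["accuracy"] == pytest.approx(full.accuracy)

    def test_seed_determinism(self):
        fvs, labels = random_fvs(240, seed=5)
        a = kfold_cv(fvs, labels, classifier=proposed_topology(), seed=9)
        b = kfold_cv(fvs, labels, classifier=proposed_topology(), seed=9)
        assert a.mean == b.mean and a.std == b.std

    def test_class_smaller_than_k_rejected(self):
        fvs, labels = random_fvs(12, seed=6)
        with pytest.raises(ValueError, match="class"):
            kfold_cv(fvs, labels, k=10, classifier=proposed_topology())

    def test_builder_classifier_refits_per_fold(self):
        from varchain import build_greedy

        fvs, labels = random_fvs(400, seed=7)

        def builder(train_fvs, train_labels):
            topo, _ = build_greedy(train_fvs, train_labels, list(FOUR),
                                   ["SPP", "NDamage"], 4)
            return topo

        s = kfold_cv(fvs, labels, k=5, classifier=builder, seed=0)
        assert 0.5 < s.mean["accuracy"] <= 1.0


class TestMonteCarlo:
    def test_fraction_one_degenerate(self):
        fvs, labels = random_fvs(300, seed=8)
        topo = proposed_topology()
        s = monte_carlo(fvs, labels, topo, fraction=1.0, replicates=20,
                        seed=0)
        full = evaluate_topology(fvs, labels, topo)
        assert s.std["accuracy"] == 0.0
        assert s.mean["accuracy"] == pytest.approx(full.accuracy)

    def test_mean_within_three_stderr_of_point_estimate(self):
        fvs, labels = random_fvs(2000, seed=9)
        topo = proposed_topology()
        s = monte_carlo(fvs, labels, topo, fraction=0.3, replicates=1000,
                        seed=1)
        full = evaluate_topology(fvs, labels, topo)
        stderr = s.std["accuracy"] / math.sqrt(s.replicates)
        assert abs(s.mean["accuracy"] - full.accuracy) <= 3 * max(stderr, 1e-9)

    def test_seed_determinism_and_bootstrap_mode(self):
        fvs, labels = random_fvs(300, seed=10)
        topo = proposed_topology()
        a = monte_carlo(fvs, labels, topo, replicates=50, seed=3)
        b = monte_carlo(fvs, labels, topo, replicates=50, seed=3)
        assert a.mean == b.mean
        boot = monte_carlo(fvs, labels, topo, fraction=1.0, replicates=50,
                           seed=3, bootstrap=True)
        assert boot.std["accuracy"] > 0.0  # resampling with replacement varies

    def test_invalid_fraction_rejected(self):
        fvs, labels = random_fvs(10, seed=11)
        with pytest.raises(ValueError):
            monte_carlo(fvs, labels, proposed_topology(), fraction=0.0)


class TestPhi:
    def test_perfect_association_and_independence(self):
        assert phi_coefficient([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)
        x = [1] * 10 + [0] * 10
        y = ([1] * 5 + [0] * 5) * 2
        assert phi_coefficient(x, y) == pytest.approx(0.0)

    def test_equals_pearson_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(10, 100))
            x = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            y = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            if len(set(x)) < 2 or len(set(y)) < 2:
                assert math.isnan(phi_coefficient(x, y))
                continue
            r = stats.pearsonr(x, y).statistic
            assert phi_coefficient(x, y) == pytest.approx(r, abs=1e-12)

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        x = (rng.random(60) < 0.5).astype(int)
        y = (rng.random(60) < 0.5).astype(int)
        assert phi_coefficient(x, y) == pytest.approx(phi_coefficient(y, x))
        assert phi_coefficient(1 - x, 1 - y) == pytest.approx(
            phi_coefficient(x, y))

    def test_degenerate_margin_is_nan(self):
        assert math.isnan(phi_coefficient([1, 1, 1], [0, 1, 0]))


class TestPairwise:
    def test_all_zero_concentrates_in_one_cell(self):
        fvs = [FeatureVector({"A": 0, "B": 0}) for _ in range(5)]
        labels = [Label.NEUTRAL] * 5
        tables = pairwise_distribution(fvs, labels, ("A", "B"))
        assert tables["neutral"][(0, 0)] == pytest.approx(100.0)
        assert all(math.isnan(v) for v in tables["pathogenic"].values())

    def test_cells_sum_to_100_and_match_tally(self):
        fvs, labels = random_fvs(500, seed=14)
        tables = pairwise_distribution(fvs, labels, ("SPP", "ExAC"))
        for cls, mask_val in (("neutral", False), ("pathogenic", True)):
            cells = tables[cls]
            assert sum(cells.values()) == pytest.approx(100.0)
            klass = [fv for fv, lab in zip(fvs, labels)
                     if (lab is Label.PATHOGENIC) == mask_val]
            for (a, b), pct in cells.items():
                cnt = sum(1 for fv in klass
                          if fv.values["SPP"] == a and fv.values["ExAC"] == b)
                assert pct == pytest.approx(100.0 * cnt / len(klass))


class TestLevelReport:
    def test_single_level_equals_single_feature_metrics(self):
        fvs, labels = random_fvs(400, seed=15)
        topo = ChainTopology(("SPP",))
        rep = level_report(fvs, labels, topo)
        direct = evaluate_topology(fvs, labels, topo)
        assert rep.rows[0].accuracy_pct == pytest.approx(
            100 * direct.accuracy)
        assert rep.rows[0].fpr_pct == pytest.approx(
            100 * direct.rate_P_given_0)
        assert rep.rows[0].fnr_pct == pytest.approx(
            100 * direct.rate_N_given_1)

    def test_false_pathogenic_rate_nonincreasing(self):
        for seed in range(5):
            fvs, labels = random_fvs(300, seed=100 + seed)
            rep = level_report(fvs, labels, proposed_topology())
            fprs = [r.fpr_pct for r in rep.rows]
            assert all(a >= b - 1e-9 for a, b in zip(fprs, fprs[1:]))

    def test_inert_constant_level_leaves_row_unchanged(self):
        fvs, labels = random_fvs(200, seed=16)
        for fv in fvs:
            fv.values["ONE"] = 1
        rep = level_report(fvs, labels, ChainTopology(("SPP", "ONE")))
        assert rep.rows[0].accuracy_pct == rep.rows[1].accuracy_pct
        assert rep.rows[0].fpr_pct == rep.rows[1].fpr_pct
        assert rep.rows[0].fnr_pct == rep.rows[1].fnr_pct
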